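"""Simulation-based calibration of the differential-expression machinery.

Two standard study designs, both mirroring the profiling experiments the
pipeline targets (two replicates per condition within a genotype, plus a
pooled set of reference control samples that enters dispersion estimation
only):

* a null study -- no condition effect -- measuring the raw p < threshold rate
  (type-I error) of the NB exact test;
* a planted study -- a handful of arms at a known fold change on a high
  baseline -- measuring how many planted arms are recovered at padj below the
  significance threshold, and how many null arms are falsely called.

Gene baseline means are drawn log-uniformly over a typical miRNA count range
at desk-scale depth (50-1000 per sample) unless planted higher.
"""

from __future__ import annotations

import numpy as np

from .diffexpr import (
    ContrastDesign,
    bh_adjust,
    estimate_dispersions,
    nb_exact_test,
    size_factors,
)
from .simulate import nb_null_matrix

__all__ = ["contrast_pvalues", "null_rates", "planted_recovery"]

MEAN_RANGE = (50.0, 1000.0)


def _design(n_a: int, n_b: int, n_ref: int):
    cols = [f"S{j + 1}" for j in range(n_a + n_b + n_ref)]
    return (
        cols,
        ContrastDesign(
            condition_a=tuple(cols[:n_a]),
            condition_b=tuple(cols[n_a : n_a + n_b]),
            reference_controls=tuple(cols[n_a + n_b :]),
        ),
    )


def contrast_pvalues(matrix, design: ContrastDesign) -> np.ndarray:
    """Raw exact-test p-values for every row of ``matrix`` under ``design``."""
    sf = size_factors(matrix)
    disp = estimate_dispersions(matrix, design, sf=sf)["final"].to_numpy()
    sfa = sf.loc[list(design.condition_a)].to_numpy()
    sfb = sf.loc[list(design.condition_b)].to_numpy()
    a = matrix[list(design.condition_a)].to_numpy()
    b = matrix[list(design.condition_b)].to_numpy()
    return np.array(
        [nb_exact_test(a[i], b[i], sfa, sfb, disp[i]) for i in range(len(matrix))]
    )


def null_rates(
    n_runs: int = 200,
    n_genes: int = 300,
    alpha: float = 0.1,
    n_a: int = 2,
    n_b: int = 2,
    n_ref: int = 8,
    threshold: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Per-run fraction of raw p-values below ``threshold`` with no true effect."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_runs)
    rates = np.empty(n_runs)
    for run in range(n_runs):
        means = np.exp(rng.uniform(np.log(MEAN_RANGE[0]), np.log(MEAN_RANGE[1]), n_genes))
        matrix = nb_null_matrix(means, n_a + n_b + n_ref, alpha, seed=int(seeds[run]))
        _, design = _design(n_a, n_b, n_ref)
        pvals = contrast_pvalues(matrix, design)
        rates[run] = float((pvals < threshold).mean())
    return rates


def planted_recovery(
    n_runs: int = 11,
    n_genes: int = 300,
    n_planted: int = 10,
    fold: float = 4.0,
    planted_mean: float = 5000.0,
    alpha: float = 0.1,
    n_a: int = 2,
    n_b: int = 2,
    n_ref: int = 8,
    threshold: float = 0.01,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Recovered planted arms and false positives at padj < threshold, per run.

    The first ``n_planted`` genes get baseline mean ``planted_mean`` and a
    ``fold``-times change in condition B; the rest stay null.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_runs)
    recovered = np.empty(n_runs, dtype=int)
    false_pos = np.empty(n_runs, dtype=int)
    n_samples = n_a + n_b + n_ref
    for run in range(n_runs):
        means = np.exp(rng.uniform(np.log(MEAN_RANGE[0]), np.log(MEAN_RANGE[1]), n_genes))
        means[:n_planted] = planted_mean
        fold_matrix = np.ones((n_genes, n_samples))
        fold_matrix[:n_planted, n_a : n_a + n_b] = fold
        matrix = nb_null_matrix(
            means, n_samples, alpha, seed=int(seeds[run]), fold=fold_matrix
        )
        _, design = _design(n_a, n_b, n_ref)
        pvals = contrast_pvalues(matrix, design)
        padj = bh_adjust(pvals)
        recovered[run] = int((padj[:n_planted] < threshold).sum())
        false_pos[run] = int((padj[n_planted:] < threshold).sum())
    return recovered, false_pos
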