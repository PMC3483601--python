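"""Negative-binomial differential expression with an augmented control reference.

The model follows the original count-based NB testing scheme for sequencing
data: per-sample size factors by the median-of-ratios method, a quadratic
variance model v = mu + alpha*mu^2 with gene-wise dispersions estimated by
method of moments from within-group replicate variability, a parametric
dispersion-mean trend alpha(mu) = a0 + a1/mu, and -- with sharing mode
"maximum" -- a final per-gene dispersion that is the pointwise maximum of the
gene-wise estimate and the fitted trend.  Dispersion estimation may pool an
additional set of reference control samples (improving the variance estimate
without entering the tested contrast), and each gene is tested with a
two-sided conditional exact test on the group count sums.

Also provided: BH multiple-testing adjustment, the per-sample correlation QC
against the median control profile, head/body enrichment classification,
cross-dataset direction concordance, and the -ddCt qPCR fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastDesign",
    "size_factors",
    "estimate_dispersions",
    "nb_exact_test",
    "bh_adjust",
    "de_table",
    "sample_correlation_qc",
    "classify_head_enrichment",
    "direction_concordance",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class ContrastDesign:
    """A two-group contrast plus reference controls used only for dispersion.

    ``condition_a`` and ``condition_b`` are disjoint, non-empty sample-id
    lists of the same genotype (e.g. uninduced vs induced); the reference
    controls enter dispersion estimation as their own replicate group and are
    never part of the tested contrast.
    """

    condition_a: tuple[str, ...]
    condition_b: tuple[str, ...]
    reference_controls: tuple[str, ...] = ()
    significance: float = 0.01
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if not self.condition_a or not self.condition_b:
            raise ValueError("both conditions must be non-empty")
        if set(self.condition_a) & set(self.condition_b):
            raise ValueError("condition groups must be disjoint")


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over rows i with all-positive counts of
    k_ij / geometric-mean over samples of row i.  Rows containing a zero are
    excluded from the reference, so adding all-zero rows never changes the
    result.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "size factors are not estimable: no row has positive counts in "
            "every sample (library overlap too sparse)"
        )
    logs = np.log(values[all_positive])
    log_geomeans = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_geomeans[:, None], axis=0))
    return pd.Series(sf, index=matrix.columns, name="size_factor")


def _replicate_groups(design: ContrastDesign) -> list[tuple[str, ...]]:
    groups = [design.condition_a, design.condition_b]
    if design.reference_controls:
        groups.append(design.reference_controls)
    return groups


def estimate_dispersions(
    matrix: pd.DataFrame,
    design: ContrastDesign,
    sharing_mode: str = "maximum",
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Gene-wise, trend-fitted and final NB dispersions.

    Gene-wise: within each replicate group (the two condition groups plus the
    reference controls as a group of their own, whenever a group has >= 2
    samples), the variance of normalized counts in excess of the shot-noise
    term q_g * mean(1/s_j) is scaled by the squared group mean; the per-group
    estimates are pooled by their degrees of freedom, so groups whose means
    differ (e.g. under a real effect) each contribute an estimate on their own
    scale.  The result is floored at zero.  Trend: alpha(mu) = a0 + a1/mu by
    non-negative least squares of the unfloored estimates on the base mean
    (falling back to the median gene-wise value when the fit degenerates).
    Final: pointwise max(gene-wise, fitted) under sharing mode "maximum",
    else the fitted value.
    """
    if sharing_mode not in ("maximum", "fit-only"):
        raise ValueError(f"unknown sharing mode {sharing_mode!r}")
    groups = [g for g in _replicate_groups(design) if len(g) >= 2]
    if not groups:
        raise ValueError(
            "dispersion not estimable: every group has a single sample; "
            "supply reference control samples"
        )
    used = [s for g in groups for s in g]
    if sf is None:
        sf = size_factors(matrix[used])
    weighted = np.zeros(matrix.shape[0])
    df_total = 0
    q_groups = []
    for g in groups:
        s = sf.loc[list(g)].to_numpy(dtype=float)
        norm = matrix[list(g)].to_numpy(dtype=float) / s
        q_g = norm.mean(axis=1)
        w_g = norm.var(axis=1, ddof=1)
        z_g = q_g * np.mean(1.0 / s)  # shot-noise part of the variance
        with np.errstate(divide="ignore", invalid="ignore"):
            a_g = np.where(q_g > 0, (w_g - z_g) / np.square(q_g), 0.0)
        df_g = len(g) - 1
        weighted += a_g * df_g
        df_total += df_g
        q_groups.append(q_g)
    gene_raw = weighted / df_total
    gene_wise = np.maximum(gene_raw, 0.0)
    q = np.mean(q_groups, axis=0)  # base mean across groups

    ok = q > 0
    fitted = np.full_like(gene_wise, np.median(gene_wise[ok]) if ok.any() else 0.0)
    if ok.sum() >= 2:
        design_mat = np.column_stack([np.ones(ok.sum()), 1.0 / q[ok]])
        coef, _ = nnls(design_mat, gene_raw[ok])
        if np.isfinite(coef).all() and coef.sum() > 0:
            with np.errstate(divide="ignore"):
                fitted = np.where(q > 0, coef[0] + coef[1] / q, coef[0])
    final = np.maximum(gene_wise, fitted) if sharing_mode == "maximum" else fitted
    return pd.DataFrame(
        {"gene_wise": gene_wise, "fitted": fitted, "final": final},
        index=matrix.index,
    )


def _group_logpmf(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log pmf of a group count sum: NB(mu, var) or Poisson when var <= mu."""
    if var <= mu * (1 + 1e-12):
        return stats.poisson.logpmf(k, mu)
    size = mu * mu / (var - mu)
    p = size / (size + mu)
    return stats.nbinom.logpmf(k, size, p)


def nb_exact_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    sf_a: Sequence[float],
    sf_b: Sequence[float],
    alpha: float,
) -> float:
    """Two-sided conditional exact NB test on group count sums.

    Under the null both group sums K_A, K_B derive from a common per-gene
    concentration q = (K_A+K_B)/(S_A+S_B): K_A ~ NB with mean q*S_A and
    variance q*S_A + alpha*q^2*sum_{j in A} s_j^2 (each sample contributes
    v = mu + alpha*mu^2), and likewise for B.  The p-value sums, over all
    splits a + b = K_A + K_B, the probabilities P(a)P(b) no larger than that
    of the observed split, normalized by the total over all splits.
    """
    if alpha < 0:
        raise ValueError("dispersion alpha must be >= 0")
    if len(counts_a) == 0 or len(counts_b) == 0:
        raise ValueError("both groups must be non-empty")
    ka = int(np.sum(counts_a))
    kb = int(np.sum(counts_b))
    k = ka + kb
    if k == 0:
        return 1.0
    sa = np.asarray(sf_a, dtype=float)
    sb = np.asarray(sf_b, dtype=float)
    q = k / (sa.sum() + sb.sum())
    mu_a = q * sa.sum()
    mu_b = q * sb.sum()
    var_a = mu_a + alpha * q * q * np.square(sa).sum()
    var_b = mu_b + alpha * q * q * np.square(sb).sum()
    a = np.arange(k + 1)
    logp = _group_logpmf(a, mu_a, var_a) + _group_logpmf(k - a, mu_b, var_b)
    # normalize in log space for numerical stability
    m = logp.max()
    probs = np.exp(logp - m)
    p_obs = probs[ka]
    p = probs[probs <= p_obs * (1 + 1e-8)].sum() / probs.sum()
    return float(min(1.0, max(0.0, p)))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    matrix: pd.DataFrame,
    design: ContrastDesign,
    sf: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression between the two condition groups.

    Size factors come from the full matrix unless supplied; dispersions from
    :func:`estimate_dispersions` (sharing mode "maximum") unless supplied.
    Genes with zero counts in every sample of the contrast and reference are
    dropped before testing (reported via ``result.attrs['n_filtered']``).
    Fold change is baseMeanB / baseMeanA, +inf when baseMeanA is 0.
    """
    used = list(design.condition_a) + list(design.condition_b) + list(
        design.reference_controls
    )
    sub = matrix[used]
    keep = sub.to_numpy().sum(axis=1) > 0
    n_filtered = int((~keep).sum())
    sub = sub.loc[keep]
    if sf is None:
        sf = size_factors(sub)
    sf = sf.loc[used]
    if dispersions is None:
        dispersions = estimate_dispersions(sub, design, sf=sf)["final"]
    else:
        dispersions = pd.Series(dispersions, index=sub.index) if not isinstance(
            dispersions, pd.Series
        ) else dispersions
    norm = sub / sf
    a_cols = list(design.condition_a)
    b_cols = list(design.condition_b)
    base_a = norm[a_cols].mean(axis=1)
    base_b = norm[b_cols].mean(axis=1)
    sf_a = sf.loc[a_cols].to_numpy()
    sf_b = sf.loc[b_cols].to_numpy()
    pvals = np.array(
        [
            nb_exact_test(
                sub.loc[g, a_cols].to_numpy(),
                sub.loc[g, b_cols].to_numpy(),
                sf_a,
                sf_b,
                float(dispersions.loc[g]),
            )
            for g in sub.index
        ]
    )
    with np.errstate(divide="ignore"):
        fold = np.where(base_a > 0, base_b / base_a, np.inf)
    result = pd.DataFrame(
        {
            "baseMeanA": base_a,
            "baseMeanB": base_b,
            "foldChange": fold,
            "pval": pvals,
            "padj": bh_adjust(pvals),
        },
        index=sub.index,
    )
    result.attrs["n_filtered"] = n_filtered
    return result


def sample_correlation_qc(
    normalized: pd.DataFrame,
    control_samples: Sequence[str] | None = None,
    log: bool = True,
) -> pd.Series:
    """Pearson r of each sample's normalized profile against the per-gene
    median over the control samples (all samples by default).

    Computed on log(1 + count) by default: miRNA expression spans several
    decades, and on the linear scale the correlation of replicate profiles is
    bounded by the biological overdispersion of the most abundant genes no
    matter how reproducible the libraries are, whereas the log scale compares
    the whole distribution the way replicate scatter plots are drawn.  Pass
    ``log=False`` for the linear-scale coefficient.  Zero-variance profiles
    yield NaN (reported as missing, not an error).
    """
    if normalized.shape[1] < 3:
        raise ValueError("correlation QC needs at least 3 samples")
    controls = list(control_samples) if control_samples is not None else list(
        normalized.columns
    )
    values = np.log1p(normalized) if log else normalized
    median_profile = values[controls].median(axis=1).to_numpy()
    out = {}
    for sample in normalized.columns:
        x = values[sample].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(median_profile) == 0:
            out[sample] = np.nan
        else:
            out[sample] = float(np.corrcoef(x, median_profile)[0, 1])
    return pd.Series(out, name="r_vs_median")


def classify_head_enrichment(
    de: pd.DataFrame, threshold: float = 0.01, use_adjusted: bool = True
) -> tuple[list[str], list[str]]:
    """Split significant genes of a body-vs-head contrast by ratio direction.

    ``de`` must come from :func:`de_table` with head as condition A and whole
    body as condition B, so foldChange is the WholeBody/Head ratio: ratios
    below 1 are head-enriched, above 1 head-depleted.  Non-significant genes
    are left unclassified.
    """
    crit = de["padj"] if use_adjusted else de["pval"]
    sig = de[crit < threshold]
    enriched = sig.index[sig["foldChange"] < 1].tolist()
    depleted = sig.index[sig["foldChange"] > 1].tolist()
    return enriched, depleted


def direction_concordance(
    ratios_1: Mapping[str, float] | pd.Series,
    ratios_2: Mapping[str, float] | pd.Series,
) -> tuple[float, int, int]:
    """Fraction of shared ids whose ratios fall on the same side of 1.

    Returns (fraction, n_shared, n_ties); a ratio exactly 1 in either vector
    is concordant with either side and counted in ``n_ties``.
    """
    r1 = pd.Series(ratios_1, dtype=float)
    r2 = pd.Series(ratios_2, dtype=float)
    shared = r1.index.intersection(r2.index)
    if len(shared) == 0:
        raise ValueError("no shared ids between the ratio vectors")
    a = r1.loc[shared].to_numpy()
    b = r2.loc[shared].to_numpy()
    ties = (a == 1) | (b == 1)
    concordant = ties | (np.sign(np.log(a)) == np.sign(np.log(b)))
    return float(concordant.mean()), int(len(shared)), int(ties.sum())


def ddct_fold_change(
    ct_target_a: float,
    ct_target_b: float,
    ct_normalizers_a: Sequence[float],
    ct_normalizers_b: Sequence[float],
) -> float:
    """Relative qPCR quantification by the comparative -ddCt method.

    dCt per group is the target Ct minus the mean of the normalizer Cts
    (two normalizer genes in the study design); the B-vs-A fold change is
    2^-(dCt_B - dCt_A).
    """
    values = [ct_target_a, ct_target_b, *ct_normalizers_a, *ct_normalizers_b]
    if not all(math.isfinite(v) for v in values):
        raise ValueError("cycle values must be finite")
    dct_a = ct_target_a - float(np.mean(ct_normalizers_a))
    dct_b = ct_target_b - float(np.mean(ct_normalizers_b))
    return float(2.0 ** (-(dct_b - dct_a)))
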