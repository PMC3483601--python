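#!/usr/bin/env python
"""Assign stem-loop reads to 5p/3p arms by the optimal-split search.

Writes the arm x sample count matrix and the per-stem-loop split diagnostics,
and verifies the matrix against the planted truth (error-free reads, so the
round trip must be exact).
"""

from pathlib import Path

import pandas as pd

from flysrna.pipeline import PipelineConfig, run_pipeline

HERE = Path(__file__).resolve().parent


def publish(out, patterns):
    """Copy the small summary tables of this stage into results/."""
    import shutil
    results = HERE.parent / "results"
    results.mkdir(exist_ok=True)
    for pattern in patterns:
        for path in sorted(out.glob(pattern)):
            shutil.copy(path, results / path.name)


def main() -> None:
    config = PipelineConfig.from_yaml(HERE / "config.yaml")
    out = run_pipeline(config, upto="arms")
    counts = pd.read_csv(out / "arm_counts.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(out / "true_counts.tsv", sep="\t", index_col=0)
    diag = pd.read_csv(out / "split_diagnostics.tsv", sep="\t")
    exact = counts.loc[truth.index, truth.columns].equals(truth)
    print(f"arm count matrix: {counts.shape[0]} arms x {counts.shape[1]} samples")
    print(f"recovered the planted count matrix exactly: {exact}")
    print(f"reads discarded at the split (spanning reads): {diag['discarded'].sum()}")
    print(diag.groupby('stemloop_id')['split'].first().rename('split_position').to_string())
    publish(out, ["arm_counts.tsv", "split_diagnostics.tsv"])


if __name__ == "__main__":
    main()
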