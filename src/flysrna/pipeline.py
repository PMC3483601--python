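"""End-to-end orchestration of the small-RNA profiling stages.

One config drives simulate -> preprocess -> annotate -> arm assignment ->
differential expression (+QC, enrichment) -> transgene repeat scan; every
stage is a pure function of the declared inputs and the seed, so a run is
reproducible byte-for-byte from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .annotate import CascadeIndex, cascade_assign
from .arms import StemLoopProfile, arm_count_matrix, profile_stemloop
from .diffexpr import (
    ContrastDesign,
    classify_head_enrichment,
    de_table,
    sample_correlation_qc,
    size_factors,
)
from .io import annotation_frame, write_bundle, write_fastq, write_sample_sheet
from .preprocess import MatchHit, filter_by_length, trim_adapter
from .scag import RepeatRegion, align_to_transgene, scag_summary
from .simulate import (
    DEFAULT_ADAPTER,
    ReferenceConfig,
    build_toy_reference,
    default_design,
    simulate_count_matrix,
    spike_repeat_reads,
    synthesize_fastq,
)

logger = logging.getLogger("flysrna")

STAGES = ("simulate", "preprocess", "annotate", "arms", "de", "scag", "all")


class ConfigError(Exception):
    """Invalid or inconsistent pipeline configuration."""


class DataError(Exception):
    """A stage failed on its input data."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults match the study conditions."""

    output_dir: str = "results/run"
    seed: int = 0
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 5
    length_threshold: int = 18  # strict: keep reads with length > threshold
    max_mismatches: int = 1
    split_window: int = 20
    significance: float = 0.01
    discard_untrimmed: bool = False
    scag_max_edits: int = 2
    scag_min_len: int = 15
    # synthetic-data knobs
    n_genotypes: int = 2
    replicates: int = 2
    dispersion: float = 0.1
    error_rate: float = 0.0
    read_length: int = 36
    end_wobble: int = 1
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    effect_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    spike_n: int = 0
    spike_edit_profile: Mapping[int, int] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        ref = raw.pop("reference", {})
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
            cfg.reference = ReferenceConfig(**ref)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        if cfg.spike_edit_profile is not None:
            cfg.spike_edit_profile = {int(k): int(v) for k, v in cfg.spike_edit_profile.items()}
        if cfg.effect_map:
            cfg.effect_map = {
                arm: {cond: float(fc) for cond, fc in per.items()}
                for arm, per in cfg.effect_map.items()
            }
        return cfg


def _check_conservation(n_in: int, table) -> None:
    n_out = table.total_matched + table.unmatched
    if n_in != n_out:
        logger.warning(
            "read-count conservation violated for %s: %d in, %d out",
            table.sample_id, n_in, n_out,
        )


def run_pipeline(config: PipelineConfig, upto: str = "all") -> Path:
    """Run the pipeline on a synthetic dataset and write reports under the run dir.

    ``upto`` stops after the named stage (simulate, preprocess, annotate,
    arms, de, scag or all).  Returns the run directory; the manifest written
    there records the seed and every parameter needed to reproduce the run.
    """
    if upto not in STAGES:
        raise ConfigError(f"unknown stage {upto!r}; expected one of {STAGES}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------------
    logger.info("stage simulate: building reference bundle and reads (seed=%d)", config.seed)
    try:
        bundle = build_toy_reference(config.reference, seed=config.seed)
        design = default_design(
            bundle,
            n_genotypes=config.n_genotypes,
            replicates=config.replicates,
            seed=config.seed,
            dispersion=config.dispersion,
            effect_map=config.effect_map,
        )
        truth_matrix = simulate_count_matrix(design, bundle)
        fastq_sets, truth = synthesize_fastq(
            truth_matrix,
            bundle,
            adapter=config.adapter,
            error_rate=config.error_rate,
            seed=config.seed,
            read_length=config.read_length,
            end_wobble=config.end_wobble,
        )
        spike_truths = []
        if config.spike_n > 0 and bundle.transgenes:
            first_sample = design.samples[0].id
            fastq_sets[first_sample], spike_truth = spike_repeat_reads(
                fastq_sets[first_sample],
                bundle.transgenes[0],
                n=config.spike_n,
                edit_profile=config.spike_edit_profile,
                seed=config.seed + 1,
                adapter=config.adapter,
                read_length=config.read_length,
            )
            spike_truths.append(spike_truth)
    except ValueError as exc:
        raise DataError(f"stage simulate failed: {exc}") from exc

    write_bundle(bundle, out / "reference")
    write_sample_sheet(design.samples, out / "sample_sheet.tsv")
    truth_matrix.to_csv(out / "true_counts.tsv", sep="\t")
    truth.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    if spike_truths:
        pd.concat(spike_truths).to_csv(out / "truth_spikes.tsv", sep="\t", index=False)
    fastq_dir = out / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    for sample, reads in fastq_sets.items():
        write_fastq(reads, fastq_dir / f"{sample}.fastq")
    if upto == "simulate":
        _write_manifest(config, out)
        return out

    # --- preprocess ---------------------------------------------------------
    logger.info("stage preprocess: trimming and length filtering")
    trimmed_all: dict[str, list] = {}
    filtered: dict[str, list] = {}
    for sample, reads in fastq_sets.items():
        try:
            trimmed = [trim_adapter(r, config.adapter, config.min_overlap) for r in reads]
        except ValueError as exc:
            raise DataError(f"stage preprocess failed on sample {sample}: {exc}") from exc
        if config.discard_untrimmed:
            trimmed = [t for t in trimmed if t.trimmed]
        trimmed_all[sample] = trimmed
        filtered[sample] = filter_by_length(trimmed, config.length_threshold)
    pd.DataFrame(
        [
            {
                "sample_id": s,
                "n_raw": len(fastq_sets[s]),
                "n_trimmed": sum(1 for t in trimmed_all[s] if t.trimmed),
                "n_length_filtered": len(filtered[s]),
            }
            for s in fastq_sets
        ]
    ).to_csv(out / "preprocess_summary.tsv", sep="\t", index=False)
    if upto == "preprocess":
        _write_manifest(config, out)
        return out

    # --- annotate -----------------------------------------------------------
    logger.info("stage annotate: six-tier cascade assignment")
    cascade = CascadeIndex(bundle)
    tables = []
    assignments: dict[str, dict] = {}
    for sample, reads in filtered.items():
        table, amap = cascade_assign(
            reads, cascade, sample_id=sample, max_mismatches=config.max_mismatches
        )
        _check_conservation(len(reads), table)
        tables.append(table)
        assignments[sample] = amap
    annotation_frame(tables).to_csv(out / "annotation_table.tsv", sep="\t", index=False)
    if upto == "annotate":
        _write_manifest(config, out)
        return out

    # --- arms ---------------------------------------------------------------
    logger.info("stage arms: stem-loop split and arm count matrix")
    lengths = {sl.id: len(sl.sequence) for sl in bundle.stemloops}
    profiles: dict[str, list[StemLoopProfile]] = {}
    for sample, amap in assignments.items():
        by_stemloop: dict[str, list[MatchHit]] = {sl.id: [] for sl in bundle.stemloops}
        for a in amap.values():
            if a.category == "miRNA" and a.hit is not None:
                by_stemloop[a.hit.ref_id].append(a.hit)
        profiles[sample] = [
            profile_stemloop(hits, sl_id, lengths[sl_id])
            for sl_id, hits in by_stemloop.items()
        ]
    counts, diagnostics = arm_count_matrix(profiles, window=config.split_window)
    counts.to_csv(out / "arm_counts.tsv", sep="\t")
    diagnostics.to_csv(out / "split_diagnostics.tsv", sep="\t", index=False)
    if upto == "arms":
        _write_manifest(config, out)
        return out

    # --- de -----------------------------------------------------------------
    logger.info("stage de: normalization, QC and per-genotype contrasts")
    sheet = pd.DataFrame(
        [
            {"sample_id": s.id, "genotype": s.genotype, "condition": s.condition, "tissue": s.tissue}
            for s in design.samples
        ]
    )
    try:
        sf = size_factors(counts)
    except ValueError as exc:
        raise DataError(f"stage de failed: {exc}") from exc
    normalized = counts / sf
    uninduced = tuple(sheet.loc[sheet.condition == "uninduced", "sample_id"])
    qc = sample_correlation_qc(normalized, control_samples=uninduced or None)
    qc.rename_axis("sample_id").to_frame().to_csv(out / "correlation_qc.tsv", sep="\t")
    for genotype, grp in sheet.groupby("genotype", sort=True):
        cond_a = tuple(grp.loc[grp.condition == "uninduced", "sample_id"])
        cond_b = tuple(grp.loc[grp.condition == "induced", "sample_id"])
        if not cond_a or not cond_b:
            continue
        contrast = ContrastDesign(
            condition_a=cond_a,
            condition_b=cond_b,
            reference_controls=tuple(sid for sid in uninduced if sid not in cond_a),
            significance=config.significance,
        )
        de = de_table(counts, contrast, sf=sf)
        de.rename_axis("id").round(6).to_csv(
            out / f"de_{genotype}_induced_vs_uninduced.tsv", sep="\t"
        )
    tissues = set(sheet.tissue)
    if tissues == {"head", "body"}:
        head = tuple(sheet.loc[sheet.tissue == "head", "sample_id"])
        body = tuple(sheet.loc[sheet.tissue == "body", "sample_id"])
        contrast = ContrastDesign(condition_a=head, condition_b=body)
        de = de_table(counts, contrast, sf=sf)
        enriched, depleted = classify_head_enrichment(de, threshold=config.significance)
        pd.DataFrame(
            {"id": enriched + depleted,
             "class": ["head_enriched"] * len(enriched) + ["head_depleted"] * len(depleted)}
        ).to_csv(out / "head_enrichment.tsv", sep="\t", index=False)
    if upto == "de":
        _write_manifest(config, out)
        return out

    # --- scag ---------------------------------------------------------------
    if bundle.transgenes:
        logger.info("stage scag: transgene repeat scan")
        tg = bundle.transgenes[0]
        region = RepeatRegion(tg.id, tg.repeat_start, tg.repeat_end)
        hit_rows = []
        summary_rows = []
        for sample, reads in trimmed_all.items():
            hits = align_to_transgene(
                reads, tg.sequence, region,
                max_edits=config.scag_max_edits, min_len=config.scag_min_len,
            )
            for h in hits:
                hit_rows.append(
                    {"sample_id": sample, "transgene_id": tg.id, "orientation": h.strand,
                     "position": h.position, "sequence": h.sequence, "edits": h.edits,
                     "size": h.length, "in_repeat": h.in_repeat}
                )
            rep = scag_summary(hits, region, len(tg.sequence))
            summary_rows.append({"sample_id": sample, **asdict(rep)})
        pd.DataFrame(
            hit_rows,
            columns=["sample_id", "transgene_id", "orientation", "position",
                     "sequence", "edits", "size", "in_repeat"],
        ).to_csv(out / "scag_hits.tsv", sep="\t", index=False)
        pd.DataFrame(summary_rows).to_csv(out / "scag_summary.tsv", sep="\t", index=False)

    _write_manifest(config, out)
    logger.info("pipeline complete: %s", out)
    return out


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    manifest = {"flysrna_version": __version__, "config": asdict(config)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
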