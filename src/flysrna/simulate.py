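"""Seeded synthetic data: toy references, NB count matrices and FASTQ read sets.

The generator emulates the statistical structure of a small-RNA profiling
study of fly neurodegeneration models: ~70-100 nt miRNA stem-loop precursors
whose 5p and 3p arms produce ~22 nt reads, a six-category reference hierarchy
(miRNA stem-loops, other ncRNAs, transposons, introns, mRNAs, intergenic), a
paired induced/uninduced design over two tissues, negative-binomially
distributed per-arm counts, the 3' sequencing adapter 5'-CTGTAGGCACCATCAAT-3'
appended to every insert, and optional spiked CAG-repeat reads for the
transgene scan.  Every output is a deterministic function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import RawRead, revcomp

__all__ = [
    "DEFAULT_ADAPTER",
    "CATEGORY_ORDER",
    "StemLoopSpec",
    "Transgene",
    "ReferenceBundle",
    "Sample",
    "SimulationDesign",
    "ReferenceConfig",
    "build_toy_reference",
    "simulate_count_matrix",
    "synthesize_fastq",
    "spike_repeat_reads",
    "default_design",
    "nb_null_matrix",
]

DEFAULT_ADAPTER = "CTGTAGGCACCATCAAT"

#: The six mutually exclusive annotation tiers, in cascade order.
CATEGORY_ORDER = ("miRNA", "ncRNA", "transposon", "intron", "mRNA", "intergenic")

#: Sub-labels of the ncRNA tier, reported separately in annotation output.
NCRNA_SUBLABELS = ("tRNA", "rRNA", "miscRNA")

_BASES = "ACGT"


@dataclass(frozen=True)
class StemLoopSpec:
    """A miRNA precursor hairpin: 70-100 nt, with the 5p arm upstream of the 3p arm.

    ``arm5p``/``arm3p`` are 0-based half-open intervals on the stem-loop;
    the mean expressions are expected read counts at unit sequencing depth.
    """

    id: str
    sequence: str
    arm5p: tuple[int, int]
    arm3p: tuple[int, int]
    mean_expression_5p: float
    mean_expression_3p: float

    def __post_init__(self) -> None:
        if not 70 <= len(self.sequence) <= 100:
            raise ValueError(f"stem-loop {self.id!r}: length must be 70-100 nt")
        if not (0 <= self.arm5p[0] < self.arm5p[1] <= self.arm3p[0] < self.arm3p[1] <= len(self.sequence)):
            raise ValueError(f"stem-loop {self.id!r}: arms must be ordered 5p before 3p within the sequence")
        if self.mean_expression_5p < 0 or self.mean_expression_3p < 0:
            raise ValueError(f"stem-loop {self.id!r}: mean expressions must be non-negative")


@dataclass(frozen=True)
class Transgene:
    """A disease construct with a declared trinucleotide repeat region.

    ``repeat_start``/``repeat_end`` use the 1-based inclusive convention of
    printed coordinate tables; ``repeat_start < repeat_end <= len(sequence)``.
    """

    id: str
    sequence: str
    repeat_start: int
    repeat_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.repeat_start < self.repeat_end <= len(self.sequence):
            raise ValueError(f"transgene {self.id!r}: invalid repeat coordinates")


@dataclass(frozen=True)
class ReferenceBundle:
    """Toy genome plus the ordered six-category reference sets planted in it."""

    genome: str
    categories: tuple[tuple[str, tuple[tuple[str, str], ...]], ...]
    stemloops: tuple[StemLoopSpec, ...]
    transgenes: tuple[Transgene, ...] = ()

    def __post_init__(self) -> None:
        names = tuple(name for name, _ in self.categories)
        if names != CATEGORY_ORDER:
            raise ValueError(f"category order must be {CATEGORY_ORDER}, got {names}")
        for name, refs in self.categories:
            for ref_id, seq in refs:
                if seq not in self.genome:
                    raise ValueError(
                        f"reference {ref_id!r} ({name}) is not a substring of the genome"
                    )

    def category_refs(self, name: str) -> tuple[tuple[str, str], ...]:
        for cat, refs in self.categories:
            if cat == name:
                return refs
        raise KeyError(name)

    @property
    def arm_ids(self) -> list[str]:
        out = []
        for sl in self.stemloops:
            out.extend([f"{sl.id}_5p", f"{sl.id}_3p"])
        return out

    def arm_mean_expression(self) -> dict[str, float]:
        means = {}
        for sl in self.stemloops:
            means[f"{sl.id}_5p"] = sl.mean_expression_5p
            means[f"{sl.id}_3p"] = sl.mean_expression_3p
        return means


@dataclass(frozen=True)
class Sample:
    id: str
    genotype: str
    condition: str  # "induced" | "uninduced"
    tissue: str  # "head" | "body"

    def __post_init__(self) -> None:
        if self.condition not in ("induced", "uninduced"):
            raise ValueError(f"sample {self.id!r}: unknown condition {self.condition!r}")
        if self.tissue not in ("head", "body"):
            raise ValueError(f"sample {self.id!r}: unknown tissue {self.tissue!r}")


@dataclass(frozen=True)
class SimulationDesign:
    """Which samples exist and how each arm's expression responds to condition.

    ``effect_map`` maps arm id -> {condition: fold change}; missing entries
    default to 1.  ``dispersion_map`` maps arm id -> NB dispersion alpha >= 0
    (variance mu + alpha*mu^2); ``depth_map`` maps sample id -> relative
    library depth (mean counts scale linearly with it).
    """

    samples: tuple[Sample, ...]
    effect_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dispersion_map: Mapping[str, float] = field(default_factory=dict)
    depth_map: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")
        for arm, per_cond in self.effect_map.items():
            for cond, fc in per_cond.items():
                if not (math.isfinite(fc) and fc >= 0):
                    raise ValueError(f"effect for {arm!r}/{cond!r} must be finite and >= 0")
        for arm, a in self.dispersion_map.items():
            if not (math.isfinite(a) and a >= 0):
                raise ValueError(f"dispersion for {arm!r} must be finite and >= 0")

    def fold_change(self, arm: str, condition: str) -> float:
        return float(self.effect_map.get(arm, {}).get(condition, 1.0))

    def depth(self, sample_id: str) -> float:
        return float(self.depth_map.get(sample_id, 1.0))


@dataclass(frozen=True)
class ReferenceConfig:
    """Sizes and counts for the toy reference bundle.

    Defaults give a 20 kb genome with 8 stem-loops and one locus of each
    remaining category -- small enough for fast matching, large enough that
    planted 20-mers are effectively unique.
    """

    genome_length: int = 20_000
    n_stemloops: int = 8
    stemloop_length: int = 80
    arm_length: int = 22
    n_trna: int = 1
    n_rrna: int = 1
    n_miscrna: int = 0
    ncrna_length: int = 90
    n_transposons: int = 1
    transposon_length: int = 300
    n_introns: int = 1
    intron_length: int = 200
    n_mrnas: int = 1
    mrna_length: int = 400
    n_intergenic: int = 1
    intergenic_length: int = 150
    mean_expression_range: tuple[float, float] = (50.0, 800.0)
    transgene_repeat_units: int = 0  # (CAG)_n; 0 = no transgene
    transgene_flank: int = 300


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def build_toy_reference(
    config: ReferenceConfig = ReferenceConfig(), seed: int = 0
) -> ReferenceBundle:
    """Plant non-overlapping reference loci on a random toy genome.

    Deterministic for a fixed seed.  Raises a sizing error when the requested
    loci cannot fit in the genome.
    """
    rng = np.random.default_rng(seed)
    if config.n_stemloops < 0 or config.genome_length <= 0:
        raise ValueError("category sizes must be >= 0 and genome length positive")
    genome = _random_seq(rng, config.genome_length)

    # Lay out loci left to right with random gaps; error out if they overflow.
    requests: list[tuple[str, str, int]] = []  # (category, id, length)
    for i in range(config.n_stemloops):
        requests.append(("miRNA", f"mir-{i + 1}", config.stemloop_length))
    for i in range(config.n_trna):
        requests.append(("ncRNA", f"tRNA-{i + 1}", config.ncrna_length))
    for i in range(config.n_rrna):
        requests.append(("ncRNA", f"rRNA-{i + 1}", config.ncrna_length))
    for i in range(config.n_miscrna):
        requests.append(("ncRNA", f"miscRNA-{i + 1}", config.ncrna_length))
    for i in range(config.n_transposons):
        requests.append(("transposon", f"TE-{i + 1}", config.transposon_length))
    for i in range(config.n_introns):
        requests.append(("intron", f"intron-{i + 1}", config.intron_length))
    for i in range(config.n_mrnas):
        requests.append(("mRNA", f"mRNA-{i + 1}", config.mrna_length))
    for i in range(config.n_intergenic):
        requests.append(("intergenic", f"intergenic-{i + 1}", config.intergenic_length))

    total = sum(length for _, _, length in requests)
    if total > config.genome_length:
        raise ValueError(
            f"requested loci ({total} nt) do not fit in a {config.genome_length} nt genome"
        )
    slack = config.genome_length - total
    gaps = rng.multinomial(slack, np.ones(len(requests) + 1) / (len(requests) + 1))

    refs: dict[str, list[tuple[str, str]]] = {name: [] for name in CATEGORY_ORDER}
    stemloops: list[StemLoopSpec] = []
    pos = 0
    lo, hi = config.mean_expression_range
    for (category, ref_id, length), gap in zip(requests, gaps[:-1]):
        pos += int(gap)
        seq = genome[pos : pos + length]
        refs[category].append((ref_id, seq))
        if category == "miRNA":
            a = config.arm_length
            # canonical hairpin layout: 5p arm near the 5' end, 3p near the 3' end
            arm5p = (1, 1 + a)
            arm3p = (length - 1 - a, length - 1)
            mean5 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            mean3 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            stemloops.append(
                StemLoopSpec(ref_id, seq, arm5p, arm3p, mean5, mean3)
            )
        pos += length

    transgenes: list[Transgene] = []
    if config.transgene_repeat_units > 0:
        left = _random_seq(rng, config.transgene_flank)
        right = _random_seq(rng, config.transgene_flank)
        repeat = "CAG" * config.transgene_repeat_units
        seq = left + repeat + right
        transgenes.append(
            Transgene(
                "transgene-1",
                seq,
                repeat_start=len(left) + 1,
                repeat_end=len(left) + len(repeat),
            )
        )

    categories = tuple((name, tuple(refs[name])) for name in CATEGORY_ORDER)
    return ReferenceBundle(genome, categories, tuple(stemloops), tuple(transgenes))


def simulate_count_matrix(
    design: SimulationDesign, bundle: ReferenceBundle
) -> pd.DataFrame:
    """Draw the arm x sample count matrix from the NB model.

    Entry (i, j) ~ NB with mean mu_ij = depth_j * q_i * foldchange_i(cond_j)
    and variance mu_ij + alpha_i * mu_ij^2 (Poisson when alpha_i = 0).
    """
    means = bundle.arm_mean_expression()
    for arm in design.effect_map:
        if arm not in means:
            raise ValueError(f"effect_map arm {arm!r} not present in the bundle")
    for arm, a in design.dispersion_map.items():
        if a < 0:
            raise ValueError(f"negative dispersion for {arm!r}")
    rng = np.random.default_rng(design.seed)
    arms = bundle.arm_ids
    samples = [s.id for s in design.samples]
    out = np.zeros((len(arms), len(samples)), dtype=np.int64)
    for i, arm in enumerate(arms):
        alpha = float(design.dispersion_map.get(arm, 0.0))
        for j, sample in enumerate(design.samples):
            mu = design.depth(sample.id) * means[arm] * design.fold_change(arm, sample.condition)
            if mu <= 0:
                out[i, j] = 0
            elif alpha == 0.0:
                out[i, j] = rng.poisson(mu)
            else:
                n = 1.0 / alpha
                p = n / (n + mu)
                out[i, j] = rng.negative_binomial(n, p)
    return pd.DataFrame(out, index=arms, columns=samples)


def _arm_interval(sl: StemLoopSpec, arm: str) -> tuple[int, int]:
    return sl.arm5p if arm == "5p" else sl.arm3p


def synthesize_fastq(
    counts: pd.DataFrame,
    bundle: ReferenceBundle,
    adapter: str = DEFAULT_ADAPTER,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length: int = 36,
    end_wobble: int = 1,
) -> tuple[dict[str, list[RawRead]], pd.DataFrame]:
    """Turn a count matrix into per-sample adapter-bearing FASTQ record sets.

    Each read is an arm-interval substring (ends jittered by at most
    ``end_wobble`` nt into the interval, carrying at most one substitution at
    rate ``error_rate``), followed by the adapter, padded with random bases or
    truncated to ``read_length``.  Read counts per arm equal the matrix
    entries exactly.  Returns (per-sample reads, truth table) where the truth
    table records each read's sample, origin arm and category.
    """
    if not set(adapter) <= set(_BASES):
        raise ValueError("adapter contains non-ACGT symbols")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    stemloops = {sl.id: sl for sl in bundle.stemloops}
    fastq: dict[str, list[RawRead]] = {str(c): [] for c in counts.columns}
    truth_rows: list[tuple[str, str, str, str]] = []
    serial = 0
    for sample in counts.columns:
        for arm_id in counts.index:
            n = int(counts.at[arm_id, sample])
            if n == 0:
                continue
            sl_id, arm = arm_id.rsplit("_", 1)
            sl = stemloops[sl_id]
            a0, a1 = _arm_interval(sl, arm)
            for _ in range(n):
                start = a0 + int(rng.integers(-end_wobble, end_wobble + 1))
                end = a1 + int(rng.integers(-end_wobble, end_wobble + 1))
                start = max(0, start)
                end = min(len(sl.sequence), end)
                insert = sl.sequence[start:end]
                if error_rate > 0 and rng.random() < error_rate:
                    pos = int(rng.integers(0, len(insert)))
                    old = insert[pos]
                    new = _BASES[(_BASES.index(old) + int(rng.integers(1, 4))) % 4]
                    insert = insert[:pos] + new + insert[pos + 1 :]
                serial += 1
                read_id = f"read{serial}:{sample}"
                seq = insert + adapter
                if len(seq) < read_length:
                    seq += _random_seq(rng, read_length - len(seq))
                seq = seq[:read_length]
                fastq[str(sample)].append(RawRead(read_id, seq, "I" * len(seq)))
                truth_rows.append((read_id, str(sample), arm_id, "miRNA"))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "sample_id", "origin", "category"])
    return fastq, truth


def _min_hamming_both_strands(read: str, reference: str) -> int:
    """Smallest ungapped Hamming distance of ``read`` at any offset, either strand."""
    best = len(read) + 1
    for q in (read, revcomp(read)):
        for off in range(len(reference) - len(q) + 1):
            window = reference[off : off + len(q)]
            d = sum(1 for x, y in zip(q, window) if x != y)
            best = min(best, d)
    return best


def spike_repeat_reads(
    reads: Sequence[RawRead],
    transgene: Transgene,
    n: int,
    length_range: tuple[int, int] = (15, 21),
    edit_profile: Mapping[int, int] | None = None,
    seed: int = 0,
    adapter: str = DEFAULT_ADAPTER,
    read_length: int = 36,
) -> tuple[list[RawRead], pd.DataFrame]:
    """Append ``n`` CAG-repeat reads sampled from the transgene's repeat region.

    ``edit_profile`` maps an edit count in {0, 1, 2} to how many spiked reads
    carry exactly that many substitutions (counts must sum to ``n``; default:
    all perfect).  Substituted positions are kept >= 4 nt apart and away from
    the read ends, and each edited read is rejection-checked to keep its
    minimum ungapped distance to the transgene equal to its planted edit
    count, so a downstream edit-tolerant scan recovers the profile exactly.
    Spiked reads are flagged by the ``spike:`` id prefix and returned in a
    truth table alongside the augmented read list.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (15 <= length_range[0] <= length_range[1] <= 30):
        raise ValueError("length_range must lie within [15, 30]")
    if edit_profile is None:
        edit_profile = {0: n}
    if sum(edit_profile.values()) != n:
        raise ValueError("edit_profile counts must sum to n")
    if any(k not in (0, 1, 2) for k in edit_profile):
        raise ValueError("edit counts must be 0, 1 or 2")

    rng = np.random.default_rng(seed)
    region = transgene.sequence[transgene.repeat_start - 1 : transgene.repeat_end]
    out = list(reads)
    truth_rows: list[tuple[str, str, int, str, int]] = []
    serial = 0
    for edits, count in sorted(edit_profile.items()):
        for _ in range(count):
            for _attempt in range(200):
                length = int(rng.integers(length_range[0], length_range[1] + 1))
                if length > len(region):
                    raise ValueError("repeat region shorter than requested read length")
                start = int(rng.integers(0, len(region) - length + 1))
                insert = region[start : start + length]
                positions: list[int] = []
                if edits:
                    candidates = list(range(2, length - 2))
                    rng.shuffle(candidates)
                    for p in candidates:
                        if all(abs(p - q) >= 4 for q in positions):
                            positions.append(p)
                        if len(positions) == edits:
                            break
                    if len(positions) < edits:
                        continue
                    for p in positions:
                        old = insert[p]
                        new = _BASES[(_BASES.index(old) + int(rng.integers(1, 4))) % 4]
                        insert = insert[:p] + new + insert[p + 1 :]
                if _min_hamming_both_strands(insert, transgene.sequence) != edits:
                    continue
                break
            else:
                raise RuntimeError("could not construct a spiked read with the requested edits")
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = insert if strand == "+" else revcomp(insert)
            serial += 1
            read_id = f"spike:{transgene.id}:{serial}"
            seq = oriented + adapter
            if len(seq) < read_length:
                seq += _random_seq(rng, read_length - len(seq))
            seq = seq[:read_length]
            out.append(RawRead(read_id, seq, "I" * len(seq)))
            truth_rows.append(
                (read_id, transgene.id, edits, strand, transgene.repeat_start + start)
            )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "transgene_id", "edits", "strand", "position"]
    )
    return out, truth


def nb_null_matrix(
    means: np.ndarray,
    n_samples: int,
    alpha: float,
    seed: int,
    fold: np.ndarray | None = None,
    sample_prefix: str = "S",
) -> pd.DataFrame:
    """Vectorized NB count matrix: gene i, sample j ~ NB(means[i] * fold[i, j], alpha).

    A sequence-free generator for calibration studies (type-I error, power)
    where only the count distribution matters.  ``fold`` is an optional
    per-gene, per-sample mean multiplier; variance is mu + alpha*mu^2
    (Poisson when alpha = 0).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = np.random.default_rng(seed)
    means = np.asarray(means, dtype=float)
    mu = np.repeat(means[:, None], n_samples, axis=1)
    if fold is not None:
        mu = mu * np.asarray(fold, dtype=float)
    if alpha == 0:
        counts = rng.poisson(mu)
    else:
        n = 1.0 / alpha
        counts = rng.negative_binomial(n, n / (n + mu))
    return pd.DataFrame(
        counts,
        index=[f"gene{i + 1}" for i in range(len(means))],
        columns=[f"{sample_prefix}{j + 1}" for j in range(n_samples)],
    )


def default_design(
    bundle: ReferenceBundle,
    n_genotypes: int = 2,
    replicates: int = 2,
    seed: int = 0,
    dispersion: float = 0.1,
    depth_range: tuple[float, float] = (0.7, 1.4),
    effect_map: Mapping[str, Mapping[str, float]] | None = None,
) -> SimulationDesign:
    """A paired induced/uninduced head design with log-uniform library depths."""
    rng = np.random.default_rng(seed)
    samples = []
    depth_map = {}
    for g in range(1, n_genotypes + 1):
        for cond in ("uninduced", "induced"):
            for r in range(1, replicates + 1):
                sid = f"G{g}_{cond}_{r}"
                samples.append(Sample(sid, f"G{g}", cond, "head"))
                depth_map[sid] = float(
                    np.exp(rng.uniform(np.log(depth_range[0]), np.log(depth_range[1])))
                )
    dispersion_map = {arm: dispersion for arm in bundle.arm_ids}
    return SimulationDesign(
        samples=tuple(samples),
        effect_map=effect_map or {},
        dispersion_map=dispersion_map,
        depth_map=depth_map,
        seed=seed,
    )
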