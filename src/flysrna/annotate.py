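"""Hierarchical mutually exclusive read annotation.

Each length-filtered read is matched (0 or 1 mismatch, both strands) against
the reference tiers in a fixed order -- miRNA stem-loops, other ncRNAs,
transposons, introns, mRNAs -- and assigned to the FIRST tier with a hit;
leftovers that still match the genome are counted as intergenic, and reads
matching nothing are reported separately as unmatched.  The six tier counts
are therefore mutually exclusive and, together, exhaustive over the
genome-matched reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .preprocess import MatchHit, ReferenceIndex, TrimmedRead, best_hit, build_index
from .simulate import CATEGORY_ORDER, ReferenceBundle

__all__ = ["Assignment", "AnnotationTable", "cascade_assign", "class_fractions"]


@dataclass(frozen=True)
class Assignment:
    """The single category (and representative reference hit) chosen for a read."""

    read_id: str
    category: str
    hit: MatchHit | None  # None for the genome-gated intergenic tier


@dataclass(frozen=True)
class AnnotationTable:
    """Per-sample read counts across the six mutually exclusive categories.

    ``sublabels`` breaks the ncRNA tier down into tRNA/rRNA/miscRNA by
    reference-id prefix; ``unmatched`` counts reads that matched nothing
    (including the genome) and sit outside the six categories.
    """

    sample_id: str
    counts: Mapping[str, int]
    total_matched: int
    sublabels: Mapping[str, int] = field(default_factory=dict)
    unmatched: int = 0

    def __post_init__(self) -> None:
        if tuple(self.counts.keys()) != CATEGORY_ORDER:
            raise ValueError(f"categories must be exactly {CATEGORY_ORDER}")
        if sum(self.counts.values()) != self.total_matched:
            raise ValueError("category counts must sum to total_matched")


class CascadeIndex:
    """Pre-built per-tier match indexes for one reference bundle."""

    def __init__(self, bundle: ReferenceBundle):
        self.bundle = bundle
        self.tier_indexes: list[tuple[str, ReferenceIndex | None]] = []
        for name, refs in bundle.categories:
            if name == "intergenic":
                continue
            self.tier_indexes.append((name, build_index(refs) if refs else None))
        self.genome_index = (
            build_index([("genome", bundle.genome)]) if bundle.genome else None
        )
        intergenic_refs = bundle.category_refs("intergenic")
        self.intergenic_index = build_index(intergenic_refs) if intergenic_refs else None


def cascade_assign(
    reads: Iterable[TrimmedRead],
    bundle: ReferenceBundle | CascadeIndex,
    sample_id: str = "",
    max_mismatches: int = 1,
) -> tuple[AnnotationTable, dict[str, Assignment]]:
    """Assign every read to exactly one of the six ordered categories.

    A read with hits in several references of one tier is counted once for
    that tier; its representative reference is the hit with the fewest
    mismatches (0-mismatch beats 1-mismatch), ties broken by lexicographic
    reference id, then smallest offset, then plus strand.
    """
    idx = bundle if isinstance(bundle, CascadeIndex) else CascadeIndex(bundle)
    counts = {name: 0 for name in CATEGORY_ORDER}
    sublabels: dict[str, int] = {}
    assignments: dict[str, Assignment] = {}
    unmatched = 0
    for read in reads:
        assigned = False
        for name, tier_index in idx.tier_indexes:
            if tier_index is None:
                continue
            hits = tier_index.find(read.sequence, max_mismatches, read_id=read.id)
            if hits:
                rep = best_hit(hits)
                counts[name] += 1
                assignments[read.id] = Assignment(read.id, name, rep)
                if name == "ncRNA":
                    label = rep.ref_id.split("-")[0]
                    sublabels[label] = sublabels.get(label, 0) + 1
                assigned = True
                break
        if assigned:
            continue
        # exhausted the five sequence tiers: intergenic iff genome-matched
        gate = idx.genome_index or idx.intergenic_index
        if gate is not None and gate.find(read.sequence, max_mismatches, read_id=read.id):
            counts["intergenic"] += 1
            assignments[read.id] = Assignment(read.id, "intergenic", None)
        else:
            unmatched += 1
    table = AnnotationTable(
        sample_id=sample_id,
        counts=counts,
        total_matched=sum(counts.values()),
        sublabels=sublabels,
        unmatched=unmatched,
    )
    return table, assignments


def class_fractions(table: AnnotationTable) -> dict[str, float]:
    """Fraction of matched reads per category; fractions sum to 1."""
    if table.total_matched <= 0:
        raise ValueError("class fractions are undefined for an empty table")
    return {name: c / table.total_matched for name, c in table.counts.items()}
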