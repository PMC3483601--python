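"""Read preprocessing: adapter trimming, length filtering and 0/1-mismatch matching.

Small-RNA libraries are sequenced through the insert into the 3' sequencing
adapter, so the first preprocessing step is to locate the adapter (fully, or a
truncated prefix of it at the read's 3' end) and clip the read there.  Reads
longer than a strict length threshold (default: >18 nt) are then matched
against reference sequence sets on both strands, tolerating at most one
substitution -- the equivalent of a ``bowtie -v1`` search, implemented here
directly with a pigeonhole (two exact half-seed) strategy so no external
aligner is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "RawRead",
    "TrimmedRead",
    "MatchHit",
    "ReferenceIndex",
    "revcomp",
    "trim_adapter",
    "filter_by_length",
    "build_index",
    "find_matches",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_READ = frozenset("ACGTN")
_VALID_REF = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """A FASTQ record: identifier, sequence and (opaque) quality string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass(frozen=True)
class TrimmedRead:
    """An adapter-clipped read with provenance to its raw record.

    ``sequence`` is always a prefix of the raw sequence; ``trimmed`` records
    whether an adapter (full or truncated) was found and removed.
    """

    id: str
    sequence: str
    trimmed: bool
    original_length: int


@dataclass(frozen=True, order=True)
class MatchHit:
    """One placement of a query on a reference at Hamming distance <= 1.

    ``offset`` is the 0-based start of the placement on the plus strand of the
    reference; a minus-strand hit means the reverse complement of the query
    matches the reference at that interval.  ``length`` is the query length,
    so the footprint is the half-open interval [offset, offset + length).
    """

    read_id: str
    ref_id: str
    offset: int
    strand: str
    mismatches: int
    length: int


def trim_adapter(read: RawRead, adapter: str, min_overlap: int = 5) -> TrimmedRead:
    """Clip ``read`` at the first occurrence of ``adapter``.

    If the full adapter is absent, the longest adapter *prefix* of length >=
    ``min_overlap`` occurring as a *suffix* of the read is clipped instead
    (the truncated-adapter case of inserts whose insert+adapter exceeds the
    read length).  Otherwise the read is returned unchanged with
    ``trimmed=False``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.sequence
    if not set(seq) <= _VALID_READ:
        raise ValueError(f"read {read.id!r} contains non-ACGTN symbols")

    pos = seq.find(adapter)
    if pos >= 0:
        return TrimmedRead(read.id, seq[:pos], True, len(seq))
    # truncated adapter at the 3' end: longest qualifying overlap wins
    max_ov = min(len(adapter) - 1, len(seq))
    for ov in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return TrimmedRead(read.id, seq[: len(seq) - ov], True, len(seq))
    return TrimmedRead(read.id, seq, False, len(seq))


def filter_by_length(
    reads: Iterable[TrimmedRead], min_exclusive: int = 18
) -> list[TrimmedRead]:
    """Retain reads strictly longer than ``min_exclusive`` nt, preserving order."""
    if min_exclusive < 0:
        raise ValueError("min_exclusive must be >= 0")
    return [r for r in reads if len(r.sequence) > min_exclusive]


def _hamming_le(a: str, b: str, cap: int) -> int:
    """Hamming distance between equal-length strings, or cap+1 once exceeded.

    An N in either string never counts as a match.
    """
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
            if d > cap:
                return d
    return d


def _exact_starts(text: str, pattern: str) -> Iterator[int]:
    start = text.find(pattern)
    while start >= 0:
        yield start
        start = text.find(pattern, start + 1)


class ReferenceIndex:
    """Both-strand 0/1-mismatch search over a set of reference sequences.

    Strategy: a query with at most one mismatch against a reference window
    must match one of its two halves exactly (pigeonhole), so exact
    occurrences of each half seed propose candidate offsets which are then
    verified by a capped Hamming scan.  Queries containing N fall back to a
    direct scan of all offsets.
    """

    def __init__(self, refs: Sequence[tuple[str, str]]):
        seen: set[str] = set()
        self._refs: list[tuple[str, str]] = []
        for ref_id, seq in refs:
            if not seq:
                raise ValueError(f"reference {ref_id!r} has an empty sequence")
            if ref_id in seen:
                raise ValueError(f"duplicate reference id {ref_id!r}")
            seen.add(ref_id)
            self._refs.append((ref_id, seq.upper()))

    @property
    def ref_ids(self) -> list[str]:
        return [rid for rid, _ in self._refs]

    def _candidates(self, ref_seq: str, query: str, max_mm: int) -> Iterator[int]:
        m = len(query)
        if "N" in query:
            yield from range(len(ref_seq) - m + 1)
            return
        if max_mm == 0:
            yield from _exact_starts(ref_seq, query)
            return
        half = m // 2
        if half == 0:  # 1-nt query: every offset is a candidate
            yield from range(len(ref_seq) - m + 1)
            return
        cand: set[int] = set()
        for start in _exact_starts(ref_seq, query[:half]):
            cand.add(start)
        for start in _exact_starts(ref_seq, query[half:]):
            cand.add(start - half)
        yield from sorted(c for c in cand if 0 <= c <= len(ref_seq) - m)

    def find(
        self, query: str, max_mismatches: int = 1, read_id: str = ""
    ) -> set[MatchHit]:
        if max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        if len(query) < 1:
            raise ValueError("query must be non-empty")
        query = query.upper()
        m = len(query)
        hits: set[MatchHit] = set()
        for strand, q in (("+", query), ("-", revcomp(query))):
            for ref_id, ref_seq in self._refs:
                if m > len(ref_seq):
                    continue
                for off in self._candidates(ref_seq, q, max_mismatches):
                    d = _hamming_le(q, ref_seq[off : off + m], max_mismatches)
                    if d <= max_mismatches:
                        hits.add(MatchHit(read_id, ref_id, off, strand, d, m))
        return hits


def build_index(refs: Sequence[tuple[str, str]]) -> ReferenceIndex:
    """Build a both-strand 0/1-mismatch search index over ``refs``."""
    return ReferenceIndex(refs)


def find_matches(
    query: str,
    index: ReferenceIndex,
    max_mismatches: int = 1,
    read_id: str = "",
) -> set[MatchHit]:
    """All placements of ``query`` on either strand at Hamming distance <= ``max_mismatches``."""
    return index.find(query, max_mismatches=max_mismatches, read_id=read_id)


def best_hit(hits: Iterable[MatchHit]) -> MatchHit | None:
    """Deterministic representative hit: fewest mismatches, then lexicographic
    reference id, then smallest offset, then plus strand."""
    return min(
        hits,
        key=lambda h: (h.mismatches, h.ref_id, h.offset, h.strand != "+"),
        default=None,
    )
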