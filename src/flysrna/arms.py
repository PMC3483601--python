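"""Stem-loop 5p/3p arm assignment by optimal split position.

Reads mapped to a miRNA precursor are partitioned into the two mature arms by
trying every split position within 20 nt of the hairpin midpoint: reads ending
at or before the split are upstream (5p), reads starting at or after it are
downstream (3p), and reads spanning the split are discarded.  The split
retained is the one whose upstream+downstream total is nearest the total read
count (equivalently, the one discarding fewest reads), which assigns 5p/3p
counts without relying on external mature-arm annotations.  When reads tile
the whole precursor the partition is arbitrary but the 5p+3p total still
reflects precursor expression.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .preprocess import MatchHit

__all__ = [
    "StemLoopProfile",
    "SplitResult",
    "profile_stemloop",
    "choose_split",
    "arm_count_matrix",
]


@dataclass(frozen=True)
class StemLoopProfile:
    """Read alignment intervals (0-based half-open) on one stem-loop."""

    stemloop_id: str
    length: int
    alignments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for start, end in self.alignments:
            if not 0 <= start < end <= self.length:
                raise ValueError(
                    f"stem-loop {self.stemloop_id!r}: interval [{start},{end}) "
                    f"outside [0,{self.length})"
                )

    @property
    def total(self) -> int:
        return len(self.alignments)


@dataclass(frozen=True)
class SplitResult:
    """Chosen split position and the resulting 5p/3p/discarded partition."""

    stemloop_id: str
    split: int
    upstream: int
    downstream: int
    discarded: int

    @property
    def count5p(self) -> int:
        return self.upstream

    @property
    def count3p(self) -> int:
        return self.downstream


def profile_stemloop(
    hits: Iterable[MatchHit], stemloop_id: str, length: int
) -> StemLoopProfile:
    """Build the interval profile for one stem-loop from its retained hits.

    Hits are deduplicated by read id (fewest mismatches, then smallest offset,
    then plus strand), so a read contributes exactly one interval; minus-strand
    hits enter as their footprint interval on the stem-loop.
    """
    best: dict[str, MatchHit] = {}
    for h in hits:
        if h.ref_id != stemloop_id:
            raise ValueError(f"hit on {h.ref_id!r} passed to profile of {stemloop_id!r}")
        if h.offset + h.length > length:
            raise ValueError(
                f"hit [{h.offset},{h.offset + h.length}) exceeds stem-loop length {length}"
            )
        key = (h.mismatches, h.offset, h.strand != "+")
        prev = best.get(h.read_id)
        if prev is None or key < (prev.mismatches, prev.offset, prev.strand != "+"):
            best[h.read_id] = h
    intervals = tuple(
        sorted((h.offset, h.offset + h.length) for h in best.values())
    )
    return StemLoopProfile(stemloop_id, length, intervals)


def choose_split(profile: StemLoopProfile, window: int = 20) -> SplitResult:
    """Pick the split position maximizing upstream+downstream reads.

    Candidate splits are the integers within ``window`` of the midpoint
    (clipped into [1, L-1]).  For a split s, upstream counts intervals with
    end <= s and downstream those with start >= s; since upstream+downstream
    can never exceed the total, maximizing it is the same as bringing it
    nearest the total.  Ties are broken by smallest |s - midpoint|, then
    smaller s, so an empty profile yields the midpoint.
    """
    mid = profile.length // 2
    lo = max(1, mid - window)
    hi = min(profile.length - 1, mid + window)
    if lo > hi:  # degenerate, extremely short reference
        lo = hi = mid
    starts = sorted(start for start, _ in profile.alignments)
    ends = sorted(end for _, end in profile.alignments)
    total = profile.total
    best: tuple[int, int, int] | None = None  # (-(U+D), |s-mid|, s)
    best_ud: tuple[int, int] = (0, 0)
    for s in range(lo, hi + 1):
        upstream = bisect_right(ends, s)
        downstream = total - bisect_left(starts, s)
        key = (-(upstream + downstream), abs(s - mid), s)
        if best is None or key < best:
            best = key
            best_ud = (upstream, downstream)
    assert best is not None
    s = best[2]
    upstream, downstream = best_ud
    return SplitResult(
        stemloop_id=profile.stemloop_id,
        split=s,
        upstream=upstream,
        downstream=downstream,
        discarded=total - upstream - downstream,
    )


def arm_count_matrix(
    profiles: Mapping[str, Sequence[StemLoopProfile]], window: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the <stemloop>_5p / <stemloop>_3p x sample count matrix.

    ``profiles`` maps sample id -> profiles for that sample.  Stem-loops
    missing in a sample contribute zero counts.  Returns the count matrix and
    a per-(stem-loop, sample) split diagnostics table (split position,
    upstream, downstream, discarded).
    """
    samples = list(profiles.keys())
    stemloop_ids = sorted({p.stemloop_id for ps in profiles.values() for p in ps})
    rows = []
    for sl in stemloop_ids:
        rows.extend([f"{sl}_5p", f"{sl}_3p"])
    matrix = pd.DataFrame(0, index=rows, columns=samples, dtype=int)
    diag_rows = []
    for sample, plist in profiles.items():
        for p in plist:
            res = choose_split(p, window=window)
            matrix.at[f"{p.stemloop_id}_5p", sample] = res.count5p
            matrix.at[f"{p.stemloop_id}_3p", sample] = res.count3p
            diag_rows.append(
                {
                    "stemloop_id": p.stemloop_id,
                    "sample_id": sample,
                    "split": res.split,
                    "upstream": res.upstream,
                    "downstream": res.downstream,
                    "discarded": res.discarded,
                }
            )
    diagnostics = pd.DataFrame(
        diag_rows,
        columns=["stemloop_id", "sample_id", "split", "upstream", "downstream", "discarded"],
    )
    return matrix, diagnostics
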