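"""Detection of small CAG-repeat RNAs (sCAG) against polyQ transgenes.

Trimmed reads (down to 15 nt, i.e. below the >18 nt cascade threshold) are
aligned to the disease transgene on both strands with an edit model of
substitutions plus single-nucleotide read insertions -- no deletions --
keeping, per read, the best placement with at most ``max_edits`` (default 2)
edits.  Hits are summarized per sample into transgene / repeat-region counts,
perfect-match counts, and reads/kb densities; the repeat length used for the
density is end - start of the printed 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .preprocess import TrimmedRead, revcomp

__all__ = [
    "RepeatRegion",
    "ScagHit",
    "ScagReport",
    "align_to_transgene",
    "scag_summary",
]


@dataclass(frozen=True)
class RepeatRegion:
    """The declared repeat tract of a transgene, in printed 1-based coordinates."""

    transgene_id: str
    start: int
    end: int
    unit: str = "CAG"

    def __post_init__(self) -> None:
        if not 1 <= self.start < self.end:
            raise ValueError("repeat region must satisfy 1 <= start < end")

    @property
    def density_length(self) -> int:
        # end - start (not end - start + 1): the convention that reproduces
        # the printed reads/kb values.
        return self.end - self.start


@dataclass(frozen=True)
class ScagHit:
    """Best placement of one read on the transgene."""

    read_id: str
    position: int  # 1-based leftmost coordinate of the alignment footprint
    strand: str
    sequence: str
    edits: int
    length: int
    in_repeat: bool


@dataclass(frozen=True)
class ScagReport:
    """Per-sample transgene scan summary (counts and nearest-rounded densities)."""

    n_in_transgene: int
    n_in_repeat: int
    n_in_repeat_perfect: int
    reads_per_kb_transgene: int
    reads_per_kb_repeat: int

    def __post_init__(self) -> None:
        if self.n_in_repeat > self.n_in_transgene:
            raise ValueError("repeat hits cannot exceed transgene hits")
        if self.n_in_repeat_perfect > self.n_in_repeat:
            raise ValueError("perfect repeat hits cannot exceed repeat hits")


def _best_placement(read: str, transgene: str) -> tuple[int, np.ndarray] | None:
    """Best edit count of ``read`` on ``transgene`` plus candidate 0-based starts.

    Semi-global dynamic program, free start and end on the transgene:
    dp[i][j] = fewest edits aligning read[:i] with the alignment consuming the
    transgene up to position j.  Transitions consume both (match cost 0,
    substitution cost 1) or the read only (insertion, cost 1); deletions from
    the read are not allowed.  Returns the minimum edit count together with
    the (deduplicated, sorted) footprint starts of the optimal placements --
    inside a trinucleotide repeat many placements tie, so the caller applies
    the tie-break policy.
    """
    m, n = len(read), len(transgene)
    if n == 0:
        raise ValueError("empty transgene sequence")
    if m == 0:
        return None
    t = np.frombuffer(transgene.encode(), dtype=np.uint8)
    prev = np.zeros(n + 1, dtype=np.int32)
    pstart = np.arange(n + 1, dtype=np.int32)  # footprint start before consuming t[j]
    for i in range(1, m + 1):
        r = ord(read[i - 1])
        mism = (t != r).astype(np.int32)
        diag = prev[:-1] + mism
        up = prev[1:] + 1
        cur = np.empty(n + 1, dtype=np.int32)
        cstart = np.empty(n + 1, dtype=np.int32)
        cur[0] = prev[0] + 1
        cstart[0] = pstart[0]
        take_diag = diag < up
        tie = diag == up
        cur[1:] = np.minimum(diag, up)
        cstart[1:] = np.where(
            take_diag,
            pstart[:-1],
            np.where(tie, np.minimum(pstart[:-1], pstart[1:]), pstart[1:]),
        )
        prev, pstart = cur, cstart
    best = int(prev.min())
    starts = np.unique(pstart[prev == best])
    return best, starts


def align_to_transgene(
    reads: Iterable[TrimmedRead],
    transgene: str,
    region: RepeatRegion | None = None,
    max_edits: int = 2,
    min_len: int = 15,
) -> list[ScagHit]:
    """Best-per-read edit-tolerant placements of small reads on a transgene.

    For each read of length >= ``min_len``, both strands are aligned and the
    best placement kept; reads needing more than ``max_edits``
    substitutions+insertions yield no hit.  ``in_repeat`` is set iff the
    footprint start (1-based) falls inside the declared repeat region.
    Tie-break among equally good placements: a start inside the declared
    repeat region wins (ties are the norm inside a trinucleotide repeat, and
    the scan's purpose is attributing reads to it), then the leftmost start,
    then the plus strand.
    """
    if max_edits < 0 or min_len < 1:
        raise ValueError("max_edits must be >= 0 and min_len >= 1")
    if not transgene:
        raise ValueError("empty transgene sequence")
    transgene = transgene.upper()
    hits: list[ScagHit] = []
    for read in reads:
        seq = read.sequence.upper()
        if len(seq) < min_len:
            continue
        # (edits, not-in-region, start, strand-rank, strand) per optimal start
        candidates: list[tuple[int, int, int, int, str]] = []
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            placed = _best_placement(q, transgene)
            if placed is None:
                continue
            edits, starts = placed
            for start in starts:
                pos = int(start) + 1
                outside = 0 if (region and region.start <= pos <= region.end) else 1
                candidates.append(
                    (edits, outside, int(start), 0 if strand == "+" else 1, strand)
                )
        if not candidates:
            continue
        edits, _, start, _, strand = min(candidates)
        if edits > max_edits:
            continue
        position = start + 1
        in_repeat = bool(region and region.start <= position <= region.end)
        hits.append(
            ScagHit(
                read_id=read.id,
                position=position,
                strand=strand,
                sequence=seq,
                edits=edits,
                length=len(seq),
                in_repeat=in_repeat,
            )
        )
    return hits


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def scag_summary(
    hits: Sequence[ScagHit], region: RepeatRegion, transgene_length: int
) -> ScagReport:
    """Summarize one sample's transgene hits into the printed-table statistics.

    reads/kb = round(1000 * N / L) with L = end - start for the repeat region
    and L = the full transgene length for the transgene row; "perfect" means
    zero edits.
    """
    if transgene_length <= 0:
        raise ValueError("transgene length must be positive")
    n_tg = len(hits)
    repeat_hits = [h for h in hits if h.in_repeat]
    n_rep = len(repeat_hits)
    n_pm = sum(1 for h in repeat_hits if h.edits == 0)
    return ScagReport(
        n_in_transgene=n_tg,
        n_in_repeat=n_rep,
        n_in_repeat_perfect=n_pm,
        reads_per_kb_transgene=_round_half_up(1000.0 * n_tg / transgene_length),
        reads_per_kb_repeat=_round_half_up(1000.0 * n_rep / region.density_length),
    )
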