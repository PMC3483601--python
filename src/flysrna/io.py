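"""Reading and writing the pipeline's standard formats.

FASTQ/FASTA go through Biopython; tabular outputs (annotation tables, count
matrices, hit lists, sample sheets, truth sidecars) are plain TSV via pandas.
Internal coordinates are 0-based half-open; TSV exports convert offsets to
1-based inclusive to match printed tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import AnnotationTable
from .preprocess import MatchHit, RawRead, TrimmedRead
from .simulate import CATEGORY_ORDER, NCRNA_SUBLABELS, ReferenceBundle


def read_fastq(path: str | Path) -> list[RawRead]:
    return [
        RawRead(
            rec.id,
            str(rec.seq),
            "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_fasta(refs: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=ref_id, description="") for ref_id, seq in refs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_trimmed(reads: Iterable[TrimmedRead], path: str | Path) -> None:
    """Trimmed reads as FASTA (insert sequences only)."""
    write_fasta(((r.id, r.sequence) for r in reads if r.sequence), path)


def write_bundle(bundle: ReferenceBundle, directory: str | Path) -> None:
    """One multi-FASTA per category plus the genome and transgenes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta([("genome", bundle.genome)], directory / "genome.fa")
    for name, refs in bundle.categories:
        write_fasta(refs, directory / f"{name}.fa")
    if bundle.transgenes:
        write_fasta(
            [(t.id, t.sequence) for t in bundle.transgenes], directory / "transgenes.fa"
        )
        pd.DataFrame(
            [
                {"transgene_id": t.id, "repeat_start": t.repeat_start, "repeat_end": t.repeat_end}
                for t in bundle.transgenes
            ]
        ).to_csv(directory / "repeat_regions.tsv", sep="\t", index=False)


def write_hits(hits: Iterable[MatchHit], path: str | Path) -> None:
    """Match hits as TSV with 1-based offsets."""
    pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "ref_id": h.ref_id,
                "offset_1based": h.offset + 1,
                "strand": h.strand,
                "mismatches": h.mismatches,
            }
            for h in hits
        ],
        columns=["read_id", "ref_id", "offset_1based", "strand", "mismatches"],
    ).to_csv(path, sep="\t", index=False)


def annotation_frame(tables: Sequence[AnnotationTable]) -> pd.DataFrame:
    """One row per sample: the six category counts, ncRNA sub-labels, unmatched."""
    rows = []
    for t in tables:
        row: dict[str, object] = {"sample_id": t.sample_id}
        row.update({name: t.counts[name] for name in CATEGORY_ORDER})
        for label in NCRNA_SUBLABELS:
            row[f"ncRNA:{label}"] = t.sublabels.get(label, 0)
        row["total_matched"] = t.total_matched
        row["unmatched"] = t.unmatched
        rows.append(row)
    return pd.DataFrame(rows)


def write_sample_sheet(samples, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": s.id, "genotype": s.genotype, "condition": s.condition, "tissue": s.tissue}
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "condition", "tissue"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    return sheet
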