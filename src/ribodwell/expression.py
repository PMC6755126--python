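"""RNA-seq expression quantification (ORF-overlap counting and RPKM).

A read counts toward a transcript when its interval overlaps the ORF by at
least one nucleotide.  RPKM divides the count by transcript length (in kb)
and library size (in millions); the library size is the total reads mapped
to identified transcripts, excluding rRNA and tRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AlignmentSet, Annotation


@dataclass(frozen=True)
class ExpressionRecord:
    transcript_id: str
    count: int
    length: int
    rpkm: float


def count_orf_overlaps(reads: AlignmentSet, annotation: Annotation) -> dict[str, int]:
    """Count reads overlapping each coding transcript's ORF by >= 1 nt.

    Intervals are half-open: a read ending exactly at ``cds_start`` does not
    overlap.
    """
    tids = list(annotation.ids)
    cds_start = np.array([annotation[t].cds_start if annotation[t].is_coding else -1 for t in tids])
    cds_end = np.array([annotation[t].cds_end if annotation[t].is_coding else -1 for t in tids])

    counts = np.zeros(len(tids), dtype=np.int64)
    if len(reads):
        ridx = pd.Index(tids).get_indexer(reads.transcript_id)
        valid = ridx >= 0
        ridx = ridx[valid]
        reads = reads.subset(valid) if not valid.all() else reads
        overlaps = (cds_start[ridx] >= 0) \
            & (reads.start < cds_end[ridx]) \
            & (reads.start + reads.length > cds_start[ridx])
        np.add.at(counts, ridx[overlaps], 1)
    return {t: int(counts[i]) for i, t in enumerate(tids) if cds_start[i] >= 0}


def library_size(reads: AlignmentSet, annotation: Annotation) -> int:
    """Total reads mapped to identified transcripts, excluding rRNA/tRNA."""
    excluded = [t.id for t in annotation if t.biotype in ("rRNA", "tRNA")]
    if not excluded or not len(reads):
        return len(reads)
    return int((~np.isin(reads.transcript_id.astype(str), excluded)).sum())


def rpkm_table(counts: dict[str, int], annotation: Annotation, lib_size: int,
               use_orf_length: bool = False) -> list[ExpressionRecord]:
    """RPKM per transcript: ``count * 1e9 / (length_nt * lib_size)``.

    ``length_nt`` is the full transcript length by default (set
    ``use_orf_length=True`` to normalize by ORF length instead).
    """
    if lib_size <= 0:
        raise ValueError("library size is zero; cannot compute RPKM")
    out = []
    for tid, n in counts.items():
        t = annotation[tid]
        length = (t.cds_end - t.cds_start) if use_orf_length else len(t)
        out.append(ExpressionRecord(tid, n, length, n * 1e9 / (length * lib_size)))
    return out


def quantify(reads: AlignmentSet, annotation: Annotation,
             use_orf_length: bool = False) -> list[ExpressionRecord]:
    """ORF-overlap counting + RPKM in one call."""
    counts = count_orf_overlaps(reads, annotation)
    if not any(counts.values()):
        raise ValueError("no mRNA reads; cannot quantify expression")
    return rpkm_table(counts, annotation, library_size(reads, annotation),
                      use_orf_length=use_orf_length)


def expression_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_expression(records: list[ExpressionRecord], path: str | Path) -> None:
    expression_frame(records).to_csv(path, sep="\t", index=False)


def rpkm_lookup(records: list[ExpressionRecord]) -> dict[str, float]:
    return {r.transcript_id: r.rpkm for r in records}
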