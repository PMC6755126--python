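"""Ribosome-footprint processing: length filter, A-site assignment, profiles.

The decoding site of a ribosome-protected fragment (RPF) is taken as read
nucleotides 16–18 counting the 5'-most nucleotide as 1, i.e. 0-based read
offsets 15–17.  Only fragments of 28–32 nt are used, and only reads whose
A site lands in-frame inside an annotated CDS contribute to codon counts;
out-of-frame reads are excluded but tallied, and the in-frame fraction is
reported.  Library size counts qualifying reads on all identified transcripts
except rRNA/tRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import AlignedRead, AlignmentSet, Annotation, TranscriptModel

ASITE_OFFSET = 15  # 0-based read offset of the A site's first nucleotide
RPF_MIN_LENGTH = 28
RPF_MAX_LENGTH = 32


def filter_by_length(reads: AlignmentSet, min_length: int = RPF_MIN_LENGTH,
                     max_length: int = RPF_MAX_LENGTH) -> AlignmentSet:
    """Keep reads with ``min_length <= length <= max_length`` (inclusive)."""
    if min_length > max_length:
        raise ValueError(f"min_length {min_length} > max_length {max_length}")
    mask = (reads.length >= min_length) & (reads.length <= max_length)
    return reads.subset(mask, by_length=int((~mask).sum()))


class ASite(NamedTuple):
    """A-site classification of one read: CDS codon index, or None + reason."""

    codon_index: int | None
    reason: str  # in_frame | out_of_frame | outside_cds | noncoding


def asite_codon(read: AlignedRead, transcript: TranscriptModel,
                offset: int = ASITE_OFFSET) -> ASite:
    """Classify a read's A site against a transcript's CDS.

    The A site starts at transcript position ``read.start + offset``.  Returns
    the 0-based CDS codon index when that position is inside the CDS and on a
    codon boundary, otherwise None with the reason.
    """
    if read.length < offset + 3:
        raise ValueError(f"read of {read.length} nt cannot contain an A site at offset {offset}")
    if not transcript.is_coding:
        return ASite(None, "noncoding")
    pos = read.start + offset
    if not transcript.cds_start <= pos < transcript.cds_end:
        return ASite(None, "outside_cds")
    rel = pos - transcript.cds_start
    if rel % 3:
        return ASite(None, "out_of_frame")
    return ASite(rel // 3, "in_frame")


@dataclass
class FootprintProfile:
    """Per-transcript, per-codon A-site counts plus normalization bookkeeping.

    ``counts[tid]`` is indexed by CDS codon index (0 = start codon; the stop
    codon occupies the last slot).  ``library_size`` is the number of
    qualifying reads on identified transcripts excluding rRNA/tRNA, whether or
    not their A site is in-frame.
    """

    counts: dict[str, np.ndarray]
    library_size: int
    in_frame_fraction: float
    n_in_frame: int = 0
    n_dropped_out_of_frame: int = 0
    n_outside_cds: int = 0
    n_dropped_by_length: int = 0
    n_dropped_rrna_trna: int = 0
    normalized: bool = False

    def total_counts(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for tid, vec in self.counts.items():
            frames.append(pd.DataFrame({
                "transcript_id": tid,
                "codon_index": np.arange(len(vec)),
                "count": vec,
            }))
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path: str | Path, annotation: Annotation) -> None:
        """Write A-site codon occupancy as bedGraph in transcript coordinates."""
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="asite_occupancy"\n')
            for tid, vec in self.counts.items():
                cds_start = annotation[tid].cds_start
                for i in np.nonzero(vec)[0]:
                    s = cds_start + 3 * int(i)
                    fh.write(f"{tid}\t{s}\t{s + 3}\t{vec[i]:g}\n")


def build_profile(reads: AlignmentSet, annotation: Annotation,
                  offset: int = ASITE_OFFSET) -> FootprintProfile:
    """Accumulate in-frame A-site codon counts over all coding transcripts.

    Reads must already be length-filtered.  Vectorized: millions of reads are
    classified with array arithmetic, not per-read Python loops.
    """
    if len(reads) and int(reads.length.min()) < offset + 3:
        short = int(reads.length.min())
        raise ValueError(f"read of {short} nt cannot contain an A site at offset {offset}")

    tids = list(annotation.ids)
    n_codons = np.array([annotation[t].n_codons if annotation[t].is_coding else 0 for t in tids])
    cds_start = np.array([annotation[t].cds_start if annotation[t].is_coding else -1 for t in tids])
    cds_end = np.array([annotation[t].cds_end if annotation[t].is_coding else -1 for t in tids])
    is_excluded = np.array([annotation[t].biotype in ("rRNA", "tRNA") for t in tids])
    offsets = np.concatenate([[0], np.cumsum(n_codons)])

    if len(reads):
        ridx = pd.Index(tids).get_indexer(reads.transcript_id)
        if (ridx < 0).any():
            missing = set(reads.transcript_id[ridx < 0])
            raise KeyError(f"reads on transcripts absent from annotation: {sorted(missing)[:5]}")
    else:
        ridx = np.empty(0, dtype=np.int64)
    on_excluded = is_excluded[ridx] if len(reads) else np.empty(0, dtype=bool)
    library_size = int((~on_excluded).sum())
    n_rrna_trna = int(on_excluded.sum())

    keep = ~on_excluded
    ridx_k = ridx[keep]
    apos = reads.start[keep] + offset
    coding = cds_start[ridx_k] >= 0
    in_cds = coding & (apos >= cds_start[ridx_k]) & (apos < cds_end[ridx_k])
    rel = apos - cds_start[ridx_k]
    in_frame = in_cds & (rel % 3 == 0)
    out_of_frame = in_cds & ~in_frame

    n_in = int(in_frame.sum())
    n_out = int(out_of_frame.sum())
    n_outside = int((~in_cds).sum())
    frac = n_in / (n_in + n_out) if (n_in + n_out) else float("nan")

    flat = np.zeros(int(offsets[-1]), dtype=np.int64)
    if n_in:
        glob = offsets[ridx_k[in_frame]] + rel[in_frame] // 3
        np.add.at(flat, glob, 1)

    counts = {
        t: flat[offsets[i] : offsets[i + 1]].copy()
        for i, t in enumerate(tids)
        if n_codons[i] > 0
    }
    return FootprintProfile(
        counts=counts,
        library_size=library_size,
        in_frame_fraction=frac,
        n_in_frame=n_in,
        n_dropped_out_of_frame=n_out,
        n_outside_cds=n_outside,
        n_dropped_by_length=reads.dropped.get("by_length", 0),
        n_dropped_rrna_trna=n_rrna_trna,
    )


def rpm(profile: FootprintProfile) -> FootprintProfile:
    """Scale counts to reads per million mapped (library-size normalization)."""
    if profile.library_size <= 0:
        raise ValueError("library size is zero; cannot normalize")
    factor = 1e6 / profile.library_size
    return FootprintProfile(
        counts={t: v * factor for t, v in profile.counts.items()},
        library_size=profile.library_size,
        in_frame_fraction=profile.in_frame_fraction,
        n_in_frame=profile.n_in_frame,
        n_dropped_out_of_frame=profile.n_dropped_out_of_frame,
        n_outside_cds=profile.n_outside_cds,
        n_dropped_by_length=profile.n_dropped_by_length,
        n_dropped_rrna_trna=profile.n_dropped_rrna_trna,
        normalized=True,
    )
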