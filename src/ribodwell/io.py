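"""Input/output for sequences, annotation and alignments.

Coordinate conventions
----------------------
Everything internal is 0-based, half-open, on the transcript strand.
SAM's 1-based POS and the 1-based "read nucleotide 16" convention used in
ribosome-profiling A-site rules are converted at the boundary (read nt 16
becomes offset 15).  Sequences are stored DNA-alphabet, uppercase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import STANDARD_CODE, GeneticCode, reverse_complement

BIOTYPES = ("mRNA", "rRNA", "tRNA", "other")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an order-preserving ``{id: sequence}`` mapping.

    Sequences are uppercased and U is normalized to T.  Duplicate record
    identifiers raise; an empty file returns an empty mapping with a warning.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not out:
        warnings.warn(f"no records in FASTA {path}", stacklevel=2)
    return out


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Transcript models


@dataclass
class TranscriptModel:
    """One transcript on its own strand, with an optional CDS interval.

    ``cds_start``/``cds_end`` are 0-based half-open transcript coordinates and
    include the stop codon.  Non-coding biotypes (rRNA, tRNA, other) carry no
    CDS.  ``genome_seqid``/``genome_start``/``genome_strand`` record the
    single-exon genomic provenance when the model came from a genomic
    annotation, enabling genome→transcript interval projection.
    """

    id: str
    sequence: str
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "mRNA"
    genome_seqid: str | None = None
    genome_start: int | None = None
    genome_strand: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.is_coding:
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise ValueError(f"{self.id}: CDS [{self.cds_start}, {self.cds_end}) outside transcript")
            if (self.cds_end - self.cds_start) % 3:
                raise ValueError(f"{self.id}: CDS length not divisible by 3")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_sequence(self) -> str:
        if not self.is_coding:
            raise ValueError(f"{self.id} has no CDS")
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def n_codons(self) -> int:
        """Number of codons in the CDS, stop codon included."""
        return (self.cds_end - self.cds_start) // 3

    def codons(self) -> list[str]:
        cds = self.cds_sequence
        return [cds[i : i + 3] for i in range(0, len(cds), 3)]

    def is_complete(self, code: GeneticCode = STANDARD_CODE) -> bool:
        cds = self.cds_sequence
        return cds[:3] == "ATG" and code.translate_codon(cds[-3:]) == "*"


class Annotation:
    """An ordered collection of :class:`TranscriptModel`, indexed by id."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._by_id: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.id in self._by_id:
                raise ValueError(f"duplicate transcript id {t.id!r}")
            self._by_id[t.id] = t

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._by_id.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self._by_id

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self._by_id[tid]

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def coding(self) -> list[TranscriptModel]:
        return [t for t in self if t.biotype == "mRNA" and t.is_coding]

    def countable(self) -> list[TranscriptModel]:
        """Transcripts that enter the library size (everything but rRNA/tRNA)."""
        return [t for t in self if t.biotype not in ("rRNA", "tRNA")]


# ---------------------------------------------------------------------------
# Annotation readers/writers

_CODING_TYPES = {"mRNA": "mRNA", "transcript": "mRNA"}
_NONCODING_TYPES = {"rRNA": "rRNA", "tRNA": "tRNA", "ncRNA": "other"}


def _gff_attributes(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_annotation(path: str | Path, fasta: dict[str, str], code: GeneticCode = STANDARD_CODE) -> Annotation:
    """Read transcript models from GFF3 or BED12.

    ``fasta`` keys are GFF seqids (genomic contigs or transcript ids) or
    BED chroms.  Minus-strand features are reverse-complemented so the
    returned models are always transcript-strand.  Records whose CDS length
    is not divisible by 3 are excluded with a warning; a CDS extending past
    its transcript is an error.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path, fasta)
    return _read_gff3(path, fasta, code)


def _read_gff3(path: Path, fasta: dict[str, str], code: GeneticCode) -> Annotation:
    parents: list[dict] = []  # transcript-level features, in file order
    cds_by_parent: dict[str, list[tuple[int, int]]] = {}
    for line in open(path):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        seqid, _, ftype, start, end, _, strand, _, attrs = f[:9]
        start0, end0 = int(start) - 1, int(end)
        a = _gff_attributes(attrs)
        if ftype in _CODING_TYPES or ftype in _NONCODING_TYPES:
            fid = a.get("ID") or a.get("Name")
            if fid is None:
                raise ValueError(f"{ftype} feature without ID at {seqid}:{start}")
            biotype = _CODING_TYPES.get(ftype) or _NONCODING_TYPES[ftype]
            parents.append(
                dict(id=fid, seqid=seqid, start=start0, end=end0, strand=strand, biotype=biotype)
            )
        elif ftype == "CDS":
            parent = a.get("Parent") or a.get("ID")
            if parent is None:
                raise ValueError(f"CDS without Parent at {seqid}:{start}")
            cds_by_parent.setdefault(parent, []).append((start0, end0))

    models: list[TranscriptModel] = []
    for p in parents:
        if p["seqid"] not in fasta:
            raise ValueError(f"seqid {p['seqid']!r} not in FASTA")
        contig = fasta[p["seqid"]]
        if p["end"] > len(contig):
            raise ValueError(f"{p['id']}: feature extends past sequence {p['seqid']}")
        seq = contig[p["start"] : p["end"]]
        minus = p["strand"] == "-"
        if minus:
            seq = reverse_complement(seq)
        cds_start = cds_end = None
        if p["id"] in cds_by_parent:
            segs = sorted(cds_by_parent[p["id"]])
            g_lo, g_hi = segs[0][0], segs[-1][1]
            if sum(e - s for s, e in segs) != g_hi - g_lo:
                raise ValueError(f"{p['id']}: non-contiguous CDS segments (spliced CDS unsupported)")
            if g_lo < p["start"] or g_hi > p["end"]:
                raise ValueError(f"{p['id']}: CDS extends past transcript")
            if minus:
                cds_start, cds_end = p["end"] - g_hi, p["end"] - g_lo
            else:
                cds_start, cds_end = g_lo - p["start"], g_hi - p["start"]
            if (cds_end - cds_start) % 3:
                warnings.warn(f"{p['id']}: CDS length not divisible by 3; record excluded", stacklevel=2)
                continue
        models.append(
            TranscriptModel(
                id=p["id"],
                sequence=seq,
                cds_start=cds_start,
                cds_end=cds_end,
                biotype=p["biotype"],
                genome_seqid=p["seqid"],
                genome_start=p["start"],
                genome_strand=p["strand"],
            )
        )
    return Annotation(models)


def _read_bed12(path: Path, fasta: dict[str, str]) -> Annotation:
    models = []
    for line in open(path):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise ValueError("BED12 requires 12 columns")
        chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        thick_s, thick_e, _, block_count = int(f[6]), int(f[7]), f[8], int(f[9])
        if block_count != 1:
            raise ValueError(f"{name}: multi-block BED12 (splicing) unsupported")
        if chrom not in fasta:
            raise ValueError(f"chrom {chrom!r} not in FASTA")
        seq = fasta[chrom][start:end]
        minus = strand == "-"
        if minus:
            seq = reverse_complement(seq)
        cds_start = cds_end = None
        if thick_e > thick_s:
            if minus:
                cds_start, cds_end = end - thick_e, end - thick_s
            else:
                cds_start, cds_end = thick_s - start, thick_e - start
            if (cds_end - cds_start) % 3:
                warnings.warn(f"{name}: CDS length not divisible by 3; record excluded", stacklevel=2)
                continue
        models.append(
            TranscriptModel(
                id=name, sequence=seq, cds_start=cds_start, cds_end=cds_end,
                biotype="mRNA" if cds_start is not None else "other",
                genome_seqid=chrom, genome_start=start, genome_strand=strand,
            )
        )
    return Annotation(models)


def write_annotation(gff_path: str | Path, fasta_path: str | Path, annotation: Annotation) -> None:
    """Write transcript-space GFF3 + FASTA (seqid = transcript id, strand +)."""
    type_for = {"mRNA": "mRNA", "rRNA": "rRNA", "tRNA": "tRNA", "other": "ncRNA"}
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for t in annotation:
            gff.write(
                f"{t.id}\tribodwell\t{type_for[t.biotype]}\t1\t{len(t)}\t.\t+\t.\tID={t.id}\n"
            )
            if t.is_coding:
                gff.write(
                    f"{t.id}\tribodwell\tCDS\t{t.cds_start + 1}\t{t.cds_end}\t.\t+\t0\t"
                    f"ID={t.id}.cds;Parent={t.id}\n"
                )
    write_fasta(fasta_path, {t.id: t.sequence for t in annotation})


def project_genome_interval(annotation: Annotation, seqid: str, start: int, end: int
                            ) -> list[tuple[str, int, int]]:
    """Project a genomic interval (0-based half-open) onto transcript coordinates.

    Returns (transcript_id, start, end) for every single-exon transcript that
    fully contains the interval.  Spliced projection is out of scope.
    """
    hits = []
    for t in annotation:
        if t.genome_seqid != seqid or t.genome_start is None:
            continue
        g_lo, g_hi = t.genome_start, t.genome_start + len(t)
        if start < g_lo or end > g_hi:
            continue
        if t.genome_strand == "-":
            hits.append((t.id, g_hi - end, g_hi - start))
        else:
            hits.append((t.id, start - g_lo, end - g_lo))
    return hits


# ---------------------------------------------------------------------------
# Alignments


class AlignedRead(NamedTuple):
    """One single-segment read in transcript coordinates (0-based start)."""

    transcript_id: str
    start: int
    length: int


@dataclass
class AlignmentSet:
    """A column-oriented set of transcript-space alignments.

    Backed by numpy arrays so that profile building and counting stay
    vectorized at millions of reads.  Iteration yields :class:`AlignedRead`.
    ``dropped`` tallies records removed while reading (secondary/supplementary,
    unmapped, reverse-strand, unknown reference).
    """

    transcript_id: np.ndarray  # dtype object/str
    start: np.ndarray  # int64
    length: np.ndarray  # int64
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transcript_id = np.asarray(self.transcript_id, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.int64)
        if not (len(self.transcript_id) == len(self.start) == len(self.length)):
            raise ValueError("column lengths differ")

    @classmethod
    def from_reads(cls, reads: Iterable[AlignedRead]) -> "AlignmentSet":
        reads = list(reads)
        return cls(
            np.array([r.transcript_id for r in reads], dtype=object),
            np.array([r.start for r in reads], dtype=np.int64),
            np.array([r.length for r in reads], dtype=np.int64),
        )

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[AlignedRead]:
        for tid, s, ln in zip(self.transcript_id, self.start, self.length):
            yield AlignedRead(str(tid), int(s), int(ln))

    def subset(self, mask: np.ndarray, **extra_dropped: int) -> "AlignmentSet":
        dropped = dict(self.dropped)
        for k, v in extra_dropped.items():
            dropped[k] = dropped.get(k, 0) + v
        return AlignmentSet(self.transcript_id[mask], self.start[mask], self.length[mask], dropped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"transcript_id": self.transcript_id, "start": self.start, "length": self.length}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_alignments(path: str | Path, annotation: Annotation) -> AlignmentSet:
    """Read SAM/BAM or 3-column TSV (``transcript<TAB>start0<TAB>length``).

    SAM/BAM records that are secondary, supplementary, unmapped or aligned to
    the reverse strand of a transcript are dropped (footprint libraries are
    sense-strand in transcript space); reads on references absent from the
    annotation are dropped and counted.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam"):
        return _read_sam(path, annotation)
    return _read_tsv_alignments(path, annotation)


def _read_sam(path: Path, annotation: Annotation) -> AlignmentSet:
    tids, starts, lengths = [], [], []
    dropped = {"secondary_or_supplementary": 0, "unmapped": 0, "reverse_strand": 0, "unknown_reference": 0}
    save = pysam.set_verbosity(0)  # silence missing-index warning on SAM
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    dropped["unmapped"] += 1
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    dropped["secondary_or_supplementary"] += 1
                    continue
                if rec.is_reverse:
                    dropped["reverse_strand"] += 1
                    continue
                if rec.reference_name not in annotation:
                    dropped["unknown_reference"] += 1
                    continue
                tids.append(rec.reference_name)
                starts.append(rec.reference_start)
                lengths.append(rec.reference_length)
    finally:
        pysam.set_verbosity(save)
    out = AlignmentSet(np.array(tids, dtype=object), np.array(starts), np.array(lengths))
    out.dropped = {k: v for k, v in dropped.items() if v}
    return out


def _read_tsv_alignments(path: Path, annotation: Annotation) -> AlignmentSet:
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "start", "length"],
                     dtype={"transcript_id": str})
    known = df["transcript_id"].map(lambda t: t in annotation).to_numpy()
    n_unknown = int((~known).sum())
    df = df[known]
    out = AlignmentSet(
        df["transcript_id"].to_numpy(dtype=object),
        df["start"].to_numpy(np.int64),
        df["length"].to_numpy(np.int64),
    )
    if n_unknown:
        out.dropped = {"unknown_reference": n_unknown}
    return out


def write_sam(path: str | Path, reads: AlignmentSet, annotation: Annotation) -> None:
    """Write alignments as a minimal SAM file against transcript references."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t.id, "LN": len(t)} for t in annotation],
    }
    ref_index = {t.id: i for i, t in enumerate(annotation)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(sam.header)
            a.query_name = f"read{i}"
            a.reference_id = ref_index[r.transcript_id]
            a.reference_start = r.start
            a.flag = 0
            a.mapping_quality = 255
            a.cigarstring = f"{r.length}M"
            a.query_sequence = annotation[r.transcript_id].sequence[r.start : r.start + r.length]
            sam.write(a)
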