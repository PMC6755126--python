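"""End-to-end orchestration: reads + annotation in, codon statistics out.

``run_all`` wires the stages together — usage table, footprint profile,
RNA-seq quantification, decoding-time fit, family report, plot — and writes
a machine-readable manifest (parameters, seed, input checksums) alongside
the outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .decoding import DecodingTimeModel
from .expression import quantify, write_expression
from .footprints import build_profile, filter_by_length
from .io import Annotation, read_alignments, read_annotation, read_fasta
from .usage import CodonUsageTable, build_codon_usage


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.

    Defaults are the analysis' canonical values: RPF lengths 28-32 nt, A-site
    offset 15 (read nt 16), gene filter RPKM >= 1, instance filter >= 1 read,
    20 codons trimmed at each ORF end.
    """

    fasta: str = ""
    annotation: str = ""
    rpf_alignments: str = ""
    rnaseq_alignments: str = ""
    out_dir: str = "ribodwell_out"
    min_rpkm: float = 1.0
    min_reads: int = 1
    trim_codons: int = 20
    rpf_length_min: int = 28
    rpf_length_max: int = 32
    asite_offset: int = 15
    seed: int = 0
    usage_table: str = ""  # optional pre-built table; else built from the CDS set
    make_plot: bool = True

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Plain-text ``key = value`` config, overridable by keyword flags."""
        kwargs = {}
        for line in open(path):
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kwargs[key.strip()] = val.strip()
        for k, v in list(kwargs.items()):
            typ = cls.__dataclass_fields__[k].type
            if typ == "int":
                kwargs[k] = int(v)
            elif typ == "float":
                kwargs[k] = float(v)
            elif typ == "bool":
                kwargs[k] = v.lower() in ("1", "true", "yes")
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Any stage failure raises with a stage-named message; outputs are the
    usage table, per-codon profile, expression table, codon statistics,
    family report, per-family plot, and a JSON manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e

    fasta = stage("read_fasta", lambda: read_fasta(config.fasta))
    annotation = stage("read_annotation", lambda: read_annotation(config.annotation, fasta))

    if config.usage_table:
        usage = stage("usage_table", lambda: CodonUsageTable.from_tsv(config.usage_table))
    else:
        cds = {t.id: t.cds_sequence for t in annotation.coding()}
        usage = stage("usage_table", lambda: build_codon_usage(cds))
    usage.to_tsv(out / "codon_usage.tsv")

    rpf = stage("rpf_alignments", lambda: read_alignments(config.rpf_alignments, annotation))
    rpf = stage("length_filter", lambda: filter_by_length(
        rpf, config.rpf_length_min, config.rpf_length_max))
    profile = stage("profile", lambda: build_profile(rpf, annotation, offset=config.asite_offset))
    profile.to_tsv(out / "asite_counts.tsv")
    profile.to_bedgraph(out / "asite_occupancy.bedgraph", annotation)

    rna = stage("rnaseq_alignments", lambda: read_alignments(config.rnaseq_alignments, annotation))
    expression = stage("expression", lambda: quantify(rna, annotation))
    write_expression(expression, out / "expression.tsv")

    results = stage("decoding_time", lambda: DecodingTimeModel(
        profile, expression, annotation,
        min_rpkm=config.min_rpkm, min_reads=config.min_reads,
        trim_codons=config.trim_codons,
    ).fit())
    results.to_tsv(out / "codon_stats.tsv")

    reports = stage("family_analysis", lambda: results.family_analysis(usage))
    with open(out / "family_report.tsv", "w") as fh:
        fh.write("amino_acid\tcodon\tfamily_fraction\tcdt\trcdt\tn_instances\t"
                 "spearman_rho\tfastest_is_most_frequent\n")
        for rep in reports:
            for _, r in rep.table.iterrows():
                fh.write(f"{rep.amino_acid}\t{r.codon}\t{r.family_fraction:.6g}\t"
                         f"{r.cdt:.6g}\t{r.rcdt:.6g}\t{int(r.n_instances)}\t"
                         f"{rep.spearman_rho:.4g}\t{rep.fastest_is_most_frequent}\n")
    if config.make_plot:
        stage("plot", lambda: results.plot_families(usage, out / "family_panels.png"))

    manifest = {
        "tool": "ribodwell",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {
            k: {"path": p, "sha256": _sha256(p)}
            for k, p in [("fasta", config.fasta), ("annotation", config.annotation),
                         ("rpf_alignments", config.rpf_alignments),
                         ("rnaseq_alignments", config.rnaseq_alignments)]
            if p
        },
        "results": {
            "reference_codon": results.reference_codon,
            "in_frame_fraction": profile.in_frame_fraction,
            "rpf_library_size": profile.library_size,
            "n_codons_measured": len(results.cdt),
            "n_families_reported": len(reports),
            "n_families_fastest_is_most_frequent":
                sum(r.fastest_is_most_frequent for r in reports),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
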