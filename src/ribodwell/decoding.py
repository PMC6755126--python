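"""Per-codon decoding-time estimation from footprint and RNA-seq data.

The statistic
-------------
For every gene with RPKM >= 1, each codon instance that (a) has at least one
A-site footprint read and (b) lies outside the first and last 20 amino acids
of the ORF contributes the quotient

    RPM(instance) / RPKM(gene)

— footprint density corrected for mRNA abundance.  The codon decoding time
CDT(c) is the mean of these quotients over all eligible instances of codon c
genome-wide, and the relative codon decoding time RCDT(c) = CDT(c)/max CDT
rescales so the slowest (most occupied) codon scores 1.  Under steady-state
elongation, A-site density is proportional to how long the ribosome dwells on
a codon, so RCDT ranks codons by relative decoding speed.

:class:`DecodingTimeModel` packages the inputs and filters;
:meth:`DecodingTimeModel.fit` returns :class:`DecodingTimeResults` carrying
the per-codon table, the reference (slowest) codon, per-family usage-vs-RCDT
reports and plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionRecord, rpkm_lookup
from .footprints import FootprintProfile
from .genetics import STANDARD_CODE, GeneticCode
from .io import Annotation
from .usage import CodonUsageTable


@dataclass(frozen=True)
class CodonStatsRow:
    codon: str
    amino_acid: str
    cdt: float
    rcdt: float
    n_instances: int


@dataclass
class FamilyReport:
    """Usage-vs-RCDT comparison within one synonymous-codon family."""

    amino_acid: str
    table: pd.DataFrame  # codon, family_fraction, cdt, rcdt, n_instances
    spearman_rho: float  # nan when undefined (constant ranks)
    fastest_is_most_frequent: bool


class DecodingTimeModel:
    """Codon decoding-time estimator.

    Parameters
    ----------
    profile
        Raw (un-normalized) A-site codon counts from :func:`build_profile`.
    expression
        RNA-seq :class:`ExpressionRecord` list from :func:`quantify`.
    annotation
        Transcript models shared by both inputs.
    min_rpkm, min_reads, trim_codons
        Eligibility filters: gene RPKM >= ``min_rpkm``; instance A-site count
        >= ``min_reads``; codon index within ``[trim_codons, n_sense -
        trim_codons)`` where ``n_sense`` counts sense codons from the start
        codon (stop excluded).
    denominator
        ``"per_codon"`` divides each codon's quotient sum by that codon's own
        instance count (a mean decoding time); ``"global"`` divides every sum
        by the grand total of eligible instances.
    """

    def __init__(
        self,
        profile: FootprintProfile,
        expression: list[ExpressionRecord],
        annotation: Annotation,
        code: GeneticCode = STANDARD_CODE,
        min_rpkm: float = 1.0,
        min_reads: int = 1,
        trim_codons: int = 20,
        denominator: str = "per_codon",
    ):
        if profile.normalized:
            raise ValueError("pass the raw-count profile; RPM scaling is internal")
        if denominator not in ("per_codon", "global"):
            raise ValueError(f"unknown denominator mode {denominator!r}")
        self.profile = profile
        self.expression = expression
        self.annotation = annotation
        self.code = code
        self.min_rpkm = min_rpkm
        self.min_reads = min_reads
        self.trim_codons = trim_codons
        self.denominator = denominator

    def fit(self) -> "DecodingTimeResults":
        code = self.code
        codon_id = {c: i for i, c in enumerate(sorted(code.table))}
        sums = np.zeros(64)
        ns = np.zeros(64, dtype=np.int64)
        rpkms = rpkm_lookup(self.expression)
        lib = self.profile.library_size
        if lib <= 0:
            raise ValueError("profile library size is zero")

        for tid, counts in self.profile.counts.items():
            rpkm_g = rpkms.get(tid, 0.0)
            if rpkm_g < self.min_rpkm or rpkm_g == 0.0:
                continue
            t = self.annotation[tid]
            codons = t.codons()
            n = len(codons)
            n_sense = n - 1 if code.translate_codon(codons[-1]) == "*" else n
            lo, hi = self.trim_codons, n_sense - self.trim_codons
            if hi <= lo:
                continue
            cvec = np.array([codon_id[c] for c in codons[:n_sense]], dtype=np.int64)
            sense = np.array([code.table[c] != "*" for c in codons[:n_sense]])
            counts_s = counts[:n_sense]
            idx = np.arange(n_sense)
            elig = (counts_s >= self.min_reads) & (idx >= lo) & (idx < hi) & sense
            if not elig.any():
                continue
            quot = counts_s[elig] * (1e6 / lib) / rpkm_g
            np.add.at(sums, cvec[elig], quot)
            np.add.at(ns, cvec[elig], 1)

        id_codon = {i: c for c, i in codon_id.items()}
        measured = [i for i in range(64) if ns[i] > 0 and code.table[id_codon[i]] != "*"]
        if not measured:
            raise ValueError("no eligible codon instances under the current filters")
        missing = [id_codon[i] for i in range(64)
                   if ns[i] == 0 and code.table[id_codon[i]] != "*"]
        if missing:
            warnings.warn(f"no eligible instances for {len(missing)} codons: "
                          f"{', '.join(missing)}", stacklevel=2)

        denom = ns.astype(float) if self.denominator == "per_codon" \
            else np.full(64, float(ns[measured].sum()))
        cdt = {id_codon[i]: sums[i] / denom[i] for i in measured}
        return DecodingTimeResults(self, cdt, {id_codon[i]: int(ns[i]) for i in measured})


def normalize_rcdt(cdt: dict[str, float]) -> tuple[dict[str, float], str]:
    """Scale CDT to the highest-occupied codon; return (rcdt, reference codon).

    Ties for the maximum break lexicographically.
    """
    if not cdt:
        raise ValueError("empty CDT set")
    peak = max(cdt.values())
    if peak <= 0:
        raise ValueError("all CDT values are zero; cannot normalize")
    reference = min(c for c, v in cdt.items() if v == peak)
    return {c: v / peak for c, v in cdt.items()}, reference


class DecodingTimeResults:
    """Fitted per-codon decoding times with family-level diagnostics."""

    def __init__(self, model: DecodingTimeModel, cdt: dict[str, float], n_instances: dict[str, int]):
        self.model = model
        self.cdt = cdt
        self.n_instances = n_instances
        self.rcdt, self.reference_codon = normalize_rcdt(cdt)

    @property
    def codon_stats(self) -> pd.DataFrame:
        code = self.model.code
        rows = [
            dict(codon=c, amino_acid=code.table[c], cdt=self.cdt[c],
                 rcdt=self.rcdt[c], n_instances=self.n_instances[c])
            for c in sorted(self.cdt)
        ]
        return pd.DataFrame(rows)

    def rows(self) -> list[CodonStatsRow]:
        return [CodonStatsRow(**r) for r in self.codon_stats.to_dict("records")]

    def to_tsv(self, path: str | Path) -> None:
        self.codon_stats.to_csv(path, sep="\t", index=False)

    # -- family-level analysis -------------------------------------------

    def family_analysis(self, usage: CodonUsageTable) -> list[FamilyReport]:
        """Per-family comparison of usage fraction against RCDT.

        Families with fewer than two measured codons are skipped with a
        warning.  ``spearman_rho`` is NaN (undefined), not 0, when either
        variable is constant within the family.
        """
        code = self.model.code
        reports = []
        for aa, fam in sorted(code.multi_codon_families().items()):
            measured = [c for c in fam if c in self.rcdt]
            if len(measured) < 2:
                warnings.warn(f"family {aa}: fewer than 2 measured codons; skipped", stacklevel=2)
                continue
            frac = np.array([usage.family_fraction[c] for c in measured])
            rc = np.array([self.rcdt[c] for c in measured])
            if len(set(frac)) < 2 or len(set(rc)) < 2:
                rho = float("nan")
            else:
                rho = float(stats.spearmanr(frac, rc).statistic)
            fastest = measured[int(np.argmin(rc))]
            most_frequent = measured[int(np.argmax(frac))]
            reports.append(FamilyReport(
                amino_acid=aa,
                table=pd.DataFrame(dict(codon=measured, family_fraction=frac,
                                        cdt=[self.cdt[c] for c in measured], rcdt=rc,
                                        n_instances=[self.n_instances[c] for c in measured])),
                spearman_rho=rho,
                fastest_is_most_frequent=(fastest == most_frequent),
            ))
        return reports

    def genomewide_spearman(self, usage: CodonUsageTable) -> float:
        """Spearman correlation of relative adaptiveness w vs RCDT over all
        measured codons of multi-codon families."""
        code = self.model.code
        multi = {c for fam in code.multi_codon_families().values() for c in fam}
        codons = sorted(c for c in self.rcdt if c in multi)
        w = [usage.w[c] for c in codons]
        rc = [self.rcdt[c] for c in codons]
        return float(stats.spearmanr(w, rc).statistic)

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        df = self.codon_stats
        lines = [
            "Codon decoding-time estimates",
            "=" * 64,
            f"codons measured:        {len(df)} / 61 sense codons",
            f"reference (slowest):    {self.reference_codon} "
            f"({self.model.code.table[self.reference_codon]})",
            f"eligible instances:     {int(df['n_instances'].sum())}",
            f"filters: RPKM >= {self.model.min_rpkm}, reads >= {self.model.min_reads}, "
            f"trim {self.model.trim_codons} aa each end",
            "-" * 64,
            df.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)

    def plot_families(self, usage: CodonUsageTable, path: str | Path | None = None):
        """Per-family panel: bars = usage fraction (left axis), dots = RCDT
        (right axis)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        reports = self.family_analysis(usage)
        ncol = 6
        nrow = int(np.ceil(len(reports) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
        for ax in axes.flat[len(reports):]:
            ax.set_visible(False)
        for ax, rep in zip(axes.flat, reports):
            t = rep.table.sort_values("family_fraction", ascending=False)
            x = np.arange(len(t))
            ax.bar(x, t["family_fraction"], color="0.7")
            ax.set_ylim(0, 1)
            ax.set_xticks(x, t["codon"], rotation=90, fontsize=7)
            ax.set_title(rep.amino_acid, fontsize=9)
            ax2 = ax.twinx()
            ax2.plot(x, t["rcdt"], "ko", ms=4)
            ax2.set_ylim(0, 1.05)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def compute_cdt(
    profile: FootprintProfile,
    expression: list[ExpressionRecord],
    annotation: Annotation,
    code: GeneticCode = STANDARD_CODE,
    min_rpkm: float = 1.0,
    min_reads: int = 1,
    trim_codons: int = 20,
    denominator: str = "per_codon",
) -> DecodingTimeResults:
    """Functional one-shot wrapper around :class:`DecodingTimeModel`."""
    return DecodingTimeModel(profile, expression, annotation, code=code,
                             min_rpkm=min_rpkm, min_reads=min_reads,
                             trim_codons=trim_codons, denominator=denominator).fit()
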