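"""Codon usage tables and codon indices.

A :class:`CodonUsageTable` tallies in-frame codons over a reference CDS set
and derives, per sense codon: the within-family usage fraction, frequency per
thousand codons, and the relative adaptiveness w (count divided by the
family's maximum count).  The codon adaptation index (CAI) is the Sharp–Li
geometric mean of w over an ORF's codons, restricted to codons of families
with at least two synonyms (Met, Trp and stops are excluded from both the
product and the count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import STANDARD_CODE, GeneticCode

DEFAULT_ZERO_W_NUMERATOR = 0.5


@dataclass(frozen=True)
class CAIValue:
    """A codon adaptation index and the number of codons in its geometric mean."""

    value: float
    n_codons_used: int


class CodonUsageTable:
    """Per-codon usage statistics for one reference CDS set.

    Parameters
    ----------
    counts
        Mapping of sense codon -> non-negative count.  Stop-codon counts may
        be supplied via ``stop_counts``; they never enter family statistics.
    zero_w_numerator
        Zero-count codons receive w = zero_w_numerator / (max family count)
        so that log w stays finite in CAI.  Set to 0 to disable the floor.
    """

    def __init__(
        self,
        counts: dict[str, int],
        code: GeneticCode = STANDARD_CODE,
        stop_counts: dict[str, int] | None = None,
        zero_w_numerator: float = DEFAULT_ZERO_W_NUMERATOR,
    ):
        self.code = code
        self.counts = {c: 0 for c in code.sense_codons}
        for codon, n in counts.items():
            codon = codon.upper().replace("U", "T")
            if codon not in self.counts:
                raise ValueError(f"{codon!r} is not a sense codon")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            self.counts[codon] = int(n)
        self.stop_counts = dict(stop_counts or {})
        self.zero_w_numerator = zero_w_numerator

        total = sum(self.counts.values())
        self.family_fraction: dict[str, float] = {}
        self.per_thousand: dict[str, float] = {}
        self.w: dict[str, float] = {}
        for aa, fam in code.families().items():
            fam_total = sum(self.counts[c] for c in fam)
            fam_max = max(self.counts[c] for c in fam)
            for c in fam:
                self.family_fraction[c] = self.counts[c] / fam_total if fam_total else np.nan
                self.per_thousand[c] = self.counts[c] * 1000.0 / total if total else np.nan
                if fam_max == 0:
                    self.w[c] = 1.0  # unobserved family: uninformative
                elif self.counts[c] == 0:
                    self.w[c] = zero_w_numerator / fam_max
                else:
                    self.w[c] = self.counts[c] / fam_max

    # -- lookups ----------------------------------------------------------

    def family(self, amino_acid: str) -> tuple[str, ...]:
        return self.code.family(amino_acid)

    def preferred_codon(self, amino_acid: str) -> str:
        """The most-used synonym (argmax family fraction; ties lexicographic)."""
        fam = self.family(amino_acid)
        best = max(self.counts[c] for c in fam)
        return min(c for c in fam if self.counts[c] == best)

    def rarest_codon(self, amino_acid: str) -> str:
        """The least-used synonym (argmin family fraction; ties lexicographic)."""
        fam = self.family(amino_acid)
        worst = min(self.counts[c] for c in fam)
        return min(c for c in fam if self.counts[c] == worst)

    # -- table form -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                codon=c,
                amino_acid=self.code.table[c],
                count=self.counts[c],
                family_fraction=self.family_fraction[c],
                per_thousand=self.per_thousand[c],
                w=self.w[c],
            )
            for c in self.code.sense_codons
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, code: GeneticCode = STANDARD_CODE) -> "CodonUsageTable":
        """Read a usage table written by :meth:`to_tsv`, or a Kazusa-style
        table with columns ``codon`` and ``per_thousand`` (RNA codons allowed;
        fractional frequencies are rescaled to integer pseudo-counts)."""
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower().strip(): c for c in df.columns}
        codon_col = cols.get("codon")
        if codon_col is None:
            raise ValueError("usage table needs a 'codon' column")
        if "count" in cols:
            counts = dict(zip(df[codon_col], df[cols["count"]].astype(int)))
        elif "per_thousand" in cols or "frequency" in cols:
            freq_col = cols.get("per_thousand", cols.get("frequency"))
            scaled = (df[freq_col].astype(float) * 1000).round().astype(int)
            counts = dict(zip(df[codon_col], scaled))
        else:
            raise ValueError("usage table needs 'count' or 'per_thousand'")
        sense = {c: n for c, n in ((k.upper().replace("U", "T"), v) for k, v in counts.items())
                 if code.table.get(c, "*") != "*"}
        return cls(sense, code=code)


def build_codon_usage(
    cds_set: dict[str, str] | list[str],
    code: GeneticCode = STANDARD_CODE,
    zero_w_numerator: float = DEFAULT_ZERO_W_NUMERATOR,
) -> CodonUsageTable:
    """Tally every in-frame codon of every CDS into a usage table.

    Stop codons are tallied separately and excluded from family statistics;
    codons containing ambiguous bases are skipped.  A CDS with an internal
    stop is counted up to the stop and flagged with a warning.  An empty CDS
    set is an error.
    """
    if isinstance(cds_set, dict):
        items = list(cds_set.items())
    else:
        items = [(f"cds{i}", s) for i, s in enumerate(cds_set)]
    if not items:
        raise ValueError("empty CDS set")
    counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    for name, seq in items:
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"{name}: CDS length not divisible by 3")
        n_codons = len(seq) // 3
        for i in range(n_codons):
            codon = seq[3 * i : 3 * i + 3]
            aa = code.table.get(codon)
            if aa is None:
                continue  # ambiguous bases
            if aa == "*":
                stop_counts[codon] = stop_counts.get(codon, 0) + 1
                if i < n_codons - 1:
                    warnings.warn(f"{name}: internal stop at codon {i}; truncating tally", stacklevel=2)
                break
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(counts, code=code, stop_counts=stop_counts,
                           zero_w_numerator=zero_w_numerator)


def preferred_codon(table: CodonUsageTable, amino_acid: str) -> str:
    return table.preferred_codon(amino_acid)


def rarest_codon(table: CodonUsageTable, amino_acid: str) -> str:
    return table.rarest_codon(amino_acid)


def cai(orf: str, table: CodonUsageTable, code: GeneticCode | None = None) -> CAIValue:
    """Codon adaptation index of an ORF (Sharp–Li geometric mean of w).

    Only codons from families with two or more synonyms enter the mean;
    Met (ATG), Trp (TGG) and stop codons are excluded from both the product
    and the denominator.  Raises if no eligible codon remains.
    """
    code = code or table.code
    orf = orf.upper().replace("U", "T")
    if len(orf) % 3:
        raise ValueError("ORF length not divisible by 3")
    multi = {c for fam in code.multi_codon_families().values() for c in fam}
    log_sum = 0.0
    n = 0
    for i in range(0, len(orf), 3):
        codon = orf[i : i + 3]
        if codon in multi:
            log_sum += np.log(table.w[codon])
            n += 1
    if n == 0:
        raise ValueError("no codons from multi-codon families in ORF")
    return CAIValue(value=float(np.exp(log_sum / n)), n_codons_used=n)
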