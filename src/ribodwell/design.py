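"""Synonymous reporter-ORF manipulations.

Codon optimization/deoptimization replaces every codon beyond a preserved
N-terminal prefix with the most/least-used synonym from a reference usage
table; windowed deoptimization and single-codon substitutions target specific
amino-acid positions (1-based, matching the R213/S284-style naming used for
reporter constructs).  Every operation preserves the encoded protein unless
the explicit alanine-scan mode is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genetics import STANDARD_CODE, GeneticCode
from .usage import CodonUsageTable


@dataclass(frozen=True)
class DesignOutcome:
    """A designed sequence plus its audit trail of codon edits.

    ``edits`` holds (codon_index 0-based, old_codon, new_codon) in strictly
    increasing index order.
    """

    sequence: str
    edits: tuple[tuple[int, str, str], ...]

    def edits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edits, columns=["codon_index", "old_codon", "new_codon"])

    def edits_to_tsv(self, path: str | Path) -> None:
        self.edits_frame().to_csv(path, sep="\t", index=False)


def _codons_of(orf: str) -> list[str]:
    orf = orf.upper().replace("U", "T")
    if len(orf) % 3:
        raise ValueError("ORF length not divisible by 3")
    return [orf[i : i + 3] for i in range(0, len(orf), 3)]


def _check_no_internal_stop(codons: list[str], code: GeneticCode) -> bool:
    """Returns True if the final codon is a stop; raises on internal stops."""
    has_stop = code.translate_codon(codons[-1]) == "*"
    body = codons[:-1] if has_stop else codons
    for i, c in enumerate(body):
        if code.translate_codon(c) == "*":
            raise ValueError(f"internal stop codon {c} at codon index {i}")
    return has_stop


def _apply(codons: list[str], replacements: dict[int, str]) -> DesignOutcome:
    edits = []
    out = list(codons)
    for i in sorted(replacements):
        new = replacements[i]
        if new != codons[i]:
            edits.append((i, codons[i], new))
            out[i] = new
    return DesignOutcome(sequence="".join(out), edits=tuple(edits))


def _recode(orf: str, table: CodonUsageTable, preserve_first: int, pick) -> DesignOutcome:
    code = table.code
    codons = _codons_of(orf)
    if codons[0] != "ATG":
        raise ValueError("ORF must start with ATG")
    has_stop = _check_no_internal_stop(codons, code)
    n_sense = len(codons) - (1 if has_stop else 0)
    if preserve_first > n_sense:
        raise ValueError(f"preserve_first={preserve_first} exceeds ORF length ({n_sense} sense codons)")
    replacements = {
        i: pick(code.translate_codon(codons[i]))
        for i in range(preserve_first, n_sense)
    }
    return _apply(codons, replacements)


def optimize(orf: str, table: CodonUsageTable, preserve_first: int = 10) -> DesignOutcome:
    """Replace every sense codon beyond the first ``preserve_first`` with its
    family's most-used synonym; stop codon untouched."""
    return _recode(orf, table, preserve_first, table.preferred_codon)


def deoptimize(orf: str, table: CodonUsageTable, preserve_first: int = 10) -> DesignOutcome:
    """Replace every sense codon beyond the first ``preserve_first`` with its
    family's least-used synonym; stop codon untouched."""
    return _recode(orf, table, preserve_first, table.rarest_codon)


def deoptimize_window(orf: str, table: CodonUsageTable, start_aa: int, end_aa: int) -> DesignOutcome:
    """Deoptimize only amino acids ``start_aa..end_aa`` (1-based, inclusive)."""
    code = table.code
    codons = _codons_of(orf)
    has_stop = _check_no_internal_stop(codons, code)
    n_sense = len(codons) - (1 if has_stop else 0)
    if start_aa > end_aa:
        raise ValueError(f"inverted window [{start_aa}, {end_aa}]")
    if start_aa < 1 or end_aa > n_sense:
        raise ValueError(f"window [{start_aa}, {end_aa}] outside ORF of {n_sense} amino acids")
    replacements = {
        i: table.rarest_codon(code.translate_codon(codons[i]))
        for i in range(start_aa - 1, end_aa)
    }
    return _apply(codons, replacements)


def substitute_codon(
    orf: str,
    aa_pos: int,
    new_codon: str,
    code: GeneticCode = STANDARD_CODE,
    allow_recode: bool = False,
) -> DesignOutcome:
    """Replace the codon at amino-acid position ``aa_pos`` (1-based).

    In the default mode the replacement must be synonymous; ``allow_recode``
    enables deliberate amino-acid changes (e.g. alanine-scanning with GCC).
    """
    codons = _codons_of(orf)
    new_codon = new_codon.upper().replace("U", "T")
    if len(new_codon) != 3 or new_codon not in code.table:
        raise ValueError(f"invalid codon {new_codon!r}")
    has_stop = _check_no_internal_stop(codons, code)
    n_sense = len(codons) - (1 if has_stop else 0)
    if not 1 <= aa_pos <= n_sense:
        raise ValueError(f"aa_pos {aa_pos} outside ORF of {n_sense} amino acids")
    i = aa_pos - 1
    old_aa = code.translate_codon(codons[i])
    new_aa = code.translate_codon(new_codon)
    if new_aa == "*":
        raise ValueError("cannot substitute a stop codon into the ORF body")
    if new_aa != old_aa and not allow_recode:
        raise ValueError(
            f"non-synonymous substitution at aa {aa_pos}: {old_aa} -> {new_aa} "
            "(pass allow_recode=True for deliberate recoding)"
        )
    return _apply(codons, {i: new_codon})


def alanine_scan(orf: str, start_aa: int, end_aa: int, code: GeneticCode = STANDARD_CODE,
                 alanine_codon: str = "GCC") -> DesignOutcome:
    """Recode amino acids ``start_aa..end_aa`` (1-based, inclusive) to alanine.

    This deliberately changes the protein; it exists for exit-tunnel context
    scans and is never implied by the synonymous operations above.
    """
    codons = _codons_of(orf)
    has_stop = _check_no_internal_stop(codons, code)
    n_sense = len(codons) - (1 if has_stop else 0)
    if start_aa > end_aa or start_aa < 1 or end_aa > n_sense:
        raise ValueError(f"bad scan window [{start_aa}, {end_aa}]")
    replacements = {i: alanine_codon for i in range(start_aa - 1, end_aa)}
    return _apply(codons, replacements)
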