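"""Standard genetic code and synonymous-codon family structure.

All codons are DNA-alphabet (T, not U) uppercase strings of length 3.
Amino acids are one-letter IUPAC codes; stop codons map to ``"*"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

STOP = "*"

_BASES = "TCAG"


def _standard_table() -> dict[str, str]:
    bio = CodonTable.unambiguous_dna_by_id[1]
    table = dict(bio.forward_table)
    for c in bio.stop_codons:
        table[c] = STOP
    return table


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid mapping with family (synonym-set) structure.

    Parameters
    ----------
    table
        Mapping of all 64 codons to one-letter amino acids or ``"*"``.
    """

    table: dict[str, str] = field(default_factory=_standard_table)

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must cover 64 codons, got {len(self.table)}")
        expected = {"".join(c) for c in product(_BASES, repeat=3)}
        if set(self.table) != expected:
            raise ValueError("genetic code keys are not the 64 DNA codons")
        n_stop = sum(1 for aa in self.table.values() if aa == STOP)
        if n_stop != 3:
            raise ValueError(f"expected 3 stop codons, got {n_stop}")
        aas = {aa for aa in self.table.values() if aa != STOP}
        if len(aas) != 20:
            raise ValueError(f"expected 20 amino acids, got {len(aas)}")

    def translate_codon(self, codon: str) -> str:
        return self.table[codon.upper().replace("U", "T")]

    def translate(self, orf: str) -> str:
        """Translate an in-frame nucleotide sequence (stops render as ``*``)."""
        orf = orf.upper().replace("U", "T")
        if len(orf) % 3:
            raise ValueError("ORF length not divisible by 3")
        return "".join(self.table[orf[i : i + 3]] for i in range(0, len(orf), 3))

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa == STOP))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa != STOP))

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted({aa for aa in self.table.values() if aa != STOP}))

    def family(self, amino_acid: str) -> tuple[str, ...]:
        """Synonymous codons of one amino acid, lexicographically sorted."""
        if amino_acid == STOP:
            raise ValueError("stop codons do not form an amino-acid family")
        fam = tuple(sorted(c for c, aa in self.table.items() if aa == amino_acid))
        if not fam:
            raise ValueError(f"unknown amino acid {amino_acid!r}")
        return fam

    def families(self) -> dict[str, tuple[str, ...]]:
        return {aa: self.family(aa) for aa in self.amino_acids}

    def multi_codon_families(self) -> dict[str, tuple[str, ...]]:
        """Families with at least two synonymous codons (18 in the standard code)."""
        return {aa: fam for aa, fam in self.families().items() if len(fam) >= 2}


STANDARD_CODE = GeneticCode()

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
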