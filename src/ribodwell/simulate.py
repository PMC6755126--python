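"""Synthetic transcriptomes and ribosome-profiling/RNA-seq read sets.

The generator plants a known "truth" — per-codon dwell times, per-gene
expression, a frame-error rate — and emits reads with the statistical
structure the decoding-time analysis assumes: the A-site codon of each
footprint is drawn with probability proportional to expression x dwell (a
steady-state density model, which is exactly what a density-ratio statistic
like CDT measures), read starts sit 15 nt upstream of the A site, fragment
lengths are uniform on 28-32 nt, and a controlled fraction of reads is
shifted +/-1 nt to mimic nuclease-digestion heterogeneity (producing
out-of-frame A sites).  RNA-seq reads start uniformly along transcripts
chosen proportional to expression x length.  rRNA/tRNA decoy transcripts
receive reads too, exercising the library-size exclusion rules.

The default scenario (200 genes of 300-600 codons, 30 footprints per codon
instance, 20% frame errors, usage-anti-correlated dwell with CCA slowest)
mirrors the qualitative features of fungal ribosome-profiling data: ~80%
in-frame reads, a CCA reference codon, and within every synonymous family
the most-used codon decoded fastest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetics import STANDARD_CODE, GeneticCode
from .io import AlignmentSet, Annotation, TranscriptModel
from .usage import CodonUsageTable

ASITE_OFFSET_TRUTH = 15

# Within-family usage fractions by family size, most- to least-used.
_RANK_FRACTIONS = {
    1: [1.0],
    2: [0.70, 0.30],
    3: [0.60, 0.28, 0.12],
    4: [0.52, 0.26, 0.14, 0.08],
    6: [0.38, 0.26, 0.16, 0.10, 0.06, 0.04],
}


def default_target_usage(code: GeneticCode = STANDARD_CODE) -> CodonUsageTable:
    """A deterministic biased usage table for back-translation.

    Within each family, ranked fractions are assigned in reverse-lexicographic
    codon order, so e.g. CCT is the preferred proline codon and CCA the rarest
    — matching the empirical observation that the slowest (most occupied)
    codon in fungal profiling data is CCA.
    """
    counts: dict[str, int] = {}
    for aa, fam in code.families().items():
        fracs = _RANK_FRACTIONS[len(fam)]
        for codon, f in zip(sorted(fam, reverse=True), fracs):
            counts[codon] = int(round(f * 10000))
    return CodonUsageTable(counts, code=code)


@dataclass
class SimTruth:
    """The planted parameters behind one synthetic dataset."""

    dwell: dict[str, float]
    expression: dict[str, float]
    frame_error_rate: float
    seed: int
    offset_truth: int = ASITE_OFFSET_TRUTH

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def plant_dwell_times(
    usage: CodonUsageTable,
    mode: str = "anti_usage",
    seed: int = 0,
    alpha: float = 0.5,
    sigma: float = 0.5,
    force_slowest: str | None = "CCA",
) -> dict[str, float]:
    """Assign a relative A-site dwell time to every sense codon.

    Modes: ``anti_usage`` makes dwell strictly decreasing in within-family
    usage fraction, ``dwell = (f_preferred / f)**alpha``, optionally forcing
    one codon (default CCA) to the global maximum; ``lognormal_independent``
    draws iid lognormal dwell; ``constant`` sets all dwell to 1 (null model).
    """
    code = usage.code
    sense = code.sense_codons
    if mode == "constant":
        return {c: 1.0 for c in sense}
    if mode == "lognormal_independent":
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(mean=0.0, sigma=sigma, size=len(sense))
        return {c: float(v) for c, v in zip(sense, vals)}
    if mode == "anti_usage":
        dwell: dict[str, float] = {}
        for aa, fam in code.families().items():
            f_pref = max(usage.family_fraction[c] for c in fam)
            for c in fam:
                dwell[c] = float((f_pref / usage.family_fraction[c]) ** alpha)
        if force_slowest is not None:
            peak = max(dwell.values())
            dwell[force_slowest] = 1.1 * peak
        return dwell
    raise ValueError(f"unknown dwell mode {mode!r}")


def generate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (300, 600),
    usage_bias_strength: float = 1.0,
    seed: int = 0,
    target_usage: CodonUsageTable | None = None,
    utr_length: int = 30,
    n_rrna: int = 2,
    n_trna: int = 2,
    code: GeneticCode = STANDARD_CODE,
) -> Annotation:
    """Random coding transcripts back-translated with biased codon usage.

    ``length_range`` is (min, max) sense codons per ORF, inclusive; codon
    probabilities within each family are proportional to the target usage
    fraction raised to ``usage_bias_strength`` (0 = uniform within family).
    UTRs of ``utr_length`` nt (>= 20) flank every CDS, and a few rRNA/tRNA
    decoy transcripts exercise library-size exclusion downstream.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 25:
        raise ValueError(f"degenerate length range {length_range} (need 25 <= min <= max)")
    if utr_length < 20:
        raise ValueError("UTRs must be >= 20 nt")
    usage = target_usage or default_target_usage(code)
    rng = np.random.default_rng(seed)

    aas = list(code.amino_acids)
    fam_codons = {aa: np.array(code.family(aa), dtype=object) for aa in aas}
    fam_probs = {}
    for aa, fam in fam_codons.items():
        w = np.array([usage.family_fraction[c] for c in fam]) ** usage_bias_strength
        fam_probs[aa] = w / w.sum()

    # Sample all genes' codons in one pass per amino acid (vectorized).
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    starts = np.concatenate([[0], np.cumsum(lengths)])
    total = int(starts[-1])
    aa_idx = rng.integers(0, len(aas), size=total)
    aa_idx[starts[:-1]] = aas.index("M")  # every ORF starts with Met
    codon_flat = np.empty(total, dtype=object)
    for ai, aa in enumerate(aas):
        where = np.nonzero(aa_idx == ai)[0]
        picks = rng.choice(len(fam_codons[aa]), size=len(where), p=fam_probs[aa])
        codon_flat[where] = fam_codons[aa][picks]
    codon_flat[starts[:-1]] = "ATG"

    bases = np.array(list("ACGT"))
    models = []
    for g in range(n_genes):
        cds = "".join(codon_flat[starts[g] : starts[g + 1]]) + "TAA"
        utr5 = "".join(rng.choice(bases, utr_length))
        utr3 = "".join(rng.choice(bases, utr_length))
        models.append(TranscriptModel(
            id=f"gene{g:04d}", sequence=utr5 + cds + utr3,
            cds_start=utr_length, cds_end=utr_length + len(cds), biotype="mRNA",
        ))
    for i in range(n_rrna):
        seq = "".join(rng.choice(list("ACGT"), 1500))
        models.append(TranscriptModel(id=f"rRNA{i}", sequence=seq, biotype="rRNA"))
    for i in range(n_trna):
        seq = "".join(rng.choice(list("ACGT"), 80))
        models.append(TranscriptModel(id=f"tRNA{i}", sequence=seq, biotype="tRNA"))
    return Annotation(models)


def plant_expression(annotation: Annotation, seed: int = 0, sigma: float = 1.0) -> dict[str, float]:
    """Lognormal relative expression for every coding transcript."""
    rng = np.random.default_rng(seed)
    coding = annotation.coding()
    vals = rng.lognormal(mean=0.0, sigma=sigma, size=len(coding))
    return {t.id: float(v) for t, v in zip(coding, vals)}


def _decoy_reads(annotation: Annotation, n: int, rng: np.random.Generator,
                 lengths: tuple[int, int] = (28, 32)) -> tuple[list, list, list]:
    decoys = [t for t in annotation if t.biotype in ("rRNA", "tRNA")]
    tids, starts, lens = [], [], []
    if not decoys or n <= 0:
        return tids, starts, lens
    for _ in range(n):
        t = decoys[rng.integers(len(decoys))]
        ln = int(rng.integers(lengths[0], lengths[1] + 1))
        ln = min(ln, len(t))
        s = int(rng.integers(0, max(1, len(t) - ln + 1)))
        tids.append(t.id)
        starts.append(s)
        lens.append(ln)
    return tids, starts, lens


def simulate_rpf(
    annotation: Annotation,
    dwell: dict[str, float],
    expression: dict[str, float],
    depth: float = 30.0,
    frame_error_rate: float = 0.2,
    seed: int = 0,
    decoy_fraction: float = 0.05,
    asite_offset: int = ASITE_OFFSET_TRUTH,
    code: GeneticCode = STANDARD_CODE,
) -> AlignmentSet:
    """Footprint reads whose A-site codon is drawn ∝ expression x dwell.

    ``depth`` is the mean number of reads per sense-codon instance; the total
    read count is ``depth x (total sense codon instances)``, allocated
    multinomially.  Read start = A-site position - ``asite_offset``; with
    probability ``frame_error_rate`` the start is shifted +/-1 nt (equal
    probability each side); lengths are uniform on 28-32 nt.  Codon instances
    whose footprint would not fit inside the transcript are excluded from
    sampling.  ``decoy_fraction`` extra reads land on rRNA/tRNA transcripts.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0 <= frame_error_rate < 1:
        raise ValueError("frame_error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    t_idx_parts, apos_parts, w_parts = [], [], []
    coding = annotation.coding()
    for t in coding:
        codons = t.codons()
        n_sense = len(codons) - 1 if code.translate_codon(codons[-1]) == "*" else len(codons)
        apos = t.cds_start + 3 * np.arange(n_sense)
        # skip the start codon (initiation footprints are atypical) and any
        # codon whose footprint, even +/-1-shifted, would not fit
        ok = (np.arange(n_sense) >= 1) \
            & (apos - asite_offset - 1 >= 0) & (apos - asite_offset + 32 + 1 <= len(t))
        d = np.array([dwell[c] for c in codons[:n_sense]])
        w = expression.get(t.id, 0.0) * d
        t_idx_parts.append(np.full(int(ok.sum()), len(t_idx_parts)))
        apos_parts.append(apos[ok])
        w_parts.append(w[ok])
    if not t_idx_parts:
        raise ValueError("no coding transcripts to simulate")
    tid_names = [t.id for t in coding]
    inst_t = np.concatenate(t_idx_parts)
    inst_pos = np.concatenate(apos_parts)
    weights = np.concatenate(w_parts)
    n_instances = len(weights)
    total = int(round(depth * n_instances))

    names = np.array(tid_names, dtype=object)
    tids = np.empty(0, dtype=object)
    start = length = np.empty(0, dtype=np.int64)
    if total > 0 and weights.sum() > 0:
        counts = rng.multinomial(total, weights / weights.sum())
        hit = counts > 0
        reps = counts[hit]
        r_t = np.repeat(inst_t[hit], reps)
        r_pos = np.repeat(inst_pos[hit], reps)
        start = r_pos - asite_offset
        err = rng.random(total) < frame_error_rate
        shift = np.where(rng.random(total) < 0.5, -1, 1)
        start = start + np.where(err, shift, 0)
        length = rng.integers(28, 33, size=total)
        tids = names[r_t]

    n_decoy = int(round(decoy_fraction * total))
    d_t, d_s, d_l = _decoy_reads(annotation, n_decoy, rng)
    return AlignmentSet(
        np.concatenate([tids, np.array(d_t, dtype=object)]),
        np.concatenate([start, np.array(d_s, dtype=np.int64)]),
        np.concatenate([length, np.array(d_l, dtype=np.int64)]),
    )


def simulate_rnaseq(
    annotation: Annotation,
    expression: dict[str, float],
    depth: int = 1_000_000,
    read_length: int = 50,
    seed: int = 0,
    decoy_fraction: float = 0.02,
) -> AlignmentSet:
    """RNA-seq reads with uniform starts, transcripts chosen ∝ expression x length."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    coding = [t for t in annotation.coding() if len(t) >= read_length]
    w = np.array([expression.get(t.id, 0.0) * len(t) for t in coding])
    tids = np.empty(0, dtype=object)
    starts = np.empty(0, dtype=np.int64)
    if depth > 0 and w.sum() > 0:
        counts = rng.multinomial(depth, w / w.sum())
        names = np.array([t.id for t in coding], dtype=object)
        span = np.array([len(t) - read_length + 1 for t in coding])
        tids = np.repeat(names, counts)
        # uniform start within each transcript's admissible span
        starts = (rng.random(counts.sum()) * np.repeat(span, counts)).astype(np.int64)
    n_decoy = int(round(decoy_fraction * depth))
    d_t, d_s, d_l = _decoy_reads(annotation, n_decoy, rng, lengths=(read_length, read_length))
    return AlignmentSet(
        np.concatenate([tids, np.array(d_t, dtype=object)]),
        np.concatenate([starts, np.array(d_s, dtype=np.int64)]),
        np.concatenate([np.full(len(starts), read_length, dtype=np.int64),
                        np.array(d_l, dtype=np.int64)]),
    )


@dataclass
class Scenario:
    """One complete synthetic dataset plus its planted truth."""

    annotation: Annotation
    truth: SimTruth
    usage: CodonUsageTable
    rpf_reads: AlignmentSet
    rnaseq_reads: AlignmentSet


def default_scenario(
    seed: int = 0,
    n_genes: int = 200,
    length_range: tuple[int, int] = (300, 600),
    depth: float = 30.0,
    frame_error_rate: float = 0.2,
    rnaseq_depth: int = 1_000_000,
    dwell_mode: str = "anti_usage",
    code: GeneticCode = STANDARD_CODE,
) -> Scenario:
    """The reference study conditions used throughout validation.

    Sub-seeds for the four stochastic stages are derived from ``seed`` so the
    whole scenario is a pure function of its parameters.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    usage = default_target_usage(code)
    annotation = generate_transcriptome(
        n_genes, length_range=length_range, seed=sub[0], target_usage=usage, code=code
    )
    dwell = plant_dwell_times(usage, mode=dwell_mode, seed=sub[1])
    expression = plant_expression(annotation, seed=sub[1])
    rpf = simulate_rpf(annotation, dwell, expression, depth=depth,
                       frame_error_rate=frame_error_rate, seed=sub[2], code=code)
    rna = simulate_rnaseq(annotation, expression, depth=rnaseq_depth, seed=sub[3])
    truth = SimTruth(dwell=dwell, expression=expression,
                     frame_error_rate=frame_error_rate, seed=seed)
    return Scenario(annotation=annotation, truth=truth, usage=usage,
                    rpf_reads=rpf, rnaseq_reads=rna)
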