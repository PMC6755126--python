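# Methods

## The decoding-time model

Under steady-state elongation with no initiation limitation inside the ORF,
the density of ribosome A sites on a codon is proportional to the time the
ribosome dwells there. The estimator therefore treats the per-instance
quotient RPM/RPKM — A-site footprint density corrected for mRNA abundance —
as a relative dwell measurement, and averages it per codon across the
genome:

- A gene enters the analysis when its RNA-seq RPKM is at least `min_rpkm`
  (default 1): below that, the quotient's denominator is too noisy to be
  meaningful.
- A codon instance enters when its raw A-site count is at least `min_reads`
  (default 1; this is a count filter, applied before RPM scaling) and when
  its index lies in `[trim_codons, n_sense − trim_codons)` with
  `trim_codons = 20` — the first codons carry initiation-ramp signal and the
  last ones termination signal, neither of which reflects elongation.
  `n_sense` counts sense codons from the start codon; the stop codon never
  enters.
- CDT(c) is the sum of quotients divided by the number of *that codon's*
  eligible instances. This per-codon denominator is the only reading under
  which CDT is a mean dwell time; dividing every codon's sum by the grand
  total of instances would confound dwell with codon abundance. Both modes
  are implemented (`denominator="per_codon" | "global"`); per-codon is the
  default.
- RCDT divides by the maximum CDT, so the slowest codon scores 1. The
  reference codon is the empirical argmax (ties broken lexicographically),
  not a hard-coded identity; on matched synthetic data, and in the fungal
  profiling data this analysis style comes from, that codon is CCA.

The RPM/RPKM construction makes the statistic insensitive to expression:
scaling one gene's expression (so its footprint and RNA-seq reads scale
together) multiplies every quotient by a factor common to all codons, which
the RCDT normalization removes. This invariance is exercised exactly in the
test suite with constructed counts.

## A-site and frame rules

Footprints of 28–32 nt are kept; the A site is read offsets 15–17 from the
5′ end (the 1-based "nucleotides 16–18" convention, converted once at the
boundary). The offset is a single constant for all lengths — per-length
offsets are a documented extension point, not implemented, because the
statistic is defined with one rule. Since 15 is a multiple of 3, a read
whose 5′ end falls on a codon boundary is always classified in-frame. The
in-frame fraction is computed over reads whose A site lies inside a CDS;
out-of-frame reads are excluded from counts but retained in the footprint
library size, as are reads whose A site falls in a UTR. Library size counts
qualifying (in-length) reads on all identified transcripts except rRNA and
tRNA. Frame assignment uses coordinates only; comparing read sequence to CDS
sequence would behave identically on error-free alignments and is not
implemented.

RNA-seq counting is interval overlap: a read counts for a transcript when it
overlaps the ORF by at least one nucleotide (half-open intervals, so a read
ending exactly at the CDS start does not count). RPKM normalizes by full
transcript length by default — that is the literal definition adopted here —
with `use_orf_length=True` available since ORF-length normalization is the
other defensible reading. Reads are never fractionally assigned; multi-mapped
reads are handled upstream by keeping primary alignments only, a stated
assumption since profiling protocols differ here.

## Codon usage and CAI

Relative adaptiveness is w(c) = count(c)/max count within the synonymous
family. Zero-count codons receive w = 0.5/(family max) so log w stays
finite; the numerator is configurable. CAI is the Sharp–Li geometric mean of
w over an ORF's codons restricted to multi-codon families: Met, Trp and
stops are excluded from both the product and the count, since their w ≡ 1
would only dilute the index. Ties for the preferred or rarest synonym break
lexicographically, making every design operation deterministic.

## Sequence design

`optimize`/`deoptimize` preserve the first 10 codons by default
(translation-initiation context is deliberately left untouched in reporter
constructs) and replace every later sense codon with the most/least-used
synonym; `deoptimize_window` and `substitute_codon` address amino-acid
positions 1-based, matching the R213-style naming used for reporter
mutants. All default-mode operations are protein-preserving by construction
and verified property-wise; recoding to alanine (GCC scans) exists only
behind an explicit flag.

## The synthetic generator

The generator is a steady-state density model, not a kinetic simulation: a
footprint's A-site codon is drawn with probability proportional to
expression × dwell over eligible codon instances. This is sufficient — and
exactly matched — to validate a density-ratio statistic like CDT; it does
not model ribosome collisions, run-off, or initiation-limited profiles
(TASEP-style kinetics are out of scope).

Defaults define the reference study conditions: 200 genes of 300–600 sense
codons; uniform 28–32 nt fragment lengths; mean depth 30 footprints per
codon instance; lognormal(σ = 1) expression; 1 M RNA-seq reads of 50 nt with
uniform starts, transcripts drawn ∝ expression × length; frame errors as
±1 nt start shifts with total probability 0.2 (digestion heterogeneity, the
simplest mechanism producing out-of-frame A sites, and matching the ~20%
out-of-frame rate typical of real libraries); rRNA/tRNA decoy transcripts
with ~5% of reads, to exercise library-size exclusion. UTRs are 30 nt, long
enough for any footprint at the second codon. The start codon itself is not
sampled: initiation-site footprints have atypical geometry in real data,
and the analysis trims the first 20 codons anyway.

The target usage table assigns within-family fractions by rank
(e.g. 0.52/0.26/0.14/0.08 for 4-codon families) in reverse-lexicographic
codon order, which places CCA as the rarest proline codon. The `anti_usage`
dwell mode sets dwell = (f_preferred/f)^0.5 within each family — strictly
decreasing in usage — and then raises CCA 10% above the global maximum so
the slowest-codon identity is part of the planted truth. `constant` is the
null model; `lognormal_independent` decouples dwell from usage. All
generators are pure functions of (parameters, seed); sub-seeds are spawned
from the scenario seed via `numpy.random.SeedSequence`.

What passing tests show, and what they do not: recovery on this generator
demonstrates that the estimator is correct for data whose A-site density is
proportional to dwell × expression with independent uniform noise. Real
libraries add sequence-biased digestion, cloning biases, multi-mapping,
splice isoforms and position-dependent elongation effects that the generator
does not emulate; conclusions about real data rest on the analysis rules
(length window, offset, frame exclusion, trimming, RPM/RPKM) being the
accepted ones, not on these simulations.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere internally; SAM's 1-based POS
  and the 1-based A-site rule are converted at I/O boundaries. DNA alphabet
  internally; U is normalized to T on read.
- Codon accumulation is vectorized (per-transcript integer codon codes,
  `np.add.at`); results match a per-instance Python loop to ~1e-9 relative
  (floating-point summation order differs).
- Codons with no eligible instance are omitted with a warning; an entirely
  empty result, an all-zero CDT vector, a zero library size and an empty CDS
  set are errors, not silent NaNs.
- Within-family Spearman correlations on constant input are reported as NaN
  (undefined), never as 0.
- Genes whose RPKM is below threshold are excluded only at the CDT stage;
  they still contribute to both library sizes.

## Problem sizes used in validation

Oracle-equivalence checks run the 200-gene scenario at reduced footprint
depth (2 reads per codon instance) so the brute-force per-read Python oracle
stays fast; parameter-recovery and null-safety checks run the full reference
conditions (depth 30) over 20 and 10 seeds respectively. These sizes give
the statistical power the checks need — the seed sweeps bound the
probability of a lucky pass — while keeping the whole suite under a minute
of simulation time.

## Known limitations

- Single-exon transcript models only; spliced genome alignments are out of
  scope (alignments must be in transcript coordinates).
- One A-site offset for all read lengths; no periodicity-based offset
  learning.
- No correction for cycloheximide artefacts, pausing-site detection, or
  codon-pair effects.
- RPKM only (no TPM or effective-length modelling).
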