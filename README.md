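# ribodwell

Per-codon ribosome decoding-time estimation from ribosome profiling, codon
usage indices, and synonymous codon optimization/deoptimization design — with
a synthetic-data generator that validates the whole pipeline against planted
truth.

## Who this is for

Groups analysing ribosome profiling (Ribo-seq) together with RNA-seq who want
to ask: *are rarely used synonymous codons decoded more slowly than common
ones?* The package turns footprint alignments into A-site codon occupancy,
corrects it for mRNA abundance, and summarizes each of the 61 sense codons by
its relative decoding time. It also produces the reporter-ORF manipulations
used to probe such effects experimentally (full optimization/deoptimization,
windowed deoptimization, single synonymous substitutions).

## The statistic

For a ribosome-protected fragment (RPF) of 28–32 nt, the ribosomal A site —
where codon decoding occurs — is taken as read nucleotides 16–18 (5′-most
nucleotide = position 1). Reads whose A site is out of frame relative to the
annotated CDS are excluded (the in-frame fraction is reported). For every
gene with RPKM ≥ 1, each codon instance with ≥ 1 A-site read, outside the
first and last 20 amino acids, contributes the quotient

```
RPM(instance) / RPKM(gene)
```

i.e. footprint density normalized by mRNA abundance. The **codon decoding
time** is the genome-wide mean of these quotients per codon,

```
CDT(c) = (1 / n_c) * Σ_instances RPM/RPKM,
```

and the **relative codon decoding time** RCDT(c) = CDT(c) / max_c CDT
rescales so the slowest (most occupied) codon scores 1. The codon adaptation
index is the Sharp–Li geometric mean of relative adaptiveness
w(c) = count(c) / max count in c's synonymous family, over codons of
multi-codon families.

## Worked example

```python
import ribodwell as rd
from scipy import stats

# a synthetic dataset with planted per-codon dwell times
sc = rd.default_scenario(seed=1)          # 200 genes, ~2.8 M footprints

profile = rd.build_profile(rd.filter_by_length(sc.rpf_reads), sc.annotation)
expr = rd.quantify(sc.rnaseq_reads, sc.annotation)
result = rd.DecodingTimeModel(profile, expr, sc.annotation).fit()

print(f"in-frame fraction: {profile.in_frame_fraction:.4f}")
print(f"slowest codon:     {result.reference_codon}")
codons = sorted(result.cdt)
rho = stats.spearmanr([sc.truth.dwell[c] for c in codons],
                      [result.cdt[c] for c in codons]).statistic
print(f"Spearman(planted dwell, CDT): {rho:.4f}")
reports = result.family_analysis(sc.usage)
print(f"families where the most-used codon is fastest: "
      f"{sum(r.fastest_is_most_frequent for r in reports)}/{len(reports)}")
```

prints

```
in-frame fraction: 0.8002
slowest codon:     CCA
Spearman(planted dwell, CDT): 0.9751
families where the most-used codon is fastest: 18/18
```

The planted 20% frame-error rate is recovered as ~80% in-frame reads; the
codon planted slowest (CCA, proline) is identified as the reference codon;
estimated decoding times rank-match the planted dwell times; and in all 18
multi-codon families the most frequently used codon has the lowest RCDT.
`result.summary()` prints the per-codon table and
`result.plot_families(sc.usage, "families.png")` draws the per-family
usage-vs-RCDT panels.

A `ribodwell` console script exposes each stage
(`simulate | usage | cai | design | profile | quant | rcdt | run-all`);
`ribodwell run-all` writes all tables, a bedGraph of A-site occupancy, the
per-family plot and a JSON manifest of parameters and input checksums.

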