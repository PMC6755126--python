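import warnings

import numpy as np
import pytest
from scipy import stats

from ribodwell import (
    DecodingTimeModel,
    ExpressionRecord,
    FootprintProfile,
    STANDARD_CODE,
    TranscriptModel,
    Annotation,
    build_profile,
    default_scenario,
    filter_by_length,
    normalize_rcdt,
    quantify,
)
from conftest import brute_cdt, brute_profile, brute_rpkm


def _toy_gene(codon: str, n_mid: int = 5, trim: int = 20):
    """A gene whose trimmed middle contains `n_mid` copies of one codon."""
    mid = codon * n_mid
    filler = "GGT" * trim
    cds = "ATG" + filler + mid + filler + "TAA"
    seq = "A" * 30 + cds + "C" * 30
    return TranscriptModel("g", seq, 30, 30 + len(cds))


def _manual_inputs(t, counts_vec, lib, rpkm_val):
    prof = FootprintProfile(counts={t.id: counts_vec}, library_size=lib,
                            in_frame_fraction=1.0)
    expr = [ExpressionRecord(t.id, 1, len(t), rpkm_val)]
    return prof, expr


def test_single_instance_arithmetic():
    """One eligible AAA instance, RPM 5 on a gene of RPKM 10 -> CDT 0.5."""
    t = _toy_gene("AAA", n_mid=1)
    vec = np.zeros(t.n_codons, dtype=np.int64)
    aaa_index = 1 + 20  # after start codon and the 20-codon trim filler
    lib = 10**6
    vec[aaa_index] = 5  # RPM = 5 at library 1e6
    prof, expr = _manual_inputs(t, vec, lib, rpkm_val=10.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = DecodingTimeModel(prof, expr, Annotation([t])).fit()
    assert res.cdt["AAA"] == pytest.approx(0.5)
    assert res.n_instances["AAA"] == 1


def test_low_rpkm_gene_contributes_nothing():
    t = _toy_gene("AAA", n_mid=3)
    vec = np.full(t.n_codons, 10, dtype=np.int64)
    prof, expr = _manual_inputs(t, vec, 10**6, rpkm_val=0.5)
    with pytest.raises(ValueError, match="no eligible"):
        DecodingTimeModel(prof, expr, Annotation([t])).fit()


def test_trim_and_min_reads_filters():
    t = _toy_gene("AAA", n_mid=3)
    vec = np.zeros(t.n_codons, dtype=np.int64)
    vec[1] = 50          # inside the first 20 aa: trimmed away
    vec[21] = 2          # eligible AAA
    vec[22] = 0          # below min_reads
    prof, expr = _manual_inputs(t, vec, 10**6, rpkm_val=10.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = DecodingTimeModel(prof, expr, Annotation([t])).fit()
    assert res.n_instances["AAA"] == 1
    assert "GGT" not in res.cdt  # filler codons have zero reads everywhere


def test_normalize_rcdt_examples():
    rcdt, ref = normalize_rcdt({"AAA": 2.0, "AAG": 1.0})
    assert rcdt == {"AAA": 1.0, "AAG": 0.5}
    assert ref == "AAA"
    rcdt, ref = normalize_rcdt({"CCC": 1.0, "AAA": 1.0})
    assert ref == "AAA"  # tie -> lexicographically first
    assert all(v == 1.0 for v in rcdt.values())
    with pytest.raises(ValueError):
        normalize_rcdt({})
    with pytest.raises(ValueError):
        normalize_rcdt({"AAA": 0.0})


def test_cdt_matches_flat_loop_oracle(small_scenario, small_filtered_rpf):
    """Every CDT equals an independent per-instance recomputation."""
    ann = small_scenario.annotation
    prof = build_profile(small_filtered_rpf, ann)
    expr = quantify(small_scenario.rnaseq_reads, ann)
    res = DecodingTimeModel(prof, expr, ann).fit()

    counts, lib, _ = brute_profile(small_filtered_rpf, ann)
    _, _, rpkm = brute_rpkm(small_scenario.rnaseq_reads, ann)
    oracle_cdt, oracle_n = brute_cdt(counts, lib, rpkm, ann)
    assert set(res.cdt) == set(oracle_cdt)
    for c in oracle_cdt:
        assert res.cdt[c] == pytest.approx(oracle_cdt[c], rel=1e-9)
        assert res.n_instances[c] == oracle_n[c]


def test_filter_monotonicity(small_scenario, small_filtered_rpf):
    """Raising min_rpkm or trim_codons never increases any n_instances."""
    ann = small_scenario.annotation
    prof = build_profile(small_filtered_rpf, ann)
    expr = quantify(small_scenario.rnaseq_reads, ann)
    base = DecodingTimeModel(prof, expr, ann).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stricter = DecodingTimeModel(prof, expr, ann, trim_codons=40).fit()
        richer = DecodingTimeModel(prof, expr, ann,
                                   min_rpkm=np.median([e.rpkm for e in expr])).fit()
    for c, n in stricter.n_instances.items():
        assert n <= base.n_instances[c]
    for c, n in richer.n_instances.items():
        assert n <= base.n_instances[c]


def test_reference_codon_is_argmax_cdt(small_scenario, small_filtered_rpf):
    ann = small_scenario.annotation
    prof = build_profile(small_filtered_rpf, ann)
    res = DecodingTimeModel(prof, quantify(small_scenario.rnaseq_reads, ann), ann).fit()
    assert res.cdt[res.reference_codon] == max(res.cdt.values())
    assert res.rcdt[res.reference_codon] == 1.0
    assert all(0 < v <= 1 for v in res.rcdt.values())


def test_family_analysis_constructed_extreme(small_scenario, small_filtered_rpf):
    """Planted usage-anti-ranked dwell: rho = -1, fastest-is-most-frequent 18/18."""
    ann = small_scenario.annotation
    prof = build_profile(small_filtered_rpf, ann)
    res = DecodingTimeModel(prof, quantify(small_scenario.rnaseq_reads, ann), ann).fit()
    # replace the estimates with the planted truth: the degenerate extreme
    res.cdt = {c: small_scenario.truth.dwell[c] for c in res.cdt}
    res.rcdt, _ = normalize_rcdt(res.cdt)
    reports = res.family_analysis(small_scenario.usage)
    assert len(reports) == 18
    assert all(r.fastest_is_most_frequent for r in reports)
    assert all(r.spearman_rho == pytest.approx(-1.0) for r in reports)


def test_family_analysis_constant_rcdt_is_nan_not_zero(small_scenario, small_filtered_rpf):
    ann = small_scenario.annotation
    prof = build_profile(small_filtered_rpf, ann)
    res = DecodingTimeModel(prof, quantify(small_scenario.rnaseq_reads, ann), ann).fit()
    res.cdt = {c: 1.0 for c in res.cdt}
    res.rcdt, _ = normalize_rcdt(res.cdt)
    reports = res.family_analysis(small_scenario.usage)
    assert all(np.isnan(r.spearman_rho) for r in reports)


def test_family_with_single_measured_codon_skipped(small_scenario, small_filtered_rpf):
    ann = small_scenario.annotation
    prof = build_profile(small_filtered_rpf, ann)
    res = DecodingTimeModel(prof, quantify(small_scenario.rnaseq_reads, ann), ann).fit()
    for c in STANDARD_CODE.family("K")[1:]:  # keep one Lys codon
        res.cdt.pop(c, None)
        res.rcdt.pop(c, None)
    with pytest.warns(UserWarning, match="fewer than 2"):
        reports = res.family_analysis(small_scenario.usage)
    assert len(reports) == 17


def test_expression_scaling_leaves_rcdt_unchanged():
    """Quadrupling one gene's expression — its footprint counts and its
    RNA-seq count scale together, and both library sizes grow accordingly —
    leaves every RCDT value exactly unchanged: the RPM/RPKM quotient controls
    for expression, and the residual library-ratio factor is common to all
    codons so the normalization removes it."""
    from ribodwell import generate_transcriptome, rpkm_table

    ann = generate_transcriptome(3, length_range=(60, 80), seed=31,
                                 n_rrna=0, n_trna=0)
    rng = np.random.default_rng(32)
    rpf_counts = {t.id: rng.integers(1, 40, t.n_codons).astype(float)
                  for t in ann.coding()}
    rna_counts = {t.id: int(rng.integers(500, 2000)) for t in ann.coding()}

    def fit(rpf_c, rna_c):
        lib_rpf = int(sum(v.sum() for v in rpf_c.values()))
        prof = FootprintProfile(counts={t: v.copy() for t, v in rpf_c.items()},
                                library_size=lib_rpf, in_frame_fraction=1.0)
        expr = rpkm_table(rna_c, ann, sum(rna_c.values()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return DecodingTimeModel(prof, expr, ann, trim_codons=5).fit()

    base = fit(rpf_counts, rna_counts)
    gene = sorted(rpf_counts)[0]
    boosted_rpf = {t: v * (4.0 if t == gene else 1.0) for t, v in rpf_counts.items()}
    boosted_rna = {t: n * (4 if t == gene else 1) for t, n in rna_counts.items()}
    boosted = fit(boosted_rpf, boosted_rna)

    assert set(base.rcdt) == set(boosted.rcdt)
    for c in base.rcdt:
        assert boosted.rcdt[c] == pytest.approx(base.rcdt[c], rel=1e-12)


def test_dwell_recovery_small(small_scenario, small_filtered_rpf):
    ann = small_scenario.annotation
    prof = build_profile(small_filtered_rpf, ann)
    res = DecodingTimeModel(prof, quantify(small_scenario.rnaseq_reads, ann), ann).fit()
    codons = sorted(res.cdt)
    rho = stats.spearmanr([small_scenario.truth.dwell[c] for c in codons],
                          [res.cdt[c] for c in codons]).statistic
    assert rho > 0.9


def test_summary_and_plot(tmp_path, small_scenario, small_filtered_rpf):
    ann = small_scenario.annotation
    prof = build_profile(small_filtered_rpf, ann)
    res = DecodingTimeModel(prof, quantify(small_scenario.rnaseq_reads, ann), ann).fit()
    s = res.summary()
    assert res.reference_codon in s and "RPKM" in s
    out = tmp_path / "fam.png"
    res.plot_families(small_scenario.usage, out)
    assert out.stat().st_size > 0

    df = res.codon_stats
    assert list(df.columns) == ["codon", "amino_acid", "cdt", "rcdt", "n_instances"]
    assert (df["n_instances"] >= 1).all()


def test_global_denominator_mode(small_scenario, small_filtered_rpf):
    ann = small_scenario.annotation
    prof = build_profile(small_filtered_rpf, ann)
    expr = quantify(small_scenario.rnaseq_reads, ann)
    per = DecodingTimeModel(prof, expr, ann).fit()
    glob = DecodingTimeModel(prof, expr, ann, denominator="global").fit()
    total = sum(per.n_instances.values())
    for c in per.cdt:
        assert glob.cdt[c] == pytest.approx(per.cdt[c] * per.n_instances[c] / total)
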