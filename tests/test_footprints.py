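import numpy as np
import pytest
from scipy import stats

from ribodwell import (
    AlignedRead,
    AlignmentSet,
    Annotation,
    TranscriptModel,
    asite_codon,
    build_profile,
    default_target_usage,
    filter_by_length,
    plant_dwell_times,
    rpm,
    simulate_rpf,
)
from conftest import brute_profile

# transcript with 30-nt UTRs and a 30-codon CDS
CDS = "ATG" + "GCT" * 28 + "TAA"
T = TranscriptModel("t", "A" * 30 + CDS + "C" * 30, 30, 30 + len(CDS))
ANN = Annotation([T])


def _reads(*pairs):
    return AlignmentSet.from_reads([AlignedRead("t", s, ln) for s, ln in pairs])


def test_filter_by_length():
    reads = _reads((0, 27), (0, 28), (0, 30), (0, 32), (0, 33))
    out = filter_by_length(reads)
    assert sorted(out.length) == [28, 30, 32]
    assert out.dropped["by_length"] == 2
    assert len(filter_by_length(_reads())) == 0
    with pytest.raises(ValueError):
        filter_by_length(reads, 30, 28)


def test_filter_retained_fraction_matches_mixture():
    rng = np.random.default_rng(0)
    lengths = rng.choice([26, 27, 28, 29, 30, 31, 32, 33], size=20_000,
                         p=[.03, .03, .2, .2, .2, .15, .15, .04])
    reads = AlignmentSet(np.array(["t"] * len(lengths), dtype=object),
                         np.zeros(len(lengths), dtype=np.int64), lengths)
    frac = len(filter_by_length(reads)) / len(reads)
    p_keep = 0.9
    sigma = np.sqrt(p_keep * (1 - p_keep) / len(reads))
    assert abs(frac - p_keep) < 4 * sigma


def test_asite_offset_arithmetic():
    """Read starting at the CDS start has its A site on codon 5 (offset 15)."""
    assert asite_codon(AlignedRead("t", 30, 28), T) == (5, "in_frame")
    assert asite_codon(AlignedRead("t", 31, 28), T) == (None, "out_of_frame")
    assert asite_codon(AlignedRead("t", 0, 28), T) == (None, "outside_cds")
    with pytest.raises(ValueError, match="A site"):
        asite_codon(AlignedRead("t", 30, 17), T)
    rrna = TranscriptModel("r", "A" * 100, biotype="rRNA")
    assert asite_codon(AlignedRead("r", 0, 30), rrna).reason == "noncoding"


def test_codon_boundary_read_always_in_frame():
    """Offset 15 is a multiple of 3: 5' ends on codon boundaries are in-frame."""
    for codon_i in range(0, 25):
        r = AlignedRead("t", 30 + 3 * codon_i, 28)
        res = asite_codon(r, T)
        assert res.reason == "in_frame"
        assert res.codon_index == codon_i + 5


def test_build_profile_counts_and_bookkeeping():
    reads = _reads((30, 28), (30, 30), (30, 32), (31, 28), (0, 28))
    prof = build_profile(reads, ANN)
    assert prof.counts["t"][5] == 3
    assert prof.counts["t"].sum() == 3
    assert prof.library_size == 5
    assert prof.n_dropped_out_of_frame == 1
    assert prof.n_outside_cds == 1
    assert prof.in_frame_fraction == pytest.approx(3 / 4)


def test_build_profile_order_independent(small_scenario, small_filtered_rpf):
    prof = build_profile(small_filtered_rpf, small_scenario.annotation)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(small_filtered_rpf))
    shuffled = AlignmentSet(small_filtered_rpf.transcript_id[perm],
                            small_filtered_rpf.start[perm],
                            small_filtered_rpf.length[perm])
    prof2 = build_profile(shuffled, small_scenario.annotation)
    assert prof.library_size == prof2.library_size
    for tid in prof.counts:
        assert np.array_equal(prof.counts[tid], prof2.counts[tid])


def test_build_profile_matches_brute_force(small_scenario, small_filtered_rpf):
    prof = build_profile(small_filtered_rpf, small_scenario.annotation)
    counts, lib, frac = brute_profile(small_filtered_rpf, small_scenario.annotation)
    assert prof.library_size == lib
    assert prof.in_frame_fraction == pytest.approx(frac)
    for tid, vec in counts.items():
        assert np.array_equal(prof.counts[tid], vec)


def test_library_excludes_rrna_trna(small_scenario, small_filtered_rpf):
    n_decoy = sum(
        1 for t in small_filtered_rpf.transcript_id
        if small_scenario.annotation[str(t)].biotype in ("rRNA", "tRNA"))
    prof = build_profile(small_filtered_rpf, small_scenario.annotation)
    assert n_decoy > 0
    assert prof.library_size == len(small_filtered_rpf) - n_decoy
    assert prof.n_dropped_rrna_trna == n_decoy


def test_planted_frame_error_recovered(small_scenario, small_filtered_rpf):
    prof = build_profile(small_filtered_rpf, small_scenario.annotation)
    n = prof.n_in_frame + prof.n_dropped_out_of_frame
    sigma = np.sqrt(0.8 * 0.2 / n)
    assert abs(prof.in_frame_fraction - 0.8) < 3 * sigma


def test_rpm_closed_form_and_scale_invariance():
    prof = build_profile(_reads((30, 28)), ANN)
    prof.library_size = 10**6
    prof.counts["t"][:] = 0
    prof.counts["t"][5] = 5
    assert rpm(prof).counts["t"][5] == pytest.approx(5.0)

    doubled = build_profile(_reads((30, 28), (30, 28)), ANN)
    single = build_profile(_reads((30, 28)), ANN)
    assert rpm(doubled).counts["t"][5] == pytest.approx(rpm(single).counts["t"][5])

    empty = build_profile(_reads(), ANN)
    with pytest.raises(ValueError, match="library size"):
        rpm(empty)


def test_constant_dwell_uniform_codon_counts():
    """One deep gene with constant dwell: counts uniform by chi-square."""
    from ribodwell import generate_transcriptome

    usage = default_target_usage()
    ann = generate_transcriptome(1, length_range=(400, 400), seed=3,
                                 n_rrna=0, n_trna=0)
    dwell = plant_dwell_times(usage, mode="constant")
    reads = simulate_rpf(ann, dwell, {ann.coding()[0].id: 1.0}, depth=50,
                         frame_error_rate=0.0, seed=3, decoy_fraction=0.0)
    prof = build_profile(filter_by_length(reads), ann)
    vec = prof.counts[ann.coding()[0].id][1:-1]  # start codon unsampled; drop stop slot
    assert stats.chisquare(vec).pvalue > 0.01
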