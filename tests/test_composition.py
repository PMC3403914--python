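import numpy as np
import pytest

from gisland._seq import reverse_complement
from gisland import synthetic as syn
from gisland.composition import (
    find_skew_reversals, gc_fraction, orf_gc_zscores, round_percent,
    windowed_skew, SkewProfile,
)
from gisland.genome_io import AnnotatedReplicon, Orf
from conftest import random_dna


@pytest.mark.parametrize("seq,expected", [
    ("GGCC", 1.0),
    ("ATGC", 0.5),
    ("ATATNNN", 0.0),
    ("GCGCNNAT", 4 / 6),
])
def test_gc_fraction_excludes_ambiguous_bases(seq, expected):
    assert gc_fraction(seq) == pytest.approx(expected)


def test_gc_fraction_undefined_inputs():
    for seq in ("", "NNNN"):
        with pytest.raises(ValueError):
            gc_fraction(seq)


def test_gc_fraction_strand_symmetric(rng):
    for _ in range(20):
        s = random_dna(rng, int(rng.integers(10, 500)), gc=rng.uniform(0.2, 0.8))
        assert gc_fraction(s) == pytest.approx(gc_fraction(reverse_complement(s)))


def test_round_percent_half_up():
    assert round_percent(0.5475) == 54.8
    assert round_percent(0.99795) == 99.8


def test_zscores_mean_zero_and_identical_gc_rejected(rng):
    seq = random_dna(rng, 3000)
    orfs = [Orf(f"L{i}", 300 * i, 300 * i + 150, "+") for i in range(8)]
    rep = AnnotatedReplicon("R", seq, "linear", orfs)
    stats = orf_gc_zscores(rep)
    assert np.mean(list(stats.z.values())) == pytest.approx(0.0, abs=1e-9)
    for locus, gc in stats.per_orf_gc.items():
        assert stats.z[locus] == pytest.approx((gc - stats.mean) / stats.sd)
    same = AnnotatedReplicon("S", "ATGC" * 100, "linear",
                             [Orf("A", 0, 40, "+"), Orf("B", 40, 80, "+")])
    with pytest.raises(ValueError):
        orf_gc_zscores(same)


def test_planted_low_gc_island_orfs_score_below_minus_two(island_bundle):
    rep = island_bundle.replicon
    truth = island_bundle.truth.of_kind("island")[0]
    stats = orf_gc_zscores(rep)
    island_z = [stats.z[o.locus_tag] for o in rep.orfs
                if truth.start <= o.start and o.end <= truth.end]
    assert len(island_z) == 30
    assert all(z <= -2.0 for z in island_z)


@pytest.mark.parametrize("seq,expected", [("GGGG", 1.0), ("GGCC", 0.0),
                                          ("AATT", 0.0)])
def test_windowed_skew_single_window(seq, expected):
    prof = windowed_skew(seq, window=4, step=4)
    assert prof.skew[0] == pytest.approx(expected)


def test_windowed_skew_validation():
    with pytest.raises(ValueError):
        windowed_skew("ACGT", window=0, step=1)
    with pytest.raises(ValueError):
        windowed_skew("ACGT", window=8, step=1)


def test_cumulative_skew_ends_at_total_g_minus_c(rng):
    s = random_dna(rng, 5000)
    prof = windowed_skew(s, 500, 100)
    assert prof.cumulative[0] == 0
    assert len(prof.cumulative) == 5001
    assert prof.cumulative[-1] == s.count("G") - s.count("C")


def test_skew_antisymmetric_under_reverse_complement(rng):
    for _ in range(10):
        s = random_dna(rng, 2000, gc=rng.uniform(0.3, 0.7))
        f = windowed_skew(s, 200, 200).skew
        r = windowed_skew(reverse_complement(s), 200, 200).skew
        assert np.allclose(f, -r[::-1])


def test_reversal_detection_on_toy_profiles():
    prof = SkewProfile(window=2, step=2, centers=np.array([1, 3, 5, 7]),
                       skew=np.array([0.2, 0.2, -0.2, -0.2]),
                       cumulative=np.zeros(9), length=8)
    rep = find_skew_reversals(prof, min_run=2, smooth=1)
    assert len(rep.reversals) == 1
    allpos = SkewProfile(window=2, step=2, centers=np.array([1, 3, 5, 7]),
                         skew=np.array([0.2, 0.3, 0.2, 0.1]),
                         cumulative=np.zeros(9), length=8)
    assert find_skew_reversals(allpos, min_run=2, smooth=1).reversals == []


def test_two_replichore_synthetic_reversals_near_planted_ori_and_ter():
    spec = syn.SyntheticSpec(length=200_000)
    bundle = syn.generate(spec, seed=3)
    rep = bundle.replicon
    prof = windowed_skew(rep.seq, 10_000, 1_000, circular=True)
    report = find_skew_reversals(prof)
    ori = bundle.truth.of_kind("ori")[0]
    truth_pts = [(ori.start + ori.end) // 2, 0]
    assert len(report.reversals) == 2
    for t in truth_pts:
        d = min(
            min(abs(r.position - t), rep.length - abs(r.position - t))
            for r in report.reversals
        )
        assert d <= prof.window
    # cumulative-skew minimum is the classical origin estimate
    d = abs(report.ori_candidate - truth_pts[0])
    assert min(d, rep.length - d) <= prof.window
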