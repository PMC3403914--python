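import numpy as np
import pytest

from gisland.composition import GcStats
from gisland.codon_usage import CaiResult
from gisland.genome_io import AnnotatedReplicon, Orf
from gisland.islands import (
    EvidenceVector, Thresholds, call_islands, predict_origin, score_orfs,
)
from gisland.recovery import evaluate_bundle, interval_jaccard
from conftest import random_dna


def _orfs(n, size=300):
    return [Orf(f"L{i:03d}", size * i, size * i + size - 50, "+")
            for i in range(n)]


def _cai(locus, norm):
    return CaiResult(locus, 0.5, 0.5 / norm, norm, norm < 1.0)


def test_score_orfs_flag_logic_and_unknowns():
    orfs = _orfs(2)
    gc = GcStats({"L000": 0.37, "L001": 0.55}, 0.54, 0.02,
                 {"L000": -3.0, "L001": 0.5})
    cai = {"L000": _cai("L000", 0.8), "L001": _cai("L001", 1.1)}
    presence = {"L000": (0.2, True), "L001": (1.0, False)}
    ev = score_orfs(orfs, gc, cai, presence, [(0, 400)])
    hot, cold = ev
    assert (hot.low_gc, hot.foreign_cai, hot.absent_majority,
            hot.in_skew_disruption) == (True, True, True, True)
    assert hot.n_true == 4
    assert cold.n_true == 0
    # missing inputs -> unknown, never False
    ev = score_orfs(orfs, gc, None, None, None)
    assert ev[0].foreign_cai is None and ev[0].absent_majority is None
    assert ev[0].n_true == 1


def test_score_orfs_rejects_unknown_loci():
    orfs = _orfs(2)
    gc = GcStats({"ZZZ": 0.5}, 0.5, 0.1, {"ZZZ": 0.0})
    with pytest.raises(ValueError, match="coordinates"):
        score_orfs(orfs, gc)


def _evidence(pattern):
    """'h' = hot (2 flags), '.' = cold."""
    out = []
    for i, c in enumerate(pattern):
        hot = c == "h"
        out.append(EvidenceVector(f"L{i:03d}", low_gc=hot, foreign_cai=hot,
                                  absent_majority=None,
                                  in_skew_disruption=False))
    return out


def test_call_islands_run_merging_rules():
    orfs = _orfs(12)
    # alternating hot/cold with no gap tolerance: runs of 1 < min_orfs
    calls = call_islands(orfs, _evidence("h.h.h.h.h.h."), min_flags=2,
                         min_orfs=4, max_gap_orfs=0)
    assert calls == []
    # same pattern with gap tolerance 1 merges into one big run
    calls = call_islands(orfs, _evidence("h.h.h.h.h.h."), min_flags=2,
                         min_orfs=4, max_gap_orfs=1)
    assert len(calls) == 1 and calls[0].n_flagged == 6
    # a contiguous block of 5 hot ORFs is one island spanning them
    calls = call_islands(orfs, _evidence("..hhhhh....."), min_flags=2,
                         min_orfs=4, max_gap_orfs=2)
    assert len(calls) == 1
    assert calls[0].interval == (orfs[2].start, orfs[6].end)
    assert calls[0].orf_ids == [o.locus_tag for o in orfs[2:7]]


def test_call_islands_outputs_sorted_disjoint_and_threshold_monotone():
    orfs = _orfs(40)
    pattern = "..hhhhh....hhhhhh....hh................."
    ev = _evidence(pattern)
    calls = call_islands(orfs, ev)
    ivs = [c.interval for c in calls]
    assert ivs == sorted(ivs)
    assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
    base = len(calls)
    for mf, mo in [(3, 4), (2, 6), (4, 8)]:
        tighter = call_islands(orfs, ev, min_flags=mf, min_orfs=mo)
        assert len(tighter) <= base


def test_planted_island_recovered_with_high_jaccard(island_bundle):
    res = evaluate_bundle(island_bundle, n_boot=200, seed=0)
    assert res.n_islands_called == 1
    assert res.island_jaccards[0] >= 0.8
    assert res.ori_error is not None and res.ori_error <= 5_000


def test_interval_jaccard():
    assert interval_jaccard((0, 10), (0, 10)) == 1.0
    assert interval_jaccard((0, 10), (5, 15)) == pytest.approx(5 / 15)
    assert interval_jaccard((0, 10), (20, 30)) == 0.0


def test_predict_origin_flat_skew_reports_box_clusters_with_zero_skew_score(rng):
    # AT-only background has zero G+C skew everywhere
    box = "TTATCCACG"
    bg = "".join(np.array(list("AT"))[rng.choice(2, 6000)])
    seq = bg[:3000] + box + "TT" + box + "AA" + box + bg[3000:]
    rep = AnnotatedReplicon("FLAT", seq, "linear", [])
    cands = predict_origin(rep, window=500, min_boxes=2,
                           skew_window=1000, skew_step=100)
    assert cands, "box cluster should be reported despite flat skew"
    assert cands[0].n_dnaA_boxes >= 3
    assert cands[0].skew_score == 0.0


def test_predict_origin_no_boxes_no_reversals_empty(rng):
    rep = AnnotatedReplicon("R", random_dna(rng, 20_000), "linear", [])
    cands = predict_origin(rep, min_boxes=5)
    assert all(c.n_dnaA_boxes >= 5 for c in cands)
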