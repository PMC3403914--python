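"""Recovery harness: run the composition/codon evidence pipeline on a
synthetic bundle and join the calls to the planted ground truth.

This is the measurement loop used to calibrate the island caller and the
origin predictor on seeded synthetic replicons: it computes GC z-scores,
normalised CAI, and skew disruptions, calls islands, predicts the origin,
and reports interval overlap (Jaccard) against every planted island.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import codon_usage, composition
from .islands import Thresholds, call_islands, predict_origin, score_orfs
from .synthetic import SyntheticBundle


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap / union of two half-open intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


@dataclass
class RecoveryResult:
    island_jaccards: list[float]   # best Jaccard per planted island
    n_islands_called: int
    ori_error: int | None          # bp distance of top ori candidate to truth
    calls: list
    ori_candidates: list


def evaluate_bundle(bundle: SyntheticBundle, n_boot: int = 200,
                    seed: int = 0, thresholds: Thresholds | None = None,
                    min_flags: int = 2, min_orfs: int = 4,
                    max_gap_orfs: int = 2) -> RecoveryResult:
    """Evidence -> calls -> truth join for one synthetic bundle."""
    rep = bundle.replicon
    orfs = [o for o in rep.orfs if not o.pseudo]
    gc_stats = composition.orf_gc_zscores(rep, orfs)
    table = codon_usage.build_codon_table([rep.feature_seq(o) for o in orfs])
    rng = np.random.default_rng(seed)
    cai_results = {
        o.locus_tag: codon_usage.normalized_cai(
            o.locus_tag, rep.feature_seq(o), table, n_boot=n_boot,
            seed=rng, aa_seq=o.translation)
        for o in orfs
    }
    circular = rep.topology == "circular"
    sw = max(1000, min(10_000, rep.length // 20))
    profile = composition.windowed_skew(rep.seq, sw, sw // 10, circular=circular)
    skew_report = composition.find_skew_reversals(profile)
    evidence = score_orfs(orfs, gc_stats, cai_results, None,
                          skew_report.disruptions, thresholds)
    calls = call_islands(orfs, evidence, min_flags, min_orfs, max_gap_orfs)
    cands = predict_origin(rep, skew_window=sw, skew_step=sw // 10)

    jaccards = []
    for t in bundle.truth.of_kind("island"):
        best = max((interval_jaccard((t.start, t.end), c.interval)
                    for c in calls), default=0.0)
        jaccards.append(best)
    ori_error = None
    oris = bundle.truth.of_kind("ori")
    if oris and cands:
        truth_mid = (oris[0].start + oris[0].end) // 2
        d = abs(cands[0].skew_extremum_pos - truth_mid)
        if circular:
            d = min(d, rep.length - d)
        ori_error = int(d)
    return RecoveryResult(island_jaccards=jaccards, n_islands_called=len(calls),
                         ori_error=ori_error, calls=calls, ori_candidates=cands)
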