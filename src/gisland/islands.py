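"""Multi-evidence genomic-island calling and replication-origin prediction.

An island call integrates four independent per-ORF signals of lateral
acquisition: GC content well below the replicon average (z-score), codon
usage atypical for the host (normalised CAI < 1.00), absence of homologs
in a majority of reference genomes, and location inside a GC-skew
disruption.  Evidence is three-valued — True / False / unknown — so that a
missing input (e.g. no reference proteomes supplied) neither creates nor
suppresses calls.  ORFs with at least ``min_flags`` True flags are "hot";
maximal runs of hot ORFs, tolerating short cold gaps, become island calls.

Origin prediction follows the skew-plus-initiator-box logic of bacterial
ori finders: candidate regions are windows around cumulative-skew extrema
and persistent skew reversals (plus any free-standing cluster of boxes);
a region qualifies with >= ``min_boxes`` DnaA-box matches on either strand
and is scored by box count, then by how extreme the cumulative skew is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .composition import GcStats, SkewProfile, find_skew_reversals, windowed_skew
from .codon_usage import CaiResult
from .genome_io import AnnotatedReplicon, Orf
from .motif_scan import scan_pattern

DNAA_BOX_PATTERN = "TT(C|A)TCCAC(A|G)"


@dataclass
class Thresholds:
    z_thresh: float = -2.0
    cai_thresh: float = 1.00
    presence_majority: float = 0.5


@dataclass
class EvidenceVector:
    locus_tag: str
    low_gc: bool | None = None
    foreign_cai: bool | None = None
    absent_majority: bool | None = None
    in_skew_disruption: bool | None = None

    def flags(self) -> tuple[bool | None, ...]:
        return (self.low_gc, self.foreign_cai, self.absent_majority,
                self.in_skew_disruption)

    @property
    def n_true(self) -> int:
        return sum(1 for f in self.flags() if f is True)


def score_orfs(
    orfs: Sequence[Orf],
    gc_stats: GcStats | None = None,
    cai_results: Mapping[str, CaiResult] | None = None,
    presence: Mapping[str, tuple[float, bool]] | None = None,
    skew_disruptions: Sequence[tuple[int, int]] | None = None,
    thresholds: Thresholds | None = None,
) -> list[EvidenceVector]:
    """One evidence vector per ORF; missing inputs stay unknown (None)."""
    th = thresholds or Thresholds()
    coords = {o.locus_tag: o for o in orfs}
    for source, name in ((gc_stats.z if gc_stats else None, "gc_stats"),
                         (cai_results, "cai_results"), (presence, "presence")):
        if source:
            missing = set(source) - set(coords)
            if missing:
                raise ValueError(f"{name} has loci without coordinates: "
                                 f"{sorted(missing)[:5]}")
    out = []
    for o in orfs:
        ev = EvidenceVector(o.locus_tag)
        if gc_stats is not None and o.locus_tag in gc_stats.z:
            ev.low_gc = gc_stats.z[o.locus_tag] <= th.z_thresh
        if cai_results is not None and o.locus_tag in cai_results:
            ev.foreign_cai = cai_results[o.locus_tag].normalized < th.cai_thresh
        if presence is not None and o.locus_tag in presence:
            ev.absent_majority = presence[o.locus_tag][0] < th.presence_majority
        if skew_disruptions is not None:
            mid = (o.start + o.end) // 2
            ev.in_skew_disruption = any(s <= mid < e for s, e in skew_disruptions)
        out.append(ev)
    return out


@dataclass
class IslandCall:
    interval: tuple[int, int]
    orf_ids: list[str]
    evidence_summary: dict[str, int]
    n_flagged: int
    label: str


def call_islands(
    orfs: Sequence[Orf],
    evidence: Sequence[EvidenceVector],
    min_flags: int = 2,
    min_orfs: int = 4,
    max_gap_orfs: int = 2,
    labels: Sequence[str] | None = None,
) -> list[IslandCall]:
    """Merge runs of multi-evidence ORFs into island calls.

    An ORF is hot when >= ``min_flags`` of its flags are True (unknowns
    count neither way).  Runs of hot ORFs tolerate up to ``max_gap_orfs``
    consecutive cold ORFs; runs containing >= ``min_orfs`` hot ORFs are
    reported.  Output intervals are sorted and disjoint.
    """
    order = sorted(range(len(orfs)), key=lambda i: orfs[i].start)
    ev_by_locus = {e.locus_tag: e for e in evidence}
    hot = []
    for i in order:
        e = ev_by_locus.get(orfs[i].locus_tag)
        hot.append(e is not None and e.n_true >= min_flags)
    calls: list[IslandCall] = []
    i = 0
    m = len(order)
    while i < m:
        if not hot[i]:
            i += 1
            continue
        j = i
        last_hot = i
        gap = 0
        while j + 1 < m:
            if hot[j + 1]:
                last_hot = j + 1
                gap = 0
                j += 1
            elif gap < max_gap_orfs:
                gap += 1
                j += 1
            else:
                break
        members = order[i : last_hot + 1]
        n_hot = sum(1 for idx in range(i, last_hot + 1) if hot[idx])
        if n_hot >= min_orfs:
            member_orfs = [orfs[k] for k in members]
            interval = (member_orfs[0].start, member_orfs[-1].end)
            summary = {"low_gc": 0, "foreign_cai": 0, "absent_majority": 0,
                       "in_skew_disruption": 0}
            for o in member_orfs:
                e = ev_by_locus.get(o.locus_tag)
                if e is None:
                    continue
                for name in summary:
                    if getattr(e, name) is True:
                        summary[name] += 1
            label = (labels[len(calls)] if labels and len(calls) < len(labels)
                     else f"island-{len(calls) + 1}")
            calls.append(IslandCall(interval=interval,
                                    orf_ids=[o.locus_tag for o in member_orfs],
                                    evidence_summary=summary,
                                    n_flagged=n_hot, label=label))
        i = last_hot + 1
    return calls


@dataclass
class OriCandidate:
    interval: tuple[int, int]
    skew_extremum_pos: int
    n_dnaA_boxes: int
    score: float
    skew_score: float
    intergenic: bool = False


def predict_origin(
    replicon: AnnotatedReplicon,
    dnaA_pattern: str = DNAA_BOX_PATTERN,
    window: int = 1_000,
    min_boxes: int = 2,
    skew_window: int | None = None,
    skew_step: int | None = None,
    min_run: int = 5,
    smooth: int = 5,
) -> list[OriCandidate]:
    """Rank candidate replication origins.

    Candidate centres are the cumulative-skew extrema, persistent skew
    reversals, and any cluster of >= ``min_boxes`` DnaA boxes; each centre
    is scored by the box count within +/- ``window`` and by the relative
    extremity of the cumulative skew there (0 for a flat profile).
    """
    n = replicon.length
    circular = replicon.topology == "circular"
    if skew_window is None:
        skew_window = max(500, min(10_000, n // 20))
    if skew_step is None:
        skew_step = max(100, skew_window // 10)
    profile = windowed_skew(replicon.seq, skew_window, skew_step, circular=circular)
    report = find_skew_reversals(profile, min_run=min_run, smooth=smooth)
    boxes = scan_pattern(replicon.seq, dnaA_pattern, pattern_id="DnaA",
                         both_strands=True, circular=circular)
    box_pos = np.array(sorted(h.position for h in boxes), dtype=np.int64)

    def count_near(center: int) -> int:
        if len(box_pos) == 0:
            return 0
        d = np.abs(box_pos - center)
        if circular:
            d = np.minimum(d, n - d)
        return int((d <= window).sum())

    cum = profile.cumulative
    lo, hi = float(cum.min()), float(cum.max())
    span = hi - lo
    seq_u = replicon.seq.upper()
    n_gc = seq_u.count("G") + seq_u.count("C")
    # a cumulative drift within random-walk noise carries no ori signal
    noise_floor = 4.0 * np.sqrt(max(n_gc, 1))

    def skew_score(center: int) -> float:
        if span <= noise_floor:
            return 0.0
        v = float(cum[min(center, n)])
        return abs(v - float(np.median(cum))) / span

    centers: list[int] = [report.ori_candidate, report.ter_candidate]
    centers += [r.position for r in report.reversals]
    # free-standing box clusters (no skew anchor needed)
    run: list[int] = []
    for p in box_pos:
        if run and p - run[-1] > window:
            if len(run) >= min_boxes:
                centers.append(int(np.mean(run)))
            run = []
        run.append(int(p))
    if len(run) >= min_boxes:
        centers.append(int(np.mean(run)))

    cands: list[OriCandidate] = []
    for c in centers:
        c = int(c) % n if circular else int(np.clip(c, 0, n))
        nb = count_near(c)
        if nb < min_boxes:
            continue
        mid_in_orf = any(o.start <= c < o.end for o in replicon.orfs)
        cands.append(OriCandidate(
            interval=(max(0, c - window), min(n, c + window)),
            skew_extremum_pos=c, n_dnaA_boxes=nb,
            score=nb + skew_score(c), skew_score=skew_score(c),
            intergenic=not mid_in_orf,
        ))
    # merge near-duplicate centres, keeping the best-scoring one
    cands.sort(key=lambda x: -x.score)
    kept: list[OriCandidate] = []
    for cand in cands:
        if all(abs(cand.skew_extremum_pos - k.skew_extremum_pos) > window
               for k in kept):
            kept.append(cand)
    return kept
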