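"""Nucleotide-composition statistics.

GC fraction, per-ORF GC z-scores against the replicon-wide ORF average,
windowed and cumulative GC-skew, and detection of skew reversals.  Skew is
defined per window as (G - C) / (G + C); the two global extrema of the
cumulative per-base (G - C) sum are the classical origin/terminus
candidates for a two-replichore bacterial chromosome, while additional
persistent sign changes of the windowed skew mark local disruptions of the
expected strand bias (a lateral-acquisition signal).

Per-ORF GC is computed on the coding strand (GC content is strand
symmetric, so this equals the forward-strand value).  z-scores use the
population standard deviation: the ORF set is the whole population of
interest, not a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import AnnotatedReplicon, Orf

_GC = frozenset("GC")
_UNAMBIG = frozenset("ACGT")


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#unambiguous bases); ambiguous bases are excluded from
    both numerator and denominator."""
    seq = seq.upper()
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("empty or all-ambiguous sequence has no GC fraction")
    return (seq.count("G") + seq.count("C")) / denom


def round_percent(x: float, ndigits: int = 1) -> float:
    """Round a fraction to a percentage, half-up, at report precision."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GcStats:
    per_orf_gc: dict[str, float]
    mean: float
    sd: float
    z: dict[str, float]


def orf_gc_zscores(replicon: AnnotatedReplicon,
                   orfs: Sequence[Orf] | None = None) -> GcStats:
    """Per-ORF GC and its z-score against the replicon-wide ORF mean/SD."""
    if orfs is None:
        orfs = [o for o in replicon.orfs if not o.pseudo]
    if len(orfs) < 2:
        raise ValueError("need at least 2 ORFs for z-scores")
    gc = {o.locus_tag: gc_fraction(replicon.feature_seq(o)) for o in orfs}
    vals = np.array(list(gc.values()))
    mean = float(vals.mean())
    sd = float(vals.std())  # population SD
    if sd == 0:
        raise ValueError("degenerate input: all ORFs have identical GC")
    z = {k: (v - mean) / sd for k, v in gc.items()}
    return GcStats(per_orf_gc=gc, mean=mean, sd=sd, z=z)


@dataclass
class SkewProfile:
    window: int
    step: int
    centers: np.ndarray  # window centre positions (bases)
    skew: np.ndarray     # (G-C)/(G+C) per window, in [-1, 1]
    cumulative: np.ndarray  # running per-base (G-C) sum, length n+1
    circular: bool = False
    length: int = 0


def windowed_skew(seq: str, window: int = 10_000, step: int = 1_000,
                  circular: bool = False) -> SkewProfile:
    """GC-skew per sliding window plus the cumulative per-base (G-C) sum.

    Windows of size ``window`` advance by ``step``; on circular sequences
    the final windows wrap the origin so every start position in
    ``range(0, n, step)`` is covered.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    n = len(seq)
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    g = (arr == ord("G")).astype(np.int64)
    c = (arr == ord("C")).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(g - c)])
    cg = np.concatenate([[0], np.cumsum(g)])
    cc = np.concatenate([[0], np.cumsum(c)])
    if circular:
        starts = np.arange(0, n, step)
    else:
        starts = np.arange(0, n - window + 1, step)
    ends = starts + window
    wrap = ends > n

    def _wsum(cumv, s, e):
        out = np.empty(len(s), dtype=np.int64)
        nw = ~wrap
        out[nw] = cumv[e[nw]] - cumv[s[nw]]
        if wrap.any():
            out[wrap] = (cumv[n] - cumv[s[wrap]]) + cumv[e[wrap] - n]
        return out

    gs = _wsum(cg, starts, ends)
    cs = _wsum(cc, starts, ends)
    tot = gs + cs
    skew = np.zeros(len(starts), dtype=float)
    nz = tot > 0
    skew[nz] = (gs[nz] - cs[nz]) / tot[nz]
    centers = (starts + window // 2) % n if circular else starts + window // 2
    return SkewProfile(window=window, step=step, centers=centers, skew=skew,
                       cumulative=cum, circular=circular, length=n)


@dataclass
class SkewReversal:
    position: int       # base position of the sign change
    direction: int      # +1: skew goes negative->positive, -1: opposite
    run_before: int     # persistent windows before the change
    run_after: int


@dataclass
class SkewReversalReport:
    reversals: list[SkewReversal]
    ori_candidate: int  # global minimum of cumulative skew
    ter_candidate: int  # global maximum
    disruptions: list[tuple[int, int]] = field(default_factory=list)


def smooth_profile(skew: np.ndarray, k: int = 5) -> np.ndarray:
    """Centred moving average over ``k`` windows (edges use shorter means)."""
    if k <= 1:
        return skew.astype(float)
    kernel = np.ones(k)
    num = np.convolve(skew, kernel, mode="same")
    den = np.convolve(np.ones_like(skew, dtype=float), kernel, mode="same")
    return num / den


def find_skew_reversals(profile: SkewProfile, min_run: int = 5,
                        smooth: int = 5) -> SkewReversalReport:
    """Persistent sign changes of the smoothed windowed skew.

    A reversal is a boundary between a run of >= ``min_run`` windows of one
    sign and a following run of >= ``min_run`` windows of the opposite
    sign.  The two global extrema of the cumulative skew are reported as
    ori/ter candidates; every reversal interval is also reported as a
    disruption interval (callers decide which reversals are the replichore
    boundaries and which are local anomalies).
    """
    sm = smooth_profile(profile.skew, smooth)
    signs = np.sign(sm)
    # collapse runs of equal nonzero sign; zeros inherit the previous sign
    runs: list[tuple[int, int, int]] = []  # (sign, start_idx, length)
    prev = 0
    for i, s in enumerate(signs):
        s = int(s) or prev
        if runs and runs[-1][0] == s:
            sgn, st, ln = runs[-1]
            runs[-1] = (sgn, st, ln + 1)
        else:
            runs.append((int(s), i, 1))
        prev = s
    reversals = []
    for (s1, st1, l1), (s2, st2, l2) in zip(runs, runs[1:]):
        if s1 != 0 and s2 != 0 and s1 != s2 and l1 >= min_run and l2 >= min_run:
            pos = int(profile.centers[st2 - 1] + profile.step // 2)
            reversals.append(
                SkewReversal(position=pos % max(profile.length, 1),
                             direction=s2, run_before=l1, run_after=l2)
            )
    if profile.circular and len(runs) >= 2:
        (sf, stf, lf), (sl, stl, ll) = runs[0], runs[-1]
        if sf != 0 and sl != 0 and sf != sl and lf >= min_run and ll >= min_run:
            # the flip wraps the coordinate origin
            pos = int(profile.centers[-1] + profile.step // 2) % max(profile.length, 1)
            reversals.append(SkewReversal(position=pos, direction=sf,
                                          run_before=ll, run_after=lf))
    ori = int(np.argmin(profile.cumulative))
    ter = int(np.argmax(profile.cumulative))
    disruptions = [
        (max(r.position - profile.window, 0), r.position + profile.window)
        for r in reversals
    ]
    return SkewReversalReport(reversals=reversals, ori_candidate=ori,
                              ter_candidate=ter, disruptions=disruptions)
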