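"""Maximal repeat detection, tandem-duplication calling, and flanking-repeat
checks around candidate genomic islands.

Maximal exact repeats (direct and inverted) are found by seed-and-extend
over a k-mer index with k = the minimum reported length: every repeated
pair is extended in both directions until a mismatch or a sequence end, so
extending any reported pair by one base breaks the match.  Tandem
duplications are built from direct-repeat seeds sharing one diagonal
offset, merged across the isolated mismatches that interrupt exact
matches, and scored by global alignment of the two blocks (identical
columns / alignment length, to one decimal) - the resolution at which
near-identical duplicated blocks are normally reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from ._seq import reverse_complement

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class RepeatPair:
    pos1: int
    pos2: int
    length: int
    orientation: str  # direct | inverted
    identity: float = 100.0

    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.pos1, self.pos1 + self.length), (self.pos2, self.pos2 + self.length)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _extend_direct(seq: str, p1: int, p2: int, k: int) -> tuple[int, int, int]:
    n = len(seq)
    left = 0
    while p1 - left - 1 >= 0 and seq[p1 - left - 1] == seq[p2 - left - 1]:
        left += 1
    right = 0
    while p2 + k + right < n and seq[p1 + k + right] == seq[p2 + k + right]:
        right += 1
    return p1 - left, p2 - left, k + left + right


def _extend_inverted(seq: str, s1: int, s2: int, k: int) -> tuple[int, int, int]:
    # seq[s1:s1+k] == revcomp(seq[s2:s2+k]) with disjoint arms (s1+L <= s2).
    # Outward: grow occurrence 1 leftward while occurrence 2 grows rightward;
    # inward: the converse, stopping when the arms would cross.
    n = len(seq)
    e1, e2 = s1 + k, s2 + k
    while s1 - 1 >= 0 and e2 < n and seq[s1 - 1] == _COMP.get(seq[e2], "?"):
        s1 -= 1
        e2 += 1
    while (e1 + 1 <= s2 - 1 and e1 < n and s2 - 1 >= 0
           and seq[e1] == _COMP.get(seq[s2 - 1], "?")):
        e1 += 1
        s2 -= 1
    return s1, s2, e1 - s1


def maximal_repeats(
    seq: str,
    min_len: int = 15,
    orientation: Literal["direct", "inverted", "both"] = "both",
) -> list[RepeatPair]:
    """All maximal exact repeated pairs of length >= ``min_len``.

    A pair is maximal when extending it by one base on either side breaks
    the match (or hits a sequence end, or — for inverted pairs — the arms
    would cross).  ``inverted`` pairs match the reverse complement and are
    reported with disjoint arms (``pos1 + length <= pos2``); direct pairs
    may overlap (tandem period < length) and satisfy ``pos1 < pos2``.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = seq.upper()
    n = len(seq)
    out: set[RepeatPair] = set()
    if min_len > n:
        return []
    idx = _kmer_index(seq, min_len)
    if orientation in ("direct", "both"):
        for positions in idx.values():
            if len(positions) < 2:
                continue
            for i, p1 in enumerate(positions):
                for p2 in positions[i + 1 :]:
                    s1, s2, L = _extend_direct(seq, p1, p2, min_len)
                    out.add(RepeatPair(s1, s2, L, "direct"))
    if orientation in ("inverted", "both"):
        for km, positions in idx.items():
            rc = reverse_complement(km)
            if rc < km:
                continue  # pair handled from the lexicographically lower k-mer
            qos = idx.get(rc, []) if rc != km else positions
            for p1 in positions:
                for p2 in qos:
                    lo, hi = (p1, p2) if p1 <= p2 else (p2, p1)
                    if lo + min_len > hi:
                        continue  # crossing arms (sub-palindrome); not reported
                    s1, s2, L = _extend_inverted(seq, lo, hi, min_len)
                    out.add(RepeatPair(s1, s2, L, "inverted"))
    return sorted(out, key=lambda r: (r.pos1, r.pos2, r.orientation))


# ---------------------------------------------------------------------------
# Tandem duplications

@dataclass
class TandemDup:
    block1: tuple[int, int]
    block2: tuple[int, int]
    length: int
    identity: float  # percent, one decimal
    gap: int         # bases between block1 end and block2 start
    n_mismatch: int = 0


def _block_identity(a: str, b: str) -> tuple[float, int, int]:
    """Global-alignment identity of two blocks: (percent, columns, mismatches)."""
    import edlib

    res = edlib.align(a, b, mode="NW", task="path")
    matches = cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ln = int(num)
            cols += ln
            if ch == "=":
                matches += ln
            num = ""
    from .composition import round_percent

    pct = round_percent(matches / cols) if cols else 0.0
    return pct, cols, cols - matches


def tandem_duplications(
    seq: str,
    min_block: int = 500,
    max_gap: int = 1_000,
    max_mismatch_frac: float = 0.05,
    seed_len: int = 20,
    max_join: int = 200,
) -> list[TandemDup]:
    """Near-identical tandemly duplicated blocks.

    Direct maximal-repeat seeds sharing one diagonal offset are merged
    (tolerating the interruptions that point mismatches cause) into block
    pairs; pairs at least ``min_block`` long, separated by at most
    ``max_gap``, and within ``max_mismatch_frac`` divergence are reported
    with their global-alignment identity.
    """
    seq = seq.upper()
    seeds = [r for r in maximal_repeats(seq, min_len=seed_len, orientation="direct")]
    by_offset: dict[int, list[RepeatPair]] = {}
    for r in seeds:
        by_offset.setdefault(r.pos2 - r.pos1, []).append(r)
    out = []
    for d, group in sorted(by_offset.items()):
        group.sort(key=lambda r: r.pos1)
        cluster_start, cluster_end = group[0].pos1, group[0].pos1 + group[0].length
        clusters = []
        for r in group[1:]:
            if r.pos1 <= cluster_end + max_join:
                cluster_end = max(cluster_end, r.pos1 + r.length)
            else:
                clusters.append((cluster_start, cluster_end))
                cluster_start, cluster_end = r.pos1, r.pos1 + r.length
        clusters.append((cluster_start, cluster_end))
        for s, e in clusters:
            span = e - s
            # the duplication period is d: block1 may not exceed it
            span = min(span, d)
            e = s + span
            gap = d - span
            if span < min_block or gap < 0 or gap > max_gap:
                continue
            b1 = seq[s:e]
            b2 = seq[s + d : e + d]
            ident, cols, mism = _block_identity(b1, b2)
            if cols and mism / cols <= max_mismatch_frac:
                out.append(
                    TandemDup(block1=(s, e), block2=(s + d, e + d),
                              length=span, identity=ident, gap=gap,
                              n_mismatch=mism)
                )
    return sorted(out, key=lambda t: t.block1)


def flanking_repeats(
    seq: str,
    island_interval: tuple[int, int],
    search_window: int = 2_000,
    min_len: int = 15,
    orientation: Literal["direct", "inverted", "both"] = "both",
) -> list[RepeatPair]:
    """Repeat pairs with one member in each flank of an island interval.

    Flanks are ``search_window`` bases on either side (truncated with a
    warning at sequence ends).  Coordinates in the result are absolute.
    Mobile elements are typically bounded by terminal direct or inverted
    repeats; an empty result is evidence against a cut-and-paste origin.
    """
    n = len(seq)
    s, e = island_interval
    lf = (max(0, s - search_window), s)
    rf = (e, min(n, e + search_window))
    if lf[0] == 0 and s - search_window < 0 or rf[1] == n and e + search_window > n:
        log.warning("island interval at sequence end; flank window truncated")
    region = seq[lf[0] : rf[1]]
    off = lf[0]
    found = maximal_repeats(region, min_len=min_len, orientation=orientation)
    out = []
    for r in found:
        (a1, a2), (b1, b2) = r.intervals()
        a1, a2, b1, b2 = a1 + off, a2 + off, b1 + off, b2 + off
        in_left = a1 < lf[1] and a2 > lf[0]
        in_right = b1 < rf[1] and b2 > rf[0]
        if in_left and in_right:
            out.append(RepeatPair(a1, b1, r.length, r.orientation, r.identity))
    return out
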