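"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by a method unrelated to the package's
implementation (quadratic DP, exhaustive position scans, anti-diagonal
run finding), so agreement is evidence of correctness rather than of
shared code paths.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Smith-Waterman with affine gaps: straightforward three-matrix DP.

def sw_affine_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Optimal local-alignment score; ``sub[(x, y)]`` is the match score.

    Affine penalty: a gap of length k costs gap_open + (k-1)*gap_extend
    (the first gapped position pays the open cost), matching the common
    BLAST-style convention.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            diag = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1], 0.0)
            M[i, j] = diag + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j], X[i, j], Y[i, j])
    return best


# ---------------------------------------------------------------------------
# Maximal repeats by exhaustive diagonal / anti-diagonal run scanning.

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs in a boolean vector."""
    if mask.size == 0:
        return
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    for s, e in zip(starts, ends):
        yield int(s), int(e - s)


def brute_direct_repeats(seq: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal direct pairs (pos1, pos2, length), pos1 < pos2."""
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(s)
    out = set()
    for d in range(1, n):
        eq = s[: n - d] == s[d:]
        for start, length in _runs(eq):
            if length >= min_len:
                out.add((start, start + d, length))
    return out


def brute_inverted_repeats(seq: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal inverted pairs with disjoint arms (pos1+len <= pos2).

    Base u of arm 1 pairs with base v of arm 2 where u + v = m is constant
    along a pair; scanning complement-match runs over each anti-diagonal m
    and truncating at the arm-crossing midpoint enumerates every maximal
    pair.
    """
    comp = np.frombuffer("".join(_COMP[c] for c in seq).encode(), dtype=np.uint8)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(s)
    out = set()
    for m in range(2 * min_len - 1, 2 * n - 1):
        pmin = max(0, m - n + 1)
        half = (m - 1) // 2  # largest p with p < m - p
        if half < pmin:
            continue
        p = np.arange(pmin, half + 1)
        b = s[p] == comp[m - p]
        for start, length in _runs(b):
            if length < min_len:
                continue
            i = pmin + start
            p1 = i + length - 1
            # maximality on the left: b[i-1] False or boundary (guaranteed
            # by _runs); on the right: run end or midpoint crossing.
            out.add((i, m - p1, length))
    return out


def brute_pattern_positions(seq: str, pattern_bases: list[set]) -> list[int]:
    L = len(pattern_bases)
    return [
        i
        for i in range(len(seq) - L + 1)
        if all(seq[i + j] in pattern_bases[j] for j in range(L))
    ]


# ---------------------------------------------------------------------------
# Genetic code, bacterial table 11, written out longhand.

_T11 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def table11_translate(dna: str) -> str:
    aa = [_T11[dna[i : i + 3]] for i in range(0, len(dna), 3)]
    if aa and aa[-1] == "*":
        aa = aa[:-1]
    return "".join(aa)
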