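"""Low-level nucleotide helpers shared across modules.

All sequences are plain uppercase Python strings over the IUPAC nucleotide
alphabet.  Ambiguity codes other than N are accepted everywhere but are
treated as N (i.e. excluded) by composition statistics.
"""

from __future__ import annotations

import re

COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)

#: IUPAC nucleotide code -> set of unambiguous bases it stands for
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_AMBIG = set("MRWSYKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern with optional ``(x|y)`` alternation groups
    into a Python regex.  ``TT(C|A)TCCAC(A|G)`` -> ``TT[CA]TCCAC[AG]``.
    """
    out = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            j = pattern.find(")", i)
            if j < 0:
                raise ValueError(f"unbalanced '(' in pattern {pattern!r}")
            alts = pattern[i + 1 : j].split("|")
            bases = set()
            for alt in alts:
                if len(alt) != 1 or alt.upper() not in IUPAC:
                    raise ValueError(f"invalid alternation {alt!r} in {pattern!r}")
                bases.update(IUPAC[alt.upper()])
            out.append("[" + "".join(sorted(bases)) + "]")
            i = j + 1
        else:
            cu = ch.upper()
            if cu not in IUPAC:
                raise ValueError(f"invalid pattern character {ch!r} in {pattern!r}")
            bases = IUPAC[cu]
            out.append(bases if len(bases) == 1 else "[" + bases + "]")
            i += 1
    return "".join(out)


def matches_iupac(site: str, pattern_bases: list[set]) -> bool:
    """Position-by-position IUPAC match of an unambiguous site."""
    if len(site) != len(pattern_bases):
        return False
    return all(b in allowed for b, allowed in zip(site, pattern_bases))


def expand_pattern(pattern: str) -> list[set]:
    """Pattern string -> list of allowed-base sets (alternation supported)."""
    rx = iupac_to_regex(pattern)
    out = []
    for m in re.finditer(r"\[([A-Z]+)\]|([A-Z])", rx):
        out.append(set(m.group(1) or m.group(2)))
    return out


def is_unambiguous(seq: str) -> bool:
    return not any(c in _AMBIG for c in seq)
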