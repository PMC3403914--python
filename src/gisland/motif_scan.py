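"""Degenerate nucleotide-pattern scanning, the CxxCH heme-motif census,
and in-silico PCR.

Patterns are IUPAC strings optionally using ``(x|y)`` alternation groups,
e.g. the DnaA-box consensus ``TT(C|A)TCCAC(A|G)``.  All scans report
overlapping occurrences.  The heme census counts CxxCH occurrences (the
covalent heme-attachment motif of c-type cytochromes) per protein; an
optional homology screen against a labelled reference set removes proteins
whose database matches are mostly not c-type cytochromes, mimicking how
spurious CxxCH hits are eliminated in practice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from ._seq import expand_pattern, iupac_to_regex, reverse_complement
from .genome_io import AnnotatedReplicon


@dataclass
class MotifHit:
    pattern_id: str
    position: int       # 0-based start on the forward strand
    strand: str         # "+" or "-"
    matched_text: str   # slice (or its reverse complement on "-")


def scan_pattern(
    seq: str,
    pattern: str,
    pattern_id: str | None = None,
    both_strands: bool = True,
    circular: bool = False,
) -> list[MotifHit]:
    """All (overlapping) occurrences of an IUPAC/alternation pattern.

    Minus-strand hits are positions where the pattern matches the reverse
    complement; their ``position`` is the forward-strand start of the site.
    On circular sequences matches spanning the origin are included.
    """
    pid = pattern_id if pattern_id is not None else pattern
    rx = re.compile("(?=(" + iupac_to_regex(pattern) + "))")
    plen = len(expand_pattern(pattern))
    n = len(seq)
    seq = seq.upper()
    search_seq = seq + seq[: plen - 1] if circular and plen > 1 else seq
    hits: list[MotifHit] = []
    seen: set[tuple[int, str]] = set()

    for m in rx.finditer(search_seq):
        pos = m.start() % n if circular else m.start()
        if (pos, "+") in seen:
            continue
        seen.add((pos, "+"))
        hits.append(MotifHit(pid, pos, "+", m.group(1)))
    if both_strands:
        rc = reverse_complement(seq)
        search_rc = rc + rc[: plen - 1] if circular and plen > 1 else rc
        for m in rx.finditer(search_rc):
            rpos = m.start() % n if circular else m.start()
            pos = (n - rpos - plen) % n if circular else n - rpos - plen
            if (pos, "-") in seen:
                continue
            seen.add((pos, "-"))
            hits.append(MotifHit(pid, pos, "-", m.group(1)))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# CxxCH heme-motif census

HEME_MOTIF = re.compile(r"(?=C..CH)")


@dataclass
class HemeCensusEntry:
    locus_tag: str
    motif_count: int
    motif_positions: list[int] = field(default_factory=list)
    status: str = "unscreened"  # unscreened | retained | rejected
    annotated_fraction: float | None = None


def heme_motif_census(
    proteome: Sequence[tuple[str, str]]
) -> list[HemeCensusEntry]:
    """Count CxxCH occurrences per protein (overlaps counted).

    ``proteome`` is a sequence of ``(locus_tag, aa_seq)`` pairs; only
    proteins with at least one motif are returned (the census of c-type
    cytochrome candidates).
    """
    out = []
    for locus, aa in proteome:
        positions = [m.start() for m in HEME_MOTIF.finditer(aa.upper())]
        if positions:
            out.append(HemeCensusEntry(locus, len(positions), positions))
    return out


@dataclass
class ReferenceProtein:
    id: str
    seq: str
    is_cytochrome: bool


def screen_cytochrome_candidates(
    census: Sequence[HemeCensusEntry],
    proteome: dict[str, str],
    reference_db: Sequence[ReferenceProtein] | None,
    evalue_cutoff: float = 1e-5,
    min_annotated_fraction: float = 0.5,
    matrix: str = "BLOSUM62",
) -> list[HemeCensusEntry]:
    """Homology screen of CxxCH candidates against a labelled reference set.

    For each candidate, reference proteins aligning below the e-value
    cutoff are its hits; the candidate is retained iff at least one hit
    exists and the fraction of hits labelled as c-type cytochromes is
    >= ``min_annotated_fraction`` (candidates *lacking over 50%* annotated
    hits are eliminated; exactly 50% retains).  Candidates without hits are
    rejected.  Without a reference set all entries stay unscreened.
    """
    if reference_db is None:
        return list(census)
    for r in reference_db:
        if not isinstance(r.is_cytochrome, bool):
            raise ValueError(f"reference {r.id} lacks a boolean cytochrome label")
    from .homology import database_hits

    out = []
    for entry in census:
        aa = proteome[entry.locus_tag]
        hits = database_hits(aa, [(r.id, r.seq) for r in reference_db],
                             cutoff_evalue=evalue_cutoff, matrix=matrix)
        labels = {r.id: r.is_cytochrome for r in reference_db}
        n_hits = len(hits)
        e = HemeCensusEntry(entry.locus_tag, entry.motif_count,
                            list(entry.motif_positions))
        if n_hits == 0:
            e.status = "rejected"
            e.annotated_fraction = None
        else:
            frac = sum(1 for h in hits if labels[h.subject_id]) / n_hits
            e.annotated_fraction = frac
            e.status = "retained" if frac >= min_annotated_fraction else "rejected"
        out.append(e)
    return out


def census_report(census: Sequence[HemeCensusEntry]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "locus_tag": e.locus_tag,
                "motif_count": e.motif_count,
                "status": e.status,
                "annotated_fraction": e.annotated_fraction,
                "multiheme_gt10": e.motif_count > 10,
            }
            for e in census
        ]
    )


# ---------------------------------------------------------------------------
# In-silico PCR

@dataclass
class Amplicon:
    fwd_start: int    # 0-based start of the forward-primer site
    rev_end: int      # half-open end of the reverse-primer site
    length: int       # product length, both primers included
    product_seq: str


def _primer_sites(seq: str, primer: str, max_mismatch: int,
                  protect_3prime_left: bool) -> list[int]:
    """Start positions where ``primer`` (given as a plus-strand pattern)
    anneals.  Mismatches are never allowed in the 3 bases at the primer's
    3' end; for a reverse primer written as its reverse complement the 3'
    end is the *left* edge of the site (``protect_3prime_left``)."""
    pat = expand_pattern(primer)
    L = len(pat)
    n = len(seq)
    if max_mismatch == 0:
        rx = re.compile("(?=(" + iupac_to_regex(primer) + "))")
        return [m.start() for m in rx.finditer(seq)]
    protected = range(0, 3) if protect_3prime_left else range(L - 3, L)
    sites = []
    for i in range(n - L + 1):
        mm = 0
        ok = True
        for j in range(L):
            if seq[i + j] not in pat[j]:
                if j in protected:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok:
            sites.append(i)
    return sites


def insilico_pcr(
    template: AnnotatedReplicon | str,
    fwd: str,
    rev: str,
    max_mismatch: int = 0,
    max_len: int = 10_000,
    circular: bool | None = None,
) -> list[Amplicon]:
    """Predict PCR products on a template.

    The forward primer is matched on the plus strand; the reverse primer
    anneals to the plus strand as its reverse complement downstream of the
    forward site.  Product length counts both primers inclusively and must
    not exceed ``max_len``.  Circular templates support products spanning
    the origin.  Ambiguous primer bases are expanded per IUPAC; mismatches
    (``max_mismatch`` > 0) are never allowed in the 3 terminal 3' bases.
    """
    if isinstance(template, AnnotatedReplicon):
        seq = template.seq
        if circular is None:
            circular = template.topology == "circular"
    else:
        seq = template.upper()
        circular = bool(circular)
    for p in (fwd, rev):
        if not (15 <= len(p) <= 35):
            raise ValueError(f"primer length {len(p)} outside 15-35 nt")
    n = len(seq)
    search = seq + seq[: min(max_len, n)] if circular else seq
    rc_rev = reverse_complement(rev.upper())
    f_sites = [s for s in _primer_sites(search, fwd, max_mismatch, False) if s < n]
    r_sites = _primer_sites(search, rc_rev, max_mismatch, True)
    r_ends = sorted(s + len(rc_rev) for s in r_sites)
    out = []
    for fs in f_sites:
        for re_ in r_ends:
            if re_ <= fs + len(fwd):
                continue
            length = re_ - fs
            if length > max_len:
                break
            product = search[fs:re_]
            out.append(Amplicon(fwd_start=fs % n, rev_end=re_ % n if circular else re_,
                                length=length, product_seq=product))
    # de-duplicate products found twice via the circular extension
    uniq: dict[tuple[int, int], Amplicon] = {}
    for a in out:
        uniq.setdefault((a.fwd_start, a.length), a)
    return sorted(uniq.values(), key=lambda a: (a.fwd_start, a.length))
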