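"""Pairwise protein alignment, best-hit search, proteome AAI, top-hit
affiliation, homolog-presence profiling, and diffing of near-identical
nucleotide sequences.

Local alignment is Smith-Waterman with affine gaps (Bio.Align's
C-accelerated PairwiseAligner).  Percent identity is identical aligned
columns divided by the alignment length, gaps included.  Significance uses
the Karlin-Altschul formula E = K.m.n.exp(-lambda.S) with the published
gapped constants for the scoring system in use; for database searches n is
the total residue count of the database, so e-values behave like BLAST's.

AAI (average amino acid identity) between two proteomes is the mean percent
identity over one-way best hits passing the e-value cutoff - the standard
whole-proteome relatedness measure for comparing bacterial genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from ._seq import reverse_complement

Proteome = Sequence[tuple[str, str]]  # (id, aa_seq) pairs

#: (matrix, gap_open, gap_extend) -> (lambda, K); NCBI gapped values
KARLIN_ALTSCHUL = {
    ("BLOSUM62", 11, 1): (0.267, 0.041),
    ("BLOSUM45", 14, 2): (0.195, 0.032),
}
#: defaults mirroring common BlastP practice
DEFAULT_PARAMS = {"BLOSUM62": (11, 1), "BLOSUM45": (14, 2)}


@dataclass
class HitRecord:
    query_id: str
    subject_id: str
    identity: float   # percent over aligned columns (gaps included)
    aln_len: int
    raw_score: float
    bit_score: float
    evalue: float


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int):
    from Bio.Align import PairwiseAligner, substitution_matrices

    try:
        m = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    return PairwiseAligner(
        mode="local",
        substitution_matrix=m,
        open_gap_score=-float(gap_open),
        extend_gap_score=-float(gap_extend),
    )


def _ka_params(matrix: str, gap_open: int, gap_extend: int) -> tuple[float, float]:
    try:
        return KARLIN_ALTSCHUL[(matrix, gap_open, gap_extend)]
    except KeyError:
        raise ValueError(
            f"no Karlin-Altschul constants for {matrix} {gap_open}/{gap_extend}; "
            f"supported: {sorted(KARLIN_ALTSCHUL)}"
        )


def _evalue(raw_score: float, m: int, n: int, lam: float, K: float) -> tuple[float, float]:
    bit = (lam * raw_score - math.log(K)) / math.log(2)
    ev = K * m * n * math.exp(-lam * raw_score)
    return bit, ev


def align_local(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int | None = None,
    gap_extend: int | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    db_residues: int | None = None,
) -> HitRecord:
    """Optimal Smith-Waterman local alignment of two proteins.

    ``db_residues`` substitutes for len(b) in the e-value when the subject
    is one member of a larger database.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if gap_open is None or gap_extend is None:
        gap_open, gap_extend = DEFAULT_PARAMS.get(matrix, (11, 1))
    aligner = _aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aln_len = aln.length
    ident = 100.0 * counts.identities / aln_len if aln_len else 0.0
    lam, K = _ka_params(matrix, gap_open, gap_extend)
    n = db_residues if db_residues is not None else len(b)
    bit, ev = _evalue(aln.score, len(a), n, lam, K)
    return HitRecord(query_id, subject_id, ident, aln_len, float(aln.score), bit, ev)


def _scores_vs_db(query: str, subjects: Proteome, matrix: str,
                  gap_open: int, gap_extend: int) -> list[float]:
    aligner = _aligner(matrix, gap_open, gap_extend)
    return [float(aligner.score(query, s)) for _, s in subjects]


def database_hits(
    query: str,
    subjects: Proteome,
    cutoff_evalue: float = 1e-5,
    matrix: str = "BLOSUM62",
    gap_open: int | None = None,
    gap_extend: int | None = None,
    query_id: str = "query",
) -> list[HitRecord]:
    """All subjects whose local alignment to the query passes the cutoff."""
    if gap_open is None or gap_extend is None:
        gap_open, gap_extend = DEFAULT_PARAMS.get(matrix, (11, 1))
    lam, K = _ka_params(matrix, gap_open, gap_extend)
    total = sum(len(s) for _, s in subjects)
    scores = _scores_vs_db(query, subjects, matrix, gap_open, gap_extend)
    hits = []
    for (sid, sseq), sc in zip(subjects, scores):
        _, ev = _evalue(sc, len(query), total, lam, K)
        if ev <= cutoff_evalue:
            rec = align_local(query, sseq, matrix, gap_open, gap_extend,
                              query_id=query_id, subject_id=sid, db_residues=total)
            hits.append(rec)
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits


def best_hit(
    query: str,
    subject_proteome: Proteome,
    cutoff_evalue: float = 1e-5,
    matrix: str = "BLOSUM62",
    gap_open: int | None = None,
    gap_extend: int | None = None,
    query_id: str = "query",
) -> HitRecord | None:
    """Highest-scoring subject under the e-value cutoff, or None.

    Ties on bit score break to the lexicographically lower subject id, so
    the result is deterministic.
    """
    if not subject_proteome:
        return None
    if gap_open is None or gap_extend is None:
        gap_open, gap_extend = DEFAULT_PARAMS.get(matrix, (11, 1))
    lam, K = _ka_params(matrix, gap_open, gap_extend)
    total = sum(len(s) for _, s in subject_proteome)
    scores = _scores_vs_db(query, subject_proteome, matrix, gap_open, gap_extend)
    order = sorted(range(len(scores)),
                   key=lambda i: (-scores[i], subject_proteome[i][0]))
    top = order[0]
    _, ev = _evalue(scores[top], len(query), total, lam, K)
    if ev > cutoff_evalue:
        return None
    sid, sseq = subject_proteome[top]
    return align_local(query, sseq, matrix, gap_open, gap_extend,
                       query_id=query_id, subject_id=sid, db_residues=total)


@dataclass
class AaiSummary:
    genome_a: str
    genome_b: str
    n_hits: int
    mean_identity: float


def aai(
    proteome_a: Proteome,
    proteome_b: Proteome,
    cutoff_evalue: float = 1e-5,
    matrix: str = "BLOSUM62",
    name_a: str = "A",
    name_b: str = "B",
) -> AaiSummary:
    """One-way (A -> B) average amino acid identity over best hits."""
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    idents = []
    for qid, qseq in proteome_a:
        h = best_hit(qseq, proteome_b, cutoff_evalue, matrix, query_id=qid)
        if h is not None:
            idents.append(h.identity)
    mean = float(np.mean(idents)) if idents else float("nan")
    return AaiSummary(genome_a=name_a, genome_b=name_b, n_hits=len(idents),
                      mean_identity=mean)


def top_hit_affiliation(
    proteome: Proteome,
    labeled_reference_sets: Mapping[str, Proteome],
    cutoff_evalue: float = 1e-5,
    matrix: str = "BLOSUM62",
) -> dict[str, float]:
    """Fraction of queries whose best hit across the reference union falls
    in each labelled group; queries without a hit are labelled ``none``."""
    union: list[tuple[str, str]] = []
    owner: dict[str, str] = {}
    for label, prot in labeled_reference_sets.items():
        for sid, sseq in prot:
            if sid in owner:
                raise ValueError(f"reference id {sid} occurs in more than one set")
            owner[sid] = label
            union.append((sid, sseq))
    counts = {label: 0 for label in labeled_reference_sets}
    counts["none"] = 0
    for qid, qseq in proteome:
        h = best_hit(qseq, union, cutoff_evalue, matrix, query_id=qid) if union else None
        counts[owner[h.subject_id] if h else "none"] += 1
    total = max(len(proteome), 1)
    return {label: c / total for label, c in counts.items()}


def presence_profile(
    proteome: Proteome,
    reference_proteomes: Sequence[Proteome],
    cutoff_evalue: float = 1e-5,
    matrix: str = "BLOSUM62",
    majority: float = 0.5,
) -> dict[str, tuple[float, bool]]:
    """Per-query fraction of reference genomes containing a homolog.

    Returns ``locus -> (fraction, absent_in_majority)`` where the flag is
    ``fraction < majority``: the query lacks homologs in a majority of the
    reference genomes, a lateral-acquisition signal.
    """
    if not reference_proteomes:
        raise ValueError("need at least one reference proteome")
    out = {}
    for qid, qseq in proteome:
        k = sum(
            1
            for ref in reference_proteomes
            if best_hit(qseq, ref, cutoff_evalue, matrix, query_id=qid) is not None
        )
        frac = k / len(reference_proteomes)
        out[qid] = (frac, frac < majority)
    return out


# ---------------------------------------------------------------------------
# Diffing near-identical nucleotide sequences

@dataclass
class VariantRecord:
    kind: str        # snp | insertion | deletion
    position: int    # 0-based position on the reference
    ref_allele: str
    alt_allele: str

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))


def apply_variants(ref: str, variants: Sequence[VariantRecord]) -> str:
    """Reconstruct the query by applying variants to the reference."""
    out = []
    pos = 0
    for v in sorted(variants, key=lambda v: (v.position, v.kind != "insertion")):
        out.append(ref[pos : v.position])
        if v.kind == "snp":
            out.append(v.alt_allele)
            pos = v.position + 1
        elif v.kind == "deletion":
            pos = v.position + len(v.ref_allele)
        elif v.kind == "insertion":
            out.append(v.alt_allele)
            pos = v.position
        else:
            raise ValueError(f"unknown variant kind {v.kind!r}")
    out.append(ref[pos:])
    return "".join(out)


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _segment_variants(ref_seg: str, q_seg: str, ref_offset: int) -> list[VariantRecord]:
    """Variants between two short segments via global edit alignment."""
    import edlib

    if ref_seg == q_seg:
        return []
    if not ref_seg:
        return [VariantRecord("insertion", ref_offset, "", q_seg)] if q_seg else []
    if not q_seg:
        return [VariantRecord("deletion", ref_offset, ref_seg, "")]
    res = edlib.align(q_seg, ref_seg, mode="NW", task="path")
    variants: list[VariantRecord] = []
    rp, qp = 0, 0
    for ln, op in _cigar_ops(res["cigar"]):
        if op == "=":
            rp += ln
            qp += ln
        elif op == "X":
            for j in range(ln):
                variants.append(
                    VariantRecord("snp", ref_offset + rp + j,
                                  ref_seg[rp + j], q_seg[qp + j])
                )
            rp += ln
            qp += ln
        elif op == "I":  # consumes query only -> insertion relative to ref
            variants.append(
                VariantRecord("insertion", ref_offset + rp, "", q_seg[qp : qp + ln])
            )
            qp += ln
        elif op == "D":  # consumes ref only -> deletion
            variants.append(
                VariantRecord("deletion", ref_offset + rp,
                              ref_seg[rp : rp + ln], "")
            )
            rp += ln
    return variants


def diff_near_identical(
    ref_seq: str, query_seq: str, anchor_k: int = 31
) -> list[VariantRecord]:
    """Variant calls between two near-identical nucleotide sequences.

    k-mers unique in both sequences are matched as anchors and chained
    colinearly (longest chain of consistent, non-overlapping anchors);
    the inter-anchor gaps are aligned globally and emitted as SNPs, short
    insertions and deletions.  Applying the variants to the reference
    reconstructs the query exactly.  When the anchor chain covers less
    than half of the reference the sequences are considered too divergent.
    """
    ref_seq = ref_seq.upper()
    query_seq = query_seq.upper()
    if ref_seq == query_seq:
        return []
    ru = _unique_kmers(ref_seq, anchor_k)
    qu = _unique_kmers(query_seq, anchor_k)
    shared = sorted(
        ((ru[km], qu[km]) for km in ru.keys() & qu.keys()), key=lambda t: t[0]
    )
    # longest strictly increasing (in query) chain of anchors
    if shared:
        qpos = [q for _, q in shared]
        tails: list[int] = []  # indices into shared
        parents = [-1] * len(shared)
        import bisect

        tailq: list[int] = []
        for i, q in enumerate(qpos):
            j = bisect.bisect_left(tailq, q)
            if j == len(tailq):
                tailq.append(q)
                tails.append(i)
            else:
                tailq[j] = q
                tails[j] = i
            parents[i] = tails[j - 1] if j > 0 else -1
        chain = []
        i = tails[-1]
        while i != -1:
            chain.append(shared[i])
            i = parents[i]
        chain.reverse()
        # drop anchors overlapping their predecessor in either sequence
        pruned = []
        last_r = last_q = -anchor_k
        for r, q in chain:
            if r >= last_r + anchor_k and q >= last_q + anchor_k:
                pruned.append((r, q))
                last_r, last_q = r, q
        chain = pruned
    else:
        chain = []
    covered = len(chain) * anchor_k
    if covered < 0.5 * len(ref_seq):
        raise ValueError("sequences too divergent for anchor-based diffing")
    variants: list[VariantRecord] = []
    pr = pq = 0
    for r, q in chain:
        variants.extend(_segment_variants(ref_seq[pr:r], query_seq[pq:q], pr))
        pr, pq = r + anchor_k, q + anchor_k
    variants.extend(_segment_variants(ref_seq[pr:], query_seq[pq:], pr))
    assert apply_variants(ref_seq, variants) == query_seq
    return variants


def write_hits_tsv(hits: Sequence[HitRecord], path) -> None:
    """12-column BLAST-like tabular output (unavailable columns as NA)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.identity:.2f}",
                        str(h.aln_len), "NA", "NA", "NA", "NA", "NA", "NA",
                        f"{h.evalue:.3g}", f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )
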