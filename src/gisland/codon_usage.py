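"""Codon adaptation index (CAI) and bootstrap-expected CAI (eCAI).

The CAI of a gene is the geometric mean, over its scored codons, of the
relative adaptiveness w of each codon: within every synonymous family,
w = count / max-family-count computed from a reference codon-usage table
(here: all intact chromosomal ORFs of the host replicon).  Stop codons are
never scored and the single-codon families Met (ATG) and Trp (TGG) are
excluded because they carry no usage information (Sharp & Li convention).
Zero counts are replaced by 0.5 before computing w so every w is positive
and log-space CAI is defined.

The expected CAI makes the index comparable across genes of different
amino-acid composition: for a query protein, ``n_boot`` random CDSs
encoding the same protein are generated with synonymous codons drawn
uniformly per amino acid (the least-informative null), and eCAI is the
95th percentile of their CAI distribution.  The normalised CAI is
CAI / eCAI; a gene scoring below 1.00 uses codons atypically for the host
at the 5% significance level and is flagged as putatively foreign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "SYNONYMOUS_FAMILIES", "CodonUsageTable", "CaiResult",
    "build_codon_table", "cai", "expected_cai", "normalized_cai",
]

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: amino acid -> tuple of codons (stop codons excluded), bacterial code
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _TABLE11.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

STOP_CODONS = frozenset(_TABLE11.stop_codons)
#: codons excluded from CAI scoring (single-codon families)
UNSCORED = frozenset({"ATG", "TGG"}) | STOP_CODONS

CODON_TO_AA = dict(_TABLE11.forward_table)


@dataclass
class CodonUsageTable:
    counts: dict[str, float]
    w: dict[str, float]
    source_orf_count: int

    def log_w(self) -> dict[str, float]:
        return {c: math.log(v) for c, v in self.w.items()}


def _codons(dna: str) -> list[str]:
    dna = dna.upper().replace("U", "T")
    if len(dna) % 3 != 0:
        raise ValueError(f"CDS length {len(dna)} is not a multiple of 3")
    return [dna[i : i + 3] for i in range(0, len(dna), 3)]


def build_codon_table(cds_seqs: Sequence[str]) -> CodonUsageTable:
    """Genome-wide codon counts and relative adaptiveness weights.

    ``cds_seqs`` are the coding-strand CDS nucleotide sequences of the
    reference ORF set (intact, non-pseudo genes).  Codons containing
    ambiguous bases and stop codons are not counted.  Zero counts become
    0.5 before w = count / max within the synonymous family.
    """
    if not cds_seqs:
        raise ValueError("empty ORF set")
    counts: dict[str, float] = {c: 0.0 for c in CODON_TO_AA}
    for dna in cds_seqs:
        for codon in _codons(dna):
            if codon in counts:
                counts[codon] += 1.0
    adj = {c: (v if v > 0 else 0.5) for c, v in counts.items()}
    w: dict[str, float] = {}
    for _aa, family in SYNONYMOUS_FAMILIES.items():
        mx = max(adj[c] for c in family)
        for c in family:
            w[c] = adj[c] / mx
    return CodonUsageTable(counts=counts, w=w, source_orf_count=len(cds_seqs))


def cai(dna: str, table: CodonUsageTable) -> float:
    """Geometric mean of w over the gene's scored codons (log space)."""
    total = 0.0
    k = 0
    logw = table.log_w()
    for codon in _codons(dna):
        if codon in UNSCORED or codon not in logw:
            continue
        total += logw[codon]
        k += 1
    if k == 0:
        raise ValueError("no scorable codons in CDS")
    return math.exp(total / k)


def _family_logw_arrays(table: CodonUsageTable) -> dict[str, np.ndarray]:
    logw = table.log_w()
    return {
        aa: np.array([logw[c] for c in fam])
        for aa, fam in SYNONYMOUS_FAMILIES.items()
        if aa not in ("M", "W")
    }


def expected_cai(
    aa_seq: str,
    table: CodonUsageTable,
    n_boot: int = 500,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap-expected CAI for a protein of this amino-acid composition.

    Uniform synonymous-codon choice per residue; returns the requested
    quantile of the ``n_boot`` CAI values.  Deterministic given ``seed``
    (an integer or a numpy Generator).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable tail quantile")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fams = _family_logw_arrays(table)
    aa_seq = aa_seq.upper().rstrip("*")
    # residue counts over scored families only
    counts: dict[str, int] = {}
    for aa in aa_seq:
        if aa in fams:
            counts[aa] = counts.get(aa, 0) + 1
    total_pos = sum(counts.values())
    if total_pos == 0:
        raise ValueError("protein contains no scored residues (only Met/Trp/stops)")
    sums = np.zeros(n_boot)
    for aa, k in counts.items():
        arr = fams[aa]
        idx = rng.integers(0, len(arr), size=(n_boot, k))
        sums += arr[idx].sum(axis=1)
    cais = np.exp(sums / total_pos)
    return float(np.quantile(cais, quantile))


@dataclass
class CaiResult:
    locus_tag: str
    cai: float
    ecai: float
    normalized: float
    foreign_flag: bool


def normalized_cai(
    locus_tag: str,
    dna: str,
    table: CodonUsageTable,
    n_boot: int = 500,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
    aa_seq: str | None = None,
) -> CaiResult:
    """CAI, bootstrap eCAI, their ratio and the foreign-usage flag.

    The flag is exactly ``normalized < 1.00``: the gene's CAI falls below
    the host-table CAI expected at the chosen significance level for a
    random gene of the same protein sequence.
    """
    c = cai(dna, table)
    if aa_seq is None:
        from .genome_io import translate_cds

        aa_seq = translate_cds(dna, is_start_annotated=True)
    e = expected_cai(aa_seq, table, n_boot=n_boot, quantile=quantile, seed=seed)
    norm = c / e
    return CaiResult(locus_tag=locus_tag, cai=c, ecai=e, normalized=norm,
                     foreign_flag=norm < 1.00)


def cai_report(results: Sequence[CaiResult]):
    """Tabular report (one row per locus) as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "locus_tag": r.locus_tag,
                "cai": r.cai,
                "ecai": r.ecai,
                "normalized": r.normalized,
                "foreign_flag": r.foreign_flag,
            }
            for r in results
        ]
    )
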