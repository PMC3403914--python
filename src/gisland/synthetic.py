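"""Synthetic annotated replicons with planted, recorded ground truth.

The generator emulates the signals the analysis stages look for in a real
bacterial replicon:

* a host coding regime — genes drawn from a Dirichlet-biased synonymous
  codon preference, GC-tilted so realised coding GC matches the host GC
  (~55% for a Geobacter-like chromosome);
* replichore strand bias — G-over-C enrichment of the leading strand that
  flips at the planted origin and terminus, so windowed skew reverses and
  cumulative skew has its minimum at the origin;
* genomic islands — contiguous blocks of ORFs drawn from an alien
  (uniform-synonymous) codon regime at their own GC (e.g. 37%), optionally
  bounded by terminal inverted repeats;
* a DnaA-box cluster at the origin, tandem duplications with a controlled
  number of substitutions, planted primer sites, and c-type cytochrome
  proteins (CxxCH motifs, homologous to a labelled reference set) plus
  CxxCH decoys with no homologs.

Every planted feature is recorded in a GroundTruth table that round-trips
through a TSV, so recovery tests can join calls to truth by interval
overlap.  Generation is fully deterministic per seed.

What this generator does *not* emulate: indels within genes, codon
autocorrelation, mobile-element gene content, or realistic intergenic
regulatory structure; recovery rates measured here bound sensitivity under
clean composition signals, not on real genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .codon_usage import SYNONYMOUS_FAMILIES
from .genome_io import AnnotatedReplicon, Orf
from ._seq import reverse_complement

#: typical bacterial amino-acid frequencies used for all generated proteins
AA_FREQS = {
    "A": 0.095, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.012, "Q": 0.044,
    "E": 0.058, "G": 0.074, "H": 0.022, "I": 0.060, "L": 0.106, "K": 0.044,
    "M": 0.026, "F": 0.039, "P": 0.044, "S": 0.058, "T": 0.054, "W": 0.014,
    "Y": 0.028, "V": 0.070,
}
_AAS = sorted(AA_FREQS)
_AAP = np.array([AA_FREQS[a] for a in _AAS])
_AAP = _AAP / _AAP.sum()

DNAA_BOX = "TT(C|A)TCCAC(A|G)"
_DNAA_CONCRETE = ["TT%sTCCAC%s" % (a, b) for a in "CA" for b in "AG"]


def _gc_count(codon: str) -> int:
    return sum(b in "GC" for b in codon)


@dataclass
class IslandSpec:
    n_orfs: int = 30
    gc: float = 0.37
    codon_regime: str = "alien"      # alien = uniform synonymous base weights
    at_fraction: float = 0.6         # fractional genome position
    terminal_repeat: int | None = None  # inverted terminal repeat length


@dataclass
class DupSpec:
    length: int = 2466
    n_edits: int = 5
    gap: int = 0
    at_fraction: float = 0.8


@dataclass
class PrimerSpec:
    fwd: str
    rev: str
    product_len: int
    at_fraction: float = 0.3


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic replicon."""

    length: int = 300_000
    host_gc: float = 0.548
    codon_bias_alpha: float = 0.25   # Dirichlet concentration of host usage
    ori_fraction: float = 0.5        # origin position as genome fraction
    skew_amplitude: float = 0.2      # leading-strand (G-C)/(G+C) tilt
    islands: list[IslandSpec] = field(default_factory=list)
    duplications: list[DupSpec] = field(default_factory=list)
    primer_pairs: list[PrimerSpec] = field(default_factory=list)
    dnaA_boxes_at_ori: int = 4
    n_cytochromes: int = 0
    heme_counts: tuple[int, ...] = (11,)
    n_decoys: int = 0
    n_reference_proteomes: int = 0
    reference_divergence: float = 0.3   # per-site aa substitution probability
    mean_gene_aa: int = 300
    sd_gene_aa: int = 80
    topology: str = "circular"

    def validate(self) -> None:
        feats = sum(i.n_orfs * (self.mean_gene_aa * 3 + 125) for i in self.islands)
        feats += sum(2 * d.length + d.gap for d in self.duplications)
        feats += sum(p.product_len for p in self.primer_pairs)
        if feats > 0.8 * self.length:
            raise ValueError("planted features do not fit in the replicon length")
        for i in self.islands:
            if not 0.25 <= i.gc <= 0.70:
                raise ValueError(f"island GC {i.gc} outside achievable range")
        if not 0.32 <= self.host_gc <= 0.66:
            raise ValueError(f"host GC {self.host_gc} outside achievable range")


@dataclass
class TruthRecord:
    kind: str
    start: int
    end: int
    params: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    records: list[TruthRecord] = field(default_factory=list)

    def add(self, kind: str, start: int, end: int, **params) -> None:
        self.records.append(TruthRecord(kind, start, end, dict(params)))

    def of_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tstart\tend\tparams\n")
        for r in truth.records:
            fh.write(f"{r.kind}\t{r.start}\t{r.end}\t{json.dumps(r.params, sort_keys=True)}\n")


def read_truth(path: str | Path) -> GroundTruth:
    truth = GroundTruth()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["kind", "start", "end", "params"]:
            raise ValueError(f"unexpected truth schema: {header}")
        for line in fh:
            kind, start, end, params = line.rstrip("\n").split("\t")
            truth.records.append(TruthRecord(kind, int(start), int(end), json.loads(params)))
    return truth


# ---------------------------------------------------------------------------
# Codon regimes

class CodonRegime:
    """Per-family codon sampling weights with a GC tilt solved so the
    expected coding GC hits a target."""

    def __init__(self, base_weights: dict[str, np.ndarray], target_gc: float):
        self.families = {aa: list(fam) for aa, fam in SYNONYMOUS_FAMILIES.items()}
        self.base = base_weights
        self.gc_counts = {
            aa: np.array([_gc_count(c) for c in fam])
            for aa, fam in self.families.items()
        }
        beta = brentq(lambda b: self._expected_gc(b) - target_gc, -8.0, 8.0)
        self.beta = float(beta)
        self.probs = self._probs(beta)

    def _probs(self, beta: float) -> dict[str, np.ndarray]:
        out = {}
        for aa, fam in self.families.items():
            w = self.base[aa] * np.exp(beta * self.gc_counts[aa])
            out[aa] = w / w.sum()
        return out

    def _expected_gc(self, beta: float) -> float:
        p = self._probs(beta)
        num = sum(
            AA_FREQS[aa] * float((p[aa] * self.gc_counts[aa]).sum())
            for aa in self.families
            if aa in AA_FREQS
        )
        return num / 3.0

    def tilted(self, skew: float) -> dict[str, np.ndarray]:
        """Codon probabilities with a G-over-C (skew > 0) or C-over-G tilt."""
        if skew == 0:
            return self.probs
        out = {}
        for aa, fam in self.families.items():
            g = np.array([c.count("G") for c in fam])
            cc = np.array([c.count("C") for c in fam])
            w = self.probs[aa] * (1 + skew) ** g * (1 - skew) ** cc
            out[aa] = w / w.sum()
        return out


def host_regime(rng: np.random.Generator, target_gc: float, alpha: float) -> CodonRegime:
    """Dirichlet-sampled (biased) host codon preference at the target GC."""
    base = {
        aa: rng.dirichlet(np.full(len(fam), alpha)) + 1e-4
        for aa, fam in SYNONYMOUS_FAMILIES.items()
    }
    return CodonRegime(base, target_gc)


def alien_regime(target_gc: float) -> CodonRegime:
    """Uniform synonymous base weights (the least-informative usage)."""
    base = {aa: np.ones(len(fam)) for aa, fam in SYNONYMOUS_FAMILIES.items()}
    return CodonRegime(base, target_gc)


# ---------------------------------------------------------------------------
# Sequence emission

def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "".join(np.array(_AAS)[rng.choice(len(_AAS), size=n_aa, p=_AAP)])


def _encode_protein(rng: np.random.Generator, protein: str,
                    probs: dict[str, np.ndarray],
                    families: dict[str, list[str]]) -> str:
    # vectorised per amino acid: one choice() call per residue type
    codons: list[str] = [""] * len(protein)
    by_aa: dict[str, list[int]] = {}
    for i, aa in enumerate(protein):
        by_aa.setdefault(aa, []).append(i)
    for aa, idxs in by_aa.items():
        fam = families[aa]
        picks = rng.choice(len(fam), size=len(idxs), p=probs[aa])
        for i, k in zip(idxs, picks):
            codons[i] = fam[k]
    stop = ("TAA", "TGA", "TAG")[rng.choice(3)]
    return "".join(codons) + stop


def _spacer(rng: np.random.Generator, n: int, gc: float, skew: float) -> str:
    pg = gc / 2 * (1 + skew)
    pc = gc / 2 * (1 - skew)
    pa = pt = (1 - gc) / 2
    return "".join(np.array(list("ACGT"))[
        rng.choice(4, size=n, p=[pa, pc, pg, pt])
    ])


def _mutate_protein(rng: np.random.Generator, protein: str, d: float,
                    keep: set[int] | None = None) -> str:
    out = list(protein)
    for i in range(len(out)):
        if keep and i in keep:
            continue
        if rng.random() < d:
            choices = [a for a in _AAS if a != out[i]]
            out[i] = choices[rng.choice(19)]
    return "".join(out)


def _cytochrome_scaffold(rng: np.random.Generator, n_motifs: int,
                         n_aa: int = 320) -> tuple[str, set[int]]:
    """Random protein with ``n_motifs`` evenly spaced CxxCH motifs; returns
    the protein and the (frozen) motif residue positions."""
    prot = list(_random_protein(rng, n_aa))
    keep: set[int] = set()
    spacing = (n_aa - 10) // max(n_motifs, 1)
    for k in range(n_motifs):
        p = 3 + k * spacing
        motif = "C" + prot[p + 1] + prot[p + 2] + "CH"
        # avoid accidental extra C/H creating overlapping motifs
        for j, ch in enumerate(motif):
            prot[p + j] = ch
        keep.update(range(p, p + 5))
    return "".join(prot), keep


# ---------------------------------------------------------------------------
# Generator

@dataclass
class SyntheticBundle:
    replicon: AnnotatedReplicon
    proteome: list[tuple[str, str]]
    truth: GroundTruth
    reference_proteomes: list[list[tuple[str, str]]] = field(default_factory=list)
    cytochrome_refs: list = field(default_factory=list)  # ReferenceProtein list


def generate(spec: SyntheticSpec, seed: int = 0) -> SyntheticBundle:
    """Emit one annotated replicon plus proteome and ground truth."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.length
    ori = int(spec.ori_fraction * n)
    host = host_regime(rng, spec.host_gc, spec.codon_bias_alpha)
    island_regimes = {
        id(isl): (alien_regime(isl.gc) if isl.codon_regime == "alien"
                  else host_regime(rng, isl.gc, spec.codon_bias_alpha))
        for isl in spec.islands
    }

    # planned events sorted by genome position
    events: list[tuple[int, str, object]] = [(ori, "ori", None)]
    for isl in spec.islands:
        events.append((int(isl.at_fraction * n), "island", isl))
    for dup in spec.duplications:
        events.append((int(dup.at_fraction * n), "dup", dup))
    for pp in spec.primer_pairs:
        events.append((int(pp.at_fraction * n), "primers", pp))
    events.sort()
    for (p1, k1, _), (p2, k2, _) in zip(events, events[1:]):
        if p2 - p1 < 1000:
            raise ValueError(f"planted features {k1}@{p1} and {k2}@{p2} too close")

    parts: list[str] = []
    features: list[Orf] = []
    truth = GroundTruth()
    cyt_specs: list[tuple[str, int]] = []  # planted at random host positions
    cytochrome_refs: list = []
    proteome_extra: list[tuple[str, str]] = []

    # pre-build cytochrome scaffolds + labelled reference set
    from .motif_scan import ReferenceProtein

    cyt_proteins: list[tuple[str, set[int], int]] = []
    for k in range(spec.n_cytochromes):
        n_motifs = spec.heme_counts[k % len(spec.heme_counts)]
        prot, keep = _cytochrome_scaffold(rng, n_motifs)
        cyt_proteins.append((prot, keep, n_motifs))
        for j in range(2):  # two labelled relatives per planted cytochrome
            ref = _mutate_protein(rng, prot, 0.25, keep)
            cytochrome_refs.append(
                ReferenceProtein(f"REFCYT_{k:03d}_{j}", ref, True)
            )
    for j in range(max(10, spec.n_cytochromes)):
        cytochrome_refs.append(
            ReferenceProtein(f"REFOTH_{j:03d}", _random_protein(rng, 300), False)
        )
    decoy_proteins = []
    for k in range(spec.n_decoys):
        n_motifs = 1 + int(rng.choice(3))
        prot, _ = _cytochrome_scaffold(rng, n_motifs, n_aa=280)
        decoy_proteins.append((prot, n_motifs))

    cursor = 0
    gene_no = 0
    host_proteins: list[tuple[str, str]] = []
    grich = False  # C-rich leading into the origin; G-rich after (ter at 0)
    ev_idx = 0
    # interleave planted cytochromes/decoys among host genes
    special_genes: list[tuple[str, object]] = [("cyt", c) for c in cyt_proteins]
    special_genes += [("decoy", d) for d in decoy_proteins]
    rng.shuffle(special_genes)  # type: ignore[arg-type]
    special_every = max(
        1, (n // (3 * (spec.mean_gene_aa * 3 + 125))) // max(len(special_genes), 1)
    )

    def strand_skew(strand: str) -> float:
        s = spec.skew_amplitude if grich else -spec.skew_amplitude
        return s if strand == "+" else -s

    def emit_gene(protein: str, regime: CodonRegime, kind: str,
                  extra_truth: dict | None = None) -> None:
        nonlocal cursor, gene_no
        gene_no += 1
        locus = f"SYN_{gene_no:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        dna = _encode_protein(rng, protein, regime.tilted(strand_skew(strand)),
                              regime.families)
        fwd = dna if strand == "+" else reverse_complement(dna)
        start = cursor
        parts.append(fwd)
        cursor += len(fwd)
        features.append(Orf(locus_tag=locus, start=start, end=cursor,
                            strand=strand, translation=protein))
        if kind != "host_gene" or extra_truth:
            truth.add(kind, start, cursor, locus=locus, **(extra_truth or {}))
        if kind == "host_gene":
            host_proteins.append((locus, protein))
        else:
            proteome_extra.append((locus, protein))

    def emit_spacer(length: int, gc: float | None = None) -> None:
        nonlocal cursor
        gc = spec.host_gc if gc is None else gc
        s = spec.skew_amplitude if grich else -spec.skew_amplitude
        parts.append(_spacer(rng, length, gc, s))
        cursor += length

    while cursor < n:
        if ev_idx < len(events) and cursor >= events[ev_idx][0]:
            _, kind, payload = events[ev_idx]
            ev_idx += 1
            if kind == "ori":
                grich = True
                start = cursor
                for b in range(spec.dnaA_boxes_at_ori):
                    emit_spacer(int(rng.integers(20, 50)))
                    box = _DNAA_CONCRETE[rng.choice(len(_DNAA_CONCRETE))]
                    truth.add("dnaA_box", cursor, cursor + len(box), seq=box)
                    parts.append(box)
                    cursor += len(box)
                emit_spacer(int(rng.integers(20, 50)))
                truth.add("ori", start, cursor, n_boxes=spec.dnaA_boxes_at_ori)
            elif kind == "island":
                isl: IslandSpec = payload  # type: ignore[assignment]
                regime = island_regimes[id(isl)]
                istart = cursor
                rep = None
                if isl.terminal_repeat:
                    rep = _spacer(rng, isl.terminal_repeat, isl.gc, 0.0)
                    parts.append(rep)
                    cursor += len(rep)
                for _ in range(isl.n_orfs):
                    emit_spacer(int(rng.integers(50, 200)), isl.gc)
                    n_aa = int(np.clip(rng.normal(spec.mean_gene_aa, spec.sd_gene_aa),
                                       100, 800))
                    emit_gene(_random_protein(rng, n_aa), regime, "island_orf")
                emit_spacer(int(rng.integers(50, 200)), isl.gc)
                if rep is not None:
                    truth.add("terminal_repeat", istart, istart + len(rep),
                              length=len(rep))
                    truth.add("terminal_repeat", cursor, cursor + len(rep),
                              length=len(rep))
                    parts.append(reverse_complement(rep))
                    cursor += len(rep)
                truth.add("island", istart, cursor, gc=isl.gc,
                          n_orfs=isl.n_orfs, regime=isl.codon_regime)
            elif kind == "dup":
                dup: DupSpec = payload  # type: ignore[assignment]
                block = _spacer(rng, dup.length, spec.host_gc,
                                spec.skew_amplitude if grich else -spec.skew_amplitude)
                # substitutions well inside the block so the duplicated span
                # stays exactly dup.length when recovered by seed-and-extend
                grid = np.arange(50, dup.length - 50, 50)
                pos = rng.choice(grid, size=min(dup.n_edits, len(grid)), replace=False)
                copy = list(block)
                for p in sorted(pos):
                    alt = [b for b in "ACGT" if b != copy[p]]
                    copy[p] = alt[rng.choice(3)]
                copy = "".join(copy)
                gapseq = _spacer(rng, dup.gap, spec.host_gc, 0.0) if dup.gap else ""
                # force mismatches at the block boundaries so the maximal
                # repeat cannot extend past the planted blocks
                pre = _spacer(rng, 30, spec.host_gc, 0.0)
                prev_last = gapseq[-1] if gapseq else block[-1]
                if pre[-1] == prev_last:
                    alt = [b for b in "ACGT" if b != prev_last]
                    pre = pre[:-1] + alt[0]
                post = _spacer(rng, 30, spec.host_gc, 0.0)
                first_after = copy[0] if not gapseq else gapseq[0]
                if post[0] == first_after:
                    alt = [b for b in "ACGT" if b != first_after]
                    post = alt[0] + post[1:]
                parts.append(pre)
                cursor += len(pre)
                b1 = cursor
                parts.append(block + gapseq + copy)
                cursor += len(block) + len(gapseq) + len(copy)
                parts.append(post)
                cursor += len(post)
                truth.add("duplication", b1, cursor - len(post),
                          length=dup.length, n_edits=int(len(pos)), gap=dup.gap)
            elif kind == "primers":
                pp: PrimerSpec = payload  # type: ignore[assignment]
                inner = pp.product_len - len(pp.fwd) - len(pp.rev)
                if inner < 0:
                    raise ValueError("product shorter than the two primers")
                site = pp.fwd.upper() + _spacer(rng, inner, spec.host_gc, 0.0) \
                    + reverse_complement(pp.rev.upper())
                truth.add("primer_site", cursor, cursor + len(site),
                          fwd=pp.fwd, rev=pp.rev, product_len=pp.product_len)
                parts.append(site)
                cursor += len(site)
            continue
        emit_spacer(int(rng.integers(50, 200)))
        if special_genes and gene_no % special_every == special_every - 1:
            skind, payload = special_genes.pop()
            if skind == "cyt":
                prot, _, n_motifs = payload  # type: ignore[misc]
                emit_gene(prot, host, "cytochrome", {"n_motifs": n_motifs})
            else:
                prot, n_motifs = payload  # type: ignore[misc]
                emit_gene(prot, host, "decoy", {"n_motifs": n_motifs})
        else:
            n_aa = int(np.clip(rng.normal(spec.mean_gene_aa, spec.sd_gene_aa),
                               100, 800))
            emit_gene(_random_protein(rng, n_aa), host, "host_gene")

    truth.add("ter", 0, 0, note="terminus at coordinate origin")
    seq = "".join(parts)
    replicon = AnnotatedReplicon(id=f"SYNTH_{seed}", seq=seq,
                                 topology=spec.topology, features=features,
                                 description="synthetic replicon")
    proteome = [(o.locus_tag, o.translation) for o in replicon.orfs if not o.pseudo]

    references: list[list[tuple[str, str]]] = []
    for g in range(spec.n_reference_proteomes):
        ref = [
            (f"G{g}_{locus}", _mutate_protein(rng, prot, spec.reference_divergence))
            for locus, prot in host_proteins
        ]
        references.append(ref)
    return SyntheticBundle(replicon=replicon, proteome=proteome, truth=truth,
                           reference_proteomes=references,
                           cytochrome_refs=cytochrome_refs)
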