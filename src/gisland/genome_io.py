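"""Readers/writers and coordinate normalisation for annotated replicons.

Internal convention everywhere in this package: coordinates are 0-based
half-open on the forward strand.  Only the readers and writers convert
(GenBank and GFF3 are 1-based inclusive; BED is already 0-based half-open).
On a circular replicon a feature may wrap the origin; such features keep
``start < length <= end`` so that ``end - start`` is always the feature
length and slicing wraps modulo the replicon length.

Pseudogenes are parsed but flagged so that codon-usage and proteome-level
statistics can exclude them (annotation tables separate pseudogenes from
intact protein-coding genes).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from ._seq import reverse_complement

log = logging.getLogger(__name__)

RNA_KINDS = ("tRNA", "rRNA_16S", "rRNA_23S", "rRNA_5S")


@dataclass
class Orf:
    """One protein-coding feature in internal coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str  # "+" or "-"
    translation: str = ""
    pseudo: bool = False
    product: str = ""
    cog_classes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"{self.locus_tag}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RnaFeature:
    kind: str  # one of RNA_KINDS
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.kind not in RNA_KINDS:
            raise ValueError(f"unknown RNA kind {self.kind!r}")


@dataclass
class AnnotatedReplicon:
    """A nucleotide replicon with its typed features.

    ``seq`` is an uppercase string; ``topology`` is ``"linear"`` or
    ``"circular"``.
    """

    id: str
    seq: str
    topology: Literal["linear", "circular"] = "linear"
    features: list = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")
        for f in self.features:
            self._check_interval(f)

    def _check_interval(self, f) -> None:
        n = len(self.seq)
        if not (0 <= f.start < n):
            raise ValueError(f"feature start {f.start} outside [0,{n})")
        limit = f.start + n if self.topology == "circular" else n
        if f.end > limit:
            raise ValueError(f"feature end {f.end} beyond replicon length {n}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def orfs(self) -> list[Orf]:
        return [f for f in self.features if isinstance(f, Orf)]

    @property
    def rnas(self) -> list[RnaFeature]:
        return [f for f in self.features if isinstance(f, RnaFeature)]

    def subseq(self, start: int, end: int) -> str:
        """Forward-strand slice; wraps the origin when circular."""
        n = len(self.seq)
        if end <= n:
            return self.seq[start:end]
        if self.topology != "circular":
            raise ValueError(f"interval [{start},{end}) beyond linear replicon")
        return self.seq[start:] + self.seq[: end - n]

    def feature_seq(self, f) -> str:
        """Coding/annotated-strand sequence of a feature."""
        s = self.subseq(f.start, f.end)
        return reverse_complement(s) if f.strand == "-" else s


class GenBankParseError(ValueError):
    pass


def translate_cds(
    dna: str, table_id: int = 11, is_start_annotated: bool = False
) -> str:
    """Translate a CDS with the bacterial code (table 11 by default).

    The terminal stop codon, when present, is removed.  When the CDS is an
    annotated gene start (``is_start_annotated``), alternative initiation
    codons such as GTG/TTG are rendered as Met, as annotation pipelines do.
    Internal stop codons are kept as ``*`` and reported via a warning rather
    than raised, so that pseudogene-like inputs survive a whole-genome pass.
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"CDS length {len(dna)} is not a multiple of 3")
    if not dna:
        return ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial-codon warnings are pre-checked
        aa = str(Seq(dna).translate(table=table_id))
    if aa.endswith("*"):
        aa = aa[:-1]
    if is_start_annotated and aa:
        # start codon recognised by the table's initiator tRNA -> fMet
        start = dna[:3].upper().replace("U", "T")
        if start in ("GTG", "TTG", "ATT", "CTG", "ATC", "ATA") or start == "ATG":
            aa = "M" + aa[1:]
    if "*" in aa:
        log.warning("internal stop codon in CDS (length %d)", len(dna))
    return aa


def _classify_rna(feature_type: str, product: str) -> str | None:
    if feature_type == "tRNA":
        return "tRNA"
    if feature_type == "rRNA":
        p = product.lower()
        if "16s" in p:
            return "rRNA_16S"
        if "23s" in p:
            return "rRNA_23S"
        if "5s" in p:
            return "rRNA_5S"
        return None
    return None


def read_genbank(path: str | Path) -> AnnotatedReplicon:
    """Read a single-record GenBank flat file into an AnnotatedReplicon.

    GenBank 1-based inclusive coordinates become 0-based half-open.  CDS
    translations are taken from the file when present, otherwise computed
    with :func:`translate_cds`.  ``join()`` locations crossing the origin
    are accepted only on circular records and are stored unwrapped
    (``end > length``).
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc
    if len(records) != 1:
        raise GenBankParseError(f"{path}: expected 1 record, found {len(records)}")
    rec = records[0]
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("linear", "circular"):
        topology = "linear"
    n = len(rec.seq)
    feats: list = []
    for f in rec.features:
        if f.type not in ("CDS", "tRNA", "rRNA"):
            continue
        strand = "-" if f.location.strand == -1 else "+"
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        start = int(parts[0].start)
        end = int(parts[-1].end)
        if len(parts) > 1 and int(parts[0].start) == 0 and int(parts[-1].end) == n:
            # origin-spanning join(); unwrap
            if topology != "circular":
                raise GenBankParseError(
                    f"{path}: origin-spanning feature on a linear record"
                )
            start = int(parts[-1].start)
            end = n + int(parts[0].end)
        if f.type == "CDS":
            quals = f.qualifiers
            locus = quals.get("locus_tag", [f"CDS_{start}"])[0]
            pseudo = "pseudo" in quals or "pseudogene" in quals
            translation = quals.get("translation", [""])[0]
            if not translation and not pseudo:
                cds = rec.seq[start:end] if end <= n else rec.seq[start:] + rec.seq[: end - n]
                cds = str(cds)
                if strand == "-":
                    cds = reverse_complement(cds)
                if len(cds) % 3 == 0:
                    translation = translate_cds(cds, is_start_annotated=True)
            feats.append(
                Orf(
                    locus_tag=locus,
                    start=start,
                    end=end,
                    strand=strand,
                    translation=translation,
                    pseudo=pseudo,
                    product=quals.get("product", [""])[0],
                )
            )
        else:
            kind = _classify_rna(f.type, f.qualifiers.get("product", [""])[0])
            if kind is not None:
                feats.append(RnaFeature(kind=kind, start=start, end=end, strand=strand))
    return AnnotatedReplicon(
        id=rec.id, seq=str(rec.seq), topology=topology, features=feats,
        description=rec.description,
    )


def write_genbank(replicon: AnnotatedReplicon, path: str | Path) -> None:
    """Write a replicon as a GenBank flat file (deterministic output)."""
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(
        Seq(replicon.seq), id=replicon.id, name=replicon.id[:16],
        description=replicon.description,
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = replicon.topology
    rec.annotations["date"] = "01-JAN-2000"  # fixed so output is reproducible
    n = replicon.length
    for f in replicon.features:
        strand = -1 if f.strand == "-" else 1
        if f.end <= n:
            loc = SimpleLocation(f.start, f.end, strand=strand)
        else:  # origin-spanning
            loc = SimpleLocation(f.start, n, strand=strand) + SimpleLocation(
                0, f.end - n, strand=strand
            )
        if isinstance(f, Orf):
            quals = {"locus_tag": [f.locus_tag]}
            if f.product:
                quals["product"] = [f.product]
            if f.pseudo:
                quals["pseudo"] = [""]
            elif f.translation:
                quals["translation"] = [f.translation]
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        else:
            ftype = "tRNA" if f.kind == "tRNA" else "rRNA"
            product = {
                "tRNA": "tRNA",
                "rRNA_16S": "16S ribosomal RNA",
                "rRNA_23S": "23S ribosomal RNA",
                "rRNA_5S": "5S ribosomal RNA",
            }[f.kind]
            rec.features.append(
                SeqFeature(loc, type=ftype, qualifiers={"product": [product]})
            )
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "genbank")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.description, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# COG maps

def read_cog_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Tab-delimited ``locus_tag<TAB>class-letters`` -> mapping.

    A duplicated locus keeps the last entry (a warning is logged).
    """
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            locus, classes = parts[0], parts[1]
            if locus in out:
                log.warning("duplicate locus %s in COG map; last wins", locus)
            out[locus] = frozenset(c for c in classes if c.strip())
    return out


def tally_cog_classes(
    orfs: Sequence[Orf], cog_map: dict[str, frozenset[str]]
) -> dict[str, int]:
    """Per-class COG counts over a set of ORFs.

    An ORF carrying several class letters increments each; the special key
    ``"assigned"`` counts ORFs in one or more COGs.  Loci absent from the
    map are unassigned.
    """
    counts: dict[str, int] = {}
    assigned = 0
    for orf in orfs:
        classes = cog_map.get(orf.locus_tag, frozenset())
        if classes:
            assigned += 1
        for c in sorted(classes):
            counts[c] = counts.get(c, 0) + 1
    counts["assigned"] = assigned
    return counts


# ---------------------------------------------------------------------------
# Interval writers (BED 0-based half-open; GFF3 1-based inclusive)

@dataclass
class Interval:
    chrom: str
    start: int
    end: int
    label: str = "."
    score: float = 0.0


def write_intervals(
    calls: Sequence[Interval],
    fmt: Literal["BED", "GFF3"],
    path: str | Path,
    replicon_length: int | None = None,
) -> None:
    if replicon_length is not None:
        for c in calls:
            if c.end > replicon_length:
                raise ValueError(
                    f"interval [{c.start},{c.end}) exceeds replicon length "
                    f"{replicon_length}"
                )
    with open(path, "w") as fh:
        if fmt == "BED":
            for c in calls:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.label}\t{c.score:g}\n")
        elif fmt == "GFF3":
            fh.write("##gff-version 3\n")
            for c in calls:
                fh.write(
                    f"{c.chrom}\tgisland\tregion\t{c.start + 1}\t{c.end}\t"
                    f"{c.score:g}\t.\t.\tName={c.label}\n"
                )
        else:
            raise ValueError(f"unknown interval format {fmt!r}")


def read_intervals(path: str | Path, fmt: Literal["BED", "GFF3"]) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if fmt == "BED":
                out.append(
                    Interval(f[0], int(f[1]), int(f[2]),
                             f[3] if len(f) > 3 else ".",
                             float(f[4]) if len(f) > 4 else 0.0)
                )
            elif fmt == "GFF3":
                label = "."
                for kv in f[8].split(";"):
                    if kv.startswith("Name="):
                        label = kv[5:]
                out.append(Interval(f[0], int(f[3]) - 1, int(f[4]), label, float(f[5])))
            else:
                raise ValueError(f"unknown interval format {fmt!r}")
    return out


def write_orf_fasta(replicon: AnnotatedReplicon, path: str | Path,
                    include_pseudo: bool = False) -> None:
    """Protein FASTA of a replicon's (intact) ORF translations."""
    entries = [
        (o.locus_tag, o.translation)
        for o in replicon.orfs
        if o.translation and (include_pseudo or not o.pseudo)
    ]
    write_fasta(entries, path)
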