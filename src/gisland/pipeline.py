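"""Pipeline orchestration: run every analysis stage over one or more
replicons and emit a per-replicon genome report.

Stage order follows the data dependencies: I/O first, then the per-ORF
statistics (composition, codon usage, motif census, homology), then
repeats, and finally the integrative island and origin calls.  Every
stage writes its TSV next to the summary so each number in the report is
traceable to one stage output.  A run manifest records input checksums,
seeds and thresholds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, codon_usage, composition, homology, motif_scan, repeats
from .genome_io import (
    AnnotatedReplicon, read_cog_map, read_fasta, read_genbank,
    tally_cog_classes, write_intervals, Interval,
)
from .islands import (
    DNAA_BOX_PATTERN, Thresholds, call_islands, predict_origin, score_orfs,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    replicons: list[str] = field(default_factory=list)
    reference_proteomes: dict[str, list[str]] = field(default_factory=dict)
    cog_map: str | None = None
    cytochrome_refs: str | None = None
    primer_pairs: list[tuple[str, str]] = field(default_factory=list)
    output_dir: str = "gisland_out"
    seed: int = 0
    n_boot: int = 500
    quantile: float = 0.95
    z_thresh: float = -2.0
    min_flags: int = 2
    min_orfs: int = 4
    max_gap_orfs: int = 2
    skew_window: int = 10_000
    skew_step: int = 1_000
    min_run: int = 5
    smooth: int = 5
    repeat_min_len: int = 15
    dnaA_pattern: str = DNAA_BOX_PATTERN
    ori_window: int = 1_000
    min_boxes: int = 2
    evalue_cutoff: float = 1e-5
    matrix: str = "BLOSUM62"
    max_amplicon: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        paths = list(self.replicons)
        for ps in self.reference_proteomes.values():
            paths += ps
        if self.cog_map:
            paths.append(self.cog_map)
        if self.cytochrome_refs:
            paths.append(self.cytochrome_refs)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input missing: {p}")


def read_labeled_cytochrome_fasta(path: str | Path):
    """Protein FASTA whose headers carry ``is_cytochrome=true|false``."""
    refs = []
    for desc, seq in read_fasta(path):
        fields = desc.split()
        label = None
        for f in fields[1:]:
            if f.startswith("is_cytochrome="):
                label = f.split("=", 1)[1].lower() in ("true", "1", "yes")
        if label is None:
            raise ValueError(f"{path}: header {desc!r} lacks is_cytochrome=")
        refs.append(motif_scan.ReferenceProtein(fields[0], seq, label))
    return refs


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class GenomeReport:
    replicon_id: str
    size: int = 0
    gc_percent: float = 0.0
    n_genes_total: int = 0
    n_pseudo: int = 0
    n_intact: int = 0
    n_trna: int = 0
    n_rrna_16s: int = 0
    cog_counts: dict[str, int] | None = None
    n_cytochromes: int | None = None
    n_multiheme_gt10: int | None = None
    affiliation: dict[str, float] | None = None
    islands: list = field(default_factory=list)
    ori_candidates: list = field(default_factory=list)
    tandem_duplications: list = field(default_factory=list)
    amplicons: list = field(default_factory=list)
    not_computed: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [f"Replicon {self.replicon_id}",
                 f"  Size (bp)\t{self.size:,}",
                 f"  GC percentage\t{self.gc_percent}",
                 f"  Protein-coding genes\t{self.n_genes_total}",
                 f"  Pseudogenes\t{self.n_pseudo}",
                 f"  Intact protein-coding genes\t{self.n_intact}",
                 f"  tRNAs\t{self.n_trna}",
                 f"  16S rRNAs\t{self.n_rrna_16s}"]
        if self.cog_counts is not None:
            lines.append(f"  In one or more COGs\t{self.cog_counts.get('assigned', 0)}")
            for cls in sorted(k for k in self.cog_counts if k != "assigned"):
                lines.append(f"  COG class {cls}\t{self.cog_counts[cls]}")
        if self.n_cytochromes is not None:
            lines.append(f"  Predicted c-type cytochromes\t{self.n_cytochromes}")
            lines.append(f"  With >10 heme-binding motifs\t{self.n_multiheme_gt10}")
        if self.affiliation is not None:
            for label, frac in sorted(self.affiliation.items()):
                lines.append(f"  Top-hit fraction {label}\t{100 * frac:.0f}%")
        lines.append(f"  Island calls\t{len(self.islands)}")
        for isl in self.islands:
            lines.append(f"    {isl.label}\t[{isl.interval[0]},{isl.interval[1]})\t"
                         f"{isl.n_flagged} flagged ORFs")
        lines.append(f"  Ori candidates\t{len(self.ori_candidates)}")
        for c in self.ori_candidates[:3]:
            lines.append(f"    pos {c.skew_extremum_pos}\t{c.n_dnaA_boxes} DnaA boxes")
        lines.append(f"  Tandem duplications\t{len(self.tandem_duplications)}")
        for t in self.tandem_duplications:
            lines.append(f"    length {t.length}\tidentity {t.identity}%\tgap {t.gap}")
        lines.append(f"  Amplicons\t{len(self.amplicons)}")
        for a in self.amplicons:
            lines.append(f"    start {a.fwd_start}\tlength {a.length}")
        for item in self.not_computed:
            lines.append(f"  {item}\tnot computed")
        return "\n".join(lines) + "\n"


def analyze_replicon(replicon: AnnotatedReplicon, cfg: PipelineConfig,
                     outdir: Path | None = None,
                     reference_proteomes: dict[str, list[tuple[str, str]]] | None = None,
                     cytochrome_refs=None,
                     cog_map=None) -> GenomeReport:
    """Run all stages on one replicon; optionally write per-stage TSVs."""
    rep = GenomeReport(replicon_id=replicon.id)
    rep.size = replicon.length
    rep.gc_percent = composition.round_percent(composition.gc_fraction(replicon.seq))
    orfs = replicon.orfs
    rep.n_genes_total = len(orfs)
    rep.n_pseudo = sum(1 for o in orfs if o.pseudo)
    rep.n_intact = rep.n_genes_total - rep.n_pseudo
    rep.n_trna = sum(1 for r in replicon.rnas if r.kind == "tRNA")
    rep.n_rrna_16s = sum(1 for r in replicon.rnas if r.kind == "rRNA_16S")
    intact = [o for o in orfs if not o.pseudo]

    if cog_map is not None:
        rep.cog_counts = tally_cog_classes(intact, cog_map)
    else:
        rep.not_computed.append("COG tallies")

    # composition
    gc_stats = composition.orf_gc_zscores(replicon) if len(intact) >= 2 else None
    circular = replicon.topology == "circular"
    sw = min(cfg.skew_window, max(1000, replicon.length // 10))
    st = min(cfg.skew_step, max(100, sw // 10))
    profile = composition.windowed_skew(replicon.seq, sw, st, circular=circular)
    skew_report = composition.find_skew_reversals(profile, cfg.min_run, cfg.smooth)

    # codon usage
    cai_results = None
    if len(intact) >= 20:
        table = codon_usage.build_codon_table(
            [replicon.feature_seq(o) for o in intact]
        )
        rng = np.random.default_rng(cfg.seed)
        cai_results = {}
        for o in intact:
            try:
                cai_results[o.locus_tag] = codon_usage.normalized_cai(
                    o.locus_tag, replicon.feature_seq(o), table,
                    n_boot=cfg.n_boot, quantile=cfg.quantile, seed=rng,
                    aa_seq=o.translation or None,
                )
            except ValueError:
                continue
    else:
        rep.not_computed.append("codon-usage flags")

    # cytochrome census
    proteome = [(o.locus_tag, o.translation) for o in intact if o.translation]
    census = motif_scan.heme_motif_census(proteome)
    if cytochrome_refs is not None:
        census = motif_scan.screen_cytochrome_candidates(
            census, dict(proteome), cytochrome_refs,
            evalue_cutoff=cfg.evalue_cutoff, matrix=cfg.matrix)
        kept = [e for e in census if e.status == "retained"]
    else:
        kept = list(census)
    rep.n_cytochromes = len(kept)
    rep.n_multiheme_gt10 = sum(1 for e in kept if e.motif_count > 10)

    # homology
    presence = None
    if reference_proteomes:
        rep.affiliation = homology.top_hit_affiliation(
            proteome, reference_proteomes, cfg.evalue_cutoff, cfg.matrix)
        presence = homology.presence_profile(
            proteome, list(reference_proteomes.values()),
            cfg.evalue_cutoff, cfg.matrix)
    else:
        rep.not_computed.append("top-hit affiliation")
        rep.not_computed.append("homolog presence")

    # repeats
    rep.tandem_duplications = repeats.tandem_duplications(replicon.seq)

    # islands + ori
    if gc_stats is not None:
        evidence = score_orfs(intact, gc_stats, cai_results, presence,
                              skew_report.disruptions,
                              Thresholds(z_thresh=cfg.z_thresh))
        rep.islands = call_islands(intact, evidence, cfg.min_flags,
                                   cfg.min_orfs, cfg.max_gap_orfs)
    rep.ori_candidates = predict_origin(
        replicon, cfg.dnaA_pattern, cfg.ori_window, cfg.min_boxes,
        skew_window=sw, skew_step=st, min_run=cfg.min_run, smooth=cfg.smooth)

    # in-silico PCR
    for fwd, rev in cfg.primer_pairs:
        rep.amplicons += motif_scan.insilico_pcr(
            replicon, fwd, rev, max_len=cfg.max_amplicon)

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        rid = replicon.id.replace("/", "_")
        if gc_stats is not None:
            pd.DataFrame({
                "locus_tag": list(gc_stats.per_orf_gc),
                "gc_percent": [composition.round_percent(v)
                               for v in gc_stats.per_orf_gc.values()],
                "z": [gc_stats.z[k] for k in gc_stats.per_orf_gc],
            }).to_csv(outdir / f"{rid}.gc.tsv", sep="\t", index=False)
        pd.DataFrame({
            "center": profile.centers, "skew": profile.skew,
        }).to_csv(outdir / f"{rid}.skew.tsv", sep="\t", index=False)
        if cai_results:
            codon_usage.cai_report(list(cai_results.values())).to_csv(
                outdir / f"{rid}.cai.tsv", sep="\t", index=False)
        motif_scan.census_report(census).to_csv(
            outdir / f"{rid}.cytochromes.tsv", sep="\t", index=False)
        write_intervals(
            [Interval(replicon.id, i.interval[0], i.interval[1], i.label,
                      i.n_flagged) for i in rep.islands],
            "BED", outdir / f"{rid}.islands.bed", replicon.length)
        with open(outdir / f"{rid}.report.txt", "w") as fh:
            fh.write(rep.to_text())
    return rep


def run(cfg: PipelineConfig) -> list[GenomeReport]:
    """Execute the full pipeline per the config; returns one report per
    replicon and writes all artifacts under ``cfg.output_dir``."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = {
        label: [
            (rid.split()[0], seq)
            for p in paths
            for rid, seq in read_fasta(p)
        ]
        for label, paths in cfg.reference_proteomes.items()
    } or None
    cyt = (read_labeled_cytochrome_fasta(cfg.cytochrome_refs)
           if cfg.cytochrome_refs else None)
    cog = read_cog_map(cfg.cog_map) if cfg.cog_map else None
    manifest: dict[str, Any] = {
        "version": __version__, "seed": cfg.seed,
        "inputs": {p: _sha256(p) for p in cfg.replicons},
        "thresholds": {
            "z_thresh": cfg.z_thresh, "min_flags": cfg.min_flags,
            "min_orfs": cfg.min_orfs, "max_gap_orfs": cfg.max_gap_orfs,
            "n_boot": cfg.n_boot, "quantile": cfg.quantile,
        },
    }
    reports = []
    for path in cfg.replicons:
        try:
            replicon = read_genbank(path)
            reports.append(
                analyze_replicon(replicon, cfg, outdir, refs, cyt, cog)
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at replicon {path}: {exc}") from exc
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return reports
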