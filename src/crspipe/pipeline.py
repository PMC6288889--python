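"""End-to-end orchestration of the screen's post-prediction analysis.

Each stage reads its inputs from, and writes its artifacts into, one working
directory, so stages can be run individually (and are idempotent for fixed
inputs and seed) or chained. The stage functions log an auditable funnel:
input counts, retained counts, and every filter's removal count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import coexpression as coex
from . import expression as expr
from . import filtering as filt
from . import loci as loci_mod
from . import simulate as sim
from . import stages as stage_mod
from .intervals import GenomicInterval, Track, merge_track, overlap_pairs
from .io import read_bed, read_gene_models, read_tsv, write_bed, write_tsv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_filter", "run_merge",
           "run_annotate", "run_express", "run_coexpress", "run_stages",
           "run_compare", "run_all"]


@dataclass
class PipelineConfig:
    """Thresholds of the analysis; defaults are the screen's stated values."""

    workdir: str = "crspipe_run"
    seed: int = 0
    pscore_min: float = 80.0
    fdr_max: float = 0.1
    merge_gap: int = 30
    expressed_frac: float = 0.5
    min_expr: int = 3
    pos_cut: float = 0.5
    neg_cut: float = -0.5
    synteny_fraction: float = 2.0 / 3.0
    max_distance: int = 20000
    window: int = 100
    n_samples: int = 10
    n_gc_bins: int = 8
    n_identity_bins: int = 8
    pscore_scan: tuple[int, int, int] = (50, 150, 10)  # start, stop, step
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)

    def validate(self) -> None:
        if not (0.0 <= self.fdr_max <= 1.0):
            raise ValueError(f"fdr_max {self.fdr_max} outside [0, 1]")
        if self.merge_gap < 0 or self.window <= 0 or self.n_samples <= 0:
            raise ValueError("merge_gap/window/n_samples out of range")
        if not (0.0 < self.expressed_frac <= 1.0):
            raise ValueError("expressed_frac must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        cfg = cls(**raw)
        if sim_raw:
            seed = sim_raw.pop("seed", cfg.seed)
            sub = {}
            for key, klass in (
                ("genome", sim.GenomeConfig), ("blocks", sim.BlockConfig),
                ("motifs", sim.MotifConfig), ("expression", sim.ExpressionConfig),
                ("orthology", sim.OrthologyConfig),
            ):
                if key in sim_raw:
                    sub[key] = klass(**sim_raw[key])
            cfg.simulation = sim.SimulationConfig(seed=seed, **sub)
        cfg.simulation.seed = cfg.seed
        return cfg


def _wd(config: PipelineConfig) -> Path:
    p = Path(config.workdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing input {path}; run the upstream stage first"
        )
    return path


def run_simulate(config: PipelineConfig) -> dict:
    """Generate and write the full synthetic input set."""
    config.validate()
    scfg = config.simulation
    scfg.seed = config.seed
    wd = _wd(config)
    genome = sim.generate_genome(scfg)
    blocks, motifs, truth = sim.generate_block_and_motif_sets(scfg, genome)
    logger.info("simulate: %d genes, %d blocks, %d motif predictions",
                len(genome.genes), len(blocks), len(motifs))

    # features to express: a provisional locus set from true-like selection is
    # not yet available, so express motifs-as-loci later; here we plant
    # patterns for gene elements and for merged high-score native motifs.
    native = motifs[(motifs.source == "native") & (motifs.pscore > config.pscore_min)]
    provisional = loci_mod.build_loci(native, max_gap=config.merge_gap)
    crs_track = loci_mod.loci_track(provisional)
    elements = Track(
        "elements",
        genome.utr_exon_track().intervals + genome.ncrna_exon_track().intervals,
    )
    features = Track("features", crs_track.intervals + elements.intervals)
    planted = []
    if len(crs_track) >= 2 and len(elements) >= 2:
        planted = [
            (crs_track.intervals[0].name, elements.intervals[0].name, "perfect_positive"),
            (crs_track.intervals[1].name, elements.intervals[1].name, "perfect_negative"),
        ]
    tracks, meta, truth = sim.generate_expression(scfg, features, planted, truth)
    pairs = [
        (crs_track.intervals[0], elements.intervals[0]),
        (crs_track.intervals[1], elements.intervals[1]),
    ] if planted else []
    orthology, gene_tracks, crs_tracks = sim.generate_orthology(scfg, pairs, truth)
    manifest = sim.write_all(scfg, wd, genome, blocks, motifs, tracks, meta, orthology)
    (wd / "species").mkdir(exist_ok=True)
    for sp in gene_tracks:
        write_bed(gene_tracks[sp], wd / "species" / f"{sp}.genes.bed")
        write_bed(crs_tracks[sp], wd / "species" / f"{sp}.crs.bed")
    return manifest


def _scan_cutoffs(config: PipelineConfig) -> list[int]:
    start, stop, step = config.pscore_scan
    return list(range(start, stop + 1, step))


def run_filter(config: PipelineConfig) -> pd.DataFrame:
    """Input filters, repeat filter, binned FDR estimation and selection."""
    config.validate()
    wd = _wd(config)
    blocks = read_tsv(_require(wd / "blocks.tsv", "filter"))
    motifs = read_tsv(_require(wd / "motifs.tsv", "filter"))
    repeats = read_bed(_require(wd / "repeats.bed", "filter"))

    blocks_kept = filt.filter_input_blocks(blocks)
    logger.info("filter: blocks %d -> %d (input filters)", len(blocks), len(blocks_kept))
    scanned = filt.filter_pscore(motifs, config.pscore_scan[0])
    logger.info("filter: motifs %d -> %d (pscore > %d)",
                len(motifs), len(scanned), config.pscore_scan[0])
    kept, removed = filt.filter_repeat_overlap(scanned, repeats)
    logger.info("filter: motifs %d -> %d (repeat overlap removed %d)",
                len(scanned), len(kept), removed)
    native = kept[kept.source == "native"].reset_index(drop=True)
    shuffled = kept[kept.source == "shuffled"].reset_index(drop=True)
    grid = filt.build_bins(native, config.n_gc_bins, config.n_identity_bins)
    fdr_table = filt.estimate_fdr(native, shuffled, blocks_kept, grid,
                                  _scan_cutoffs(config))
    selected = filt.select_crs_motifs(native, fdr_table,
                                      config.pscore_min, config.fdr_max)
    logger.info("filter: native %d -> %d selected (pscore>%s & FDR<=%s)",
                len(native), len(selected), config.pscore_min, config.fdr_max)
    write_tsv(fdr_table.table, wd / "fdr_table.tsv")
    write_tsv(selected, wd / "selected_motifs.tsv")
    return selected


def run_merge(config: PipelineConfig) -> pd.DataFrame:
    config.validate()
    wd = _wd(config)
    selected = read_tsv(_require(wd / "selected_motifs.tsv", "merge"))
    loci = loci_mod.build_loci(selected, max_gap=config.merge_gap)
    logger.info("merge: %d motifs -> %d loci (gap <= %d, strand-independent)",
                len(selected), len(loci), config.merge_gap)
    write_bed(loci_mod.loci_track(loci), wd / "loci.bed")
    table = loci_mod.loci_table(loci)
    write_tsv(table, wd / "loci.tsv")
    return table


def _load_ncrna_features(wd: Path) -> list[ann.NcRnaFeature]:
    track = read_bed(wd / "ncrna.bed")
    classes = read_tsv(wd / "ncrna_classes.tsv").set_index("id")
    feats = []
    for iv in track:
        row = classes.loc[iv.name]
        feats.append(ann.NcRnaFeature(iv, row["rna_class"],
                                      float(row["base_pair_content"])))
    return feats


def _blocks_track(blocks: pd.DataFrame) -> Track:
    ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end), ".", r.block_id)
           for r in blocks.itertuples(index=False)]
    return Track("blocks", ivs)


def run_annotate(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Unified annotation, category assignment/enrichment, ncRNA recovery."""
    config.validate()
    wd = _wd(config)
    genes = read_gene_models(_require(wd / "genes.gff", "annotate"))
    loci = read_bed(_require(wd / "loci.bed", "annotate"), "loci")
    loci.merged = True
    blocks = filt.filter_input_blocks(read_tsv(_require(wd / "blocks.tsv", "annotate")))
    repeats = read_bed(_require(wd / "repeats.bed", "annotate"))
    feats = _load_ncrna_features(wd)
    nc_track = Track("ncrna", [f.interval for f in feats])

    unified = ann.unify_annotation(genes, nc_track)
    write_bed(Track("unified", list(unified.iter_segments()), merged=True),
              wd / "unified.bed")
    table1 = ann.annotation_enrichment_table(loci, unified, _blocks_track(blocks))
    write_tsv(table1, wd / "category_enrichment.tsv")
    filtered = ann.filter_ncrna_features(feats, _blocks_track(blocks), repeats)
    logger.info("annotate: ncRNA features %d -> %d after structure/block/repeat filters",
                len(feats), len(filtered))
    table2 = ann.ncrna_recovery_table(loci, filtered)
    write_tsv(table2, wd / "ncrna_recovery.tsv")
    return {"categories": table1, "ncrna": table2}


def _experiment_tracks(wd: Path) -> tuple[dict[str, Track], pd.DataFrame]:
    meta = read_tsv(_require(wd / "experiments.tsv", "express"))
    tracks = {}
    for exp_id in meta["experiment_id"]:
        path = wd / "expression" / f"{exp_id}.bed"
        tracks[exp_id] = read_bed(path, exp_id) if path.exists() else Track(exp_id)
    return tracks, meta


def _matrix_features(wd: Path, loci: Track, genes, nc_track) -> Track:
    gd = sim.GenomeData(genes, [], Track())
    elements = gd.utr_exon_track().intervals + gd.ncrna_exon_track().intervals
    return Track("features", list(loci.intervals) + elements)


def run_express(config: PipelineConfig) -> pd.DataFrame:
    """Expression matrix over loci + gene elements, and window enrichment."""
    config.validate()
    wd = _wd(config)
    loci = read_bed(_require(wd / "loci.bed", "express"), "loci")
    loci.merged = True
    genes = read_gene_models(_require(wd / "genes.gff", "express"))
    nc_track = read_bed(_require(wd / "ncrna.bed", "express"))
    tracks, meta = _experiment_tracks(wd)
    features = _matrix_features(wd, loci, genes, nc_track)
    matrix = expr.build_matrix(features.intervals, tracks, config.expressed_frac)
    matrix.astype(int).to_csv(wd / "expression_matrix.tsv", sep="\t")

    unified = ann.unify_annotation(genes, nc_track)
    exonic = Track("exonic", [
        iv for iv in unified.iter_segments()
        if iv.name in ("coding_exon", "utr5_exon", "utr3_exon", "both_utr_exon")
    ], merged=True)
    reports = []
    for excl, tag in ((None, "unfiltered"), (exonic, "filtered")):
        rep = expr.expression_enrichment(
            loci, genes.chrom_sizes, tracks,
            window=config.window, n_replicates=config.n_samples,
            exclude_exonic=excl, seed=config.seed,
            min_frac=config.expressed_frac,
        )
        reports.append(rep)
    report = pd.concat(reports, ignore_index=True)
    write_tsv(report, wd / "expression_enrichment.tsv")
    return report


def intergenic_only(loci: Track, unified: ann.UnifiedAnnotation) -> Track:
    """Loci whose every overlapped unified element is intergenic."""
    keep = []
    for iv in loci:
        elements = unified.overlapping_elements(iv)
        if elements and all(cat == "intergenic" for _, cat in elements):
            keep.append(iv)
    return Track("intergenic_loci", keep, merged=loci.merged)


def run_coexpress(config: PipelineConfig) -> pd.DataFrame:
    config.validate()
    wd = _wd(config)
    loci = read_bed(_require(wd / "loci.bed", "coexpress"), "loci")
    loci.merged = True
    genes = read_gene_models(_require(wd / "genes.gff", "coexpress"))
    nc_track = read_bed(_require(wd / "ncrna.bed", "coexpress"))
    matrix = pd.read_csv(
        _require(wd / "expression_matrix.tsv", "coexpress"), sep="\t", index_col=0
    ).astype(bool)
    unified = ann.unify_annotation(genes, nc_track)
    inter = intergenic_only(loci, unified)
    gd = sim.GenomeData(genes, [], Track())
    elements = Track("elements",
                     gd.utr_exon_track().intervals + gd.ncrna_exon_track().intervals)
    element_gene = {iv.name: iv.name.split(":")[0] for iv in elements}
    records = coex.compute_coexpression(
        inter, elements, matrix, element_gene,
        min_expr=config.min_expr, pos_cut=config.pos_cut, neg_cut=config.neg_cut,
    )
    df = pd.DataFrame([vars(r) for r in records])
    write_tsv(df, wd / "coexpression.tsv")
    logger.info("coexpress: %d intergenic loci, %d scored, %d positive, %d negative",
                len(inter), len(records),
                sum(r.coexpr_class == "positive" for r in records),
                sum(r.coexpr_class == "negative" for r in records))

    orth_path = wd / "orthology.tsv"
    if orth_path.exists() and (wd / "species").exists():
        orthology = read_tsv(orth_path)
        sp_ids = sorted({p.stem.split(".")[0] for p in (wd / "species").glob("*.bed")})
        gene_tracks = {sp: read_bed(wd / "species" / f"{sp}.genes.bed") for sp in sp_ids}
        crs_tracks = {sp: read_bed(wd / "species" / f"{sp}.crs.bed") for sp in sp_ids}
        focal_genes = Track("genes", [
            GenomicInterval(g.chrom, g.start, g.end, g.strand, g.gene_id)
            for g in genes
        ])
        candidates = [r for r in records if r.coexpr_class in ("positive", "negative")]
        # synteny evaluates the CRS against its closest *gene*; map elements
        for r in candidates:
            r.gene_id = element_gene.get(r.element_id, r.gene_id)
        verdicts = coex.synteny_tests(
            candidates, orthology, gene_tracks, crs_tracks, inter, focal_genes,
            required_fraction=config.synteny_fraction,
            max_distance=config.max_distance,
        )
        if verdicts:
            vdf = pd.DataFrame(
                {
                    "crs_id": [v.crs_id for v in verdicts],
                    "gene_id": [v.gene_id for v in verdicts],
                    "n_species": [v.n_available for v in verdicts],
                    "strict_pass": [v.strict_pass for v in verdicts],
                    "orientation_pass": [v.orientation_pass for v in verdicts],
                    "distance_pass": [v.distance_pass for v in verdicts],
                }
            )
            write_tsv(vdf, wd / "synteny.tsv")
    return df


def build_biotype_instances(
    genes, nc_features: Sequence[ann.NcRnaFeature], unified: ann.UnifiedAnnotation,
    loci: Track, tracks: Mapping[str, Track], meta: pd.DataFrame,
    min_frac: float = 0.5,
) -> dict[str, list[stage_mod.BiotypeInstance]]:
    """Instances per biotype with CRS flags and expression vectors.

    Biotypes: coding/UTR exon segments and introns from the unified
    annotation, plus each annotated ncRNA class. ``has_crs`` uses the
    either-sided 50% overlap rule against the locus track.
    """
    exp_ids = list(meta["experiment_id"])
    merged = {e: (t if t.merged else merge_track(t, 0)) for e, t in tracks.items()}

    def _vector(iv: GenomicInterval) -> np.ndarray:
        return np.fromiter(
            (expr.is_expressed(iv, merged[e], min_frac) for e in exp_ids),
            dtype=bool, count=len(exp_ids),
        )

    def _has_crs(iv: GenomicInterval) -> bool:
        return bool(overlap_pairs(
            Track("q", [iv]), loci, min_frac_query=min_frac,
            min_frac_target=min_frac, either_suffices=True, min_bp=1,
        ))

    out: dict[str, list[stage_mod.BiotypeInstance]] = {}
    for seg in unified.iter_segments():
        if seg.name not in ("coding_exon", "utr5_exon", "utr3_exon", "intron"):
            continue
        inst = stage_mod.BiotypeInstance(
            f"{seg.name}:{seg.chrom}:{seg.start}", seg.name, seg,
            _has_crs(seg), _vector(seg),
        )
        out.setdefault(seg.name, []).append(inst)
    for f in nc_features:
        inst = stage_mod.BiotypeInstance(
            f.interval.name, f.rna_class, f.interval,
            _has_crs(f.interval), _vector(f.interval),
        )
        out.setdefault(f.rna_class, []).append(inst)
    return out


def run_stages(config: PipelineConfig) -> pd.DataFrame:
    config.validate()
    wd = _wd(config)
    loci = read_bed(_require(wd / "loci.bed", "stages"), "loci")
    loci.merged = True
    genes = read_gene_models(_require(wd / "genes.gff", "stages"))
    feats = _load_ncrna_features(wd)
    nc_track = Track("ncrna", [f.interval for f in feats])
    blocks = filt.filter_input_blocks(read_tsv(_require(wd / "blocks.tsv", "stages")))
    tracks, meta = _experiment_tracks(wd)
    unified = ann.unify_annotation(genes, nc_track)
    instances = build_biotype_instances(genes, feats, unified, loci, tracks, meta,
                                        config.expressed_frac)
    filtered = {
        bt: stage_mod.filter_instances(insts, _blocks_track(blocks),
                                       min_expressed=config.min_expr)
        for bt, insts in instances.items()
    }
    filtered = {bt: v for bt, v in filtered.items() if v}
    table = stage_mod.stage_enrichment_table(filtered, list(meta["experiment_id"]))
    write_tsv(table, wd / "stage_enrichment.tsv")
    (wd / "ediff").mkdir(exist_ok=True)
    for bt, insts in filtered.items():
        matdf = pd.DataFrame(
            stage_mod.diff_expression_matrix(insts, len(meta)),
            index=meta["experiment_id"], columns=meta["experiment_id"],
        )
        safe = bt.replace("/", "_").replace(" ", "_")
        matdf.to_csv(wd / "ediff" / f"{safe}.tsv", sep="\t")
    return table


def run_compare(config: PipelineConfig) -> pd.DataFrame:
    """Overlap matrix between the selected-locus screen and the raw screens."""
    config.validate()
    wd = _wd(config)
    loci = read_bed(_require(wd / "loci.bed", "compare"), "loci")
    motifs = read_tsv(_require(wd / "motifs.tsv", "compare"))
    screens = {
        "crs_loci": loci,
        "native_raw": filt.motif_track(motifs[motifs.source == "native"], "native"),
        "shuffled_raw": filt.motif_track(motifs[motifs.source == "shuffled"], "shuffled"),
    }
    mat = ann.compare_screens(screens)
    mat.to_csv(wd / "screen_overlaps.tsv", sep="\t")
    return mat


def run_all(config: PipelineConfig) -> None:
    run_simulate(config)
    run_filter(config)
    run_merge(config)
    run_annotate(config)
    run_express(config)
    run_coexpress(config)
    run_stages(config)
    run_compare(config)
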