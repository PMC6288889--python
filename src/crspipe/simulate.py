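"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates every input of a genome-wide conserved-RNA-structure
screen: an annotated genome (coding and non-coding gene models, structured
ncRNA features, repeats), multiple-alignment block metadata with realistic
GC/identity/species-count distributions, motif predictions on the native and
a shuffled companion screen with a *planted* per-bin false discovery rate,
tiling-expression tracks over grouped experiments with planted
ubiquitous/stage-specific/co-expressed loci, and a per-species orthology set
with controllable synteny violations. Every planted quantity is recorded in
a GroundTruth object so recovery can be tested end-to-end.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children, so runs are byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import NcRnaFeature
from .intervals import GenomicInterval, Track
from .io import GeneModel, GeneSet, write_bed, write_gene_models, write_tsv

__all__ = [
    "GenomeConfig",
    "BlockConfig",
    "MotifConfig",
    "ExpressionConfig",
    "OrthologyConfig",
    "SimulationConfig",
    "GroundTruth",
    "GenomeData",
    "generate_genome",
    "generate_block_and_motif_sets",
    "generate_expression",
    "generate_orthology",
    "write_all",
]

NCRNA_CLASSES = (
    "tRNA", "miRNA", "rRNA", "C/D-box snoRNA", "H/ACA-box snoRNA", "scaRNA",
    "snRNA", "lncRNA", "cis-regulatory element", "SRP RNA",
    "histone stem-loop", "ribozyme", "retroelement",
)


class ConfigError(ValueError):
    pass


@dataclass
class GenomeConfig:
    n_chroms: int = 3
    chrom_length: int = 200_000
    n_genes: int = 48
    frac_noncoding: float = 0.15
    exon_length: tuple[int, int] = (100, 400)
    intron_length: tuple[int, int] = (80, 1200)
    n_exons: tuple[int, int] = (2, 4)
    utr_length: tuple[int, int] = (40, 160)
    intergenic_gap: tuple[int, int] = (800, 6000)
    n_ncrna_features: int = 40
    ncrna_length: tuple[int, int] = (70, 200)
    # target fraction of UTR-exon nucleotides overlapped by ncRNA features
    utr_ncrna_overlap_frac: float = 0.05
    repeat_coverage: float = 0.05
    repeat_length: tuple[int, int] = (100, 400)


@dataclass
class BlockConfig:
    coverage: float = 0.5
    length: tuple[int, int] = (50, 300)
    # GC mass concentrated in 0.30-0.60, identity in 0.40-0.80
    gc_beta: tuple[float, float] = (3.0, 3.0)
    gc_range: tuple[float, float] = (0.20, 0.70)
    identity_beta: tuple[float, float] = (3.0, 3.0)
    identity_range: tuple[float, float] = (0.35, 0.85)
    species_mean: float = 20.0
    species_sd: float = 4.0
    species_range: tuple[int, int] = (3, 27)
    frac_substandard: float = 0.05  # blocks violating the input filters


@dataclass
class MotifConfig:
    false_rate_per_block: float = 1.0
    false_pscore_scale: float = 12.0  # pscore = 50 + Exp(scale)
    true_pscore_scale: float = 40.0  # pscore = 80.01 + Exp(scale)
    planted_fdr: float = 0.10  # at the pscore>80 selection cutoff
    frac_true_in_ncrna: float = 0.6  # preference for annotated ncRNA blocks
    motif_length: tuple[int, int] = (30, 100)
    jitter: float = 0.02  # motif gc/identity jitter around its block


@dataclass
class ExpressionConfig:
    n_experiments: int = 80
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "embryo": 30, "larva": 12, "prepupa": 6, "adult": 12, "cell_line": 20,
        }
    )
    frac_ubiquitous: float = 1.0 / 6.0
    frac_stage_specific: float = 0.5
    background_p_on: float = 0.25
    # detection-dropout noise: an expressed cell is missed with this
    # probability (tiling arrays under-call expression; false positives are
    # negligible after score thresholding upstream)
    noise: float = 0.0


@dataclass
class OrthologyConfig:
    n_species: int = 11
    insertion_rate: float = 0.0  # gene inserted between CRS and ortholog
    rearrangement_rate: float = 0.0  # ortholog flipped to the other side
    distance_inflation: int = 0  # added to the focal distance per species
    missing_rate: float = 0.0  # ortholog absent in a species
    jitter: int = 50


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    blocks: BlockConfig = field(default_factory=BlockConfig)
    motifs: MotifConfig = field(default_factory=MotifConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    orthology: OrthologyConfig = field(default_factory=OrthologyConfig)

    def validate(self) -> None:
        g = self.genome
        for frac in (
            g.frac_noncoding, g.utr_ncrna_overlap_frac, g.repeat_coverage,
            self.blocks.coverage, self.motifs.planted_fdr,
            self.motifs.frac_true_in_ncrna, self.expression.frac_ubiquitous,
            self.expression.frac_stage_specific, self.expression.noise,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError(f"fraction {frac} outside [0, 1]")
        if sum(self.expression.group_sizes.values()) != self.expression.n_experiments:
            raise ConfigError("group sizes must sum to n_experiments")


@dataclass
class GroundTruth:
    true_motif_ids: set[str] = field(default_factory=set)
    planted_bin_fdr: float = float("nan")
    expression_pattern: dict[str, str] = field(default_factory=dict)
    planted_pairs: list[dict] = field(default_factory=list)  # crs, element, kind, expected score
    syntenic_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class GenomeData:
    genes: GeneSet
    ncrna_features: list[NcRnaFeature]
    repeats: Track

    def utr_exon_track(self) -> Track:
        """UTR-exon elements with names, for closest-gene-element queries."""
        ivs = []
        for g in self.genes:
            if not g.is_coding:
                continue
            cds_lo = min(c.start for c in g.cds)
            cds_hi = max(c.end for c in g.cds)
            for ex in g.exons:
                for s, e, tag in (
                    (ex.start, min(ex.end, cds_lo), "L"),
                    (max(ex.start, cds_hi), ex.end, "R"),
                ):
                    if s < e:
                        before = tag == "L"
                        five = before if g.strand != "-" else not before
                        ivs.append(
                            GenomicInterval(
                                g.chrom, s, e, g.strand,
                                f"{g.gene_id}:utr{'5' if five else '3'}:{s}",
                            )
                        )
        return Track("utr_exons", ivs)

    def ncrna_exon_track(self) -> Track:
        ivs = []
        for g in self.genes:
            if g.is_coding:
                continue
            for k, ex in enumerate(g.exons):
                ivs.append(
                    GenomicInterval(g.chrom, ex.start, ex.end, g.strand,
                                    f"{g.gene_id}:ncexon{k}")
                )
        return Track("ncrna_exons", ivs)

    def gene_track(self) -> Track:
        return Track("genes", [g.span for g in self.genes])


def _rng(seed_seq: np.random.SeedSequence, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed_seq.entropy, spawn_key=key
    ))


def generate_genome(config: SimulationConfig) -> GenomeData:
    """Deterministically lay out genes, ncRNA features and repeats.

    Genes are packed left to right per chromosome with random intergenic
    gaps; packing overflow (too many/too long genes for the chromosome)
    raises a ConfigError. A configurable share of UTR-exon nucleotides is
    overlapped by planted ncRNA features; remaining features fall in introns
    or intergenic space.
    """
    config.validate()
    g = config.genome
    root = np.random.SeedSequence(config.seed)
    rng = _rng(root, 0)
    chroms = [f"chr{i + 1}" for i in range(g.n_chroms)]
    gs = GeneSet(chrom_sizes={c: g.chrom_length for c in chroms})
    cursor = {c: 0 for c in chroms}
    n_noncoding = int(round(g.n_genes * g.frac_noncoding))
    coding_flags = [i >= n_noncoding for i in range(g.n_genes)]
    rng.shuffle(coding_flags)
    for idx in range(g.n_genes):
        chrom = chroms[idx % len(chroms)]
        gap = int(rng.integers(*g.intergenic_gap))
        start = cursor[chrom] + gap
        n_ex = int(rng.integers(g.n_exons[0], g.n_exons[1] + 1))
        exon_lens = rng.integers(g.exon_length[0], g.exon_length[1] + 1, size=n_ex)
        intron_lens = rng.integers(g.intron_length[0], g.intron_length[1] + 1,
                                   size=max(0, n_ex - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{idx + 1:04d}"
        exons = []
        pos = start
        for k in range(n_ex):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_ex - 1:
                pos += int(intron_lens[k])
        end = pos
        if end > g.chrom_length:
            raise ConfigError(
                f"gene packing exceeds chromosome length on {chrom}: "
                f"reduce n_genes or gene sizes"
            )
        model = GeneModel(gid, chrom, start, end, strand, exons=exons)
        if coding_flags[idx]:
            u5 = int(rng.integers(*g.utr_length))
            u3 = int(rng.integers(*g.utr_length))
            chain = sum(len(e) for e in exons)
            u5 = min(u5, len(exons[0]) - 10)
            u3 = min(u3, len(exons[-1]) - 10)
            lead, trail = (u5, u3) if strand != "-" else (u3, u5)
            cds_lo = start + lead
            cds_hi = end - trail
            for ex in exons:
                s, e = max(ex.start, cds_lo), min(ex.end, cds_hi)
                if s < e:
                    model.cds.append(GenomicInterval(chrom, s, e, strand))
        gs.genes[gid] = model
        cursor[chrom] = end

    # structured ncRNA features: some overlap UTR exons up to the target
    features: list[NcRnaFeature] = []
    utr_ivs = GenomeData(gs, [], Track()).utr_exon_track().intervals
    utr_nt = sum(len(iv) for iv in utr_ivs)
    target_overlap = int(round(g.utr_ncrna_overlap_frac * utr_nt))
    covered = 0
    f_idx = 0
    utr_order = list(range(len(utr_ivs)))
    rng.shuffle(utr_order)
    for ui in utr_order:
        if covered >= target_overlap:
            break
        utr = utr_ivs[ui]
        length = int(rng.integers(*g.ncrna_length))
        want = min(len(utr), target_overlap - covered, length)
        start = utr.start + int(rng.integers(0, max(1, len(utr) - want + 1)))
        iv = GenomicInterval(utr.chrom, start, start + length, "+",
                             f"ncfeat{f_idx + 1:04d}")
        ov = iv.overlap(utr)
        covered += ov
        features.append(
            NcRnaFeature(iv, str(rng.choice(NCRNA_CLASSES)),
                         float(rng.uniform(0.15, 0.95)))
        )
        f_idx += 1
    while f_idx < g.n_ncrna_features:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(*g.ncrna_length))
        start = int(rng.integers(0, g.chrom_length - length))
        iv = GenomicInterval(chrom, start, start + length, "+",
                             f"ncfeat{f_idx + 1:04d}")
        features.append(
            NcRnaFeature(iv, str(rng.choice(NCRNA_CLASSES)),
                         float(rng.uniform(0.15, 0.95)))
        )
        f_idx += 1

    repeat_ivs = []
    need = int(g.repeat_coverage * g.n_chroms * g.chrom_length)
    got = 0
    r_idx = 0
    while got < need:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(*g.repeat_length))
        start = int(rng.integers(0, g.chrom_length - length))
        repeat_ivs.append(
            GenomicInterval(chrom, start, start + length, ".", f"rep{r_idx + 1:04d}")
        )
        got += length
        r_idx += 1
    return GenomeData(gs, features, Track("repeats", repeat_ivs))


def _draw_scaled_beta(rng, ab, lohi, size):
    lo, hi = lohi
    return lo + (hi - lo) * rng.beta(ab[0], ab[1], size=size)


def generate_block_and_motif_sets(
    config: SimulationConfig, genome: GenomeData
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Alignment-block metadata plus native and shuffled motif predictions.

    False motifs arise from one Poisson process applied with independent
    random streams to the native and shuffled screens, so per-bin
    shuffled/native ratios among false-only predictions are ~1. True motifs
    (native only) receive pscores above the selection cutoff and are planted
    so that the FDR at pscore>80 equals ``planted_fdr`` in expectation; a
    configurable fraction lands in blocks overlapping annotated ncRNA
    features. Returns (blocks, motifs, ground truth); motifs carry a
    ``source`` column (native | shuffled).
    """
    config.validate()
    b, m = config.blocks, config.motifs
    root = np.random.SeedSequence(config.seed)
    rng = _rng(root, 1)
    chrom_sizes = genome.genes.chrom_sizes
    block_rows = []
    bid = 0
    for chrom in sorted(chrom_sizes):
        pos = 0
        size = chrom_sizes[chrom]
        while pos < size:
            length = int(rng.integers(*b.length))
            if rng.random() < b.frac_substandard:
                length = int(rng.integers(20, 49))  # fails the length filter
            if pos + length > size:
                break
            n_sp = int(np.clip(round(rng.normal(b.species_mean, b.species_sd)),
                               *b.species_range))
            if rng.random() < b.frac_substandard:
                n_sp = 2  # fails the species filter
            gc = float(_draw_scaled_beta(rng, b.gc_beta, b.gc_range, None))
            ident = float(_draw_scaled_beta(rng, b.identity_beta, b.identity_range, None))
            block_rows.append(
                {
                    "block_id": f"blk{bid + 1:06d}", "chrom": chrom, "start": pos,
                    "end": pos + length, "n_species": n_sp,
                    "gc": round(gc, 4), "identity": round(ident, 4),
                }
            )
            bid += 1
            # spacing tuned so blocks cover ~`coverage` of the genome
            gap = int(length * (1.0 - b.coverage) / max(b.coverage, 1e-9))
            pos += length + max(gap, 1)
    blocks = pd.DataFrame(block_rows)

    usable = blocks[
        ((blocks.end - blocks.start) >= 50) & (blocks.n_species >= 3)
    ].reset_index(drop=True)

    nc_track = Track("nc", [f.interval for f in genome.ncrna_features])
    nc_by_chrom = nc_track.by_chrom()

    def _overlaps_ncrna(row) -> bool:
        for iv in nc_by_chrom.get(row.chrom, []):
            if iv.start < row.end and row.start < iv.end:
                return True
        return False

    nc_mask = np.array([_overlaps_ncrna(r) for r in usable.itertuples(index=False)])

    truth = GroundTruth(planted_bin_fdr=m.planted_fdr)
    motif_rows = []
    mid = 0

    def _emit(row, pscore, source, is_true, rng_local):
        nonlocal mid
        blen = row.end - row.start
        length = int(rng_local.integers(m.motif_length[0],
                                        min(m.motif_length[1], blen) + 1))
        start = row.start + int(rng_local.integers(0, blen - length + 1))
        mid += 1
        mot_id = f"{'nat' if source == 'native' else 'shf'}{mid:07d}"
        if is_true:
            truth.true_motif_ids.add(mot_id)
        motif_rows.append(
            {
                "id": mot_id, "chrom": row.chrom, "start": start,
                "end": start + length,
                "strand": "+" if rng_local.random() < 0.5 else "-",
                "pscore": round(float(pscore), 3),
                "energy": round(float(-rng_local.gamma(4.0, 2.5)), 2),
                "gc": round(float(np.clip(row.gc + rng_local.normal(0, m.jitter), 0, 1)), 4),
                "identity": round(float(np.clip(
                    row.identity + rng_local.normal(0, m.jitter), 0, 1)), 4),
                "n_species": int(row.n_species), "source": source,
            }
        )

    # false motifs: the same process, independent streams per screen
    for source, stream in (("native", _rng(root, 1, 1)), ("shuffled", _rng(root, 1, 2))):
        for row in usable.itertuples(index=False):
            k = stream.poisson(m.false_rate_per_block)
            for _ in range(k):
                pscore = 50.0 + stream.exponential(m.false_pscore_scale)
                _emit(row, pscore, source, False, stream)

    # true motifs, native only, planted to realize the target FDR at pscore>80
    p_false_above = math.exp(-30.0 / m.false_pscore_scale)
    lam_false_above = m.false_rate_per_block * p_false_above * len(usable)
    f = m.planted_fdr
    lam_true_total = lam_false_above * (1.0 - f) / f if f > 0 else 0.0
    true_stream = _rng(root, 1, 3)
    if lam_true_total > 0 and len(usable):
        n_true = true_stream.poisson(lam_true_total)
        weights = np.where(nc_mask, m.frac_true_in_ncrna / max(nc_mask.sum(), 1),
                           (1 - m.frac_true_in_ncrna) / max((~nc_mask).sum(), 1))
        if weights.sum() == 0:
            weights = np.ones(len(usable))
        weights = weights / weights.sum()
        choices = true_stream.choice(len(usable), size=n_true, p=weights)
        for ci in choices:
            row = usable.iloc[int(ci)]
            pscore = 80.01 + true_stream.exponential(m.true_pscore_scale)
            _emit(row, pscore, "native", True, true_stream)

    motifs = pd.DataFrame(motif_rows)
    return blocks, motifs, truth


def assign_experiment_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Experiment table: id, sample_class, strain, stage_group, rna_fraction."""
    e = config.expression
    rng = _rng(np.random.SeedSequence(config.seed), 2, 0)
    rows = []
    i = 0
    for group, size in e.group_sizes.items():
        for _ in range(size):
            i += 1
            rows.append(
                {
                    "experiment_id": f"exp{i:03d}",
                    "sample_class": "cell_line" if group == "cell_line" else "fly",
                    "strain": ("-" if group == "cell_line"
                               else ["ycnbwsp", "OregonR"][int(rng.integers(0, 2))]),
                    "stage_group": group,
                    "rna_fraction": ["total", "polyA", "nuclear"][int(rng.integers(0, 3))],
                    "compartment": "",
                }
            )
    return pd.DataFrame(rows)


def generate_expression(
    config: SimulationConfig,
    features: Track,
    planted_pairs: Sequence[tuple[str, str, str]] = (),
    truth: GroundTruth | None = None,
) -> tuple[dict[str, Track], pd.DataFrame, GroundTruth]:
    """Boolean expression patterns realized as per-experiment region tracks.

    ``features`` must carry unique names (CRS loci and gene elements alike).
    ``planted_pairs`` are (crs_name, element_name, kind) with kind in
    {perfect_positive, perfect_negative, independent}; their patterns realize
    E_co of exactly +1 / -1 / 0 at noise 0. Remaining features are assigned
    ubiquitous / stage-specific / background patterns by the configured
    fractions. Returns (experiment tracks, experiment metadata, ground truth).
    """
    config.validate()
    e = config.expression
    meta = assign_experiment_metadata(config)
    n = len(meta)
    groups = meta["stage_group"].to_numpy()
    rng = _rng(np.random.SeedSequence(config.seed), 2, 1)
    truth = truth or GroundTruth()

    states: dict[str, np.ndarray] = {}
    planted_names = set()
    for crs_name, el_name, kind in planted_pairs:
        k = int(rng.integers(8, max(9, n // 3)))
        on_idx = rng.choice(n, size=k, replace=False)
        crs_vec = np.zeros(n, dtype=bool)
        crs_vec[on_idx] = True
        if kind == "perfect_positive":
            el_vec = crs_vec.copy()
            expected = 1.0
        elif kind == "perfect_negative":
            el_vec = ~crs_vec
            expected = -1.0
        elif kind == "independent":
            el_vec = np.ones(n, dtype=bool)
            expected = 0.0
        else:
            raise ConfigError(f"unknown planted pair kind {kind!r}")
        states[crs_name] = crs_vec
        states[el_name] = el_vec
        planted_names |= {crs_name, el_name}
        truth.planted_pairs.append(
            {"crs": crs_name, "element": el_name, "kind": kind,
             "expected_score": expected}
        )
        truth.expression_pattern[crs_name] = kind
        truth.expression_pattern[el_name] = f"{kind}:element"

    group_names = [g for g in e.group_sizes if g != "cell_line"] or list(e.group_sizes)
    for iv in features:
        if iv.name in planted_names:
            continue
        u = rng.random()
        if u < e.frac_ubiquitous:
            vec = np.ones(n, dtype=bool)
            pattern = "ubiquitous"
        elif u < e.frac_ubiquitous + e.frac_stage_specific:
            grp = group_names[int(rng.integers(0, len(group_names)))]
            vec = groups == grp
            pattern = f"specific:{grp}"
        else:
            vec = rng.random(n) < e.background_p_on
            pattern = "background"
        states[iv.name] = vec
        truth.expression_pattern[iv.name] = pattern

    if e.noise > 0:
        for name, vec in states.items():
            dropped = rng.random(n) < e.noise
            states[name] = vec & ~dropped

    by_name = {iv.name: iv for iv in features}
    tracks: dict[str, Track] = {}
    for j, exp_id in enumerate(meta["experiment_id"]):
        ivs = [
            GenomicInterval(by_name[nm].chrom, by_name[nm].start, by_name[nm].end,
                            ".", f"t:{nm}")
            for nm, vec in states.items()
            if nm in by_name and vec[j]
        ]
        tracks[exp_id] = Track(exp_id, sorted(
            ivs, key=lambda i: (i.chrom, i.start, i.end)))
    return tracks, meta, truth


def generate_orthology(
    config: SimulationConfig,
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval]],
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, dict[str, Track], dict[str, Track]]:
    """Per-species gene annotations and ortholog table for CRS-gene pairs.

    Each (crs, gene) pair is copied into every species with a small
    coordinate jitter, preserving side and distance; per species and pair,
    configured violation events fire independently: a gene inserted between
    CRS and ortholog (breaks the strict closest-gene criterion only), a side
    flip (breaks orientation), distance inflation (breaks the distance
    criterion when pushed beyond the cutoff), or a missing ortholog (species
    excluded from the denominator). A far decoy gene per pair keeps the
    "closest gene" question non-trivial. Returns (orthology table,
    per-species gene tracks, per-species CRS tracks).
    """
    o = config.orthology
    rng = _rng(np.random.SeedSequence(config.seed), 3)
    truth = truth or GroundTruth()
    species = [f"sp{i + 1:02d}" for i in range(o.n_species)]
    orth_rows = []
    genes_per_sp: dict[str, list[GenomicInterval]] = {sp: [] for sp in species}
    crs_per_sp: dict[str, list[GenomicInterval]] = {sp: [] for sp in species}
    for pair_idx, (crs_iv, gene_iv) in enumerate(pairs):
        truth.syntenic_pairs.append((crs_iv.name, gene_iv.name))
        upstream = gene_iv.end <= crs_iv.start
        dist = (crs_iv.start - gene_iv.end) if upstream else (gene_iv.start - crs_iv.end)
        glen = len(gene_iv)
        clen = len(crs_iv)
        for sp in species:
            if rng.random() < o.missing_rate:
                continue
            shift = int(rng.integers(0, o.jitter + 1))
            c_start = 10_000 + shift
            # one scaffold per pair so pairs cannot shadow each other's
            # closest-gene relation
            crs_sp = GenomicInterval(f"{sp}_scaf{pair_idx + 1}", c_start,
                                     c_start + clen, ".", crs_iv.name)
            d = dist + o.distance_inflation
            flip = rng.random() < o.rearrangement_rate
            place_up = upstream ^ flip
            if place_up:
                g_end = crs_sp.start - d
                g_start = g_end - glen
            else:
                g_start = crs_sp.end + d
                g_end = g_start + glen
            if g_start < 0:
                g_start, g_end = crs_sp.end + d, crs_sp.end + d + glen
            orth_id = f"{gene_iv.name}@{sp}"
            genes_per_sp[sp].append(
                GenomicInterval(crs_sp.chrom, g_start, g_end, gene_iv.strand, orth_id)
            )
            if rng.random() < o.insertion_rate:
                # a novel gene strictly between CRS and ortholog
                gap_lo = min(crs_sp.end, g_end)
                gap_hi = max(crs_sp.start, g_start)
                if gap_hi - gap_lo > 40:
                    ins_len = min(30, gap_hi - gap_lo - 10)
                    mid_point = (gap_lo + gap_hi) // 2
                    genes_per_sp[sp].append(
                        GenomicInterval(crs_sp.chrom, mid_point,
                                        mid_point + ins_len, "+",
                                        f"inserted:{gene_iv.name}@{sp}")
                    )
            # far decoy so "closest" is informative
            decoy_start = crs_sp.end + max(d, 0) + 50_000
            genes_per_sp[sp].append(
                GenomicInterval(crs_sp.chrom, decoy_start, decoy_start + 500, "+",
                                f"decoy:{gene_iv.name}@{sp}")
            )
            crs_per_sp[sp].append(crs_sp)
            orth_rows.append(
                {"gene": gene_iv.name, "species": sp, "ortholog": orth_id}
            )
    orthology = pd.DataFrame(orth_rows, columns=["gene", "species", "ortholog"])
    gene_tracks = {sp: Track(sp, ivs) for sp, ivs in genes_per_sp.items()}
    crs_tracks = {sp: Track(sp, ivs) for sp, ivs in crs_per_sp.items()}
    return orthology, gene_tracks, crs_tracks


def write_all(
    config: SimulationConfig,
    outdir: str | Path,
    genome: GenomeData,
    blocks: pd.DataFrame,
    motifs: pd.DataFrame,
    expression_tracks: Mapping[str, Track] | None = None,
    experiment_meta: pd.DataFrame | None = None,
    orthology: pd.DataFrame | None = None,
) -> dict:
    """Serialize all generated inputs plus a manifest; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "files": {}}

    write_gene_models(genome.genes, out / "genes.gff")
    manifest["files"]["genes"] = "genes.gff"
    write_bed(Track("ncrna", [f.interval for f in genome.ncrna_features]),
              out / "ncrna.bed")
    write_tsv(
        pd.DataFrame(
            {
                "id": [f.interval.name for f in genome.ncrna_features],
                "rna_class": [f.rna_class for f in genome.ncrna_features],
                "base_pair_content": [f.base_pair_content for f in genome.ncrna_features],
            }
        ),
        out / "ncrna_classes.tsv",
    )
    manifest["files"]["ncrna"] = ["ncrna.bed", "ncrna_classes.tsv"]
    write_bed(genome.repeats, out / "repeats.bed")
    manifest["files"]["repeats"] = "repeats.bed"
    write_tsv(blocks, out / "blocks.tsv")
    manifest["files"]["blocks"] = "blocks.tsv"
    write_tsv(motifs, out / "motifs.tsv")
    manifest["files"]["motifs"] = "motifs.tsv"
    if expression_tracks is not None:
        (out / "expression").mkdir(exist_ok=True)
        for exp_id, track in expression_tracks.items():
            write_bed(track, out / "expression" / f"{exp_id}.bed")
        manifest["files"]["expression_dir"] = "expression"
    if experiment_meta is not None:
        write_tsv(experiment_meta, out / "experiments.tsv")
        manifest["files"]["experiments"] = "experiments.tsv"
    if orthology is not None:
        write_tsv(orthology, out / "orthology.tsv")
        manifest["files"]["orthology"] = "orthology.tsv"
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
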