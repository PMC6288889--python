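"""Unified genome annotation and overlap/enrichment statistics.

The screen assigns every nucleotide exactly one category so that locus counts
over categories are unambiguous. Priority (highest wins): coding exon >
ncRNA exon > both-UTR exon > single-UTR exon > intron > intergenic. ncRNA
exons override UTR exons because an annotated structured RNA inside a UTR is
the stronger statement about the base; coding sequence overrides everything.

Loci are then counted *fractionally*: a locus overlapping k distinct unified
elements contributes 1/k to each element's category, so category counts sum
exactly to the number of loci. Enrichment is a fold change of the overlap
rate over the size-expected rate, with a normal (binomial-variance)
approximation for significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalError, Track, merge_track, coverage_fraction, overlap_pairs
from .io import GeneSet

__all__ = [
    "CATEGORIES",
    "UnifiedAnnotation",
    "unify_annotation",
    "assign_fractional_categories",
    "fold_enrichment",
    "enrichment_pvalue",
    "annotation_enrichment_table",
    "NcRnaFeature",
    "filter_ncrna_features",
    "ncrna_recovery_table",
    "compare_screens",
    "expected_overlap",
    "round_half_up",
]

CATEGORIES = (
    "intergenic",
    "intron",
    "utr5_exon",
    "utr3_exon",
    "both_utr_exon",
    "ncrna_exon",
    "coding_exon",
)
_CAT_CODE = {c: i for i, c in enumerate(CATEGORIES)}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style half-up rounding (report-time display convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class UnifiedAnnotation:
    """Single-label partition of every annotated chromosome.

    ``segments`` maps chromosome -> (starts, ends, codes) arrays of maximal
    runs of one category; runs abut exactly (partition, no gaps/overlaps).
    """

    chrom_sizes: dict[str, int]
    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def iter_segments(self) -> Iterable[GenomicInterval]:
        for chrom in sorted(self.segments):
            starts, ends, codes = self.segments[chrom]
            for s, e, c in zip(starts, ends, codes):
                yield GenomicInterval(chrom, int(s), int(e), ".", CATEGORIES[c])

    def category_track(self, category: str) -> Track:
        code = _CAT_CODE[category]
        ivs = [iv for iv in self.iter_segments() if _CAT_CODE[iv.name] == code]
        return Track(category, ivs, merged=True)

    def category_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in CATEGORIES}
        for chrom, (starts, ends, codes) in self.segments.items():
            lengths = ends - starts
            for code in np.unique(codes):
                sizes[CATEGORIES[code]] += int(lengths[codes == code].sum())
        return sizes

    def overlapping_elements(self, iv: GenomicInterval) -> list[tuple[int, str]]:
        """(element index, category) for every unified element overlapping iv."""
        if iv.chrom not in self.segments:
            return []
        starts, ends, codes = self.segments[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        return [(i, CATEGORIES[codes[i]]) for i in range(lo, hi)]


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return starts, ends, labels[starts]


def unify_annotation(
    gene_models: GeneSet, ncrna_features: Track | None = None
) -> UnifiedAnnotation:
    """Collapse gene models plus ncRNA features into the one-label partition.

    UTR assignment uses the merged CDS span of each coding gene: exon bases
    outside the CDS intervals are 5'-UTR when on the transcription-upstream
    side of the CDS span and 3'-UTR on the downstream side (strand-aware);
    exon bases inside CDS intervals are coding. Non-coding genes' exons and
    the ncRNA feature track paint the ncRNA-exon layer. Positions where 5'-
    and 3'-UTR exons of (possibly different) genes overlap become the
    both-UTR category.
    """
    if not gene_models.chrom_sizes:
        raise IntervalError("gene model set carries no chromosome sizes")
    ua = UnifiedAnnotation(dict(gene_models.chrom_sizes))
    labels = {
        chrom: np.zeros(size, dtype=np.uint8)
        for chrom, size in gene_models.chrom_sizes.items()
    }
    utr5 = {c: np.zeros(s, dtype=bool) for c, s in gene_models.chrom_sizes.items()}
    utr3 = {c: np.zeros(s, dtype=bool) for c, s in gene_models.chrom_sizes.items()}

    def _paint(arr, iv, value):
        arr[iv.start : iv.end] = value

    # layer 1: gene spans -> intron (refined by exon layers below)
    for g in gene_models:
        if g.chrom not in labels:
            raise IntervalError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        if not g.exons:
            raise IntervalError(f"gene {g.gene_id} has no exons")
        _paint(labels[g.chrom], g.span, _CAT_CODE["intron"])

    # layer 2: UTR masks from coding genes
    for g in gene_models:
        if not g.is_coding:
            continue
        cds_lo = min(c.start for c in g.cds)
        cds_hi = max(c.end for c in g.cds)
        for ex in g.exons:
            for s, e in [(ex.start, min(ex.end, cds_lo)), (max(ex.start, cds_hi), ex.end)]:
                if s >= e:
                    continue
                before_cds = e <= cds_lo
                is_five = before_cds if g.strand != "-" else not before_cds
                (utr5 if is_five else utr3)[g.chrom][s:e] = True

    for chrom, lab in labels.items():
        only5 = utr5[chrom] & ~utr3[chrom]
        only3 = utr3[chrom] & ~utr5[chrom]
        both = utr5[chrom] & utr3[chrom]
        lab[only5] = _CAT_CODE["utr5_exon"]
        lab[only3] = _CAT_CODE["utr3_exon"]
        lab[both] = _CAT_CODE["both_utr_exon"]

    # layer 3: ncRNA exons (non-coding genes' exons + annotated ncRNA features)
    for g in gene_models:
        if g.is_coding:
            continue
        for ex in g.exons:
            _paint(labels[g.chrom], ex, _CAT_CODE["ncrna_exon"])
    if ncrna_features is not None:
        for iv in ncrna_features:
            if iv.chrom in labels:
                _paint(labels[iv.chrom], iv, _CAT_CODE["ncrna_exon"])

    # layer 4: coding exon = exon bases inside the merged CDS intervals
    for g in gene_models:
        for c in g.cds:
            _paint(labels[g.chrom], c, _CAT_CODE["coding_exon"])

    for chrom, lab in labels.items():
        ua.segments[chrom] = _runs(lab)
    return ua


def assign_fractional_categories(
    loci: Track, unified: UnifiedAnnotation
) -> dict[str, float]:
    """Fractional locus counts per category (plus ``unmapped``).

    Each locus distributes a total weight of 1 equally over the distinct
    unified *elements* it overlaps by >=1 bp (two intron elements and one
    intergenic element -> intron += 2/3, intergenic += 1/3). Loci on
    chromosomes absent from the annotation count as ``unmapped``. The sum of
    all counts equals the number of loci exactly.
    """
    counts: dict[str, float] = {c: 0.0 for c in CATEGORIES}
    counts["unmapped"] = 0.0
    for locus in loci:
        elements = unified.overlapping_elements(locus)
        if not elements:
            counts["unmapped"] += 1.0
            continue
        w = 1.0 / len(elements)
        for _, cat in elements:
            counts[cat] += w
    return counts


def fold_enrichment(
    n_overlap: float, n_queries: int, target_size_nt: int, background_size_nt: int
) -> float:
    """(overlap rate among queries) / (target share of the background)."""
    if n_queries <= 0 or background_size_nt <= 0:
        raise ValueError("n_queries and background_size_nt must be positive")
    if target_size_nt <= 0:
        return float("nan")  # undefined, flagged as NaN
    return (n_overlap / n_queries) / (target_size_nt / background_size_nt)


def enrichment_pvalue(n_overlap: float, n_queries: int, target_fraction: float) -> float:
    """One-sided normal-approximation p for the observed overlap count.

    Null: overlaps ~ Binomial(n_queries, target_fraction), approximated as
    Normal(mu, sigma) with mu = n*f and sigma = sqrt(n*f*(1-f)). Upper tail
    when the observation exceeds mu, lower tail otherwise.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must lie strictly in (0, 1)")
    mu = n_queries * target_fraction
    sigma = math.sqrt(n_queries * target_fraction * (1.0 - target_fraction))
    if sigma == 0.0:
        return float("nan")
    z = (n_overlap - mu) / sigma
    return float(stats.norm.sf(z)) if n_overlap > mu else float(stats.norm.cdf(z))


def annotation_enrichment_table(
    loci: Track, unified: UnifiedAnnotation, blocks: Track
) -> pd.DataFrame:
    """Per-category fractional counts, percentages, FE and p (Table-1 layout).

    Target size per category = nt of that category's elements overlapping any
    input alignment block by >=1 nt; background size = total block columns.
    FE/p use the fractional overlap counts (the same quantity the table
    prints); categories lacking any block overlap get NaN FE/p.
    """
    merged_blocks = blocks if blocks.merged else merge_track(blocks, 0)
    counts = assign_fractional_categories(loci, unified)
    n_loci = len(loci)
    background = merged_blocks.total_length()
    rows = []
    for cat in CATEGORIES:
        target = 0
        for iv in unified.category_track(cat):
            if coverage_fraction(iv, merged_blocks) > 0.0:
                target += len(iv)
        n_ov = counts[cat]
        fe = fold_enrichment(n_ov, n_loci, target, background) if target else float("nan")
        frac = target / background if background else float("nan")
        p = (
            enrichment_pvalue(n_ov, n_loci, frac)
            if target and 0.0 < frac < 1.0
            else float("nan")
        )
        rows.append(
            {
                "category": cat,
                "n_overlap": n_ov,
                "n_overlap_rounded": int(round_half_up(n_ov)),
                "percentage": 100.0 * n_ov / n_loci if n_loci else float("nan"),
                "fold_enrichment": fe,
                "p_value": p,
                "target_size_nt": target,
                "background_size_nt": background,
            }
        )
    rows.append(
        {
            "category": "unmapped",
            "n_overlap": counts["unmapped"],
            "n_overlap_rounded": int(round_half_up(counts["unmapped"])),
            "percentage": 100.0 * counts["unmapped"] / n_loci if n_loci else float("nan"),
            "fold_enrichment": float("nan"),
            "p_value": float("nan"),
            "target_size_nt": 0,
            "background_size_nt": background,
        }
    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NcRnaFeature:
    """An annotated structured-RNA feature with its secondary-structure load.

    ``base_pair_content`` is the fraction of positions involved in base
    pairing in the reference structure; weakly structured annotations
    (< 30% by default) are excluded from recovery statistics.
    """

    interval: GenomicInterval
    rna_class: str
    base_pair_content: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_pair_content <= 1.0):
            raise ValueError(
                f"base_pair_content outside [0,1] for {self.interval.name!r}"
            )


def filter_ncrna_features(
    features: Sequence[NcRnaFeature],
    blocks: Track,
    repeats: Track,
    min_bp_content: float = 0.3,
    min_block_frac: float = 0.5,
    max_repeat_frac: float = 0.5,
) -> list[NcRnaFeature]:
    """Keep features assessable by the screen: structured, inside the input
    alignment blocks by >=50% of their size, and not repeat-dominated
    (repeat coverage strictly below 50%)."""
    mb = blocks if blocks.merged else merge_track(blocks, 0)
    mr = repeats if repeats.merged else merge_track(repeats, 0)
    out = []
    for f in features:
        if f.base_pair_content < min_bp_content:
            continue
        if coverage_fraction(f.interval, mb) < min_block_frac:
            continue
        if coverage_fraction(f.interval, mr) >= max_repeat_frac:
            continue
        out.append(f)
    return out


def ncrna_recovery_table(
    loci: Track, filtered_features: Sequence[NcRnaFeature], min_frac: float = 0.5
) -> pd.DataFrame:
    """Per-class recovery of annotated ncRNA features by CRS loci.

    A feature counts as overlapped when some locus covers >= ``min_frac`` of
    the locus *or* of the feature (either side suffices). The table reports,
    per RNA class and overall, the filtered feature count, features
    overlapped, the percentage (one decimal; NaN when no features), and the
    number of distinct loci involved.
    """
    feat_track = Track(
        "features", [f.interval for f in filtered_features]
    )
    pairs = overlap_pairs(
        loci, feat_track, min_frac_query=min_frac, min_frac_target=min_frac,
        either_suffices=True, min_bp=1,
    )
    feat_class = {id(f.interval): f.rna_class for f in filtered_features}
    hit_features: dict[str, set] = {}
    hit_loci: dict[str, set] = {}
    key_of = {
        (f.interval.chrom, f.interval.start, f.interval.end, f.interval.name): f.rna_class
        for f in filtered_features
    }
    for p in pairs:
        t = p.target
        cls = key_of[(t.chrom, t.start, t.end, t.name)]
        hit_features.setdefault(cls, set()).add((t.chrom, t.start, t.end, t.name))
        hit_loci.setdefault(cls, set()).add(
            (p.query.chrom, p.query.start, p.query.end, p.query.name)
        )
    classes = sorted({f.rna_class for f in filtered_features})
    rows = []
    all_hit_feats: set = set()
    all_hit_loci: set = set()
    for cls in classes:
        n_filtered = sum(1 for f in filtered_features if f.rna_class == cls)
        feats = hit_features.get(cls, set())
        lcs = hit_loci.get(cls, set())
        all_hit_feats |= feats
        all_hit_loci |= lcs
        rows.append(
            {
                "rna_class": cls,
                "n_filtered": n_filtered,
                "n_overlapped": len(feats),
                "pct_overlapped": (
                    round_half_up(100.0 * len(feats) / n_filtered, 1)
                    if n_filtered
                    else float("nan")
                ),
                "n_crs": len(lcs),
            }
        )
    n_all = len(filtered_features)
    rows.append(
        {
            "rna_class": "All",
            "n_filtered": n_all,
            "n_overlapped": len(all_hit_feats),
            "pct_overlapped": (
                round_half_up(100.0 * len(all_hit_feats) / n_all, 1)
                if n_all
                else float("nan")
            ),
            "n_crs": len(all_hit_loci),
        }
    )
    return pd.DataFrame(rows)


def compare_screens(screens: Mapping[str, Track]) -> pd.DataFrame:
    """Pairwise overlap matrix between prediction screens.

    Cell (A, B) is the number of A predictions overlapping at least one B
    prediction by >=1 bp (asymmetric when prediction counts differ); the
    diagonal holds screen sizes.
    """
    if len(screens) < 2:
        raise ValueError("need at least two screens to compare")
    names = list(screens)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            if a == b:
                mat.loc[a, b] = len(screens[a])
                continue
            pairs = overlap_pairs(screens[a], screens[b], min_bp=1)
            hit = {
                (p.query.chrom, p.query.start, p.query.end, p.query.name)
                for p in pairs
            }
            mat.loc[a, b] = len(hit)
    return mat


def expected_overlap(sensitivity_a: float, sensitivity_b: float) -> float:
    """Expected overlap fraction of two independent surveys of one genome:
    the product of their sensitivities."""
    for s in (sensitivity_a, sensitivity_b):
        if not (0.0 <= s <= 1.0):
            raise ValueError("sensitivities must lie in [0, 1]")
    return sensitivity_a * sensitivity_b
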