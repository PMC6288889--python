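"""Tiling-array expression: the "expressed" predicate, boolean matrices, and
CRS-vs-expression association against sampled genomic windows.

A feature is *expressed* in an experiment when merged transcript regions of
that experiment cover at least half of the feature (a strict 100% variant is
used for fine-grained case studies). Expression states across ~80
experiments form a boolean feature x experiment matrix that every downstream
score (co-expression, stage specificity, differential expression) consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, Track, coverage_fraction, merge_track, overlap_pairs

__all__ = [
    "ExperimentMeta",
    "is_expressed",
    "build_matrix",
    "fisher_exact_greater",
    "expression_enrichment",
    "tile_windows",
]

STAGE_GROUPS = ("embryo", "larva", "prepupa", "adult", "cell_line")


@dataclass(frozen=True)
class ExperimentMeta:
    """Metadata of one tiling experiment."""

    experiment_id: str
    sample_class: str  # "cell_line" | "fly"
    strain: str
    stage_group: str  # one of STAGE_GROUPS
    rna_fraction: str = "total"  # total | polyA | nuclear
    compartment: str = ""

    def __post_init__(self) -> None:
        if self.stage_group not in STAGE_GROUPS:
            raise ValueError(f"unknown stage group {self.stage_group!r}")


def is_expressed(
    feature: GenomicInterval, experiment_regions: Track, min_frac: float = 0.5
) -> bool:
    """True when merged transcript regions cover >= ``min_frac`` of the feature."""
    return coverage_fraction(feature, experiment_regions) >= min_frac


def build_matrix(
    features: Sequence[GenomicInterval],
    experiment_tracks: Mapping[str, Track],
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Boolean expression matrix: rows = features (input order), columns =
    experiment ids (mapping order). Transcript regions are merged per
    experiment (gap 0) before coverage is computed; an experiment with an
    empty track yields an all-False column with a warning."""
    names = []
    seen = set()
    for f in features:
        if not f.name:
            raise ValueError("matrix features must carry names")
        if f.name in seen:
            raise ValueError(f"duplicate feature name {f.name!r}")
        seen.add(f.name)
        names.append(f.name)
    data = {}
    for exp_id, track in experiment_tracks.items():
        if len(track) == 0:
            warnings.warn(f"experiment {exp_id} has an empty transcript track")
            data[exp_id] = np.zeros(len(names), dtype=bool)
            continue
        merged = track if track.merged else merge_track(track, 0)
        data[exp_id] = np.fromiter(
            (is_expressed(f, merged, min_frac) for f in features),
            dtype=bool,
            count=len(names),
        )
    return pd.DataFrame(data, index=names)


def fisher_exact_greater(table):
    """One-sided (enrichment) Fisher exact p for a 2x2 table [[a,b],[c,d]].

    P(X >= a) under the hypergeometric null with the table's margins fixed;
    degenerate tables (an empty margin) return 1.0 with a warning. Cells may
    be equal-shape arrays, in which case an array of p-values is returned.
    """
    (a, b), (c, d) = table
    a = np.asarray(a)
    b = np.asarray(b)
    c = np.asarray(c)
    d = np.asarray(d)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("negative cell in contingency table")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    degenerate = (n == 0) | (r1 == 0) | (c1 == 0) | (r1 == n) | (c1 == n)
    if np.any(degenerate):
        warnings.warn("degenerate contingency table (empty margin); p = 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.hypergeom.sf(a - 1, np.maximum(n, 1), r1, c1)
    p = np.where(degenerate, 1.0, p)
    return float(p) if p.ndim == 0 else p


def tile_windows(chrom_sizes: Mapping[str, int], window: int = 100) -> Track:
    """Non-overlapping tiling of the genome into fixed-size windows.

    A trailing remainder shorter than ``window`` is dropped so all windows are
    the same size as the typical CRS they stand in for.
    """
    ivs = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for s in range(0, size - window + 1, window):
            ivs.append(GenomicInterval(chrom, s, s + window, ".", f"w:{chrom}:{s}"))
    return Track("windows", ivs)


def expression_enrichment(
    crs_loci: Track,
    chrom_sizes: Mapping[str, int],
    experiment_tracks: Mapping[str, Track],
    window: int = 100,
    n_replicates: int = 10,
    min_experiments: Sequence[int] = (1, 2, 3, 4),
    exclude_exonic: Track | None = None,
    n_windows: int | None = None,
    seed: int = 0,
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Association of CRS overlap with expression among sampled windows.

    The genome is tiled into ``window``-bp windows; per replicate, as many
    windows as there are CRS loci (or ``n_windows``) are sampled without
    replacement using a sub-seed, and a 2x2 table is built: window expressed
    in >= k experiments (rows) x window overlapping a CRS by >=50% of the
    CRS-or-window size (columns). The reported p per k is the *maximum*
    one-sided Fisher p over the replicates (the conservative summary).
    ``exclude_exonic`` removes windows and CRSs touching the given exon track
    by >=1 bp before analysis.
    """
    windows = tile_windows(chrom_sizes, window)
    loci = crs_loci
    if exclude_exonic is not None:
        ex = exclude_exonic if exclude_exonic.merged else merge_track(exclude_exonic, 0)
        windows = Track(
            windows.name,
            [w for w in windows if coverage_fraction(w, ex) == 0.0],
        )
        loci = Track(
            loci.name,
            [l for l in loci if coverage_fraction(l, ex) == 0.0],
            merged=loci.merged,
        )
    merged_exps = {
        e: (t if t.merged else merge_track(t, 0)) for e, t in experiment_tracks.items()
    }
    sample_size = n_windows if n_windows is not None else len(loci)
    if sample_size > len(windows):
        raise ValueError(
            f"cannot sample {sample_size} windows from {len(windows)} available"
        )
    loci_track_merged = Track(loci.name, list(loci.intervals), merged=True)

    # Per-window statistics are sample-independent: compute them once.
    win_list = windows.intervals
    n_expr = np.zeros(len(win_list), dtype=int)
    for t in merged_exps.values():
        n_expr += np.fromiter(
            (is_expressed(w, t, min_frac) for w in win_list), dtype=int,
            count=len(win_list),
        )
    crs_hits = overlap_pairs(
        windows, loci_track_merged,
        min_frac_query=min_frac, min_frac_target=min_frac,
        either_suffices=True, min_bp=1,
    )
    hit_names = {p.query.name for p in crs_hits}
    has_crs = np.fromiter(
        (w.name in hit_names for w in win_list), dtype=bool, count=len(win_list)
    )

    rows = []
    root = np.random.SeedSequence(seed)
    for k in min_experiments:
        rep_seeds = root.spawn(n_replicates)  # fresh sub-seeds per k
        worst_p = 0.0
        for ss in rep_seeds:
            rng = np.random.default_rng(ss)
            idx = rng.choice(len(win_list), size=sample_size, replace=False)
            expressed = n_expr[idx] >= k
            crs = has_crs[idx]
            a = int(np.sum(expressed & crs))
            b = int(np.sum(expressed & ~crs))
            c = int(np.sum(~expressed & crs))
            d = int(np.sum(~expressed & ~crs))
            p = fisher_exact_greater([[a, b], [c, d]])
            worst_p = max(worst_p, p)
        rows.append(
            {
                "min_experiments": k,
                "filtered": exclude_exonic is not None,
                "max_p": worst_p,
                "n_windows": sample_size,
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
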