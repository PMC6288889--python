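"""Screen-side filtering and binned false-discovery-rate estimation.

Covariance-model screens over genome alignments produce motif predictions on
the native alignment and on a composition-preserving shuffled companion. The
shuffled screen carries no conserved-structure signal, so within a bin of
comparable (GC content, sequence identity) the FDR among native predictions
above a score cutoff is estimated as

    FDR = (# shuffled predictions above cutoff) / (# native predictions above cutoff)

capped at 1. High-confidence motifs are then those with pscore above the
selection cutoff whose bin FDR is at or below the FDR ceiling.

Motif tables are pandas DataFrames with columns
``id, chrom, start, end, strand, pscore, energy, gc, identity, n_species,
source`` (``source`` in {native, shuffled}); block metadata tables carry
``chrom, start, end, n_species, gc, identity``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Track, coverage_fraction, merge_track

logger = logging.getLogger(__name__)

__all__ = [
    "MOTIF_COLUMNS",
    "filter_input_blocks",
    "filter_pscore",
    "filter_repeat_overlap",
    "BinGrid",
    "build_bins",
    "FdrTable",
    "estimate_fdr",
    "select_crs_motifs",
    "motif_track",
]

MOTIF_COLUMNS = [
    "id", "chrom", "start", "end", "strand", "pscore", "energy",
    "gc", "identity", "n_species", "source",
]

MIN_BLOCK_LEN = 50
MIN_BLOCK_SPECIES = 3
MIN_MOTIF_LEN = 30


def filter_input_blocks(
    blocks: pd.DataFrame,
    min_length: int = MIN_BLOCK_LEN,
    min_species: int = MIN_BLOCK_SPECIES,
) -> pd.DataFrame:
    """Drop alignment blocks shorter than 50 bp or with fewer than 3 species
    (both boundaries inclusive for retention)."""
    length = blocks["end"] - blocks["start"]
    keep = (length >= min_length) & (blocks["n_species"] >= min_species)
    return blocks.loc[keep].reset_index(drop=True)


def filter_pscore(motifs: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Keep motifs with pscore strictly greater than *cutoff*."""
    return motifs.loc[motifs["pscore"] > cutoff].reset_index(drop=True)


def motif_track(motifs: pd.DataFrame, name: str = "motifs") -> Track:
    """View a motif table as a Track of named intervals."""
    ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.id)
        for r in motifs.itertuples(index=False)
    ]
    return Track(name, ivs)


def filter_repeat_overlap(
    motifs: pd.DataFrame, repeats: Track, max_frac: float = 0.5
) -> tuple[pd.DataFrame, int]:
    """Remove motifs covered by annotated repeats by >= half their length.

    Returns (retained motifs, number removed). Repeat-dominated predictions
    are unreliable because the underlying alignments are.
    """
    merged = repeats if repeats.merged else merge_track(repeats, 0)
    keep_mask = []
    for r in motifs.itertuples(index=False):
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.id)
        keep_mask.append(coverage_fraction(iv, merged) < max_frac)
    keep = pd.Series(keep_mask, index=motifs.index)
    removed = int((~keep).sum())
    return motifs.loc[keep].reset_index(drop=True), removed


@dataclass(frozen=True)
class BinGrid:
    """Marginal-quantile bin edges over GC content and sequence identity.

    Edges are strictly increasing and span the data range; a (gc, identity)
    pair maps to exactly one bin, with out-of-range values clamped to the
    edge bins.
    """

    gc_edges: np.ndarray
    identity_edges: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.gc_edges) - 1, len(self.identity_edges) - 1

    def assign(self, gc, identity) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized bin indices (gc_bin, identity_bin), clamped to range."""
        gi = np.clip(
            np.searchsorted(self.gc_edges, np.asarray(gc), side="right") - 1,
            0, self.shape[0] - 1,
        )
        ii = np.clip(
            np.searchsorted(self.identity_edges, np.asarray(identity), side="right") - 1,
            0, self.shape[1] - 1,
        )
        return gi, ii


def _quantile_edges(values: np.ndarray, n_bins: int, label: str) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(values, qs))
    if len(edges) < 2:
        warnings.warn(
            f"all motifs share one {label} value; using a single degenerate bin"
        )
        edges = np.array([edges[0], edges[0] + 1e-9])
    elif len(edges) < n_bins + 1:
        warnings.warn(
            f"quantile ties reduce {label} bins from {n_bins} to {len(edges) - 1}"
        )
    return edges


def build_bins(
    native_motifs: pd.DataFrame, n_gc_bins: int = 8, n_identity_bins: int = 8
) -> BinGrid:
    """Marginal-quantile grid on the native motifs' GC and identity.

    Each marginal bin then holds a comparable number of native motifs (up to
    quantile-tie slack). Shuffled motifs and alignment blocks are mapped onto
    the same edges downstream.
    """
    if len(native_motifs) < n_gc_bins * n_identity_bins:
        raise ValueError(
            f"{len(native_motifs)} motifs cannot support a "
            f"{n_gc_bins}x{n_identity_bins} grid; use fewer bins"
        )
    return BinGrid(
        _quantile_edges(native_motifs["gc"].to_numpy(), n_gc_bins, "GC"),
        _quantile_edges(native_motifs["identity"].to_numpy(), n_identity_bins, "identity"),
    )


@dataclass
class FdrTable:
    """Per (gc_bin, identity_bin, pscore_cutoff) native/shuffled counts and
    FDR estimates, plus per-bin MAF-block counts for the reliability note
    (bins backed by fewer than 100 blocks are flagged)."""

    table: pd.DataFrame  # gc_bin, id_bin, cutoff, native, shuffled, fdr, n_blocks
    grid: BinGrid
    min_reliable_blocks: int = 100

    def lookup(self, gc_bin: int, id_bin: int, cutoff: float) -> float:
        sel = self.table[
            (self.table.gc_bin == gc_bin)
            & (self.table.id_bin == id_bin)
            & (self.table.cutoff == cutoff)
        ]
        if sel.empty:
            raise KeyError(f"no FDR cell for bin ({gc_bin},{id_bin}) cutoff {cutoff}")
        return float(sel["fdr"].iloc[0])


def estimate_fdr(
    native_motifs: pd.DataFrame,
    shuffled_motifs: pd.DataFrame,
    blocks: pd.DataFrame,
    grid: BinGrid,
    pscore_cutoffs=tuple(range(50, 151, 10)),
) -> FdrTable:
    """Tabulate shuffled/native counts per bin per cutoff (strict > pscore).

    The estimate is capped at 1; bins with zero native predictions above a
    cutoff yield NaN (undefined) and are excluded from selection downstream.
    """
    cutoffs = sorted(pscore_cutoffs)
    if len(native_motifs) == 0:
        warnings.warn("empty native motif set: FDR table is all-undefined")
    n_gc, n_id = grid.shape
    bg, bi = grid.assign(blocks["gc"].to_numpy(), blocks["identity"].to_numpy()) if len(blocks) else (np.array([], int), np.array([], int))
    block_counts = np.zeros((n_gc, n_id), dtype=int)
    np.add.at(block_counts, (bg, bi), 1)

    def _counts(motifs: pd.DataFrame, cutoff: float) -> np.ndarray:
        out = np.zeros((n_gc, n_id), dtype=int)
        if len(motifs) == 0:
            return out
        sel = motifs[motifs["pscore"] > cutoff]
        if len(sel):
            g, i = grid.assign(sel["gc"].to_numpy(), sel["identity"].to_numpy())
            np.add.at(out, (g, i), 1)
        return out

    rows = []
    for cutoff in cutoffs:
        nat = _counts(native_motifs, cutoff)
        shuf = _counts(shuffled_motifs, cutoff)
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.minimum(1.0, shuf / nat)
        fdr[nat == 0] = np.nan
        for g in range(n_gc):
            for i in range(n_id):
                rows.append(
                    {
                        "gc_bin": g,
                        "id_bin": i,
                        "cutoff": cutoff,
                        "native": int(nat[g, i]),
                        "shuffled": int(shuf[g, i]),
                        "fdr": fdr[g, i],
                        "n_blocks": int(block_counts[g, i]),
                    }
                )
    table = pd.DataFrame(rows)
    low = table[table.n_blocks < 100][["gc_bin", "id_bin"]].drop_duplicates()
    if len(low):
        logger.info("%d bins backed by <100 MAF blocks (low reliability)", len(low))
    return FdrTable(table, grid)


def select_crs_motifs(
    motifs: pd.DataFrame,
    fdr_table: FdrTable,
    pscore_min: float = 80.0,
    fdr_max: float = 0.1,
) -> pd.DataFrame:
    """High-confidence motifs: pscore > ``pscore_min`` and bin FDR <= ``fdr_max``.

    Each retained motif carries the FDR of its (bin, cutoff) cell in an
    ``fdr`` column plus its ``gc_bin``/``id_bin``. Motifs falling in bins with
    undefined FDR are excluded (conservative) and their number logged.
    """
    sub = fdr_table.table[fdr_table.table.cutoff == pscore_min]
    if sub.empty:
        raise KeyError(f"FDR table holds no cutoff {pscore_min}")
    fdr_grid = np.full(fdr_table.grid.shape, np.nan)
    for r in sub.itertuples(index=False):
        fdr_grid[r.gc_bin, r.id_bin] = r.fdr
    g, i = fdr_table.grid.assign(motifs["gc"].to_numpy(), motifs["identity"].to_numpy())
    out = motifs.copy()
    out["gc_bin"] = g
    out["id_bin"] = i
    out["fdr"] = fdr_grid[g, i]
    passed_pscore = out["pscore"] > pscore_min
    undefined = out["fdr"].isna() & passed_pscore
    if int(undefined.sum()):
        logger.info(
            "%d motifs above pscore cutoff fall in undefined-FDR bins; excluded",
            int(undefined.sum()),
        )
    keep = passed_pscore & (out["fdr"] <= fdr_max)
    return out.loc[keep].reset_index(drop=True)
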