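"""Input filters, bin construction and FDR estimation."""

import numpy as np
import pandas as pd
import pytest

from crspipe.filtering import (
    BinGrid,
    build_bins,
    estimate_fdr,
    filter_input_blocks,
    filter_pscore,
    filter_repeat_overlap,
    select_crs_motifs,
)
from crspipe.intervals import GenomicInterval, Track, merge_track


def motif_df(rows):
    base = dict(id="m", chrom="c", start=0, end=60, strand="+", pscore=90.0,
                energy=-10.0, gc=0.4, identity=0.6, n_species=10, source="native")
    return pd.DataFrame([{**base, "id": f"m{i}", **r} for i, r in enumerate(rows)])


class TestInputFilters:
    def test_block_length_and_species_boundaries(self):
        blocks = pd.DataFrame(
            {
                "chrom": ["c"] * 4,
                "start": [0, 0, 0, 0],
                "end": [49, 50, 100, 100],
                "n_species": [5, 3, 2, 3],
                "gc": [0.4] * 4,
                "identity": [0.6] * 4,
            }
        )
        kept = filter_input_blocks(blocks)
        assert list(kept["end"]) == [50, 100] and list(kept["n_species"]) == [3, 3]

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "n_species", "gc", "identity"])
        assert len(filter_input_blocks(empty)) == 0

    def test_pscore_strictly_greater(self):
        m = motif_df([{"pscore": 50.0}, {"pscore": 50.0001}, {"pscore": 80.01}])
        assert list(filter_pscore(m, 50)["pscore"]) == [50.0001, 80.01]
        assert len(filter_pscore(m, float("-inf"))) == 3

    def test_repeat_overlap_half_rule(self):
        m = motif_df([
            {"start": 0, "end": 60},    # 30/60 covered -> removed
            {"start": 100, "end": 160},  # 29/60 covered -> kept
            {"start": 300, "end": 360},  # untouched
        ])
        repeats = merge_track(
            Track("r", [GenomicInterval("c", 30, 60), GenomicInterval("c", 131, 160)]), 0
        )
        kept, removed = filter_repeat_overlap(m, repeats)
        assert removed == 1
        assert list(kept["start"]) == [100, 300]

    def test_no_repeats_keeps_all(self):
        m = motif_df([{}, {}])
        kept, removed = filter_repeat_overlap(m, merge_track(Track("r", []), 0))
        assert removed == 0 and len(kept) == 2


class TestBins:
    def test_quartile_edges_on_uniform_values(self):
        vals = np.linspace(0.0, 1.0, 101)
        m = motif_df([{"gc": v, "identity": v} for v in vals])
        grid = build_bins(m, 4, 4)
        assert np.allclose(grid.gc_edges, [0.0, 0.25, 0.5, 0.75, 1.0])
        g, i = grid.assign(m["gc"], m["identity"])
        counts = np.bincount(g, minlength=4)
        assert counts.max() - counts.min() <= 1

    def test_degenerate_single_value_warns(self):
        m = motif_df([{"gc": 0.4, "identity": v} for v in np.linspace(0, 1, 30)])
        with pytest.warns(UserWarning, match="GC"):
            grid = build_bins(m, 4, 2)
        assert grid.shape[0] == 1

    def test_too_few_motifs_is_an_error(self):
        m = motif_df([{}] * 10)
        with pytest.raises(ValueError, match="fewer bins"):
            build_bins(m, 8, 8)

    def test_balanced_bins_on_generated_data(self, screen):
        _, motifs, _ = screen
        native = motifs[motifs.source == "native"]
        grid = build_bins(native, 8, 8)
        g, i = grid.assign(native["gc"], native["identity"])
        for axis_counts in (np.bincount(g, minlength=8), np.bincount(i, minlength=8)):
            assert axis_counts.max() / max(axis_counts.min(), 1) <= 1.5

    def test_out_of_range_values_clamped(self):
        grid = BinGrid(np.array([0.2, 0.4, 0.6]), np.array([0.3, 0.5, 0.7]))
        g, i = grid.assign([0.0, 0.99], [0.0, 0.99])
        assert list(g) == [0, 1] and list(i) == [0, 1]


def single_bin_grid():
    return BinGrid(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestEstimateFdr:
    def blocks(self, n=150):
        return pd.DataFrame(
            {"chrom": "c", "start": range(n), "end": [s + 100 for s in range(n)],
             "n_species": 10, "gc": 0.4, "identity": 0.6}
        )

    def counts_case(self, native_n, shuffled_n):
        native = motif_df([{"pscore": 90.0}] * native_n)
        shuffled = motif_df([{"pscore": 90.0, "source": "shuffled"}] * shuffled_n)
        return estimate_fdr(native, shuffled, self.blocks(), single_bin_grid(), [80])

    def test_rfam_region_ratio_below_twelve_percent(self):
        table = self.counts_case(76, 9)
        fdr = table.lookup(0, 0, 80)
        assert fdr == pytest.approx(9 / 76)
        assert fdr < 0.12

    def test_zero_shuffled_gives_zero(self):
        assert self.counts_case(50, 0).lookup(0, 0, 80) == 0.0

    def test_capped_at_one(self):
        assert self.counts_case(100, 120).lookup(0, 0, 80) == 1.0

    def test_zero_native_is_undefined(self):
        table = self.counts_case(0, 5)
        assert np.isnan(table.lookup(0, 0, 80))

    def test_permutation_invariance_and_counting_oracle(self, screen, rng):
        blocks, motifs, _ = screen
        native = motifs[motifs.source == "native"].reset_index(drop=True)
        shuffled = motifs[motifs.source == "shuffled"].reset_index(drop=True)
        grid = build_bins(native, 3, 3)
        cutoffs = [60, 80, 100]
        t1 = estimate_fdr(native, shuffled, blocks, grid, cutoffs)
        shuffled_rows = native.sample(frac=1.0, random_state=3).reset_index(drop=True)
        t2 = estimate_fdr(shuffled_rows, shuffled, blocks, grid, cutoffs)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        # direct-count oracle on a few cells
        for _, row in t1.table.sample(10, random_state=1).iterrows():
            for df, col in ((native, "native"), (shuffled, "shuffled")):
                g, i = grid.assign(df["gc"], df["identity"])
                n = int(np.sum((g == row.gc_bin) & (i == row.id_bin)
                               & (df["pscore"].to_numpy() > row.cutoff)))
                assert n == row[col]


class TestSelect:
    def test_selection_gates_and_annotation(self):
        native = motif_df([
            {"pscore": 90.0, "gc": 0.2},   # low-FDR bin -> kept
            {"pscore": 79.0, "gc": 0.2},   # fails pscore gate
            {"pscore": 90.0, "gc": 0.8},   # high-FDR bin -> dropped
        ])
        shuffled_low = motif_df([{"pscore": 90.0, "gc": 0.2, "source": "shuffled"}] * 1)
        shuffled_high = motif_df([{"pscore": 90.0, "gc": 0.8, "source": "shuffled"}] * 9)
        native_pad = motif_df([{"pscore": 90.0, "gc": 0.2}] * 12
                              + [{"pscore": 90.0, "gc": 0.8}] * 12)
        grid = BinGrid(np.array([0.0, 0.5, 1.0]), np.array([0.0, 1.0]))
        blocks = pd.DataFrame({"chrom": "c", "start": [0], "end": [100],
                               "n_species": 10, "gc": 0.2, "identity": 0.6})
        table = estimate_fdr(
            pd.concat([native, native_pad], ignore_index=True),
            pd.concat([shuffled_low, shuffled_high], ignore_index=True),
            blocks, grid, [80],
        )
        selected = select_crs_motifs(native, table, pscore_min=80, fdr_max=0.1)
        assert list(selected["id"]) == ["m0"]
        assert selected["fdr"].iloc[0] == pytest.approx(1 / 13)
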