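import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from crspipe.simulate import (
    BlockConfig,
    ExpressionConfig,
    GenomeConfig,
    MotifConfig,
    SimulationConfig,
    generate_block_and_motif_sets,
    generate_genome,
)


def small_config(seed: int = 11) -> SimulationConfig:
    """A fast, fully featured simulation used across the suite."""
    return SimulationConfig(
        seed=seed,
        genome=GenomeConfig(n_chroms=2, chrom_length=120_000, n_genes=24,
                            n_ncrna_features=20),
        blocks=BlockConfig(),
        motifs=MotifConfig(),
        expression=ExpressionConfig(
            n_experiments=20,
            group_sizes={"embryo": 8, "larva": 3, "prepupa": 2, "adult": 3,
                         "cell_line": 4},
        ),
    )


@pytest.fixture(scope="session")
def sim_config():
    return small_config()


@pytest.fixture(scope="session")
def genome(sim_config):
    return generate_genome(sim_config)


@pytest.fixture(scope="session")
def screen(sim_config, genome):
    """(blocks, motifs, truth) of the small simulation."""
    return generate_block_and_motif_sets(sim_config, genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def brute_force_covered(query, targets) -> int:
    """Per-base oracle: covered bases of query by any target interval."""
    return sum(
        1
        for pos in range(query.start, query.end)
        if any(
            t.chrom == query.chrom and t.start <= pos < t.end for t in targets
        )
    )


def brute_force_merge(intervals, max_gap):
    """Per-base oracle for gap-merging: paint, dilate by max_gap, re-segment.

    Two intervals belong to one merged interval iff chained by gaps <= max_gap,
    which equals connectivity after extending each interval by max_gap to the
    right.
    """
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom, ivs in sorted(by_chrom.items()):
        hi = max(i.end for i in ivs) + max_gap + 2
        paint = np.zeros(hi, dtype=bool)
        for i in ivs:
            paint[i.start : i.end + max_gap] = True
        pos = 0
        while pos < hi:
            if paint[pos]:
                s = pos
                while pos < hi and paint[pos]:
                    pos += 1
                # trim the dilation tail: the true end is the max member end
                members_end = max(i.end for i in ivs if s <= i.start < pos)
                out.append((chrom, s, members_end))
            else:
                pos += 1
    return out
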