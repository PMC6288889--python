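"""Stage- and cell-line-specific expression of CRS-containing biotypes, and
pairwise differential-expression scoring.

Instances of a biotype (introns, 5'-UTR exons, snoRNAs, ...) are split into
a CRS-containing and a CRS-free stratum. For experiment l the stratum ratio

    R(B, l) = N(B, l) / sum_{m != l} N(B, m)

normalizes the count expressed in l by the expression mass in all other
experiments, and the ratio difference R_d = R_CRS - R_notCRS asks whether
structured instances favour that experiment. Significance compares the
observed R_CRS against the sample of non-CRS ratios over all experiments
(one-sided t-test for coding-exon and 5'-UTR biotypes, Wilcoxon signed-rank
otherwise), Bonferroni-adjusted over all tests performed.

The differential-expression score between experiments i and j is

    E_diff(i, j) = D_H(CRS) * |D_H(CRS) - D_H(notCRS)|

with D_H the length-normalized Hamming distance between the stratum's
boolean expression columns in i and j.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import BinGrid
from .intervals import GenomicInterval, Track
from .io import GeneModel

__all__ = [
    "BiotypeInstance",
    "filter_instances",
    "ratio_difference",
    "test_ratio_difference",
    "stage_enrichment_table",
    "intergenic_window_ratios",
    "diff_expression_score",
    "diff_expression_matrix",
    "find_independent_introns",
]

T_TEST_BIOTYPES = frozenset({"coding_exon", "utr5_exon"})


@dataclass
class BiotypeInstance:
    """One annotated feature with its CRS-containment flag and expression
    vector (boolean over experiments, fixed order)."""

    instance_id: str
    biotype: str
    interval: GenomicInterval
    has_crs: bool
    expression: np.ndarray  # bool per experiment

    @property
    def n_expressed(self) -> int:
        return int(np.asarray(self.expression, dtype=bool).sum())


def filter_instances(
    instances: Sequence[BiotypeInstance],
    blocks: Track | None = None,
    min_expressed: int = 3,
    min_block_frac: float = 0.5,
) -> list[BiotypeInstance]:
    """Analysis inclusion filter: expressed in >= 3 experiments and, when a
    block track is given, lying within the screen's input alignments by >=
    half the feature size."""
    from .intervals import coverage_fraction, merge_track

    mb = None
    if blocks is not None:
        mb = blocks if blocks.merged else merge_track(blocks, 0)
    out = []
    for inst in instances:
        if inst.n_expressed < min_expressed:
            continue
        if mb is not None and coverage_fraction(inst.interval, mb) < min_block_frac:
            continue
        out.append(inst)
    return out


def _stratum_ratio(
    mat: np.ndarray, exp_index: int, denominator: str = "share"
) -> float:
    """R(B, l) for one stratum's boolean matrix (instances x experiments).

    ``denominator="share"``: sum over other experiments of per-experiment
    expressed counts. ``denominator="any"``: number of instances expressed in
    at least one other experiment. NaN when the denominator is zero.
    """
    num = int(mat[:, exp_index].sum())
    others = np.delete(mat, exp_index, axis=1)
    if denominator == "share":
        den = int(others.sum())
    elif denominator == "any":
        den = int(others.any(axis=1).sum())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return num / den if den > 0 else float("nan")


def ratio_difference(
    instances: Sequence[BiotypeInstance],
    exp_index: int,
    denominator: str = "share",
) -> tuple[float, float, float]:
    """(R_CRS, R_notCRS, R_d) of one biotype at one experiment.

    Instances must already satisfy the inclusion filter. NaN components make
    R_d NaN; callers exclude those cells from testing.
    """
    crs = np.array([i.expression for i in instances if i.has_crs], dtype=bool)
    non = np.array([i.expression for i in instances if not i.has_crs], dtype=bool)
    r_crs = _stratum_ratio(crs, exp_index, denominator) if crs.size else float("nan")
    r_non = _stratum_ratio(non, exp_index, denominator) if non.size else float("nan")
    return r_crs, r_non, r_crs - r_non


def test_ratio_difference(
    r_crs: float,
    non_crs_ratios: Sequence[float],
    biotype: str,
    n_tests: int = 1,
) -> tuple[float, float, str, str]:
    """(raw p, Bonferroni p, test name, alternative) for one (biotype, exp).

    One-sample location test of the non-CRS ratio sample against the observed
    R_CRS: Student's t for biotypes with near-normal non-CRS ratios (coding
    exons, 5'-UTR exons), Wilcoxon signed-rank otherwise. The alternative is
    'less' when R_d > 0 (the non-CRS sample sits below R_CRS) and 'greater'
    when R_d < 0. A constant sample under the t-test falls back to a sign
    test, flagged in the test name.
    """
    x = np.asarray([v for v in non_crs_ratios if not math.isnan(v)], dtype=float)
    if len(x) < 2:
        raise ValueError("need >=2 non-CRS ratios to test")
    r_d = r_crs - float(np.mean(x))
    alternative = "less" if r_d > 0 else "greater"
    use_t = biotype in T_TEST_BIOTYPES
    if use_t and np.ptp(x) == 0.0:
        # degenerate for t; sign test on the (constant) differences
        diffs = x - r_crs
        k = int((diffs < 0).sum()) if alternative == "less" else int((diffs > 0).sum())
        p = float(stats.binom.sf(k - 1, len(x), 0.5)) if k else 1.0
        return p, min(1.0, p * n_tests), "sign(fallback)", alternative
    if use_t:
        p = float(stats.ttest_1samp(x, popmean=r_crs, alternative=alternative).pvalue)
        test = "t"
    else:
        d = x - r_crs
        if np.all(d == 0):
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.wilcoxon(d, alternative=alternative).pvalue)
        test = "wilcoxon"
    return p, min(1.0, p * n_tests), test, alternative


def stage_enrichment_table(
    instances_by_biotype: Mapping[str, Sequence[BiotypeInstance]],
    experiment_ids: Sequence[str],
    denominator: str = "share",
    alpha_adjust: bool = True,
) -> pd.DataFrame:
    """R_CRS / R_notCRS / R_d with adjusted p per (biotype, experiment).

    Bonferroni multiplies by the number of tests actually performed (cells
    with defined ratios and a testable non-CRS sample).
    """
    cells = []
    for biotype, insts in instances_by_biotype.items():
        insts = list(insts)
        if not insts:
            continue
        non = [i for i in insts if not i.has_crs]
        non_mat = np.array([i.expression for i in non], dtype=bool)
        non_ratios = [
            _stratum_ratio(non_mat, l, denominator) if non_mat.size else float("nan")
            for l in range(len(experiment_ids))
        ]
        for l, exp_id in enumerate(experiment_ids):
            r_crs, r_non, r_d = ratio_difference(insts, l, denominator)
            testable = (
                not math.isnan(r_crs)
                and sum(1 for v in non_ratios if not math.isnan(v)) >= 2
            )
            cells.append(
                {
                    "biotype": biotype, "experiment": exp_id, "exp_index": l,
                    "R_CRS": r_crs, "R_notCRS": r_non, "R_d": r_d,
                    "testable": testable, "_non_ratios": non_ratios,
                }
            )
    n_tests = sum(1 for c in cells if c["testable"]) if alpha_adjust else 1
    rows = []
    for c in cells:
        if c["testable"]:
            p, p_adj, test, alt = test_ratio_difference(
                c["R_CRS"], c["_non_ratios"], c["biotype"], n_tests=max(n_tests, 1)
            )
        else:
            p, p_adj, test, alt = float("nan"), float("nan"), "none", ""
        rows.append(
            {
                "biotype": c["biotype"], "experiment": c["experiment"],
                "R_CRS": c["R_CRS"], "R_notCRS": c["R_notCRS"], "R_d": c["R_d"],
                "p": p, "p_adj": p_adj, "test": test, "alternative": alt,
            }
        )
    return pd.DataFrame(rows)


def intergenic_window_ratios(
    windows: pd.DataFrame,
    grid: BinGrid,
    crs_bin_counts: Mapping[tuple[int, int], int],
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified sample of 100-bp intergenic windows matched per (GC,
    identity) bin to the CRS counts in that bin.

    ``windows`` needs columns chrom, start, end, gc, identity (GC/identity
    inherited from the overlapping alignment block). Bins with fewer windows
    than requested contribute all their windows, with a warning.
    """
    g, i = grid.assign(windows["gc"].to_numpy(), windows["identity"].to_numpy())
    windows = windows.assign(gc_bin=g, id_bin=i)
    rng = np.random.default_rng(seed)
    parts = []
    for (gb, ib), want in sorted(crs_bin_counts.items()):
        if want <= 0:
            continue
        pool = windows[(windows.gc_bin == gb) & (windows.id_bin == ib)]
        if len(pool) < want:
            warnings.warn(
                f"bin ({gb},{ib}): only {len(pool)} windows for {want} CRSs; "
                "sampling all"
            )
            parts.append(pool)
            continue
        idx = rng.choice(len(pool), size=want, replace=False)
        parts.append(pool.iloc[np.sort(idx)])
    if not parts:
        return windows.iloc[0:0]
    return pd.concat(parts, ignore_index=True)


def diff_expression_score(
    crs_mat: np.ndarray, non_mat: np.ndarray, i: int, j: int
) -> float:
    """E_diff(i, j) for one biotype from the two strata's boolean matrices.

    D_H is the fraction of instances whose expressed flag differs between
    experiments i and j. An empty stratum yields NaN (undefined).
    """
    if crs_mat.size == 0 or non_mat.size == 0:
        return float("nan")
    d_crs = float(np.mean(crs_mat[:, i] != crs_mat[:, j]))
    d_non = float(np.mean(non_mat[:, i] != non_mat[:, j]))
    return d_crs * abs(d_crs - d_non)


def diff_expression_matrix(
    instances: Sequence[BiotypeInstance], n_experiments: int
) -> np.ndarray:
    """Symmetric zero-diagonal experiments x experiments E_diff matrix."""
    crs = np.array([x.expression for x in instances if x.has_crs], dtype=bool)
    non = np.array([x.expression for x in instances if not x.has_crs], dtype=bool)
    out = np.zeros((n_experiments, n_experiments))
    if crs.size == 0 or non.size == 0:
        out[:] = np.nan
        np.fill_diagonal(out, 0.0)
        return out
    for i in range(n_experiments):
        for j in range(i + 1, n_experiments):
            v = diff_expression_score(crs, non, i, j)
            out[i, j] = out[j, i] = v
    return out


def find_independent_introns(
    intron_instances: Sequence[BiotypeInstance],
    gene_models: Mapping[str, GeneModel],
    intron_gene: Mapping[str, str],
    exon_expression: Mapping[str, np.ndarray],
    exp_index: int,
) -> tuple[list[str], list[str]]:
    """Introns expressed independently of their host gene in one experiment.

    Tier 1: the intron is expressed while both directly flanking exons are
    not (gene-edge introns are evaluated on the available flank(s), flagged
    by inclusion). Tier 2: the intron is expressed while no exon of the
    parent gene is. The tiers use different predicates (flanking vs any
    exon), so neither is a subset of the other by construction.
    ``exon_expression`` maps exon names (``<gene>:exon<k>``) to boolean
    vectors.
    """
    tier1: list[str] = []
    tier2: list[str] = []
    for inst in intron_instances:
        if not bool(np.asarray(inst.expression, dtype=bool)[exp_index]):
            continue
        gid = intron_gene[inst.instance_id]
        gene = gene_models[gid]
        # left flank = last exon ending at/before the intron; right flank =
        # first exon starting at/after it (gene-edge introns may lack one)
        lefts = [
            f"{gid}:exon{k}"
            for k, ex in enumerate(gene.exons)
            if ex.end <= inst.interval.start
        ]
        rights = [
            f"{gid}:exon{k}"
            for k, ex in enumerate(gene.exons)
            if ex.start >= inst.interval.end
        ]
        flanks = ([lefts[-1]] if lefts else []) + ([rights[0]] if rights else [])
        flank_expr = [
            bool(np.asarray(exon_expression[f], dtype=bool)[exp_index])
            for f in flanks
            if f in exon_expression
        ]
        if flank_expr and not any(flank_expr):
            tier1.append(inst.instance_id)
        all_exons = [
            f"{gid}:exon{k}" for k in range(len(gene.exons))
        ]
        any_exon_expr = any(
            bool(np.asarray(exon_expression[f], dtype=bool)[exp_index])
            for f in all_exons
            if f in exon_expression
        )
        if not any_exon_expr:
            tier2.append(inst.instance_id)
    return tier1, tier2
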