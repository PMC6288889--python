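"""Co-expression of intergenic CRS loci with their closest gene element, and
synteny of the CRS-gene arrangement across related species.

The co-expression score compares how often the CRS and its closest annotated
gene element (UTR or ncRNA exon) are expressed together versus apart:

    E_co = E_cg / E_c  -  E_gnc / E_nc

where E_cg counts experiments expressing both, E_c those expressing the CRS,
E_gnc those expressing the gene element but not the CRS, and E_nc those not
expressing the CRS. +1 is perfect positive co-expression (the gene element
is expressed exactly when the CRS is), -1 perfect negative (they are only
expressed apart, and the gene fills every CRS-free experiment), 0
independence. Only CRSs expressed in at least 3 experiments are scored.

Synteny asks whether the CRS-gene adjacency is conserved: per species the
ortholog of the focal closest gene is checked for (a) still being the
closest gene, (b) lying on the same side of the CRS, and (c) same side
within a maximal distance; each criterion passes overall when satisfied in
at least a required fraction (default 2/3) of species with data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, Track, closest_features

__all__ = [
    "coexpression_score",
    "CoexpressionRecord",
    "compute_coexpression",
    "SyntenyVerdict",
    "synteny_tests",
]


def coexpression_score(e_cg: int, e_c: int, e_gnc: int, e_nc: int) -> float:
    """Eq. E_co = E_cg/E_c - E_gnc/E_nc; Ratio2 := 0 when E_nc = 0.

    A CRS expressed in every experiment has no CRS-free experiment in which
    the gene could appear alone, so Ratio2 measures nothing and is taken as 0.
    """
    if min(e_cg, e_c, e_gnc, e_nc) < 0:
        raise ValueError("experiment counts must be non-negative")
    if e_c == 0:
        raise ValueError("E_c = 0: score undefined (caller filters at >=3)")
    if e_cg > e_c or e_gnc > e_nc:
        raise ValueError("joint counts cannot exceed their marginals")
    ratio2 = e_gnc / e_nc if e_nc > 0 else 0.0
    return e_cg / e_c - ratio2


@dataclass
class CoexpressionRecord:
    crs_id: str
    element_id: str  # closest gene element (UTR or ncRNA exon)
    gene_id: str
    distance: int
    e_cg: int
    e_c: int
    e_gnc: int
    e_nc: int
    score: float
    coexpr_class: str  # positive | negative | independent
    tied: bool = False
    status: str = "ok"  # or "no_neighbor"


def _classify(score: float, pos_cut: float, neg_cut: float) -> str:
    if score >= pos_cut:
        return "positive"
    if score <= neg_cut:
        return "negative"
    return "independent"


def compute_coexpression(
    intergenic_loci: Track,
    gene_elements: Track,
    matrix: pd.DataFrame,
    element_gene: Mapping[str, str] | None = None,
    min_expr: int = 3,
    pos_cut: float = 0.5,
    neg_cut: float = -0.5,
) -> list[CoexpressionRecord]:
    """Score every sufficiently-expressed intergenic CRS against its closest
    gene element.

    ``matrix`` must contain boolean rows for each locus and each gene element
    (by name). ``element_gene`` maps element names to their parent gene (the
    element name itself is used when absent). Ties in the closest element
    produce one record per tied element, flagged ``tied``; chromosomes
    without any gene element yield a ``no_neighbor`` record. Classification
    thresholds are inclusive (>= pos_cut, <= neg_cut).
    """
    n_exp = matrix.shape[1]
    records: list[CoexpressionRecord] = []
    for locus in intergenic_loci:
        if locus.name not in matrix.index:
            raise KeyError(f"locus {locus.name!r} missing from expression matrix")
        crs_vec = matrix.loc[locus.name].to_numpy(dtype=bool)
        e_c = int(crs_vec.sum())
        if e_c < min_expr:
            continue
        neighbors = closest_features(locus, gene_elements)
        if not neighbors:
            records.append(
                CoexpressionRecord(
                    locus.name, "", "", -1, 0, e_c, 0, n_exp - e_c,
                    float("nan"), "independent", status="no_neighbor",
                )
            )
            continue
        tied = len(neighbors) > 1
        for nb in neighbors:
            el = nb.feature.name
            if el not in matrix.index:
                raise KeyError(f"gene element {el!r} missing from expression matrix")
            g_vec = matrix.loc[el].to_numpy(dtype=bool)
            e_cg = int((crs_vec & g_vec).sum())
            e_gnc = int((g_vec & ~crs_vec).sum())
            e_nc = n_exp - e_c
            score = coexpression_score(e_cg, e_c, e_gnc, e_nc)
            records.append(
                CoexpressionRecord(
                    locus.name,
                    el,
                    element_gene.get(el, el) if element_gene else el,
                    nb.distance,
                    e_cg, e_c, e_gnc, e_nc,
                    score,
                    _classify(score, pos_cut, neg_cut),
                    tied=tied,
                )
            )
    return records


@dataclass
class SyntenyVerdict:
    crs_id: str
    gene_id: str
    per_species: pd.DataFrame  # species, closest_match, orientation_match, within_distance, available
    n_available: int = 0
    strict_pass: bool = False
    orientation_pass: bool = False
    distance_pass: bool = False


def _side(crs: GenomicInterval, gene: GenomicInterval) -> str:
    if gene.end <= crs.start:
        return "upstream"
    if gene.start >= crs.end:
        return "downstream"
    return "overlapping"


def synteny_tests(
    records: Sequence[CoexpressionRecord],
    orthology: pd.DataFrame,
    species_genes: Mapping[str, Track],
    species_crs: Mapping[str, Track],
    focal_crs: Track,
    focal_genes: Track,
    required_fraction: float = 2.0 / 3.0,
    max_distance: int = 20000,
) -> list[SyntenyVerdict]:
    """Evaluate the three synteny criteria for each co-expressed CRS-gene pair.

    ``orthology`` has columns (gene, species, ortholog). ``species_genes`` /
    ``species_crs`` give per-species gene and CRS positions (gene names =
    per-species gene ids; CRS names = focal locus ids). Criteria per species:

    * strict  — the ortholog of the focal closest gene is (one of) the
      closest gene(s) to the CRS in that species;
    * orientation — the ortholog lies on the same side of the CRS as the
      focal gene does in the focal species;
    * distance — orientation plus separation <= ``max_distance``.

    With tied closest genes, one satisfying tie member suffices. Species with
    no ortholog or no mapped CRS are excluded from that pair's denominator.
    Each aggregate criterion passes iff it holds in >= ceil(required_fraction
    x available species).
    """
    focal_crs_by_name = {iv.name: iv for iv in focal_crs}
    focal_gene_by_name = {iv.name: iv for iv in focal_genes}
    orth = {
        (r.gene, r.species): r.ortholog
        for r in orthology.itertuples(index=False)
        if isinstance(r.ortholog, str) and r.ortholog
    }
    verdicts = []
    species_list = sorted(species_genes)
    for rec in records:
        if rec.status != "ok" or rec.gene_id not in focal_gene_by_name:
            continue
        crs_iv = focal_crs_by_name[rec.crs_id]
        focal_gene_iv = focal_gene_by_name[rec.gene_id]
        focal_side = _side(crs_iv, focal_gene_iv)
        rows = []
        for sp in species_list:
            ortholog = orth.get((rec.gene_id, sp))
            sp_crs = next(
                (iv for iv in species_crs.get(sp, Track()) if iv.name == rec.crs_id),
                None,
            )
            if ortholog is None or sp_crs is None:
                rows.append(
                    {
                        "species": sp, "available": False, "closest_match": False,
                        "orientation_match": False, "within_distance": False,
                    }
                )
                continue
            genes = species_genes[sp]
            orth_ivs = [iv for iv in genes if iv.name == ortholog]
            if not orth_ivs:
                rows.append(
                    {
                        "species": sp, "available": False, "closest_match": False,
                        "orientation_match": False, "within_distance": False,
                    }
                )
                continue
            neighbors = closest_features(sp_crs, genes)
            closest_names = {nb.feature.name for nb in neighbors}
            closest_match = ortholog in closest_names
            # at least one placement of the ortholog may satisfy orientation
            orientation_match = any(
                iv.chrom == sp_crs.chrom and _side(sp_crs, iv) == focal_side
                for iv in orth_ivs
            )
            within = any(
                iv.chrom == sp_crs.chrom
                and _side(sp_crs, iv) == focal_side
                and max(0, iv.start - sp_crs.end, sp_crs.start - iv.end) <= max_distance
                for iv in orth_ivs
            )
            rows.append(
                {
                    "species": sp, "available": True, "closest_match": closest_match,
                    "orientation_match": orientation_match, "within_distance": within,
                }
            )
        df = pd.DataFrame(rows)
        avail = df[df.available]
        n_av = len(avail)
        need = math.ceil(required_fraction * n_av) if n_av else 1
        verdicts.append(
            SyntenyVerdict(
                rec.crs_id,
                rec.gene_id,
                df,
                n_available=n_av,
                strict_pass=bool(n_av and avail.closest_match.sum() >= need),
                orientation_pass=bool(n_av and avail.orientation_match.sum() >= need),
                distance_pass=bool(n_av and avail.within_distance.sum() >= need),
            )
        )
    return verdicts
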