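"""Collapse selected motifs into strand-independent CRS loci.

RNA secondary structures are nearly symmetric under strand reversal, so a
prediction on either strand is evidence for one genomic locus; overlapping
and near-adjacent motifs (gap <= 30 nt, the typical hole between alignment
blocks) are merged regardless of strand. Locus ids are assigned in
(chromosome, start) order as a zero-padded counter with a configurable
prefix, so the id set is stable for a given selected-motif set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval, Track

__all__ = ["CRSLocus", "build_loci", "loci_track", "loci_table"]


@dataclass
class CRSLocus:
    id: str
    interval: GenomicInterval  # unstranded
    member_ids: list[str] = field(default_factory=list)
    best_pscore: float = float("nan")
    min_fdr: float = float("nan")


def build_loci(
    selected_motifs: pd.DataFrame, max_gap: int = 30, id_prefix: str = "DC"
) -> list[CRSLocus]:
    """Merge selected motifs strand-independently into loci.

    Two motifs join the same locus iff they are chained by gaps of at most
    ``max_gap`` nt on one chromosome (transitive). The locus interval spans
    the member union; membership, best pscore and minimum member FDR are kept.
    Input order does not matter: motifs are canonically sorted first.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    motifs = selected_motifs.sort_values(
        ["chrom", "start", "end", "id"], kind="mergesort"
    ).reset_index(drop=True)
    loci: list[CRSLocus] = []
    cur = None  # (chrom, start, end, members, best_pscore, min_fdr)
    has_fdr = "fdr" in motifs.columns

    def _flush(c):
        if c is not None:
            loci.append(
                CRSLocus(
                    id="",
                    interval=GenomicInterval(c[0], c[1], c[2], "."),
                    member_ids=c[3],
                    best_pscore=c[4],
                    min_fdr=c[5],
                )
            )

    for r in motifs.itertuples(index=False):
        fdr = float(r.fdr) if has_fdr else float("nan")
        if cur is not None and r.chrom == cur[0] and int(r.start) - cur[2] <= max_gap:
            cur[2] = max(cur[2], int(r.end))
            cur[3].append(r.id)
            cur[4] = max(cur[4], float(r.pscore))
            cur[5] = min(cur[5], fdr) if cur[5] == cur[5] else fdr
        else:
            _flush(cur)
            cur = [r.chrom, int(r.start), int(r.end), [r.id], float(r.pscore), fdr]
    _flush(cur)
    width = 7
    for i, locus in enumerate(loci, 1):
        locus.id = f"{id_prefix}{i:0{width}d}"
        locus.interval = GenomicInterval(
            locus.interval.chrom,
            locus.interval.start,
            locus.interval.end,
            ".",
            locus.id,
        )
    return loci


def loci_track(loci: list[CRSLocus], name: str = "crs_loci") -> Track:
    return Track(name, [l.interval for l in loci], merged=True)


def loci_table(loci: list[CRSLocus]) -> pd.DataFrame:
    """TSV-ready sidecar: id, members, best_pscore, min_fdr."""
    return pd.DataFrame(
        {
            "id": [l.id for l in loci],
            "chrom": [l.interval.chrom for l in loci],
            "start": [l.interval.start for l in loci],
            "end": [l.interval.end for l in loci],
            "members": [",".join(l.member_ids) for l in loci],
            "best_pscore": [l.best_pscore for l in loci],
            "min_fdr": [l.min_fdr for l in loci],
        }
    )
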