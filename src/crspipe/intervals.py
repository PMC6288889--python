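"""Genomic interval algebra shared by every pipeline stage.

All coordinates are 0-based, half-open (BED convention). The operations here
mirror the standard genome-arithmetic toolbox (merge with a gap tolerance,
fractional coverage, reciprocal-overlap pairing, closest feature with ties)
but with semantics pinned down exactly, because downstream statistics depend
on boundary behaviour (e.g. a gap equal to ``max_gap`` *is* merged; a motif
covered by exactly half its length by repeats *is* discarded).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "GenomicInterval",
    "Track",
    "merge_track",
    "coverage_fraction",
    "overlap_pairs",
    "closest_features",
    "interval_distance",
]

STRANDS = ("+", "-", ".")


class IntervalError(ValueError):
    """Raised for malformed genomic intervals or tracks."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded). ``name`` carries
    the record identifier when the interval stands for an annotated feature,
    motif, or locus.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError(f"empty chromosome name in record {self.name!r}")
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"invalid coordinates [{self.start}, {self.end}) in record "
                f"{self.name!r} on {self.chrom}: require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise IntervalError(
                f"invalid strand {self.strand!r} in record {self.name!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared nucleotides with *other* (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge-to-edge distance between half-open intervals; 0 when overlapping.

    Raises if the intervals lie on different chromosomes (distance undefined).
    """
    if a.chrom != b.chrom:
        raise IntervalError(f"distance undefined across chromosomes {a.chrom}/{b.chrom}")
    return max(0, b.start - a.end, a.start - b.end)


@dataclass
class Track:
    """A named collection of intervals, sortable by (chrom, start, end)."""

    name: str = ""
    intervals: list[GenomicInterval] = field(default_factory=list)
    merged: bool = False  # set by merge_track; consumers may require it

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "Track":
        ivs = sorted(self.intervals, key=lambda i: (i.chrom, i.start, i.end))
        return Track(self.name, ivs, self.merged)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        # Cached: tracks are treated as immutable once queried.
        cache = self.__dict__.get("_chrom_cache")
        if cache is not None and cache[0] == len(self.intervals):
            return cache[1]
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        for lst in out.values():
            lst.sort(key=lambda i: (i.start, i.end))
        self.__dict__["_chrom_cache"] = (len(self.intervals), out)
        return out

    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def merge_track(track: Track, max_gap: int = 0, strand_aware: bool = False) -> Track:
    """Merge intervals separated by a gap of at most ``max_gap`` nucleotides.

    Two intervals are merged iff they lie on the same chromosome (and the same
    strand when ``strand_aware``) and ``start2 - end1 <= max_gap`` after
    sorting. Merging is transitive, so the result is the connected-component
    union. Output intervals are pairwise non-overlapping and sorted; names are
    dropped (a merged interval no longer stands for a single record); strand is
    kept only in strand-aware mode.
    """
    if max_gap < 0:
        raise IntervalError(f"max_gap must be non-negative, got {max_gap}")
    groups: dict[tuple, list[GenomicInterval]] = {}
    for iv in track.intervals:
        key = (iv.chrom, iv.strand) if strand_aware else (iv.chrom,)
        groups.setdefault(key, []).append(iv)

    out: list[GenomicInterval] = []
    for key in sorted(groups):
        ivs = sorted(groups[key], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        strand = ivs[0].strand if strand_aware else "."
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(key[0], cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(key[0], cur_start, cur_end, strand))
    out.sort(key=lambda i: (i.chrom, i.start, i.end))
    return Track(track.name, out, merged=True)


def _covered_bases(query: GenomicInterval, targets: Sequence[GenomicInterval]) -> int:
    """Bases of *query* covered by sorted non-overlapping same-chrom targets."""
    starts = [t.start for t in targets]
    lo = bisect_right(starts, query.start) - 1
    lo = max(lo, 0)
    covered = 0
    for t in targets[lo:]:
        if t.start >= query.end:
            break
        covered += max(0, min(t.end, query.end) - max(t.start, query.start))
    return covered


def coverage_fraction(
    query: GenomicInterval, targets: Track, strand_aware: bool = False
) -> float:
    """Fraction of *query* bases covered by the merged target track.

    ``targets`` must be merged (non-overlapping): overlapping targets would
    double-count bases, so an unmerged track raises.
    """
    if not targets.merged:
        raise IntervalError(
            "coverage_fraction requires a merged target track (double-counting "
            "hazard); call merge_track first"
        )
    per_chrom = targets.by_chrom()
    ivs = per_chrom.get(query.chrom, [])
    if strand_aware:
        ivs = [t for t in ivs if t.strand == query.strand]
    if not ivs:
        return 0.0
    return _covered_bases(query, ivs) / len(query)


@dataclass(frozen=True)
class OverlapPair:
    query: GenomicInterval
    target: GenomicInterval
    overlap: int


def overlap_pairs(
    queries: Track,
    targets: Track,
    min_frac_query: float = 0.0,
    min_frac_target: float = 0.0,
    either_suffices: bool = True,
    min_bp: int = 1,
) -> list[OverlapPair]:
    """All (query, target) pairs passing the overlap thresholds.

    A pair is reported iff overlap >= ``min_bp`` and the fractional thresholds
    hold: with ``either_suffices`` the overlap must reach at least
    ``min_frac_query*|q|`` OR ``min_frac_target*|t|``; otherwise both.
    Strand is ignored throughout (the screens merge strands upstream).
    """
    if not (0.0 <= min_frac_query <= 1.0 and 0.0 <= min_frac_target <= 1.0):
        raise IntervalError("fractional thresholds must lie in [0, 1]")
    if min_bp < 1:
        raise IntervalError("min_bp must be >= 1")
    t_by_chrom = targets.by_chrom()
    out: list[OverlapPair] = []
    for q in sorted(queries.intervals, key=lambda i: (i.chrom, i.start, i.end)):
        cands = t_by_chrom.get(q.chrom, [])
        for t in cands:
            if t.start >= q.end:
                break
            ov = q.overlap(t)
            if ov < min_bp:
                continue
            ok_q = ov >= min_frac_query * len(q)
            ok_t = ov >= min_frac_target * len(t)
            if (ok_q or ok_t) if either_suffices else (ok_q and ok_t):
                out.append(OverlapPair(q, t, ov))
    return out


@dataclass(frozen=True)
class Neighbor:
    feature: GenomicInterval
    distance: int
    side: str  # "upstream" | "downstream" | "overlapping"


def closest_features(query: GenomicInterval, features: Track) -> list[Neighbor]:
    """All features at minimum distance from *query* (ties preserved).

    Distance is edge-to-edge between half-open intervals, 0 iff overlapping.
    Only features on the query's chromosome are considered; an empty candidate
    set returns an empty list (an explicit "no neighbor" result).
    ``side`` is relative to genome coordinates: "upstream" features end at or
    before the query start.
    """
    cands = features.by_chrom().get(query.chrom, [])
    if not cands:
        return []
    best = None
    result: list[Neighbor] = []
    for f in cands:
        d = interval_distance(query, f)
        if best is None or d < best:
            best = d
            result = []
        if d == best:
            if d == 0 and query.overlap(f) > 0:
                side = "overlapping"
            elif f.end <= query.start:
                side = "upstream"
            else:
                side = "downstream"
            result.append(Neighbor(f, d, side))
    return result
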