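"""Readers and writers for the plain-text formats the pipeline consumes.

Formats:

* **BED6** — tab-separated, 0-based half-open, strand in column 6 (``.`` for
  unstranded). Round-trips losslessly for coordinates, name and strand.
* **GFF-like gene models** — tab-separated, 1-based closed coordinates
  (converted to 0-based half-open on read), feature types ``gene``, ``mRNA``,
  ``exon``, ``CDS`` with ``ID=``/``Parent=`` attribute links.
* **Generic TSV** — a header row, read into pandas.

Coordinate conversion happens only at the GFF boundary; everything in memory
is BED-convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from .intervals import GenomicInterval, IntervalError, Track

__all__ = [
    "read_bed",
    "write_bed",
    "read_tsv",
    "write_tsv",
    "GeneModel",
    "GeneSet",
    "read_gene_models",
    "write_gene_models",
]


def read_bed(path: str | os.PathLike, name: str = "") -> Track:
    """Read a BED3/BED6 file into a Track (score column ignored)."""
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IntervalError(f"{path}:{ln}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            nm = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            ivs.append(GenomicInterval(chrom, start, end, strand, nm))
    return Track(name or Path(path).stem, ivs)


def write_bed(track: Track, path: str | os.PathLike) -> None:
    """Write a Track as BED6 (name '.', score 0 placeholders where absent)."""
    with open(path, "w") as fh:
        for iv in sorted(track.intervals, key=lambda i: (i.chrom, i.start, i.end)):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class GeneModel:
    """One gene with its exon and CDS structure (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.gene_id)


@dataclass
class GeneSet:
    """All gene models of an annotation plus the chromosome sizes."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self):
        return len(self.genes)


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for kv in s.strip().split(";"):
        kv = kv.strip()
        if kv and "=" in kv:
            k, v = kv.split("=", 1)
            out[k] = v
    return out


def read_gene_models(path: str | os.PathLike) -> GeneSet:
    """Read GFF-like gene models (1-based closed -> 0-based half-open).

    ``##sequence-region <chrom> <start> <end>`` pragmas populate chromosome
    sizes. Exon/CDS rows attach to their gene via ``Parent=`` (directly or
    through an mRNA). Exon rows whose parent is unknown raise.
    """
    gs = GeneSet()
    mrna_parent: dict[str, str] = {}
    pending: list[tuple[str, str, GenomicInterval]] = []  # (ftype, parent, iv)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, s, e = line.split()
                gs.chrom_sizes[chrom] = int(e) - (int(s) - 1)
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise IntervalError(f"{path}:{ln}: expected 9 GFF columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs_s = cols
            start, end = int(start1) - 1, int(end1)
            attrs = _parse_attrs(attrs_s)
            if ftype == "gene":
                gid = attrs["ID"]
                gs.genes[gid] = GeneModel(gid, chrom, start, end, strand)
            elif ftype == "mRNA":
                mrna_parent[attrs["ID"]] = attrs["Parent"]
            elif ftype in ("exon", "CDS"):
                pending.append(
                    (ftype, attrs["Parent"], GenomicInterval(chrom, start, end, strand))
                )
    for ftype, parent, iv in pending:
        gid = mrna_parent.get(parent, parent)
        if gid not in gs.genes:
            raise IntervalError(f"{ftype} with unknown parent gene {parent!r}")
        (gs.genes[gid].exons if ftype == "exon" else gs.genes[gid].cds).append(iv)
    for g in gs:
        g.exons.sort(key=lambda i: (i.start, i.end))
        g.cds.sort(key=lambda i: (i.start, i.end))
    return gs


def write_gene_models(gs: GeneSet, path: str | os.PathLike) -> None:
    """Write a GeneSet as GFF-like text (lossless round-trip with the reader)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(gs.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {gs.chrom_sizes[chrom]}\n")
        for gid in sorted(gs.genes, key=lambda g: (gs.genes[g].chrom, gs.genes[g].start)):
            g = gs.genes[gid]
            fh.write(
                f"{g.chrom}\tcrspipe\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            mid = f"{gid}.t1"
            fh.write(
                f"{g.chrom}\tcrspipe\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent={gid}\n"
            )
            for iv in g.exons:
                fh.write(
                    f"{g.chrom}\tcrspipe\texon\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t"
                    f"Parent={mid}\n"
                )
            for iv in g.cds:
                fh.write(
                    f"{g.chrom}\tcrspipe\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t0\t"
                    f"Parent={mid}\n"
                )
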