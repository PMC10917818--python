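"""Genomic interval data model and set algebra.

All coordinates are 0-based half-open (BED convention). Strand is carried
but ignored by every overlap computation: H3K27ac peaks and candidate
enhancers are unstranded features.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "TssAnnotation",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_tss_table",
    "write_tss_table",
    "merge_intervals",
    "count_overlaps",
    "overlap_width",
    "remove_near_tss",
]

_VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised for malformed BED-like input; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open region ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def overlap_width(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; <= 0 means no overlap."""
    if a.chrom != b.chrom:
        return 0
    return min(a.end, b.end) - max(a.start, b.start)


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    ``sorted`` records whether intervals are ordered by (chrom, start, end);
    operations that promise disjointness (e.g. :func:`merge_intervals`)
    return sorted, pairwise non-overlapping sets.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), *, sorted: bool = False):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.sorted = sorted
        if sorted:
            for prev, cur in zip(self.intervals, self.intervals[1:]):
                if cur.sort_key() < prev.sort_key():
                    raise ValueError("intervals are not sorted but sorted=True was given")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, sorted={self.sorted})"

    def sort(self) -> "IntervalSet":
        """Return a sorted copy (by chrom, start, end; stable)."""
        return IntervalSet(
            sorted(self.intervals, key=GenomicInterval.sort_key), sorted=True
        )

    def total_bp(self) -> int:
        """Total bp covered (counts overlapping bases once)."""
        merged = merge_intervals(self, max_gap=0)
        return sum(iv.width for iv in merged)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass
class TssAnnotation:
    """Transcription start sites plus (optionally) the gene bodies they belong to.

    ``tss`` rows are (chrom, position, gene_id, strand); ``genes`` maps
    gene_id -> (interval, biotype).
    """

    tss: list[tuple[str, int, str, str]] = field(default_factory=list)
    genes: dict[str, tuple[GenomicInterval, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos, gene_id, strand in self.tss:
            if gene_id in self.genes:
                giv, _ = self.genes[gene_id]
                if not (giv.chrom == chrom and giv.start <= pos < giv.end):
                    raise ValueError(
                        f"TSS of {gene_id} at {chrom}:{pos} lies outside its gene interval"
                    )

    def positions(self) -> list[tuple[str, int]]:
        return [(c, p) for c, p, _, _ in self.tss]

    def protein_coding_tss(self) -> list[tuple[str, int, str, str]]:
        if not self.genes:
            return list(self.tss)
        return [
            row for row in self.tss
            if self.genes.get(row[2], (None, "protein_coding"))[1] == "protein_coding"
        ]


# ---------------------------------------------------------------------------
# readers / writers

def _open_text(path: str | Path | io.TextIOBase):
    if isinstance(path, io.TextIOBase):
        return path, False
    return open(path, "rt"), True


def read_bed(path: str | Path | io.TextIOBase, expected_columns: int | None = None) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet` (line order preserved).

    track/browser/comment (#) lines are skipped. Malformed coordinates raise
    :class:`BedParseError` naming the line number. Unknown chromosome names
    are accepted: no assembly registry is assumed.
    """
    fh, close = _open_text(path)
    intervals: list[GenomicInterval] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 tab-separated fields")
            if expected_columns is not None and len(fields) < expected_columns:
                raise BedParseError(
                    f"line {lineno}: expected >= {expected_columns} columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            fh.close()
    return IntervalSet(intervals)


def write_bed(s: IntervalSet, path: str | Path, *, provenance: str = "faceenh",
              scores: Sequence[float] | None = None) -> None:
    """Write a sorted BED6 file with a header comment recording provenance."""
    order = sorted(range(len(s)), key=lambda i: s[i].sort_key())
    with open(path, "wt") as fh:
        fh.write(f"# {provenance}\n")
        for i in order:
            iv = s[i]
            score = 0 if scores is None else scores[i]
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score:g}\t{iv.strand}\n"
            )


def read_tss_table(path: str | Path | io.TextIOBase) -> TssAnnotation:
    """Read a minimal GFF3-like TSS table.

    Tab-separated columns: chrom, position (0-based), strand, gene_id,
    biotype[, gene_start, gene_end]. Comment lines start with '#'.
    """
    fh, close = _open_text(path)
    tss: list[tuple[str, int, str, str]] = []
    genes: dict[str, tuple[GenomicInterval, str]] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise BedParseError(f"line {lineno}: expected >= 5 columns")
            chrom, pos_s, strand, gene_id, biotype = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer TSS position") from exc
            tss.append((chrom, pos, gene_id, strand))
            if len(fields) >= 7:
                gstart, gend = int(fields[5]), int(fields[6])
                genes[gene_id] = (
                    GenomicInterval(chrom, gstart, gend, gene_id, strand), biotype
                )
    finally:
        if close:
            fh.close()
    return TssAnnotation(tss=tss, genes=genes)


def write_tss_table(ann: TssAnnotation, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("# chrom\tposition\tstrand\tgene_id\tbiotype\tgene_start\tgene_end\n")
        for chrom, pos, gene_id, strand in ann.tss:
            if gene_id in ann.genes:
                giv, biotype = ann.genes[gene_id]
                fh.write(f"{chrom}\t{pos}\t{strand}\t{gene_id}\t{biotype}\t{giv.start}\t{giv.end}\n")
            else:
                fh.write(f"{chrom}\t{pos}\t{strand}\t{gene_id}\tprotein_coding\n")


# ---------------------------------------------------------------------------
# set algebra

def merge_intervals(
    s: IntervalSet, max_gap: int = 0, carry_support: bool = False
) -> IntervalSet | tuple[IntervalSet, list[frozenset[str]]]:
    """Merge intervals closer than ``max_gap`` bp (bedtools-merge semantics).

    ``max_gap=0`` merges overlapping AND bookended intervals. With
    ``carry_support``, returns ``(merged, supports)`` where ``supports[i]``
    is the set of distinct input interval names contributing to region i
    (unnamed inputs are ignored for support).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    svs = s.sort()
    out: list[GenomicInterval] = []
    supports: list[set[str]] = []
    cur: list[int | str] | None = None  # [chrom, start, end]
    cur_support: set[str] = set()
    for iv in svs:
        if cur is not None and iv.chrom == cur[0] and iv.start - cur[2] <= max_gap:
            cur[2] = max(cur[2], iv.end)
            if iv.name is not None:
                cur_support.add(iv.name)
        else:
            if cur is not None:
                out.append(GenomicInterval(cur[0], cur[1], cur[2]))
                supports.append(cur_support)
            cur = [iv.chrom, iv.start, iv.end]
            cur_support = {iv.name} if iv.name is not None else set()
    if cur is not None:
        out.append(GenomicInterval(cur[0], cur[1], cur[2]))
        supports.append(cur_support)
    merged = IntervalSet(out, sorted=True)
    if carry_support:
        return merged, [frozenset(x) for x in supports]
    return merged


def _build_trees(s: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(s):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    return trees


def count_overlaps(
    query: IntervalSet, subject: IntervalSet, min_overlap: int = 1
) -> list[list[tuple[int, int]]]:
    """Per-query overlap records against ``subject``.

    Returns, for each query interval, the list of ``(subject_index,
    overlap_width)`` with width >= ``min_overlap`` on the same chromosome.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = _build_trees(subject)
    hits: list[list[tuple[int, int]]] = []
    for q in query:
        tree = trees.get(q.chrom)
        rec: list[tuple[int, int]] = []
        if tree is not None:
            for node in tree.overlap(q.start, q.end):
                width = min(q.end, node.end) - max(q.start, node.begin)
                if width >= min_overlap:
                    rec.append((node.data, width))
        rec.sort()
        hits.append(rec)
    return hits


def remove_near_tss(s: IntervalSet, tss: TssAnnotation, radius: int = 1000) -> IntervalSet:
    """Drop intervals overlapping any TSS window ``[pos - radius, pos + radius)``.

    This is the distal filter applied to merged peak sets: any >= 1 bp
    overlap with a TSS window removes the interval, strand-agnostic.
    Survivors are returned in their original order.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for chrom, pos in tss.positions():
        lo, hi = max(0, pos - radius), pos + radius
        if hi <= lo:
            hi = lo + 1  # radius 0: the single TSS base
        trees.setdefault(chrom, IntervalTree()).addi(lo, hi)
    kept = [
        iv for iv in s
        if not (iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end))
    ]
    return IntervalSet(kept, sorted=s.sorted)
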