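"""Genomic interval primitives.

All internal coordinates are 0-based, half-open ``[start, end)``. GTF input is
1-based closed and converted on load; BED files share the internal convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlap_fraction(a: GenomicInterval, b: GenomicInterval, *, method: str = "min") -> float:
    """Fraction of the smaller locus covered by the other.

    ``method='min'`` (default) divides the overlap by the shorter interval's
    length, so a locus nested inside another scores 1.0 — nested duplicate
    annotations are the common redundancy case. ``method='jaccard'`` divides by
    the union length instead.
    """
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    if method == "min":
        return ov / min(a.length, b.length)
    if method == "jaccard":
        union = a.length + b.length - ov
        return ov / union
    raise ValueError(f"unknown overlap method {method!r}")


def distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap between two intervals: 0 if they overlap, inf across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def promoter(
    tss_position: int,
    chrom: str,
    strand: str = "+",
    up: int = 2000,
    down: int = 2000,
    chrom_size: int | None = None,
) -> GenomicInterval:
    """Window around a TSS (default 2 kb up- and downstream), clipped at chromosome ends.

    ``up``/``down`` are strand-relative: on the minus strand the upstream side
    extends toward larger coordinates.
    """
    if tss_position < 0:
        raise ValueError("TSS must be >= 0")
    if strand == "-":
        start, end = tss_position - down, tss_position + up
    else:
        start, end = tss_position - up, tss_position + down
    start = max(0, start)
    if chrom_size is not None:
        end = min(end, chrom_size)
    return GenomicInterval(chrom, start, end, strand)


def tss(region: GenomicInterval) -> int:
    """Strand-aware 5' end of a transcript span."""
    return region.end if region.strand == "-" else region.start


class IntervalIndex:
    """Per-chromosome interval tree over (interval, payload) records."""

    def __init__(self, records: Iterable[tuple[GenomicInterval, object]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for iv, payload in records:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: object = None) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (iv, payload))

    def overlapping(self, iv: GenomicInterval, slop: int = 0) -> list[tuple[GenomicInterval, object]]:
        """Records overlapping ``iv`` extended by ``slop`` on both sides."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = tree.overlap(max(0, iv.start - slop), iv.end + slop)
        return [h.data for h in hits]

    def within(self, iv: GenomicInterval, window: int) -> list[tuple[GenomicInterval, object, float]]:
        """Records whose gap to ``iv`` is <= window, with the gap distance."""
        out = []
        for other, payload in self.overlapping(iv, slop=window):
            d = distance(iv, other)
            if d <= window:
                out.append((other, payload, d))
        return out

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())
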