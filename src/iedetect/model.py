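"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion
to and from 1-based conventions happens only at the GTF reader and the
report writers.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence


class InputFormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ChromosomeMismatchError(ValueError):
    """Raised when chromosome name sets of two inputs cannot be reconciled."""


@dataclass
class ExonModel:
    """One exon of a gene.

    ``ordinal`` is the 1-based position of the exon in genomic order within
    its gene (1..L).  ``gc_fraction`` is None until computed from the
    reference, and stays None for all-N sequence (the exon then falls back to
    the uncorrected global median downstream).  ``covered_fraction`` is the
    fraction of exon bases inside capture-kit target regions.
    """

    gene_id: str
    ordinal: int
    chromosome: str
    start: int
    end: int
    gc_fraction: Optional[float] = None
    covered_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"exon {self.gene_id}:{self.ordinal} has end <= start "
                f"({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Ordered union-exon model of one gene plus its callability status."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[ExonModel] = field(default_factory=list)
    callable: Optional[bool] = None
    failing_exons: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for i, exon in enumerate(self.exons, start=1):
            if exon.chromosome != self.chromosome:
                raise ValueError(
                    f"gene {self.gene_id}: exon on {exon.chromosome}, "
                    f"gene on {self.chromosome}"
                )
            if exon.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            if exon.ordinal != i:
                raise ValueError(f"gene {self.gene_id}: ordinals not 1..L")
            prev_end = exon.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals into a sorted list."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


class CaptureIndex:
    """Interval index over capture-kit target regions.

    Regions are normalized per chromosome: sorted, merged, non-abutting.
    Supports overlap tests and exact covered-base counts against any
    half-open query interval.
    """

    def __init__(self, regions: dict[str, Iterable[tuple[int, int]]]):
        self._regions: dict[str, list[tuple[int, int]]] = {}
        self._starts: dict[str, list[int]] = {}
        for chrom, ivals in regions.items():
            for s, e in ivals:
                if s >= e:
                    raise ValueError(f"empty capture region {chrom}:{s}-{e}")
            merged = merge_intervals(ivals)
            if merged:
                self._regions[chrom] = merged
                self._starts[chrom] = [s for s, _ in merged]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._regions)

    def regions(self, chromosome: str) -> list[tuple[int, int]]:
        return list(self._regions.get(chromosome, []))

    def __len__(self) -> int:
        return sum(len(v) for v in self._regions.values())

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in self.chromosomes:
            for s, e in self._regions[chrom]:
                yield chrom, s, e

    def _overlapping(self, chromosome: str, start: int, end: int):
        regs = self._regions.get(chromosome)
        if not regs:
            return
        starts = self._starts[chromosome]
        # First region that could overlap: the one before the first start >= query start.
        i = max(bisect_right(starts, start) - 1, 0)
        for s, e in regs[i:]:
            if s >= end:
                break
            if e > start:
                yield s, e

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        for _ in self._overlapping(chromosome, start, end):
            return True
        return False

    def covered_bases(self, chromosome: str, start: int, end: int) -> int:
        """Number of bases of [start, end) inside any target region."""
        total = 0
        for s, e in self._overlapping(chromosome, start, end):
            total += min(e, end) - max(s, start)
        return total

    def total_bases(self, chromosome: Optional[str] = None) -> int:
        chroms = [chromosome] if chromosome is not None else self.chromosomes
        return sum(e - s for c in chroms for s, e in self._regions.get(c, []))
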