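"""Genomic interval primitives and interval-set algebra.

All intervals are stored internally as 0-based, half-open ``[start, end)``.
Printed/HGVS-like coordinates in the field are 1-based inclusive; the two
helpers :func:`from_1based` and :meth:`GenomicInterval.to_1based` convert
between the conventions at the package boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UsageError


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval on a single chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open bounds, ``start < end``.
    label : str, optional
        Free-text annotation carried through reports.
    """

    chrom: str
    start: int
    end: int
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise UsageError("chrom must be non-empty")
        if not self.start < self.end:
            raise UsageError(f"require start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def to_1based(self) -> tuple[int, int]:
        """Return (start, end) in the 1-based inclusive convention."""
        return self.start + 1, self.end

    def __str__(self) -> str:  # echoes the printed convention
        s, e = self.to_1based()
        return f"{self.chrom}:{s:,}-{e:,}"


def from_1based(chrom: str, start_1b: int, end_1b: int, label: str | None = None) -> GenomicInterval:
    """Build an interval from 1-based inclusive coordinates as printed."""
    return GenomicInterval(chrom, start_1b - 1, end_1b, label=label)


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or book-ended intervals (single chromosome)."""
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise UsageError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.start, x.end)):
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def intersect_sets(a: list[GenomicInterval], b: list[GenomicInterval]) -> list[GenomicInterval]:
    """Intersection of two merged, sorted interval sets."""
    out: list[GenomicInterval] = []
    for x in a:
        for y in b:
            hit = x.intersect(y)
            if hit is not None:
                out.append(hit)
    return merge_intervals(out)
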