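"""Genomic interval primitives shared by every other module.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start`` .. ``end - 1``.  Formats using
1-based closed coordinates (GTF) are converted at read time, never stored.
Overlap requires at least one shared base, so adjacent intervals
(``a.end == b.start``) do not overlap.  Strand is carried on every
interval but ignored by overlap tests unless explicitly requested,
because ChIP-seq fragments are counted regardless of which strand they
aligned to.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRAND_FWD = "+"
STRAND_REV = "-"
STRAND_NONE = "."

_VALID_STRANDS = frozenset({STRAND_FWD, STRAND_REV, STRAND_NONE})


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A non-empty span on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name; must be non-empty.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must exceed ``start``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:[{self.start},{self.end}): "
                "start must be < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(_VALID_STRANDS)}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:[{self.start},{self.end})/{self.strand}"


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """A single aligned read: its genomic span plus mapping quality.

    The strand on ``interval`` is the alignment strand; the 5'-most
    aligned base is ``start`` for forward reads and ``end - 1`` for
    reverse reads.
    """

    interval: GenomicInterval
    mapping_quality: int = 0

    def __post_init__(self) -> None:
        if self.mapping_quality < 0:
            raise ValueError("mapping_quality must be >= 0")

    @property
    def five_prime(self) -> int:
        """0-based genomic coordinate of the 5'-most aligned base."""
        iv = self.interval
        return iv.end - 1 if iv.strand == STRAND_REV else iv.start


def overlaps(a: GenomicInterval, b: GenomicInterval, *, match_strand: bool = False) -> bool:
    """True iff ``a`` and ``b`` share at least one base.

    Half-open semantics: ``a.end == b.start`` is adjacency, not overlap.
    Strand is ignored unless ``match_strand`` is set, in which case the
    two strands must be equal (unstranded matches only unstranded).
    """
    if a.chrom != b.chrom:
        return False
    if match_strand and a.strand != b.strand:
        return False
    return a.start < b.end and b.start < a.end


def _trees_by_chrom(subjects: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    # data payload keeps duplicate coordinates distinct (IntervalTree is a set)
    for i, iv in enumerate(subjects):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def count_overlapping(
    queries: Sequence[GenomicInterval], subjects: Iterable[GenomicInterval]
) -> list[int]:
    """Number of ``subjects`` overlapping each query, in query order.

    Built on an interval tree per chromosome, so repeated queries against
    a large subject set stay fast; semantics match :func:`overlaps`.
    """
    trees = _trees_by_chrom(subjects)
    counts = []
    for q in queries:
        tree = trees.get(q.chrom)
        counts.append(len(tree.overlap(q.start, q.end)) if tree is not None else 0)
    return counts


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse overlapping or bookended intervals into disjoint spans.

    Output is sorted by (chrom, start); strand is dropped (merged spans
    are unstranded).  The set of covered bases is exactly preserved;
    abutting intervals ([0,10) + [10,20)) merge even though they do not
    overlap, so the result is also non-adjacent.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = spans[0].start, spans[0].end
        for iv in spans[1:]:
            if iv.start <= cur_end:  # overlap or bookended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def clamp(interval: GenomicInterval, chrom_length: int) -> GenomicInterval:
    """Truncate an interval to ``[0, chrom_length)``.

    Raises
    ------
    ValueError
        If the interval lies entirely off the chromosome, which signals
        a derived window that fell off a contig edge.
    """
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    start = max(interval.start, 0)
    end = min(interval.end, chrom_length)
    if start >= end:
        raise ValueError(
            f"interval {interval} is empty after clamping to length {chrom_length}"
        )
    if (start, end) == (interval.start, interval.end):
        return interval
    return replace(interval, start=start, end=end)


def write_bed6(intervals: Iterable[tuple[GenomicInterval, str, float]], path) -> None:
    """Write (interval, name, score) triples as BED6, for inspection."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )
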