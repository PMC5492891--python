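"""Stranded genomic intervals and interval algebra.

All coordinates are 0-based half-open ``[start, end)`` regardless of the
source file format; converters live in :mod:`rbptargets.io`.  The three
operations here — merge, overlap query, whole-region subtraction — are the
interval arithmetic of a CLIP/RIP region-calling pipeline: reads are merged
into regions, regions present in a control immunoprecipitation are removed,
and regions are classified by overlap with annotation features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."

_VALID_STRANDS = frozenset({STRAND_PLUS, STRAND_MINUS, STRAND_NONE})


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A stranded genomic span, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.  Compared by exact string match (no
        ``chr`` aliasing).
    start, end : int
        0-based half-open coordinates; ``end > start >= 0``.  Empty
        intervals are rejected.
    strand : str
        ``+``, ``-`` or ``.`` (unstranded).
    name : str, optional
        Feature label (BED column 4).
    score : float, optional
        Numeric score (BED column 5); also used to carry merged-tag counts.
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        # U+2212 minus occasionally appears in hand-written tables
        if self.strand == "−":
            object.__setattr__(self, "strand", STRAND_MINUS)
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . — got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = False) -> bool:
        """True iff the two spans share >= 1 base (half-open semantics)."""
        if self.chrom != other.chrom:
            return False
        if same_strand and not _strands_compatible(self.strand, other.strand):
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand, self.name or "")


def _strands_compatible(a: str, b: str) -> bool:
    """Unstranded matches anything; otherwise strands must be equal."""
    return a == STRAND_NONE or b == STRAND_NONE or a == b


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Normalisation sorts by ``(chrom, start, end, strand, name)`` — the last
    two keys break ties so outputs are deterministic.  An interval tree per
    chromosome is built lazily for overlap queries; the set is treated as
    immutable after construction.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), *, _sorted: bool = False):
        self._intervals: list[GenomicInterval] = list(intervals)
        self._sorted = _sorted
        self._trees: Optional[dict[str, IntervalTree]] = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.normalized()._intervals == other.normalized()._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    # -- normalisation ------------------------------------------------------
    @property
    def is_sorted(self) -> bool:
        return self._sorted

    def normalized(self) -> "IntervalSet":
        """Return a sorted copy (stable; self if already normalised)."""
        if self._sorted:
            return self
        return IntervalSet(
            sorted(self._intervals, key=GenomicInterval.sort_key), _sorted=True
        )

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self._intervals) + list(other._intervals))

    # -- indexed queries ----------------------------------------------------
    def _tree(self, chrom: str) -> Optional[IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self._intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees = trees
        return self._trees.get(chrom)

    def overlapping(
        self, query: GenomicInterval, same_strand: bool = False
    ) -> list[GenomicInterval]:
        """All members sharing >= 1 base with *query*, in sorted order."""
        tree = self._tree(query.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(query.start, query.end)]
        if same_strand:
            hits = [iv for iv in hits if _strands_compatible(iv.strand, query.strand)]
        return sorted(hits, key=GenomicInterval.sort_key)


def overlaps_any(
    query: GenomicInterval, index: IntervalSet, same_strand: bool = False
) -> bool:
    """True iff some member of *index* shares >= 1 base with *query*.

    Strand is ignored unless ``same_strand``; book-ended intervals
    (``[10,20)`` vs ``[20,30)``) never overlap.
    """
    tree = index._tree(query.chrom)
    if tree is None:
        return False
    if not same_strand:
        return tree.overlaps(query.start, query.end)
    return any(
        _strands_compatible(node.data.strand, query.strand)
        for node in tree.overlap(query.start, query.end)
    )


def merge_intervals(
    intervals: IntervalSet, max_gap: int = 0, strand_aware: bool = False
) -> IntervalSet:
    """Merge intervals whose gap is <= ``max_gap`` into single spans.

    With ``max_gap=0`` both overlapping and book-ended intervals merge,
    matching the default of the standard merge tool.  Each output interval
    carries the number of inputs merged into it in its ``score`` field.
    When ``strand_aware``, only same-strand intervals merge and the output
    keeps the strand; otherwise output intervals are unstranded.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    groups: dict[tuple, list[GenomicInterval]] = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand) if strand_aware else (iv.chrom,)
        groups.setdefault(key, []).append(iv)

    merged: list[GenomicInterval] = []
    for key in groups:
        chrom = key[0]
        strand = key[1] if strand_aware else STRAND_NONE
        run_start = run_end = None
        count = 0
        for iv in sorted(groups[key], key=GenomicInterval.sort_key):
            if run_start is None:
                run_start, run_end, count = iv.start, iv.end, 1
            elif iv.start - run_end <= max_gap:
                run_end = max(run_end, iv.end)
                count += 1
            else:
                merged.append(
                    GenomicInterval(chrom, run_start, run_end, strand, score=count)
                )
                run_start, run_end, count = iv.start, iv.end, 1
        if run_start is not None:
            merged.append(
                GenomicInterval(chrom, run_start, run_end, strand, score=count)
            )
    return IntervalSet(merged).normalized()


def subtract_regions(
    a: IntervalSet, b: IntervalSet, same_strand: bool = False
) -> IntervalSet:
    """Whole-region subtraction: drop every member of *a* overlapping *b*.

    A single shared base removes the entire region; regions are never
    truncated.  This is the control-IP filter of the CLIP pipeline: any
    region with any presence in the control sample is discarded.
    """
    kept = [iv for iv in a if not overlaps_any(iv, b, same_strand=same_strand)]
    return IntervalSet(kept, _sorted=a.is_sorted)
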