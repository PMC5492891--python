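"""Readers and writers for BED and GFF3 interval files.

BED is natively 0-based half-open and is passed through verbatim; GFF3 is
1-based inclusive and is converted to the internal half-open convention on
read (``[s, e]`` -> ``[s-1, e)``) and back on write.
"""

from __future__ import annotations

import os
from typing import Iterable, Union

from .intervals import STRAND_NONE, GenomicInterval, IntervalSet

_BED_SKIP_PREFIXES = ("track", "browser", "#")

PathLike = Union[str, os.PathLike]


class ParseError(ValueError):
    """Malformed interval file; message names the file and line number."""


def _parse_strand(token: str) -> str:
    if token in ("+", "-"):
        return token
    return STRAND_NONE


def read_bed(path: PathLike) -> IntervalSet:
    """Read a BED3+/BED6 file into an :class:`IntervalSet`.

    Lines starting with ``track``, ``browser`` or ``#`` are skipped.  The
    strand is taken from column 6 when present, else unstranded.  Raises
    :class:`ParseError` naming the offending line for non-integer
    coordinates or ``end <= start``.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None  # BED allows arbitrary text here
            strand = _parse_strand(fields[5]) if len(fields) > 5 else STRAND_NONE
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand, name=name, score=score)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(regions: IntervalSet, path: PathLike) -> None:
    """Write BED6 such that ``read_bed`` round-trips exactly."""
    with open(path, "w") as fh:
        for iv in regions:
            score = "." if iv.score is None else format_score(iv.score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def format_score(score: float) -> str:
    """Integral scores print without a decimal point (tag counts stay ints)."""
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def read_gff3(paths: Union[PathLike, Iterable[PathLike]]) -> IntervalSet:
    """Read one or more GFF3 files into a single :class:`IntervalSet`.

    GFF3 coordinates are 1-based inclusive; they are converted to 0-based
    half-open.  Several files may be given (e.g. peak calls run separately
    per strand) and are concatenated.  Rows must have 9 tab-separated
    columns; ``#`` lines are comments.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    intervals: list[GenomicInterval] = []
    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ParseError(
                        f"{path}:{lineno}: expected 9 columns, got {len(fields)}"
                    )
                chrom = fields[0]
                try:
                    start1, end1 = int(fields[3]), int(fields[4])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from exc
                if start1 < 1:
                    raise ParseError(
                        f"{path}:{lineno}: GFF3 start must be >= 1, got {start1}"
                    )
                if end1 < start1:
                    raise ParseError(
                        f"{path}:{lineno}: end {end1} < start {start1}"
                    )
                score = None
                if fields[5] not in (".", ""):
                    try:
                        score = float(fields[5])
                    except ValueError:
                        score = None
                strand = _parse_strand(fields[6])
                name = _gff3_attr(fields[8], "ID") or _gff3_attr(fields[8], "Name")
                try:
                    intervals.append(
                        GenomicInterval(
                            chrom, start1 - 1, end1, strand, name=name, score=score
                        )
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def _gff3_attr(column9: str, key: str) -> Union[str, None]:
    for part in column9.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff3(regions: IntervalSet, path: PathLike, source: str = "rbptargets",
               feature_type: str = "region") -> None:
    """Write GFF3 (converting back to 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, iv in enumerate(regions, start=1):
            score = "." if iv.score is None else format_score(iv.score)
            attrs = f"ID={iv.name or f'{feature_type}_{i}'}"
            fh.write(
                f"{iv.chrom}\t{source}\t{feature_type}\t{iv.start + 1}\t{iv.end}\t"
                f"{score}\t{iv.strand}\t.\t{attrs}\n"
            )
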