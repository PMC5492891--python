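"""iCLIP tag processing and binding-region calling.

The pipeline mirrors the standard CLIP workflow downstream of alignment:
sequence tags are demultiplexed by barcode and collapsed to unique
sequences; aligned tag intervals are merged into candidate regions; regions
with any presence in the control (irrelevant-antibody) immunoprecipitation
are removed whole; surviving regions are classified as exonic, intronic or
intergenic against an annotation bundle, with UTR and lncRNA overlap
recorded as independent flags.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import yaml
from Bio import SeqIO

from . import io as _io
from .intervals import GenomicInterval, IntervalSet, merge_intervals, overlaps_any, subtract_regions

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

CATEGORY_EXONIC = "exonic"
CATEGORY_INTRONIC = "intronic"
CATEGORY_INTERGENIC = "intergenic"
CATEGORIES = (CATEGORY_EXONIC, CATEGORY_INTRONIC, CATEGORY_INTERGENIC)

FLAG_UTR = "UTR"
FLAG_LNCRNA = "lncRNA"


@dataclass
class ReadTag:
    """A sequence tag; ``count`` is its multiplicity after deduplication."""

    id: str
    sequence: str
    sample: Optional[str] = None
    count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("tag sequence must be non-empty")
        if self.count < 1:
            raise ValueError(f"tag count must be >= 1, got {self.count}")


@dataclass
class RegionCall:
    """A merged binding region with its supporting-tag count and labels."""

    interval: GenomicInterval
    n_tags: int
    category: Optional[str] = None
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.n_tags < 1:
            raise ValueError(f"n_tags must be >= 1, got {self.n_tags}")


@dataclass
class AnnotationBundle:
    """Indexed feature sets: genes, exons, UTRs, lncRNAs and repeats.

    The repeats set (BED with ``class/family`` name fields) is consumed by
    the RIP-peak classifier; the rest drive CLIP region annotation.  On
    load, exons and UTRs not contained in any gene raise a warning but are
    kept — real annotation builds contain such records.
    """

    genes: IntervalSet = field(default_factory=IntervalSet)
    exons: IntervalSet = field(default_factory=IntervalSet)
    utrs: IntervalSet = field(default_factory=IntervalSet)
    lncrnas: IntervalSet = field(default_factory=IntervalSet)
    repeats: IntervalSet = field(default_factory=IntervalSet)

    @classmethod
    def from_files(
        cls,
        genes: Optional[str] = None,
        exons: Optional[str] = None,
        utrs: Optional[str] = None,
        lncrnas: Optional[str] = None,
        repeats: Optional[str] = None,
        validate: bool = True,
    ) -> "AnnotationBundle":
        bundle = cls(
            genes=_io.read_bed(genes).normalized() if genes else IntervalSet(),
            exons=_io.read_bed(exons).normalized() if exons else IntervalSet(),
            utrs=_io.read_bed(utrs).normalized() if utrs else IntervalSet(),
            lncrnas=_io.read_bed(lncrnas).normalized() if lncrnas else IntervalSet(),
            repeats=_io.read_bed(repeats).normalized() if repeats else IntervalSet(),
        )
        if validate:
            bundle.validate()
        return bundle

    def validate(self) -> int:
        """Warn about exons/UTRs not contained in any gene; return count."""
        orphans = 0
        for label, features in (("exon", self.exons), ("UTR", self.utrs)):
            for iv in features:
                contained = any(
                    g.start <= iv.start and iv.end <= g.end
                    for g in self.genes.overlapping(iv)
                )
                if not contained:
                    orphans += 1
                    warnings.warn(
                        f"{label} {iv.chrom}:{iv.start}-{iv.end} not contained in any gene"
                    )
        return orphans


# ---------------------------------------------------------------------------
# tag-level processing
# ---------------------------------------------------------------------------

def read_tags(path: str, fmt: Optional[str] = None) -> list[ReadTag]:
    """Read sequence tags from FASTA or FASTQ (format inferred from suffix)."""
    if fmt is None:
        lower = str(path).lower()
        fmt = "fastq" if lower.endswith((".fastq", ".fq")) else "fasta"
    return [ReadTag(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]


def demultiplex(
    tags: Iterable[ReadTag],
    barcode_table: Mapping[str, str],
    barcode_offset: int = 0,
) -> dict[str, list[ReadTag]]:
    """Split tags by exact barcode match and strip the barcode bases.

    Barcodes must be the same length and mutually distinct.  A tag whose
    sequence matches no barcode — or is too short to contain one — goes to
    the ``unassigned`` bin unchanged.  Total tag multiplicity is conserved
    across output bins.
    """
    barcodes = dict(barcode_table)
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("duplicate barcode strings in barcode table")
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) > 1:
        raise ValueError(f"barcodes must be equal length, got lengths {sorted(lengths)}")
    bc_len = lengths.pop() if lengths else 0
    by_barcode = {b: sample for sample, b in barcodes.items()}

    bins: dict[str, list[ReadTag]] = {sample: [] for sample in barcodes}
    bins[UNASSIGNED] = []
    for tag in tags:
        if bc_len == 0 or len(tag.sequence) < barcode_offset + bc_len:
            if bc_len and len(tag.sequence) < barcode_offset + bc_len:
                warnings.warn(
                    f"tag {tag.id} shorter than barcode_offset + barcode length; unassigned"
                )
            bins[UNASSIGNED].append(tag)
            continue
        observed = tag.sequence[barcode_offset : barcode_offset + bc_len]
        sample = by_barcode.get(observed)
        if sample is None:
            bins[UNASSIGNED].append(tag)
            continue
        stripped = tag.sequence[:barcode_offset] + tag.sequence[barcode_offset + bc_len :]
        bins[sample].append(
            ReadTag(tag.id, stripped, sample=sample, count=tag.count)
        )
    return bins


def collapse_duplicates(tags: Iterable[ReadTag]) -> list[ReadTag]:
    """Collapse tags to one record per distinct sequence.

    Output is ordered lexicographically by sequence; each record's count is
    the summed multiplicity of its occurrences, so total multiplicity is
    conserved.
    """
    counts: Counter[str] = Counter()
    first_id: dict[str, str] = {}
    sample: dict[str, Optional[str]] = {}
    for tag in tags:
        counts[tag.sequence] += tag.count
        first_id.setdefault(tag.sequence, tag.id)
        sample.setdefault(tag.sequence, tag.sample)
    return [
        ReadTag(first_id[seq], seq, sample=sample[seq], count=counts[seq])
        for seq in sorted(counts)
    ]


# ---------------------------------------------------------------------------
# region calling and annotation
# ---------------------------------------------------------------------------

def call_regions(
    ip_tags: IntervalSet,
    control_tags: IntervalSet,
    min_tags: int = 1,
    strand_aware: bool = True,
    merge_control: bool = True,
) -> list[RegionCall]:
    """Merge IP tag intervals into regions and subtract control presence.

    The IP tags are merged (gap 0, strand-aware by default — iCLIP is
    strand-specific); the control tags are merged identically (or used raw
    with ``merge_control=False``); every IP region overlapping any control
    region by >= 1 bp is removed whole; finally regions supported by fewer
    than ``min_tags`` tags are dropped.  The default ``min_tags=1`` applies
    no support threshold.
    """
    if min_tags < 1:
        raise ValueError(f"min_tags must be >= 1, got {min_tags}")
    ip_regions = merge_intervals(ip_tags, max_gap=0, strand_aware=strand_aware)
    control = (
        merge_intervals(control_tags, max_gap=0, strand_aware=strand_aware)
        if merge_control
        else control_tags.normalized()
    )
    kept = subtract_regions(ip_regions, control, same_strand=strand_aware)
    return [
        RegionCall(interval=iv, n_tags=int(iv.score))
        for iv in kept
        if int(iv.score) >= min_tags
    ]


def annotate_region(region: RegionCall, ann: AnnotationBundle) -> RegionCall:
    """Assign the region's category and feature flags.

    Exonic if it overlaps any exon; else intronic if it overlaps any gene;
    all other regions are intergenic.  UTR and lncRNA overlap are recorded
    as flags independent of the category.  Overlap is strand-blind with
    half-open semantics.
    """
    iv = region.interval
    if overlaps_any(iv, ann.exons):
        category = CATEGORY_EXONIC
    elif overlaps_any(iv, ann.genes):
        category = CATEGORY_INTRONIC
    else:
        category = CATEGORY_INTERGENIC
    flags = set()
    if overlaps_any(iv, ann.utrs):
        flags.add(FLAG_UTR)
    if overlaps_any(iv, ann.lncrnas):
        flags.add(FLAG_LNCRNA)
    return dataclasses.replace(region, category=category, flags=frozenset(flags))


def annotate_regions(
    regions: Iterable[RegionCall], ann: AnnotationBundle
) -> list[RegionCall]:
    return [annotate_region(r, ann) for r in regions]


def summarize_annotation(regions: Sequence[RegionCall]) -> dict[str, int]:
    """Count regions per category and per flag.

    Categories are exclusive and sum to the number of regions; flags are
    not exclusive.  Raises if any region is unannotated.
    """
    for r in regions:
        if r.category is None:
            raise ValueError("summarize_annotation called on unannotated regions")
    summary = {"total": len(regions)}
    cat_counts = Counter(r.category for r in regions)
    for cat in CATEGORIES:
        summary[cat] = cat_counts.get(cat, 0)
    for flag in (FLAG_UTR, FLAG_LNCRNA):
        summary[flag] = sum(1 for r in regions if flag in r.flags)
    return summary


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class ClipPipelineConfig:
    """File locations and parameters for one region-calling run."""

    ip_bed: str
    control_bed: str
    out_dir: str
    genes_bed: Optional[str] = None
    exons_bed: Optional[str] = None
    utrs_bed: Optional[str] = None
    lncrnas_bed: Optional[str] = None
    min_tags: int = 1
    strand_aware: bool = True
    merge_control: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "ClipPipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_clip_pipeline(config: ClipPipelineConfig) -> tuple[list[RegionCall], dict[str, int]]:
    """Execute region calling, annotation and reporting for one sample.

    Writes ``regions.bed`` (BED6, score = supporting tag count),
    ``summary.tsv`` and ``run_log.txt`` (parameters plus input checksums)
    into ``config.out_dir``.  Output is deterministic given identical
    inputs and configuration.
    """
    inputs = {"ip_bed": config.ip_bed, "control_bed": config.control_bed}
    for key in ("genes_bed", "exons_bed", "utrs_bed", "lncrnas_bed"):
        value = getattr(config, key)
        if value is not None:
            inputs[key] = value
    for key, path in inputs.items():
        if not os.path.isfile(path):
            raise FileNotFoundError(f"{key}: no such file {path!r}")

    ann = AnnotationBundle.from_files(
        genes=config.genes_bed,
        exons=config.exons_bed,
        utrs=config.utrs_bed,
        lncrnas=config.lncrnas_bed,
        validate=False,
    )
    ip = _io.read_bed(config.ip_bed)
    control = _io.read_bed(config.control_bed)
    regions = call_regions(
        ip,
        control,
        min_tags=config.min_tags,
        strand_aware=config.strand_aware,
        merge_control=config.merge_control,
    )
    regions = annotate_regions(regions, ann)
    summary = summarize_annotation(regions)

    os.makedirs(config.out_dir, exist_ok=True)
    out_bed = os.path.join(config.out_dir, "regions.bed")
    _io.write_bed(
        IntervalSet(
            dataclasses.replace(
                r.interval, name=r.category, score=r.n_tags
            )
            for r in regions
        ),
        out_bed,
    )
    with open(os.path.join(config.out_dir, "summary.tsv"), "w") as fh:
        fh.write("key\tcount\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
    with open(os.path.join(config.out_dir, "run_log.txt"), "w") as fh:
        fh.write("rbptargets clip pipeline\n")
        for f in dataclasses.fields(config):
            fh.write(f"param\t{f.name}\t{getattr(config, f.name)}\n")
        for key, path in sorted(inputs.items()):
            fh.write(f"input\t{key}\t{path}\tmd5={_md5(path)}\n")
        fh.write(f"n_regions\t{len(regions)}\n")
    return regions, summary


def _md5(path: str) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
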