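"""Synthetic inputs with machine-readable truth tables.

Three generators cover every input the pipeline consumes:

* :func:`make_annotation` — a toy genome annotation (genes with exons and
  UTRs, lncRNAs, repeat elements with class labels) packed into a small
  number of chromosomes;
* :func:`simulate_clip_experiment` — stranded tag intervals with planted
  binding regions, optional Poisson background, control-IP contamination
  on a chosen fraction of regions, and FASTA tag sequences with barcodes
  and PCR-style duplicates;
* :func:`simulate_gene_sets` — three gene sets over a finite symbol
  universe either achieving an exact target Venn partition or drawn
  uniformly (the permutation null).

Every generator is a pure function of its configuration and seed: reruns
are byte-identical.  Truth tables are plain DataFrames/TSVs so tests can
be data-driven.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .clip import AnnotationBundle, ReadTag
from .intervals import (
    STRAND_MINUS,
    STRAND_NONE,
    STRAND_PLUS,
    GenomicInterval,
    IntervalSet,
)
from .overlap import REGION_KEYS, GeneSet, GeneUniverse, VennPartition

_NUCLEOTIDES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Infeasible or inconsistent generator configuration."""


# ---------------------------------------------------------------------------
# annotation generator
# ---------------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    """Layout of the toy genome.

    Defaults give a compact two-chromosome genome dense enough that every
    placement category (exonic / intronic / intergenic / repeat) exists.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 200_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 5)
    utr_fraction: float = 0.5
    n_lncrnas: int = 4
    n_repeats: int = 30
    repeat_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"LINE": 0.4, "SINE": 0.3, "LTR": 0.2, "other": 0.1}
    )
    gene_span: tuple[int, int] = (2_000, 5_000)
    lncrna_span: tuple[int, int] = (500, 1_500)
    repeat_span: tuple[int, int] = (150, 500)
    min_gap: int = 300
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.repeat_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"repeat_class_mix proportions sum to {total}, expected 1"
            )
        if not 0.0 <= self.utr_fraction <= 1.0:
            raise ConfigurationError("utr_fraction must lie in [0, 1]")


@dataclass
class SimulatedAnnotation:
    """Annotation bundle plus its truth table and chromosome sizes."""

    bundle: AnnotationBundle
    truth: pd.DataFrame  # one row per feature: type, chrom, start, end, strand, label
    chrom_lengths: dict[str, int]
    introns: IntervalSet
    intergenic: IntervalSet

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name in ("genes", "exons", "utrs", "lncrnas", "repeats"):
            _io.write_bed(getattr(self.bundle, name), os.path.join(out_dir, f"{name}.bed"))
        self.truth.to_csv(os.path.join(out_dir, "annotation_truth.tsv"),
                          sep="\t", index=False)


def make_annotation(config: AnnotationConfig) -> SimulatedAnnotation:
    """Build a toy genome annotation; deterministic given the seed.

    Genes and lncRNAs are packed without overlap on each chromosome with at
    least ``min_gap`` between features; exons (and per-gene UTRs) sit
    inside their gene; repeats are dropped into intronic or intergenic
    space.  Infeasible packings raise :class:`ConfigurationError` naming
    the violated budget.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chromosome_length for c in chroms}

    # round-robin distribution of genes + lncRNAs over chromosomes
    features = [("gene", i) for i in range(config.n_genes)]
    features += [("lncrna", i) for i in range(config.n_lncrnas)]
    per_chrom: dict[str, list[tuple[str, int]]] = {c: [] for c in chroms}
    for idx, feat in enumerate(features):
        per_chrom[chroms[idx % len(chroms)]].append(feat)

    genes, exons, utrs, lncrnas, repeats = [], [], [], [], []
    truth_rows = []
    introns: list[GenomicInterval] = []
    intergenic: list[GenomicInterval] = []

    max_span = {"gene": config.gene_span[1], "lncrna": config.lncrna_span[1]}
    span_range = {"gene": config.gene_span, "lncrna": config.lncrna_span}

    for chrom in chroms:
        feats = per_chrom[chrom]
        slot = config.min_gap + max(max_span.values())
        needed = len(feats) * slot
        if needed > config.chromosome_length:
            raise ConfigurationError(
                f"feature budget exceeds chromosome capacity on {chrom}: "
                f"{len(feats)} features x {slot} bp = {needed} > "
                f"{config.chromosome_length} bp"
            )
        slack = config.chromosome_length - needed
        offsets = np.sort(rng.integers(0, slack + 1, size=len(feats)))
        cursor = 0
        for i, (kind, idx) in enumerate(feats):
            start = int(offsets[i]) + i * slot
            lo, hi = span_range[kind]
            span = int(rng.integers(lo, hi + 1))
            end = start + span
            strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
            if kind == "gene":
                name = f"gene_{idx + 1}"
                gene = GenomicInterval(chrom, start, end, strand, name=name)
                genes.append(gene)
                truth_rows.append(("gene", chrom, start, end, strand, name))
                gene_exons = _make_exons(rng, gene, config.exons_per_gene)
                exons.extend(gene_exons)
                for ex in gene_exons:
                    truth_rows.append(("exon", chrom, ex.start, ex.end, strand, ex.name))
                for a, b in zip(gene_exons[:-1], gene_exons[1:]):
                    if b.start > a.end:
                        introns.append(GenomicInterval(chrom, a.end, b.start, strand))
                if rng.random() < config.utr_fraction:
                    first = gene_exons[0]
                    utr_end = first.start + max(1, len(first) // 2)
                    utr = GenomicInterval(chrom, first.start, utr_end, strand,
                                          name=f"{name}_utr")
                    utrs.append(utr)
                    truth_rows.append(("utr", chrom, utr.start, utr.end, strand, utr.name))
            else:
                name = f"lncrna_{idx + 1}"
                lnc = GenomicInterval(chrom, start, end, strand, name=name)
                lncrnas.append(lnc)
                truth_rows.append(("lncrna", chrom, start, end, strand, name))
            if start > cursor:
                intergenic.append(GenomicInterval(chrom, cursor, start, STRAND_NONE))
            cursor = end
        if cursor < config.chromosome_length:
            intergenic.append(
                GenomicInterval(chrom, cursor, config.chromosome_length, STRAND_NONE)
            )

    # repeats go into intronic or intergenic space
    classes = sorted(config.repeat_class_mix)
    probs = np.array([config.repeat_class_mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    hosts = [("intron", iv) for iv in introns] + [("intergenic", iv) for iv in intergenic]
    hosts = [h for h in hosts if len(h[1]) >= config.repeat_span[1] + 2]
    if config.n_repeats > 0 and not hosts:
        raise ConfigurationError(
            "no intronic or intergenic space can host a repeat of "
            f"{config.repeat_span[1]} bp"
        )
    for i in range(config.n_repeats):
        host_kind, host = hosts[int(rng.integers(0, len(hosts)))]
        span = int(rng.integers(config.repeat_span[0], config.repeat_span[1] + 1))
        start = int(rng.integers(host.start, host.end - span + 1))
        cls = classes[int(rng.choice(len(classes), p=probs))]
        name = f"{cls}/{cls}_fam{i + 1}"
        rep = GenomicInterval(host.chrom, start, start + span, host.strand, name=name)
        repeats.append(rep)
        truth_rows.append(("repeat", host.chrom, rep.start, rep.end, rep.strand, name))

    bundle = AnnotationBundle(
        genes=IntervalSet(genes).normalized(),
        exons=IntervalSet(exons).normalized(),
        utrs=IntervalSet(utrs).normalized(),
        lncrnas=IntervalSet(lncrnas).normalized(),
        repeats=IntervalSet(repeats).normalized(),
    )
    truth = pd.DataFrame(
        truth_rows, columns=["type", "chrom", "start", "end", "strand", "label"]
    ).sort_values(["type", "chrom", "start", "end"], kind="stable").reset_index(drop=True)
    return SimulatedAnnotation(
        bundle=bundle,
        truth=truth,
        chrom_lengths=chrom_lengths,
        introns=IntervalSet(introns).normalized(),
        intergenic=IntervalSet(intergenic).normalized(),
    )


def _make_exons(
    rng: np.random.Generator, gene: GenomicInterval, exons_per_gene: tuple[int, int]
) -> list[GenomicInterval]:
    n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
    chunk = len(gene) // n_ex
    exons = []
    for i in range(n_ex):
        c_start = gene.start + i * chunk
        c_end = gene.start + (i + 1) * chunk if i < n_ex - 1 else gene.end
        span = max(1, (c_end - c_start) // 2)
        offset = int(rng.integers(0, c_end - c_start - span + 1))
        exons.append(
            GenomicInterval(
                gene.chrom, c_start + offset, c_start + offset + span, gene.strand,
                name=f"{gene.name}_ex{i + 1}",
            )
        )
    return exons


# ---------------------------------------------------------------------------
# CLIP experiment generator
# ---------------------------------------------------------------------------

@dataclass
class ClipSimConfig:
    """Planted-region CLIP simulation parameters.

    ``tags_per_target`` is the per-region tag coverage (tags tile the
    region so that they always merge back into a single interval, which
    requires ``region_length <= tags_per_target * tag_length``).
    ``control_shared_fraction`` of the planted regions also receive
    control-IP tags and must be removed by the pipeline;
    ``background_tag_rate`` is the expected number of background tags per
    base per chromosome (Poisson-placed, uniform positions).
    """

    n_target_regions: int = 50
    target_placement: Mapping[str, float] = field(
        default_factory=lambda: {
            "exonic": 0.4, "intronic": 0.3, "intergenic": 0.2, "repeat": 0.1
        }
    )
    tags_per_target: int = 5
    background_tag_rate: float = 0.0
    control_shared_fraction: float = 0.2
    duplication_rate: float = 0.1
    barcode_table: Mapping[str, str] = field(
        default_factory=lambda: {"ip": "ACGT", "control": "TGCA"}
    )
    region_length: int = 60
    tag_length: int = 30
    seed: int = 0

    def validate(self) -> None:
        for key, rate in (
            ("control_shared_fraction", self.control_shared_fraction),
            ("duplication_rate", self.duplication_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{key} must lie in [0, 1], got {rate}")
        if self.background_tag_rate < 0:
            raise ConfigurationError("background_tag_rate must be >= 0")
        if self.tags_per_target < 1:
            raise ConfigurationError("tags_per_target must be >= 1")
        if self.region_length > self.tags_per_target * self.tag_length:
            raise ConfigurationError(
                "region_length exceeds tags_per_target * tag_length; "
                "tags could not tile a planted region into one merged interval"
            )
        total = sum(self.target_placement.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"target_placement proportions sum to {total}, expected 1"
            )


@dataclass
class SimulatedClip:
    """Simulated tag files plus the truth tables describing them."""

    ip_tags: IntervalSet
    control_tags: IntervalSet
    fasta_tags: list[ReadTag]
    region_truth: pd.DataFrame  # region_id, chrom, start, end, strand, placement,
                                # category, control_shared
    tag_truth: pd.DataFrame     # tag_id, sample, chrom, start, end, strand, origin,
                                # n_copies

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        _io.write_bed(self.ip_tags, os.path.join(out_dir, "ip_tags.bed"))
        _io.write_bed(self.control_tags, os.path.join(out_dir, "control_tags.bed"))
        with open(os.path.join(out_dir, "tags.fasta"), "w") as fh:
            for tag in self.fasta_tags:
                fh.write(f">{tag.id}\n{tag.sequence}\n")
        self.region_truth.to_csv(os.path.join(out_dir, "region_truth.tsv"),
                                 sep="\t", index=False)
        self.tag_truth.to_csv(os.path.join(out_dir, "tag_truth.tsv"),
                              sep="\t", index=False)


def simulate_clip_experiment(
    ann: SimulatedAnnotation, config: ClipSimConfig
) -> SimulatedClip:
    """Plant binding regions and emit IP/control tag intervals and sequences.

    Regions are placed according to the placement mix (exonic targets
    inside exons, intronic inside introns, intergenic in annotation-free
    gaps, repeat targets inside repeat elements), mutually separated so
    that distinct planted regions never merge.  Exactly
    ``round(control_shared_fraction * n)`` regions also get control tags.
    Each tag interval yields one FASTA record (barcode + random sequence);
    a ``duplication_rate`` fraction of records is emitted twice to
    exercise deduplication.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    candidates = _placement_candidates(ann, config.region_length)
    for category, weight in config.target_placement.items():
        if weight > 0 and not candidates.get(category):
            raise ConfigurationError(
                f"placement mix requests {category!r} targets but the annotation "
                "offers no such space"
            )

    categories = sorted(k for k, w in config.target_placement.items() if w > 0)
    weights = np.array([config.target_placement[c] for c in categories], dtype=float)
    weights /= weights.sum()
    n = config.n_target_regions
    drawn = [categories[int(j)] for j in rng.choice(len(categories), size=n, p=weights)]

    placed: list[GenomicInterval] = []
    region_rows = []
    for i, placement in enumerate(drawn):
        region, category = _place_region(rng, candidates[placement], placement,
                                         config.region_length, placed)
        placed.append(region)
        region_rows.append(
            dict(region_id=f"region_{i + 1}", chrom=region.chrom, start=region.start,
                 end=region.end, strand=region.strand, placement=placement,
                 category=category, control_shared=False)
        )

    m = round(config.control_shared_fraction * n)
    for j in rng.choice(n, size=m, replace=False):
        region_rows[int(j)]["control_shared"] = True

    ip_ivs: list[GenomicInterval] = []
    control_ivs: list[GenomicInterval] = []
    tag_rows = []
    fasta: list[ReadTag] = []
    counter = 0

    def emit(sample: str, iv: GenomicInterval, origin: str) -> None:
        nonlocal counter
        counter += 1
        tag_id = f"tag_{counter}"
        iv = GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand, name=tag_id)
        (ip_ivs if sample == "ip" else control_ivs).append(iv)
        barcode = config.barcode_table.get(sample, "")
        seq = barcode + "".join(rng.choice(_NUCLEOTIDES, size=config.tag_length))
        n_copies = 2 if rng.random() < config.duplication_rate else 1
        for copy in range(n_copies):
            fasta.append(ReadTag(f"{tag_id}" + (f"_dup{copy}" if copy else ""), seq))
        tag_rows.append(
            dict(tag_id=tag_id, sample=sample, chrom=iv.chrom, start=iv.start,
                 end=iv.end, strand=iv.strand, origin=origin, n_copies=n_copies)
        )

    for i, row in enumerate(region_rows):
        region = placed[i]
        for tag_iv in _tile_tags(region, config.tags_per_target, config.tag_length):
            emit("ip", tag_iv, row["region_id"])
        if row["control_shared"]:
            k = max(1, config.tags_per_target // 2)
            for tag_iv in _tile_tags(region, k, config.tag_length):
                emit("control", tag_iv, row["region_id"])

    if config.background_tag_rate > 0:
        for chrom, length in sorted(ann.chrom_lengths.items()):
            n_bg = int(rng.poisson(config.background_tag_rate * length))
            for _ in range(n_bg):
                start = int(rng.integers(0, length - config.tag_length))
                strand = STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
                emit("ip", GenomicInterval(chrom, start, start + config.tag_length,
                                           strand), "background")

    return SimulatedClip(
        ip_tags=IntervalSet(ip_ivs).normalized(),
        control_tags=IntervalSet(control_ivs).normalized(),
        fasta_tags=fasta,
        region_truth=pd.DataFrame(region_rows),
        tag_truth=pd.DataFrame(tag_rows),
    )


def _placement_candidates(
    ann: SimulatedAnnotation, region_length: int
) -> dict[str, list[tuple[GenomicInterval, str]]]:
    """Host intervals per placement category, with the gene-level category
    a region planted there will carry (repeats inherit their host's)."""
    out: dict[str, list[tuple[GenomicInterval, str]]] = {
        "exonic": [], "intronic": [], "intergenic": [], "repeat": []
    }
    for ex in ann.bundle.exons:
        if len(ex) >= region_length:
            out["exonic"].append((ex, "exonic"))
    for intr in ann.introns:
        if len(intr) >= region_length:
            out["intronic"].append((intr, "intronic"))
    for gap in ann.intergenic:
        if len(gap) >= region_length + 2:
            clipped = GenomicInterval(gap.chrom, gap.start + 1, gap.end - 1, gap.strand)
            if len(clipped) >= region_length:
                out["intergenic"].append((clipped, "intergenic"))
    introns = ann.introns
    for rep in ann.bundle.repeats:
        if len(rep) < region_length:
            continue
        host_cat = "intronic" if any(
            i.start <= rep.start and rep.end <= i.end for i in introns.overlapping(rep)
        ) else "intergenic"
        out["repeat"].append((rep, host_cat))
    return out


def _place_region(
    rng: np.random.Generator,
    hosts: Sequence[tuple[GenomicInterval, str]],
    placement: str,
    region_length: int,
    placed: Sequence[GenomicInterval],
    max_tries: int = 200,
) -> tuple[GenomicInterval, str]:
    for _ in range(max_tries):
        host, category = hosts[int(rng.integers(0, len(hosts)))]
        start = int(rng.integers(host.start, host.end - region_length + 1))
        strand = host.strand if host.strand != STRAND_NONE else (
            STRAND_PLUS if rng.random() < 0.5 else STRAND_MINUS
        )
        region = GenomicInterval(host.chrom, start, start + region_length, strand)
        # keep >= 2 bp clear of other planted regions so merges never bridge
        padded = GenomicInterval(region.chrom, max(0, region.start - 1),
                                 region.end + 1, region.strand)
        if not any(padded.overlaps(other) for other in placed):
            return region, category
    raise ConfigurationError(
        f"could not place a {placement!r} region of {region_length} bp after "
        f"{max_tries} attempts; annotation space is too crowded"
    )


def _tile_tags(
    region: GenomicInterval, k: int, tag_length: int
) -> list[GenomicInterval]:
    """k tag intervals tiling the region so they merge into one span."""
    span = len(region)
    tl = min(tag_length, span)
    if k == 1:
        return [GenomicInterval(region.chrom, region.start, region.start + tl,
                                region.strand)]
    starts = np.linspace(region.start, region.end - tl, k).round().astype(int)
    return [
        GenomicInterval(region.chrom, int(s), int(s) + tl, region.strand)
        for s in starts
    ]


# ---------------------------------------------------------------------------
# gene-set generator
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGeneSets:
    sets: tuple[GeneSet, GeneSet, GeneSet]
    universe: GeneUniverse
    truth: dict

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for gs, fname in zip(self.sets, ("set_a.txt", "set_b.txt", "set_c.txt")):
            with open(os.path.join(out_dir, fname), "w") as fh:
                for sym in sorted(gs.symbols):
                    fh.write(sym + "\n")
        with open(os.path.join(out_dir, "background.txt"), "w") as fh:
            for sym in sorted(self.universe.symbols):
                fh.write(sym + "\n")
        pd.DataFrame([self.truth["partition"]]).to_csv(
            os.path.join(out_dir, "genesets_truth.tsv"), sep="\t", index=False
        )


def simulate_gene_sets(
    universe_size: int,
    set_sizes: tuple[int, int, int],
    target_partition: Optional[Mapping[str, int] | VennPartition] = None,
    seed: int = 0,
    mixed_case_fraction: float = 0.0,
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> SimulatedGeneSets:
    """Three gene sets over a synthetic symbol universe.

    With ``target_partition`` (the four shared-region counts, or all
    seven), sets are constructed to achieve those exclusive region counts
    exactly; without it, each set is drawn uniformly without replacement —
    the null of the permutation test.  ``mixed_case_fraction`` of the
    emitted set symbols are presented in lower case to exercise
    case-folding.  Deterministic given the seed.
    """
    ka, kb, kc = set_sizes
    for size in set_sizes:
        if size > universe_size:
            raise ConfigurationError(
                f"set size {size} exceeds universe size {universe_size}"
            )
    rng = np.random.default_rng(seed)
    symbols = np.array([f"G{i + 1:06d}" for i in range(universe_size)])

    if target_partition is None:
        idx = {
            label: rng.choice(universe_size, size, replace=False)
            for label, size in zip(labels, set_sizes)
        }
        sets = tuple(
            _emit_set(rng, label, symbols[idx[label]], mixed_case_fraction)
            for label in labels
        )
        truth = {"partition": None, "set_sizes": set_sizes, "seed": seed}
        return SimulatedGeneSets(sets, GeneUniverse(symbols), truth)

    if isinstance(target_partition, VennPartition):
        target = target_partition.region_counts()
    else:
        target = dict(target_partition)
    shared_keys = ("ab_only", "ac_only", "bc_only", "abc")
    missing = [key for key in shared_keys if key not in target]
    if missing:
        raise ConfigurationError(f"target partition missing regions: {missing}")
    derived = {
        "a_only": ka - target["ab_only"] - target["ac_only"] - target["abc"],
        "b_only": kb - target["ab_only"] - target["bc_only"] - target["abc"],
        "c_only": kc - target["ac_only"] - target["bc_only"] - target["abc"],
    }
    for key, value in derived.items():
        stated = target.get(key)
        if stated is not None and stated != value:
            raise ConfigurationError(
                f"{key}={stated} inconsistent with set sizes (implies {value})"
            )
        if value < 0:
            raise ConfigurationError(
                f"target partition infeasible: {key} would be {value} < 0 "
                "given the set sizes"
            )
        target[key] = value
    total = sum(target[key] for key in REGION_KEYS)
    if total > universe_size:
        raise ConfigurationError(
            f"target partition needs {total} distinct genes but the universe "
            f"holds only {universe_size}"
        )

    perm = rng.permutation(universe_size)
    cursor = 0
    region_members: dict[str, np.ndarray] = {}
    for key in REGION_KEYS:
        count = target[key]
        region_members[key] = perm[cursor : cursor + count]
        cursor += count
    in_a = np.concatenate([region_members[k] for k in ("a_only", "ab_only", "ac_only", "abc")])
    in_b = np.concatenate([region_members[k] for k in ("b_only", "ab_only", "bc_only", "abc")])
    in_c = np.concatenate([region_members[k] for k in ("c_only", "ac_only", "bc_only", "abc")])
    sets = tuple(
        _emit_set(rng, label, symbols[idx], mixed_case_fraction)
        for label, idx in zip(labels, (in_a, in_b, in_c))
    )
    truth = {"partition": {key: int(target[key]) for key in REGION_KEYS},
             "set_sizes": set_sizes, "seed": seed}
    return SimulatedGeneSets(sets, GeneUniverse(symbols), truth)


def _emit_set(
    rng: np.random.Generator, label: str, symbols: np.ndarray, mixed_case_fraction: float
) -> GeneSet:
    emitted = []
    for sym in symbols:
        if mixed_case_fraction and rng.random() < mixed_case_fraction:
            emitted.append(str(sym).lower())
        else:
            emitted.append(str(sym))
    return GeneSet(label, emitted)
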