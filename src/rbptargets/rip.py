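"""RIP-peak classification against repeat and transcript annotations.

Peaks from an RNA-immunoprecipitation caller (GFF3, typically separate
plus- and minus-strand runs combined) are labelled ``repeat`` if they
overlap any RepeatMasker-style feature, else ``transcript`` if they overlap
any annotated transcript, else ``unannotated``.  The summary reports the
three-way partition and the within-repeat class breakdown
(LINE / SINE / LTR / other), the structure of a RIP-seq pie-chart summary.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from . import io as _io
from .clip import AnnotationBundle
from .intervals import GenomicInterval, IntervalSet

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "other")
_CLASS_ORDER = {cls: i for i, cls in enumerate(REPEAT_CLASSES)}

LABEL_REPEAT = "repeat"
LABEL_TRANSCRIPT = "transcript"
LABEL_UNANNOTATED = "unannotated"

#: Accession prefix regarded as protein-coding (mRNA) when counting
#: transcript overlaps that are mRNAs; RefSeq curated mRNAs are ``NM_``.
MRNA_ID_PATTERN = r"^NM_"


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat-element interval with its class and subfamily label."""

    interval: GenomicInterval
    repeat_class: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")


@dataclass(frozen=True)
class PeakClassification:
    """Exactly one label per peak; repeat label carries a repeat class."""

    peak: GenomicInterval
    label: str
    repeat_class: Optional[str] = None
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label == LABEL_REPEAT and self.repeat_class is None:
            raise ValueError("repeat classification requires a repeat_class")


def normalize_repeat_class(raw: str) -> str:
    """Map a free-text class string onto the closed enumeration.

    RepeatMasker class strings such as ``LINE/L1`` or ``SINE/Alu`` keep
    their top-level class; anything outside {LINE, SINE, LTR} maps to
    ``other`` with a warning.
    """
    top = raw.split("/", 1)[0].strip()
    if top in ("LINE", "SINE", "LTR"):
        return top
    if top != "other":
        warnings.warn(f"unknown repeat class {raw!r}; mapping to 'other'")
    return "other"


def read_repeats_bed(path: str) -> list[RepeatFeature]:
    """Read a RepeatMasker-style BED whose name field is ``class/family``."""
    features = []
    for iv in _io.read_bed(path):
        name = iv.name or "other"
        cls = normalize_repeat_class(name)
        family = name.split("/", 1)[1] if "/" in name else ""
        features.append(RepeatFeature(iv, cls, family))
    return features


def classify_peak(
    peak: GenomicInterval,
    repeats: Sequence[RepeatFeature],
    transcripts: IntervalSet,
    repeat_precedence: bool = True,
) -> PeakClassification:
    """Label one peak by overlap with repeats and transcripts.

    Repeats take precedence over transcripts by default (invertible).  When
    several repeats overlap, the class comes from the feature with the
    largest overlap length; ties break by class order LINE < SINE < LTR <
    other, then by leftmost feature.  Overlap is strand-blind, >= 1 bp.
    """
    hits = [
        f for f in repeats if peak.overlaps(f.interval)
    ]
    tx_hits = transcripts.overlapping(peak)

    def repeat_call() -> PeakClassification:
        best = max(
            hits,
            key=lambda f: (
                peak.overlap_length(f.interval),
                -_CLASS_ORDER[f.repeat_class],
                -f.interval.start,
                -f.interval.end,
            ),
        )
        return PeakClassification(peak, LABEL_REPEAT, repeat_class=best.repeat_class)

    def transcript_call() -> PeakClassification:
        return PeakClassification(
            peak, LABEL_TRANSCRIPT, transcript_id=tx_hits[0].name
        )

    if repeat_precedence:
        if hits:
            return repeat_call()
        if tx_hits:
            return transcript_call()
    else:
        if tx_hits:
            return transcript_call()
        if hits:
            return repeat_call()
    return PeakClassification(peak, LABEL_UNANNOTATED)


def classify_peaks(
    peaks: IntervalSet,
    repeats: Sequence[RepeatFeature],
    transcripts: IntervalSet,
    repeat_precedence: bool = True,
    mrna_id_pattern: str = MRNA_ID_PATTERN,
) -> tuple[list[PeakClassification], dict]:
    """Classify every peak and build the two-level summary.

    The summary counts repeat / transcript / unannotated peaks (a partition
    of the input), the within-repeat class breakdown, and additionally the
    number of transcript peaks whose transcript identifier matches the
    protein-coding accession pattern (``mrna``).
    """
    mrna_re = re.compile(mrna_id_pattern)
    calls = [
        classify_peak(p, repeats, transcripts, repeat_precedence=repeat_precedence)
        for p in peaks
    ]
    label_counts = Counter(c.label for c in calls)
    class_counts = Counter(
        c.repeat_class for c in calls if c.label == LABEL_REPEAT
    )
    summary = {
        "total": len(calls),
        LABEL_REPEAT: label_counts.get(LABEL_REPEAT, 0),
        LABEL_TRANSCRIPT: label_counts.get(LABEL_TRANSCRIPT, 0),
        LABEL_UNANNOTATED: label_counts.get(LABEL_UNANNOTATED, 0),
        "repeat_classes": {cls: class_counts.get(cls, 0) for cls in REPEAT_CLASSES},
        "mrna": sum(
            1
            for c in calls
            if c.label == LABEL_TRANSCRIPT
            and c.transcript_id
            and mrna_re.search(c.transcript_id)
        ),
    }
    assert (
        summary[LABEL_REPEAT] + summary[LABEL_TRANSCRIPT] + summary[LABEL_UNANNOTATED]
        == summary["total"]
    ), "classification labels must partition the peaks"
    return calls, summary


def repeats_from_bundle(ann: AnnotationBundle) -> list[RepeatFeature]:
    """Interpret a bundle's repeats set (name = ``class/family``) as features."""
    features = []
    for iv in ann.repeats:
        name = iv.name or "other"
        cls = normalize_repeat_class(name)
        family = name.split("/", 1)[1] if "/" in name else ""
        features.append(RepeatFeature(iv, cls, family))
    return features
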