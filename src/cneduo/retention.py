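"""Read classification against one transcript model and intron-retention summary.

A spliced read (BED12 blocks) is classified by where its aligned bases
fall relative to the designated transcript model: ``exon`` if every base
is exonic, ``intron`` if every base is intronic, ``junction`` if bases
fall in both exon and intron of the same model, and ``unassigned`` if
any base lies outside the transcript span.  A read whose blocks skip an
intron exactly (a spliced read) has no intronic base and is therefore
exonic evidence.

Retention is summarized as intron_fraction = (intron + junction) /
(exon + intron + junction); junction reads count toward retention
because they demonstrate unspliced molecules, while the raw per-category
counts are always preserved.  Comparing subcellular compartments,
log2(nuclear fraction / cytosolic fraction) quantifies nuclear
enrichment of the unspliced species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import SplicedRead, TranscriptModel

CATEGORIES = ("exon", "intron", "junction", "unassigned")


@dataclass
class ReadClassCounts:
    library_id: str
    exon: int = 0
    intron: int = 0
    junction: int = 0
    unassigned: int = 0

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            if getattr(self, cat) < 0:
                raise ValueError(f"negative {cat} count")

    @property
    def total(self) -> int:
        return self.exon + self.intron + self.junction + self.unassigned

    @property
    def assigned(self) -> int:
        return self.exon + self.intron + self.junction

    @property
    def intron_fraction(self) -> float:
        if self.assigned == 0:
            raise ValueError(
                f"no transcript-overlapping reads in library {self.library_id!r}"
            )
        return (self.intron + self.junction) / self.assigned


@dataclass
class RetentionSummary:
    intron_fraction: dict[str, float]
    counts: dict[str, ReadClassCounts]
    compartment_log2_ratio: float | None = None
    per_intron_coverage: pd.DataFrame | None = field(default=None, repr=False)


def classify_read(read: SplicedRead, model: TranscriptModel) -> str:
    """Classify one read against one transcript model (strand-agnostic).

    Classification ignores read strand by default (unstranded library
    convention); strand filtering, when wanted, is applied by the caller
    before counting.
    """
    if read.seq_id != model.seq_id:
        return "unassigned"
    span = model.interval
    in_exon = False
    in_intron = False
    exons = model.exons
    introns = model.introns
    for block in read.blocks:
        if block.width <= 0:
            raise ValueError("zero-length block")
        if block.start < span.start or block.end > span.end:
            return "unassigned"
        cursor = block.start
        while cursor < block.end:
            hit = None
            for ex in exons:
                if ex.start <= cursor < ex.end:
                    hit = ("exon", ex.end)
                    break
            if hit is None:
                for iv in introns:
                    if iv.start <= cursor < iv.end:
                        hit = ("intron", iv.end)
                        break
            if hit is None:  # gap not covered by exon or intron: outside model
                return "unassigned"
            kind, feat_end = hit
            if kind == "exon":
                in_exon = True
            else:
                in_intron = True
            cursor = min(block.end, feat_end)
    if in_exon and in_intron:
        return "junction"
    if in_intron:
        return "intron"
    return "exon"


def count_library(
    reads: Iterable[SplicedRead], model: TranscriptModel, library_id: str = ""
) -> ReadClassCounts:
    """Tally read classes for one library; categories conserve the input count."""
    counts = ReadClassCounts(library_id)
    n = 0
    for read in reads:
        n += 1
        cat = classify_read(read, model)
        setattr(counts, cat, getattr(counts, cat) + 1)
    if n == 0:
        raise ValueError("no reads supplied")
    assert counts.total == n
    return counts


def intron_coverage(reads: Iterable[SplicedRead], model: TranscriptModel) -> pd.DataFrame:
    """Reads overlapping each intron (intronic or junction evidence)."""
    introns = model.introns
    rows = []
    counts = [0] * len(introns)
    for read in reads:
        for i, intr in enumerate(introns):
            if any(b.overlaps(intr) for b in read.blocks):
                counts[i] += 1
    for i, intr in enumerate(introns):
        rows.append(
            {
                "intron_index": i,
                "start": intr.start,
                "end": intr.end,
                "length": intr.width,
                "overlapping_reads": counts[i],
            }
        )
    return pd.DataFrame(rows)


def summarize_retention(
    counts_per_library: Mapping[str, ReadClassCounts],
    nuclear: str = "nuclear",
    cytosolic: str = "cytosolic",
    per_intron_coverage: pd.DataFrame | None = None,
) -> RetentionSummary:
    """Per-library intron fractions and the nuclear/cytosolic log2 ratio.

    The compartment ratio is defined only when both compartments are
    present and the cytosolic fraction is positive; otherwise it is None.
    """
    if not counts_per_library:
        raise ValueError("no libraries supplied")
    fractions = {}
    for lib, counts in counts_per_library.items():
        if counts.assigned == 0:
            raise ValueError(f"no transcript-overlapping reads in library {lib!r}")
        fractions[lib] = counts.intron_fraction
    ratio = None
    if nuclear in fractions and cytosolic in fractions and fractions[cytosolic] > 0:
        ratio = math.log2(fractions[nuclear] / fractions[cytosolic])
    return RetentionSummary(
        intron_fraction=fractions,
        counts=dict(counts_per_library),
        compartment_log2_ratio=ratio,
        per_intron_coverage=per_intron_coverage,
    )
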