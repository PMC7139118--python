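"""Enhancer-state calling: CTSS clustering, divergent eRNA pairs, chromatin signals.

Active enhancers are recognized by unstable bidirectional (divergent)
CAGE transcription flanking the element at roughly nucleosome-scale
spacing, together with open chromatin and H3K27ac; poised enhancers by
open chromatin with bimodal H3K4me1 and high H3K27me3 (plus p300) but no
transcription; everything else with closed chromatin is called closed.
An element sitting inside an annotated promoter cannot be distinguished
from that promoter by chromatin signals alone and is reported as
promoter-ambiguous regardless of its signal profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import CtssRecord, ExpressionMatrix, GenomicInterval, SignalTrack

SIGNAL_MARKS = ("dhs", "h3k4me1", "h3k27ac", "h3k27me3", "p300")
STATES = ("closed", "poised_enhancer", "active_enhancer", "promoter_ambiguous")


@dataclass
class StateThresholds:
    """Free parameters of the decision ladder (documented defaults).

    open_threshold: DHS core/background ratio above which chromatin
        counts as open.
    high_ratio: a histone/p300 mark is "high" when its core-or-flank mean
        is at least this multiple of the mark's local background.
    bimodal_ratio: H3K4me1 is bimodal when both flank means are at least
        this multiple of the core mean.
    max_gap: CTSS single-linkage clustering gap (bp).
    window: maximal distance (bp) of a divergent dominant TSS from the element.
    spacing_band: nucleosome-scale spacing range (bp) between divergent
        dominant TSSs (core particle ~147 bp plus linker).
    tpm_threshold: expression cutoff for expressing/non-expressing groups.
    """

    open_threshold: float = 2.0
    high_ratio: float = 2.0
    bimodal_ratio: float = 1.5
    max_gap: int = 20
    window: int = 300
    spacing_band: tuple[int, int] = (100, 250)
    tpm_threshold: float = 1.0


@dataclass(frozen=True)
class TssCluster:
    interval: GenomicInterval
    dominant_position: int
    total_tags: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.dominant_position < self.interval.end):
            raise ValueError("dominant position outside cluster interval")
        if self.total_tags < 1:
            raise ValueError("cluster must contain at least one tag")

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class BidirectionalPair:
    minus: TssCluster
    plus: TssCluster
    spacing: int
    divergent: bool
    nucleosome_scale: bool

    @property
    def total_tags(self) -> int:
        return self.minus.total_tags + self.plus.total_tags


@dataclass
class StateCall:
    element: GenomicInterval
    cell_type: str
    state: str
    evidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")


def cluster_ctss(records: Sequence[CtssRecord], max_gap: int = 20) -> list[TssCluster]:
    """Single-linkage clustering of CTSS per strand.

    Consecutive CTSS at most ``max_gap`` bp apart join one cluster; the
    dominant position is the highest tag count (leftmost on tie).
    Returns clusters sorted by (seq_id, start, strand); the empty input
    yields an empty list.
    """
    clusters: list[TssCluster] = []
    for strand in ("+", "-"):
        stranded = sorted(
            (r for r in records if r.position.strand == strand and r.tag_count > 0),
            key=lambda r: (r.position.seq_id, r.position.start),
        )
        run: list[CtssRecord] = []
        for rec in stranded:
            if run and (
                rec.position.seq_id != run[-1].position.seq_id
                or rec.position.start - run[-1].position.start > max_gap
            ):
                clusters.append(_finish_cluster(run))
                run = []
            run.append(rec)
        if run:
            clusters.append(_finish_cluster(run))
    clusters.sort(key=lambda c: (c.interval.seq_id, c.interval.start, c.interval.strand))
    return clusters


def _finish_cluster(run: list[CtssRecord]) -> TssCluster:
    start = run[0].position.start
    end = run[-1].position.start + 1
    dominant = max(run, key=lambda r: (r.tag_count, -r.position.start))
    return TssCluster(
        GenomicInterval(run[0].position.seq_id, start, end, run[0].position.strand),
        dominant.position.start,
        sum(r.tag_count for r in run),
    )


def find_bidirectional_pairs(
    clusters: Sequence[TssCluster],
    element: GenomicInterval,
    window: int = 300,
    spacing_band: tuple[int, int] = (100, 250),
) -> list[BidirectionalPair]:
    """Divergent (-,+) cluster pairs around the element.

    A pair qualifies when both dominant positions lie within ``window``
    bp of the element, the minus cluster's dominant position precedes the
    plus cluster's (divergent geometry), and the two dominants sit on
    opposite sides of (or overlap) the element.  Pairs are sorted by
    total tags, descending.
    """
    lo, hi = spacing_band
    minus = [c for c in clusters if c.strand == "-" and c.interval.seq_id == element.seq_id]
    plus = [c for c in clusters if c.strand == "+" and c.interval.seq_id == element.seq_id]
    pairs = []
    for m in minus:
        for p in plus:
            if not (m.dominant_position < p.dominant_position):
                continue
            if _distance_to(element, m.dominant_position) > window:
                continue
            if _distance_to(element, p.dominant_position) > window:
                continue
            # opposite sides of the element, or overlapping it
            if m.dominant_position >= element.end or p.dominant_position < element.start:
                continue
            spacing = p.dominant_position - m.dominant_position
            pairs.append(
                BidirectionalPair(
                    minus=m,
                    plus=p,
                    spacing=spacing,
                    divergent=True,
                    nucleosome_scale=lo <= spacing <= hi,
                )
            )
    pairs.sort(key=lambda pr: -pr.total_tags)
    return pairs


def _distance_to(element: GenomicInterval, position: int) -> int:
    if position < element.start:
        return element.start - position
    if position >= element.end:
        return position - element.end + 1
    return 0


def signal_features(
    tracks: Mapping[str, SignalTrack],
    element: GenomicInterval,
    flank: int = 500,
    bimodal_ratio: float = 1.5,
) -> dict[str, float]:
    """Evidence vector from per-base signal tracks around the element.

    For each mark: mean over the element core, over both flanks of width
    ``flank``, and over the local background (element +- 10 x flank).
    DHS openness is core mean / background mean; H3K4me1 bimodality
    requires both flank means >= bimodal_ratio x core mean.  Uncovered
    positions count as 0 and are tallied in ``uncovered_positions``.
    """
    evidence: dict[str, float] = {}
    uncovered_total = 0
    for mark, track in tracks.items():
        core, unc1 = track.mean(element.start, element.end)
        left, unc2 = track.mean(element.start - flank, element.start)
        right, unc3 = track.mean(element.end, element.end + flank)
        bg_start = max(0, element.start - 10 * flank)
        background, unc4 = track.mean(bg_start, element.end + 10 * flank)
        uncovered_total += unc1 + unc2 + unc3 + unc4
        evidence[f"{mark}_core"] = core
        evidence[f"{mark}_left_flank"] = left
        evidence[f"{mark}_right_flank"] = right
        evidence[f"{mark}_background"] = background
    if "dhs" in tracks:
        bg = evidence["dhs_background"]
        evidence["dhs_openness"] = evidence["dhs_core"] / bg if bg > 0 else 0.0
    if "h3k4me1" in tracks:
        core = evidence["h3k4me1_core"]
        bimodal = (
            evidence["h3k4me1_left_flank"] >= bimodal_ratio * core
            and evidence["h3k4me1_right_flank"] >= bimodal_ratio * core
            and max(evidence["h3k4me1_left_flank"], evidence["h3k4me1_right_flank"]) > 0
        )
        evidence["h3k4me1_bimodal"] = float(bimodal)
    evidence["uncovered_positions"] = float(uncovered_total)
    return evidence


def _mark_high(evidence: Mapping[str, float], mark: str, high_ratio: float) -> bool:
    peak = max(
        evidence[f"{mark}_core"],
        evidence[f"{mark}_left_flank"],
        evidence[f"{mark}_right_flank"],
    )
    background = evidence[f"{mark}_background"]
    return background > 0 and peak >= high_ratio * background


def call_state(
    evidence: Mapping[str, float],
    pairs: Sequence[BidirectionalPair],
    element: GenomicInterval,
    cell_type: str = "",
    overlaps_promoter: bool = False,
    thresholds: StateThresholds | None = None,
) -> StateCall:
    """Deterministic decision ladder over the evidence vector.

    1. element overlaps an annotated promoter -> promoter_ambiguous;
    2. chromatin not open -> closed;
    3. open and (H3K27ac high or a divergent pair present) -> active_enhancer
       (bidirectional CAGE is the decisive active hallmark, so active
       outranks poised when both pattern sets hold);
    4. open and H3K4me1 bimodal and H3K27me3 high -> poised_enhancer;
    5. otherwise closed, with a low-confidence note in the evidence.
    """
    th = thresholds or StateThresholds()
    required = ["dhs_openness", "h3k4me1_bimodal"] + [
        f"{m}_{part}" for m in ("h3k27ac", "h3k27me3") for part in ("core", "left_flank", "right_flank", "background")
    ]
    missing = [k for k in required if k not in evidence]
    if missing:
        raise ValueError(f"missing required evidence keys: {missing}")
    ev = dict(evidence)
    divergent = [p for p in pairs if p.divergent]
    ev["n_divergent_pairs"] = float(len(divergent))
    ev["erna"] = float(bool(divergent))
    if overlaps_promoter:
        state = "promoter_ambiguous"
    elif ev["dhs_openness"] < th.open_threshold:
        state = "closed"
    elif _mark_high(ev, "h3k27ac", th.high_ratio) or divergent:
        state = "active_enhancer"
    elif ev["h3k4me1_bimodal"] > 0 and _mark_high(ev, "h3k27me3", th.high_ratio):
        state = "poised_enhancer"
    else:
        state = "closed"
        ev["low_confidence"] = 1.0
    return StateCall(element=element, cell_type=cell_type, state=state, evidence=ev)


def group_cell_types(
    matrix: ExpressionMatrix, feature_id: str, threshold: float = 1.0
) -> tuple[list[str], list[str]]:
    """Partition samples into (expressing, non-expressing) by a TPM cutoff."""
    values = matrix.feature(feature_id)
    expressing = [s for s in matrix.sample_ids if values[s] >= threshold]
    non_expressing = [s for s in matrix.sample_ids if values[s] < threshold]
    return expressing, non_expressing
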