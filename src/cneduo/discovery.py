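"""Homology scan for the element, synteny assignment, presence/absence matrix.

The scan is a seed-and-extend search without gaps: every exact match of
a ``seed_len``-mer of the query nominates a full-length window, which is
scored as ungapped identity (matches / query length).  Both strands are
searched; overlapping hits on one strand are merged keeping the
maximal-identity hit (leftmost on ties).  Hits are then assigned to the
C or D paralog cluster when they fall strictly between the cluster's
gene11 and gene12 spans, and summarized per species into a
presence/absence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .complementarity import revcomp
from .io_formats import GenomicInterval, TranscriptModel

DEFAULT_MIN_IDENTITY = 0.75
DEFAULT_SEED_LEN = 12

#: substring patterns identifying the flanking genes of each cluster on gene ids
DEFAULT_CLUSTER_PATTERNS: dict[str, tuple[str, str]] = {
    "C": ("c11", "c12"),
    "D": ("d11", "d12"),
}


@dataclass(frozen=True)
class CneHit:
    """One homology match of the query element in a genome."""

    species: str
    interval: GenomicInterval
    strand: str
    identity: float
    matched_sequence: str  # read in query orientation (revcomp of + genome for - hits)
    cluster: str = "unassigned"  # C | D | unassigned

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("hit strand must be + or -")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")
        if len(self.matched_sequence) != self.interval.width:
            raise ValueError("matched sequence length must equal interval width")


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def scan_homologs(
    query: str,
    genome: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_len: int = DEFAULT_SEED_LEN,
    species: str = "",
) -> list[CneHit]:
    """Seed-and-extend ungapped scan of ``query`` against both genome strands.

    Returns hits with ``cluster`` unassigned, sorted by
    (seq_id, start, strand).  Overlapping same-strand hits are merged,
    keeping the maximal identity (leftmost on tie).
    """
    query = query.upper()
    bad = set(query) - set("ACGTN")
    if bad:
        raise ValueError(f"query contains invalid characters {sorted(bad)}")
    if not genome:
        raise ValueError("genome is empty")
    if len(query) < seed_len:
        raise ValueError(f"query shorter than seed_len ({len(query)} < {seed_len})")

    qlen = len(query)
    raw: dict[tuple[str, str, int], float] = {}
    for strand in ("+", "-"):
        oriented = query if strand == "+" else revcomp(query)
        for seq_id, seq in genome.items():
            for q_off in range(qlen - seed_len + 1):
                seed = oriented[q_off : q_off + seed_len]
                pos = seq.find(seed)
                while pos != -1:
                    w_start = pos - q_off
                    if 0 <= w_start <= len(seq) - qlen:
                        key = (seq_id, strand, w_start)
                        if key not in raw:
                            raw[key] = _identity(oriented, seq[w_start : w_start + qlen])
                    pos = seq.find(seed, pos + 1)

    # Merge overlapping same-strand candidates: keep max identity, leftmost tie.
    hits: list[CneHit] = []
    by_group: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for (seq_id, strand, start), ident in raw.items():
        if ident >= min_identity:
            by_group.setdefault((seq_id, strand), []).append((start, ident))
    for (seq_id, strand), cands in by_group.items():
        cands.sort()
        cluster_best: tuple[int, float] | None = None
        cluster_end = -1
        merged: list[tuple[int, float]] = []
        for start, ident in cands:
            if cluster_best is None or start >= cluster_end:
                if cluster_best is not None:
                    merged.append(cluster_best)
                cluster_best = (start, ident)
                cluster_end = start + qlen
            else:
                if ident > cluster_best[1]:
                    cluster_best = (start, ident)
                cluster_end = max(cluster_end, start + qlen)
        if cluster_best is not None:
            merged.append(cluster_best)
        for start, ident in merged:
            window = genome[seq_id][start : start + qlen]
            matched = window if strand == "+" else revcomp(window)
            hits.append(
                CneHit(
                    species=species,
                    interval=GenomicInterval(seq_id, start, start + qlen, strand),
                    strand=strand,
                    identity=ident,
                    matched_sequence=matched,
                )
            )
    hits.sort(key=lambda h: (h.interval.seq_id, h.interval.start, h.strand))
    return hits


def _gene_span(transcripts: Sequence[TranscriptModel], pattern: str, seq_id: str) -> GenomicInterval | None:
    pattern = pattern.lower()
    spans = [
        t.interval
        for t in transcripts
        if pattern in t.gene_id.lower() and t.seq_id == seq_id
    ]
    if not spans:
        return None
    return GenomicInterval(
        seq_id, min(s.start for s in spans), max(s.end for s in spans), spans[0].strand
    )


def assign_synteny(
    hit: CneHit,
    annotation: Sequence[TranscriptModel],
    cluster_patterns: Mapping[str, tuple[str, str]] = DEFAULT_CLUSTER_PATTERNS,
) -> CneHit:
    """Label a hit C / D / unassigned by its position between flanking genes.

    A hit belongs to a cluster when it lies strictly between the
    cluster's gene11 and gene12 spans on the same sequence (no overlap
    with either gene).  A hit on a sequence absent from the annotation
    stays unassigned.
    """
    matches = []
    for label, (p11, p12) in cluster_patterns.items():
        g11 = _gene_span(annotation, p11, hit.interval.seq_id)
        g12 = _gene_span(annotation, p12, hit.interval.seq_id)
        if g11 is None or g12 is None:
            continue
        lo = min(g11.end, g12.end)
        hi = max(g11.start, g12.start)
        if lo <= hit.interval.start and hit.interval.end <= hi:
            if not hit.interval.overlaps(g11) and not hit.interval.overlaps(g12):
                matches.append(label)
    if len(matches) > 1:
        raise ValueError(
            f"hit {hit.interval} lies between flanking genes of multiple clusters "
            f"{matches}; annotation malformed"
        )
    return replace(hit, cluster=matches[0] if matches else "unassigned")


PRESENT = "present"
ABSENT = "absent"
NO_ASSEMBLY = "no-assembly"


def build_presence_matrix(
    hits_by_species: Mapping[str, Sequence[CneHit]],
    species: Sequence[str],
    no_assembly: Sequence[str] = (),
) -> pd.DataFrame:
    """Species x {C, D} matrix of present / absent / no-assembly cells.

    Row order follows the supplied species list (typically tree leaf
    order).  A species listed in ``no_assembly`` gets a no-assembly row.
    """
    unknown = sorted(set(hits_by_species) - set(species))
    if unknown:
        raise ValueError(f"hits reported for species not in the species list: {unknown}")
    rows = {}
    for sp in species:
        if sp in no_assembly:
            rows[sp] = {"C": NO_ASSEMBLY, "D": NO_ASSEMBLY}
        else:
            labels = {h.cluster for h in hits_by_species.get(sp, ())}
            rows[sp] = {
                "C": PRESENT if "C" in labels else ABSENT,
                "D": PRESENT if "D" in labels else ABSENT,
            }
    return pd.DataFrame.from_dict(rows, orient="index", columns=["C", "D"]).loc[list(species)]
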