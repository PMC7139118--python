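"""Synthetic data with planted ground truth for every analysis stage.

The generator emulates the data situation the analysis assumes:

* an ancestral Hox-like cluster carrying one short conserved noncoding
  element (CNE) strictly between its gene11 and gene12;
* a whole-genome duplication giving every extant species a C-cluster and
  a D-cluster copy, with the D copy planted as the reverse complement of
  the C copy (perfect antiparallel complementarity in host-transcript
  orientation) and lineage substitutions drawn per branch under a
  Jukes-Cantor model, plus planted compensatory double substitutions;
* an intron-retained host transcript sampled into whole-cell, nuclear
  and cytosolic read libraries with a tunable retention fraction;
* divergent CAGE tag clusters flanking the element at nucleosome-scale
  spacing together with chromatin-signal profiles for closed / poised /
  active states;
* an expression matrix with planted positive (cis) and negative (trans)
  couplings between the element and target genes.

Every generator is deterministic given the config seed, and everything
planted is recorded in a TruthLedger so downstream results can be scored
against the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .complementarity import OrientedPair, _label_tree, revcomp
from .io_formats import (
    CtssRecord,
    ExpressionMatrix,
    GenomicInterval,
    SignalTrack,
    SplicedRead,
    TranscriptModel,
)

import pandas as pd

DEFAULT_TREE = "((human:1,mouse:1):1,(gar:1,shark:1):1);"

BASES = "ACGT"
_OTHER = {b: [x for x in BASES if x != b] for b in BASES}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

STATES = ("closed", "poised", "active")


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the study-condition defaults."""

    seed: int = 0
    cne_length: int = 32
    tree: str = DEFAULT_TREE
    substitution_rate: float = 0.02  # per site, per branch
    n_compensatory_events: int = 0
    drop_c_in: tuple[str, ...] = ()  # teleost-like loss of the C copy
    no_assembly: tuple[str, ...] = ()
    omit_host_transcript_in: tuple[str, ...] = ()  # forces orientation inference
    # intron retention
    retention_fraction: float = 0.4
    junction_share: float = 0.2  # share of the retention mass given to junction reads
    cytosolic_depletion: float = 10.0  # fold depletion of intron mass in cytosol
    read_depth: int = 10000
    read_length: int = 50
    # CAGE / chromatin
    cage_spacing: int = 180  # bp between divergent dominant TSSs (~one nucleosome)
    cage_tag_count: int = 30
    signal_noise: float = 0.0  # sd of additive noise, as a fraction of peak amplitude
    # expression
    couplings: dict[str, float] = field(
        default_factory=lambda: {
            "HOXC11": 0.9,
            "HOXC12": 0.5,
            "HOXD11": -0.3,
            "HOXD12": -0.9,
        }
    )
    nc_coding_pair: tuple[str, str, float] = ("ncHOXD11", "HOXD11", 3.0)
    n_samples: int = 200
    zero_fraction: float = 0.3  # samples with the element feature zeroed

    def __post_init__(self) -> None:
        if self.cne_length < 8:
            raise ValueError("cne_length must be >= 8")
        if not (0.0 <= self.retention_fraction <= 1.0):
            raise ValueError("retention_fraction must be in [0, 1]")
        if not (0.0 <= self.junction_share <= 1.0):
            raise ValueError("junction_share must be in [0, 1]")
        for gene, c in self.couplings.items():
            if abs(c) > 1:
                raise ValueError(f"|coupling| must be <= 1, got {c} for {gene}")
        if not (0.0 <= self.zero_fraction <= 1.0):
            raise ValueError("zero_fraction must be in [0, 1]")
        if self.substitution_rate < 0 or self.substitution_rate > 0.75:
            raise ValueError("substitution_rate must be in [0, 0.75]")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, named random stream derived from the root seed."""
        key = int.from_bytes(stream.encode(), "little") % (2**31)
        return np.random.default_rng(np.random.SeedSequence((self.seed, key)))


@dataclass(frozen=True)
class PlantedEvent:
    """One compensatory double substitution planted on a tree branch."""

    branch: str
    c_column: int
    d_column: int
    event_class: str  # gain | retention | loss
    c_from: str
    c_to: str
    d_from: str
    d_to: str


@dataclass
class TruthLedger:
    """Everything that was planted, resolvable to scoreable coordinates."""

    cne_intervals: dict[tuple[str, str], GenomicInterval] = field(default_factory=dict)
    host_orientation: dict[tuple[str, str], str] = field(default_factory=dict)
    pairs: dict[str, OrientedPair] = field(default_factory=dict)
    events: list[PlantedEvent] = field(default_factory=list)
    dropped_c: tuple[str, ...] = ()
    no_assembly: tuple[str, ...] = ()
    retention_fraction: float | None = None
    tss_positions: dict[str, int] = field(default_factory=dict)
    chromatin_state: dict[str, str] = field(default_factory=dict)
    couplings: dict[str, float] = field(default_factory=dict)
    zeroed_samples: tuple[str, ...] = ()
    nc_coding_fold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-friendly view (section, key, value)."""
        rows = []
        for (sp, cl), iv in self.cne_intervals.items():
            rows.append(("cne_interval", f"{sp}/{cl}",
                         f"{iv.seq_id}:{iv.start}-{iv.end}({iv.strand})"))
        for (sp, cl), s in self.host_orientation.items():
            rows.append(("host_orientation", f"{sp}/{cl}", s))
        for ev in self.events:
            rows.append(("compensatory_event", ev.branch,
                         f"c{ev.c_column}:{ev.c_from}>{ev.c_to},"
                         f"d{ev.d_column}:{ev.d_from}>{ev.d_to},{ev.event_class}"))
        for sp in self.dropped_c:
            rows.append(("dropped_c", sp, "true"))
        if self.retention_fraction is not None:
            rows.append(("retention_fraction", "", str(self.retention_fraction)))
        for k, v in self.tss_positions.items():
            rows.append(("tss_position", k, str(v)))
        for k, v in self.chromatin_state.items():
            rows.append(("chromatin_state", k, v))
        for k, v in self.couplings.items():
            rows.append(("coupling", k, str(v)))
        for s in self.zeroed_samples:
            rows.append(("zeroed_sample", s, "true"))
        return pd.DataFrame(rows, columns=["section", "key", "value"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ancestral cluster
# ---------------------------------------------------------------------------

_CHROM_LEN = 6000
_GENE11 = (500, 1500)
_GENE12 = (4000, 5000)
_CNE_C_START = 2600  # C-cluster element start (plus-strand coordinates)
_HOST_C = (2500, 2900)  # intron-retained host transcript span (minus strand)
_HOST_C_EXON1 = (2500, 2560)
_HOST_C_EXON2 = (2700, 2900)
_HOST_D = (2300, 2800)  # single-exon host over the D element (minus strand)
_D_TSS_OFFSET = 55  # element starts 55 nt downstream of the host TSS


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _mrna(gene_id: str, seq_id: str, start: int, end: int) -> TranscriptModel:
    third = (end - start) // 3
    exons = (
        GenomicInterval(seq_id, start, start + third, "+"),
        GenomicInterval(seq_id, end - third, end, "+"),
    )
    return TranscriptModel(
        transcript_id=f"{gene_id}.t1",
        gene_id=gene_id,
        interval=GenomicInterval(seq_id, start, end, "+"),
        exons=exons,
        biotype="coding",
    )


@dataclass
class AncestralCluster:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    cne_interval: GenomicInterval
    cne_seq: str  # 5'->3' in the (minus-strand) host-transcript orientation
    ledger: TruthLedger


def simulate_ancestral_cluster(config: SimulationConfig) -> AncestralCluster:
    """One ancestral cluster: gene11, a planted element, gene12.

    The element sequence is recorded in host-transcript orientation (the
    host noncoding transcript runs antisense to gene11); the plus strand
    of the genome therefore carries its reverse complement.
    """
    gap = _GENE12[0] - _GENE11[1]
    if config.cne_length > gap - 200:
        raise ValueError(
            f"cluster too short: element of {config.cne_length} nt does not fit "
            f"between gene11 and gene12 (gap {gap} nt)"
        )
    rng = config.rng("ancestor")
    seq = list(_random_seq(rng, _CHROM_LEN))
    cne_seq = _random_seq(rng, config.cne_length)  # host (minus-strand) orientation
    start = _CNE_C_START
    end = start + config.cne_length
    seq[start:end] = revcomp(cne_seq)
    transcripts = [
        _mrna("gene11", "anc", *_GENE11),
        _mrna("gene12", "anc", *_GENE12),
    ]
    interval = GenomicInterval("anc", start, end, "-")
    ledger = TruthLedger(
        cne_intervals={("ancestor", "C/D"): interval},
        host_orientation={("ancestor", "C/D"): "-"},
    )
    return AncestralCluster(
        genome={"anc": "".join(seq)},
        transcripts=transcripts,
        cne_interval=interval,
        cne_seq=cne_seq,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# WGD + divergence along the species tree
# ---------------------------------------------------------------------------


@dataclass
class SimulatedClade:
    genomes: dict[str, dict[str, str]]  # species -> seq_id -> sequence
    annotations: dict[str, list[TranscriptModel]]
    pairs: dict[str, OrientedPair]
    ledger: TruthLedger
    tree: str


def _safe_event_branches(tree: dendropy.Tree) -> list[str]:
    """Branches on which a planted double substitution is recovered exactly.

    Parsimony places a single change unambiguously on a branch unless
    the derived clade covers half or more of the leaves while hanging
    directly off the root in the outgroup (last-child) position; those
    branches are excluded.
    """
    n = len(tree.leaf_nodes())
    safe = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        s = len(node.leaf_nodes())
        if 2 * s < n:
            safe.append(node._cid)
        elif 2 * s == n:
            parent = node.parent_node
            if parent.parent_node is not None or node is not parent.child_nodes()[-1]:
                safe.append(node._cid)
    return safe


def _plan_events(
    config: SimulationConfig,
    tree: dendropy.Tree,
    root_c: list[str],
    root_d: list[str],
    rng: np.random.Generator,
) -> list[PlantedEvent]:
    length = len(root_c)
    if config.n_compensatory_events > length // 2:
        raise ValueError(
            f"{config.n_compensatory_events} events exceed the "
            f"{length // 2} available column pairs"
        )
    safe = _safe_event_branches(tree)
    events = []
    used_cols: set[int] = set()
    classes = ["retention", "loss", "gain"]
    for i in range(config.n_compensatory_events):
        branch = safe[int(rng.integers(len(safe)))]
        while True:
            c_col = int(rng.integers(length))
            d_col = length - 1 - c_col
            if c_col != d_col and c_col not in used_cols and d_col not in used_cols:
                break
        used_cols.update({c_col, d_col})
        event_class = classes[i % len(classes)]
        c0 = root_c[c_col]
        c1 = _OTHER[c0][int(rng.integers(3))]
        if event_class == "retention":
            d0, d1 = _COMP[c0], _COMP[c1]
        elif event_class == "loss":
            d0 = _COMP[c0]
            choices = [b for b in BASES if b not in (d0, _COMP[c1])]
            d1 = choices[int(rng.integers(len(choices)))]
        else:  # gain: make the root non-complementary at this column first
            choices = [b for b in BASES if b not in (_COMP[c0], _COMP[c1])]
            d0 = choices[int(rng.integers(len(choices)))]
            root_d[length - 1 - c_col] = d0
            d1 = _COMP[c1]
        events.append(
            PlantedEvent(branch, c_col, d_col, event_class, c0, c1, d0, d1)
        )
    return events


def simulate_wgd_and_divergence(
    ancestor: AncestralCluster, config: SimulationConfig
) -> SimulatedClade:
    """Evolve the duplicated element down the species tree.

    The root D copy is the reverse complement of the root C copy (in
    host-transcript orientation), so complementarity is perfect at the
    root.  Each branch applies Jukes-Cantor substitutions independently
    to both sides at ``substitution_rate`` per site; planted compensatory
    events are simultaneous double substitutions at paired columns on
    ledger-recorded branches (those columns are shielded from random
    substitution so the planted before/after states are exact).
    """
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    _label_tree(tree)
    rng = config.rng("divergence")
    length = config.cne_length
    root_c = list(ancestor.cne_seq)
    root_d = list(revcomp(ancestor.cne_seq))
    events = _plan_events(config, tree, root_c, root_d, rng)
    events_by_branch: dict[str, list[PlantedEvent]] = {}
    shielded: set[tuple[str, int]] = set()
    for ev in events:
        events_by_branch.setdefault(ev.branch, []).append(ev)
        shielded.add(("C", ev.c_column))
        shielded.add(("D", ev.d_column))

    # evolve pairs down the tree
    node_pairs: dict[str, tuple[list[str], list[str]]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_pairs[node._cid] = (root_c, root_d)
            continue
        pc, pd_ = node_pairs[node.parent_node._cid]
        c, d = list(pc), list(pd_)
        for side, seq in (("C", c), ("D", d)):
            for col in range(length):
                if (side, col) in shielded:
                    continue
                if rng.random() < config.substitution_rate:
                    seq[col] = _OTHER[seq[col]][int(rng.integers(3))]
        for ev in events_by_branch.get(node._cid, ()):
            c[ev.c_column] = ev.c_to
            d[ev.d_column] = ev.d_to
        node_pairs[node._cid] = (c, d)

    species = [n._cid for n in tree.leaf_node_iter()]
    genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, list[TranscriptModel]] = {}
    pairs: dict[str, OrientedPair] = {}
    ledger = TruthLedger(
        events=list(events),
        dropped_c=tuple(config.drop_c_in),
        no_assembly=tuple(config.no_assembly),
    )
    for sp in species:
        if sp in config.no_assembly:
            continue
        seq_c, seq_d = ("".join(s) for s in node_pairs[sp])
        sp_rng = config.rng(f"genome:{sp}")
        chr_c, chr_d = f"{sp}_chrC", f"{sp}_chrD"
        host_present = sp not in config.omit_host_transcript_in
        provenance = "annotated" if host_present else "inferred"
        genome: dict[str, str] = {}
        annotation: list[TranscriptModel] = []

        # --- C cluster ---
        c_seq = list(_random_seq(sp_rng, _CHROM_LEN))
        if sp not in config.drop_c_in:
            start, end = _CNE_C_START, _CNE_C_START + length
            c_seq[start:end] = revcomp(seq_c)  # host transcript on minus strand
            ledger.cne_intervals[(sp, "C")] = GenomicInterval(chr_c, start, end, "-")
            ledger.host_orientation[(sp, "C")] = "-"
        genome[chr_c] = "".join(c_seq)
        annotation.append(_mrna(f"gene_c11_{sp}", chr_c, *_GENE11))
        annotation.append(_mrna(f"gene_c12_{sp}", chr_c, *_GENE12))
        if host_present and sp not in config.drop_c_in:
            annotation.append(
                TranscriptModel(
                    transcript_id=f"hostC_{sp}.t1",
                    gene_id=f"hostC_{sp}",
                    interval=GenomicInterval(chr_c, *_HOST_C, "-"),
                    exons=(
                        GenomicInterval(chr_c, *_HOST_C_EXON1, "-"),
                        GenomicInterval(chr_c, *_HOST_C_EXON2, "-"),
                    ),
                    biotype="noncoding",
                )
            )

        # --- D cluster ---
        d_seq = list(_random_seq(sp_rng, _CHROM_LEN))
        d_tss = _HOST_D[1]  # minus-strand TSS (rightmost base of the host span)
        d_end = d_tss - _D_TSS_OFFSET
        d_start = d_end - length
        d_seq[d_start:d_end] = revcomp(seq_d)  # host transcript on minus strand
        genome[chr_d] = "".join(d_seq)
        ledger.cne_intervals[(sp, "D")] = GenomicInterval(chr_d, d_start, d_end, "-")
        ledger.host_orientation[(sp, "D")] = "-"
        annotation.append(_mrna(f"gene_d11_{sp}", chr_d, *_GENE11))
        annotation.append(_mrna(f"gene_d12_{sp}", chr_d, *_GENE12))
        if host_present:
            annotation.append(
                TranscriptModel(
                    transcript_id=f"hostD_{sp}.t1",
                    gene_id=f"hostD_{sp}",
                    interval=GenomicInterval(chr_d, *_HOST_D, "-"),
                    exons=(GenomicInterval(chr_d, *_HOST_D, "-"),),
                    biotype="noncoding",
                )
            )

        genomes[sp] = genome
        annotations[sp] = annotation
        if sp not in config.drop_c_in:
            pairs[sp] = OrientedPair(sp, seq_c, seq_d, provenance, provenance)
            ledger.pairs[sp] = pairs[sp]
    return SimulatedClade(
        genomes=genomes,
        annotations=annotations,
        pairs=pairs,
        ledger=ledger,
        tree=config.tree,
    )


# ---------------------------------------------------------------------------
# Intron-retained read libraries
# ---------------------------------------------------------------------------

LIBRARIES = ("whole_cell", "nuclear", "cytosolic")


def _exonic_read(
    model: TranscriptModel, tstart: int, read_length: int
) -> tuple[GenomicInterval, ...]:
    """Map a transcript-coordinate window onto genomic exon blocks."""
    blocks = []
    remaining = read_length
    offset = tstart
    for ex in model.exons:
        w = ex.width
        if offset >= w:
            offset -= w
            continue
        take = min(remaining, w - offset)
        blocks.append(
            GenomicInterval(ex.seq_id, ex.start + offset, ex.start + offset + take, ex.strand)
        )
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read runs past the transcript 3' end")
    return tuple(blocks)


def simulate_intron_retained_reads(
    model: TranscriptModel, config: SimulationConfig
) -> dict[str, list[SplicedRead]]:
    """Reads for whole-cell, nuclear and cytosolic libraries.

    Per library, each read's category is multinomial: the combined
    intron + junction mass equals ``retention_fraction`` in whole-cell
    and nuclear libraries and ``retention_fraction / cytosolic_depletion``
    in the cytosolic library; placement is uniform within the category.
    """
    introns = model.introns
    if not introns:
        raise ValueError(f"transcript {model.transcript_id} has no intron")
    rl = config.read_length
    exonic_len = sum(e.width for e in model.exons)
    if exonic_len < rl:
        raise ValueError("read_length exceeds exonic length")
    wide_introns = [i for i in introns if i.width >= rl]
    if not wide_introns:
        raise ValueError("no intron long enough to host a read")
    rng = config.rng("reads")
    out: dict[str, list[SplicedRead]] = {}
    for lib in LIBRARIES:
        r = config.retention_fraction
        if lib == "cytosolic":
            r = r / config.cytosolic_depletion
        p = [1 - r, r * (1 - config.junction_share), r * config.junction_share]
        counts = rng.multinomial(config.read_depth, p)
        reads: list[SplicedRead] = []
        idx = 0
        for _ in range(counts[0]):  # exonic (possibly splice-spanning)
            tstart = int(rng.integers(exonic_len - rl + 1))
            reads.append(SplicedRead(f"{lib}_{idx}", _exonic_read(model, tstart, rl)))
            idx += 1
        weights = np.array([i.width - rl + 1 for i in wide_introns], dtype=float)
        weights /= weights.sum()
        for _ in range(counts[1]):  # fully intronic
            intron = wide_introns[int(rng.choice(len(wide_introns), p=weights))]
            start = intron.start + int(rng.integers(intron.width - rl + 1))
            reads.append(
                SplicedRead(
                    f"{lib}_{idx}",
                    (GenomicInterval(intron.seq_id, start, start + rl, model.strand),),
                )
            )
            idx += 1
        boundaries = []
        for intron, prev_ex, next_ex in zip(introns, model.exons, model.exons[1:]):
            boundaries.append((intron.start, prev_ex.width, intron.width))  # exon|intron
            boundaries.append((intron.end, intron.width, next_ex.width))  # intron|exon
        for _ in range(counts[2]):  # boundary-spanning
            b, left_w, right_w = boundaries[int(rng.integers(len(boundaries)))]
            lo = max(1, rl - left_w)
            hi = min(rl - 1, right_w)
            over = int(rng.integers(lo, hi + 1))
            reads.append(
                SplicedRead(
                    f"{lib}_{idx}",
                    (GenomicInterval(model.seq_id, b - (rl - over), b + over, model.strand),),
                )
            )
            idx += 1
        order = rng.permutation(len(reads))
        out[lib] = [reads[i] for i in order]
    return out


def example_retained_transcript(seq_id: str = "chr1") -> TranscriptModel:
    """A small two-exon noncoding transcript with one retainable intron."""
    return TranscriptModel(
        transcript_id="host.t1",
        gene_id="host",
        interval=GenomicInterval(seq_id, 1000, 2000, "-"),
        exons=(
            GenomicInterval(seq_id, 1000, 1300, "-"),
            GenomicInterval(seq_id, 1700, 2000, "-"),
        ),
        biotype="noncoding",
    )


# ---------------------------------------------------------------------------
# CAGE + chromatin signals
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryScenario:
    element: GenomicInterval
    state: str
    ctss: list[CtssRecord]
    promoter_ctss: list[CtssRecord]
    tracks: dict[str, SignalTrack]
    truth: dict


def _gaussian(x: np.ndarray, center: float, amp: float, sd: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - center) / sd) ** 2)


def simulate_cage_and_signals(
    element: GenomicInterval,
    state: str,
    config: SimulationConfig,
    promoter_position: int | None = None,
    promoter_coupling: float = 0.9,
) -> RegulatoryScenario:
    """CTSS records and chromatin-signal tracks for one element and state.

    active: divergent CTSS clusters whose dominant positions flank the
    element exactly ``cage_spacing`` bp apart, open chromatin, bimodal
    H3K4me1, high H3K27ac.  poised: open chromatin, bimodal H3K4me1,
    broad H3K27me3 with a central dip, p300, no CTSS.  closed: baseline
    noise only, no CTSS.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    rng = config.rng(f"signals:{state}:{element.start}")
    center = (element.start + element.end) // 2
    region_start = max(0, center - 5200)
    region_end = center + 5200
    x = np.arange(region_start, region_end)
    baseline = 0.1

    profiles = {m: np.full(len(x), baseline) for m in ("dhs", "h3k4me1", "h3k27ac", "h3k27me3", "p300")}
    amplitudes = {m: baseline for m in profiles}
    if state in ("active", "poised"):
        profiles["dhs"] += _gaussian(x, center, 8.0, 80.0)
        amplitudes["dhs"] = 8.0
        for side in (-1, 1):
            profiles["h3k4me1"] += _gaussian(x, center + side * 250, 8.0, 120.0)
        amplitudes["h3k4me1"] = 8.0
    if state == "active":
        for side in (-1, 1):
            profiles["h3k27ac"] += _gaussian(x, center + side * 250, 6.0, 120.0)
        amplitudes["h3k27ac"] = 6.0
        profiles["p300"] += _gaussian(x, center, 3.0, 100.0)
        amplitudes["p300"] = 3.0
    if state == "poised":
        plateau = 5.0 * np.clip((1000.0 - np.abs(x - center)) / 200.0, 0.0, 1.0)
        dip = 1.0 - 0.8 * np.exp(-0.5 * ((x - center) / 60.0) ** 2)
        profiles["h3k27me3"] += plateau * dip
        amplitudes["h3k27me3"] = 5.0
        profiles["p300"] += _gaussian(x, center, 4.0, 100.0)
        amplitudes["p300"] = 4.0

    if config.signal_noise > 0:
        for mark in profiles:
            noise = rng.normal(0.0, config.signal_noise * amplitudes[mark], len(x))
            profiles[mark] = np.maximum(profiles[mark] + noise, 0.0)

    tracks = {
        mark: SignalTrack(element.seq_id, dict(zip(x.tolist(), prof.tolist())))
        for mark, prof in profiles.items()
    }

    ctss: list[CtssRecord] = []
    truth: dict = {"state": state}
    if state == "active":
        minus_dom = center - config.cage_spacing // 2
        plus_dom = minus_dom + config.cage_spacing
        amp = config.cage_tag_count
        for pos, count, strand in (
            (minus_dom, amp, "-"),
            (minus_dom - 3, max(1, amp // 4), "-"),
            (minus_dom + 2, max(1, amp // 5), "-"),
            (plus_dom, amp, "+"),
            (plus_dom - 2, max(1, amp // 4), "+"),
            (plus_dom + 3, max(1, amp // 5), "+"),
        ):
            if config.signal_noise > 0:
                count = max(1, int(rng.poisson(count)))
            ctss.append(
                CtssRecord(GenomicInterval(element.seq_id, pos, pos + 1, strand), count)
            )
        truth["minus_dominant"] = minus_dom
        truth["plus_dominant"] = plus_dom
        truth["spacing"] = config.cage_spacing
    promoter_ctss: list[CtssRecord] = []
    if promoter_position is not None and state == "active":
        count = max(1, round(abs(promoter_coupling) * config.cage_tag_count))
        promoter_ctss.append(
            CtssRecord(
                GenomicInterval(element.seq_id, promoter_position, promoter_position + 1, "+"),
                count,
            )
        )
    return RegulatoryScenario(
        element=element,
        state=state,
        ctss=ctss,
        promoter_ctss=promoter_ctss,
        tracks=tracks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Expression matrix with planted couplings
# ---------------------------------------------------------------------------

ELEMENT_FEATURE = "CNE"


def simulate_expression_matrix(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TruthLedger]:
    """TPM matrix with a latent element activity and planted couplings.

    The element's log2 activity is Gaussian (so TPM is log-normal); each
    target gene's log2 expression is coupling x latent + independent
    Gaussian noise, exponentiated to TPM.  A ``zero_fraction`` of
    samples have the element feature zeroed (non-expressing cell types).
    The noncoding/coding promoter pair is planted at a fixed fold so the
    noncoding side inherits the coding gene's coupling.
    """
    if config.n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = config.rng("expression")
    n = config.n_samples
    samples = [f"s{i:04d}" for i in range(n)]
    z = rng.normal(0.0, 1.0, n)
    data: dict[str, np.ndarray] = {}
    data[ELEMENT_FEATURE] = np.power(2.0, 4.0 + 1.5 * z)
    for gene, rho in config.couplings.items():
        eps = rng.normal(0.0, 1.0, n)
        log2g = 3.0 + 1.5 * (rho * z + math.sqrt(1.0 - rho * rho) * eps)
        data[gene] = np.power(2.0, log2g)
    nc_id, coding_id, fold = config.nc_coding_pair
    if coding_id not in data:
        eps = rng.normal(0.0, 1.0, n)
        data[coding_id] = np.power(2.0, 3.0 + 1.5 * eps)
    data[nc_id] = data[coding_id] * fold * np.power(2.0, rng.normal(0.0, 0.15, n))

    n_zero = int(round(config.zero_fraction * n))
    zero_idx = rng.choice(n, size=n_zero, replace=False)
    data[ELEMENT_FEATURE] = data[ELEMENT_FEATURE].copy()
    data[ELEMENT_FEATURE][zero_idx] = 0.0

    df = pd.DataFrame(data, index=samples).T
    matrix = ExpressionMatrix(df)
    ledger = TruthLedger(
        couplings=dict(config.couplings),
        zeroed_samples=tuple(samples[i] for i in sorted(zero_idx)),
        nc_coding_fold=fold,
    )
    return matrix, ledger
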