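"""Orientation-aware complementarity and compensatory-substitution analysis.

The two paralogous copies of the element are written 5'->3' in the
orientation of their host transcripts.  Two RNAs hybridize antiparallel,
so column ``i`` of the C-side sequence is tested against column
``L-1-i`` of the D-side sequence; a column is complementary when the two
bases form a Watson-Crick pair (A:T, C:G at the DNA level; G:T wobble is
off by default).

Compensatory substitutions are detected on a species tree: ancestral
states for every column of both sides are reconstructed by Fitch
parsimony, each branch whose child state differs from its parent state
is a substitution event, and a branch carrying events on *both* sides at
a complementarity-paired column pair is a compensatory call, classified
as gain / retention / loss of complementarity by comparing the paired
states before and after the branch.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import dendropy

from .io_formats import GenomicInterval, TranscriptModel

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence over {A,C,G,T,N} (case kept upper)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from exc


def is_wc_pair(a: str, b: str, allow_wobble: bool = False) -> bool:
    """True if bases a and b can pair (Watson-Crick; optionally G:T wobble)."""
    a, b = a.upper(), b.upper()
    if _COMPLEMENT.get(a) == b and a != "N":
        return True
    if allow_wobble and {a, b} == {"G", "T"}:
        return True
    return False


@dataclass(frozen=True)
class OrientedPair:
    """Paralog element sequences, each 5'->3' in host-transcript orientation."""

    species: str
    seq_c: str
    seq_d: str
    provenance_c: str = "annotated"  # annotated | inferred
    provenance_d: str = "annotated"

    def __post_init__(self) -> None:
        if len(self.seq_c) != len(self.seq_d):
            raise ValueError(
                f"{self.species}: side lengths differ "
                f"({len(self.seq_c)} vs {len(self.seq_d)})"
            )
        for seq in (self.seq_c, self.seq_d):
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(f"{self.species}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq_c)


@dataclass(frozen=True)
class ComplementarityProfile:
    """Per-column complementarity flags and the overall fraction."""

    columns: tuple[bool, ...]
    score: float


@dataclass(frozen=True)
class SubstitutionEvent:
    branch: str  # id of the child node of the edge
    side: str  # C | D
    column: int
    from_base: str
    to_base: str


@dataclass(frozen=True)
class CompensatoryCall:
    branch: str
    c_column: int
    d_column: int
    call_class: str  # gain | retention | loss
    events: tuple[SubstitutionEvent, SubstitutionEvent]


def complementarity_profile(pair: OrientedPair, allow_wobble: bool = False) -> ComplementarityProfile:
    """Column-wise antiparallel complementarity of a pair.

    Column i of seq_c pairs with column L-1-i of seq_d; the score equals
    the fraction of complementary columns (identically, the identity of
    seq_c against revcomp(seq_d)).
    """
    length = len(pair)
    cols = tuple(
        is_wc_pair(pair.seq_c[i], pair.seq_d[length - 1 - i], allow_wobble)
        for i in range(length)
    )
    return ComplementarityProfile(cols, sum(cols) / length)


def infer_orientation(
    hit_interval: GenomicInterval,
    transcripts: list[TranscriptModel],
    gene11_pattern: str,
    flank_rule: str = "antisense_gene11",
) -> tuple[str, str]:
    """Host-transcript strand of an element, with provenance.

    If a stranded transcript overlaps the element, its strand is used
    (provenance ``annotated``).  Otherwise the configured flank rule
    applies (default: antisense to the strand of the cluster's gene11,
    identified by substring match of ``gene11_pattern`` on gene ids),
    with provenance ``inferred``.
    """
    overlapping = [
        t for t in transcripts
        if t.interval.overlaps(hit_interval) and t.strand in ("+", "-")
    ]
    strands = {t.strand for t in overlapping}
    if len(strands) > 1:
        ids = sorted(t.transcript_id for t in overlapping)
        raise ValueError(f"transcripts on both strands overlap the element: {ids}")
    if overlapping:
        return overlapping[0].strand, "annotated"
    if flank_rule != "antisense_gene11":
        raise ValueError(f"unknown flank rule {flank_rule!r}")
    pattern = gene11_pattern.lower()
    gene11 = [
        t for t in transcripts
        if pattern in t.gene_id.lower() and t.seq_id == hit_interval.seq_id
    ]
    if not gene11:
        raise ValueError(
            f"no transcript and no gene matching {gene11_pattern!r} on "
            f"{hit_interval.seq_id}; cannot infer orientation"
        )
    g_strand = gene11[0].strand
    return ("-" if g_strand == "+" else "+"), "inferred"


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


def _label_tree(tree: dendropy.Tree) -> None:
    """Give every unnamed internal node a deterministic postorder label."""
    counter = 0
    for node in tree.postorder_node_iter():
        if node.taxon is not None:
            node._cid = node.taxon.label
        elif node.label:
            node._cid = node.label
        else:
            counter += 1
            node._cid = f"node{counter}"


def fitch_states(
    tree: dendropy.Tree, leaf_states: dict[str, str]
) -> dict[str, str]:
    """Fitch parsimony ancestral reconstruction for one character.

    ``leaf_states`` maps leaf label -> state (single character).  Returns
    node id -> assigned state for every node (leaves keep their observed
    state).  Tie handling: a non-root node keeps its parent's state when
    that state is in its Fitch set; the root prefers the state held by
    the majority of leaves, residual ties go to the state present in the
    root's last-listed child subtree (the conventional outgroup
    position), and any remaining tie is broken alphabetically.
    Multifurcating trees are accepted (the set operations generalize).
    """
    down: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = leaf_states.get(node._cid)
            if state is None:
                raise ValueError(f"leaf {node._cid!r} has no observed state")
            down[id(node)] = frozenset(state)
        else:
            child_sets = [down[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*child_sets)
            down[id(node)] = inter if inter else frozenset.union(*child_sets)

    leaf_counts = Counter(leaf_states.values())
    assigned: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        options = down[id(node)]
        if node.parent_node is None:
            if len(options) == 1:
                state = next(iter(options))
            else:
                best = max(leaf_counts[s] for s in options)
                majority = sorted(s for s in options if leaf_counts[s] == best)
                if len(majority) == 1:
                    state = majority[0]
                else:
                    last_child = node.child_nodes()[-1]
                    in_last = sorted(set(majority) & down[id(last_child)])
                    state = in_last[0] if in_last else majority[0]
        else:
            parent_state = assigned[node.parent_node._cid]
            if parent_state in options:
                state = parent_state
            else:
                best = max(leaf_counts[s] for s in options)
                state = sorted(s for s in options if leaf_counts[s] == best)[0]
        assigned[node._cid] = state
    return assigned


def _load_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        t = dendropy.Tree.get(data=tree, schema="newick")
    _label_tree(t)
    return t


@dataclass
class CompensatoryResult:
    events: list[SubstitutionEvent]
    calls: list[CompensatoryCall]
    ancestral_c: dict[str, str] = field(default_factory=dict)  # node id -> sequence
    ancestral_d: dict[str, str] = field(default_factory=dict)
    multifurcations: int = 0


def detect_compensatory_events(
    pairs: dict[str, OrientedPair],
    tree: str | dendropy.Tree,
    allow_wobble: bool = False,
) -> CompensatoryResult:
    """Map substitutions onto the tree and call compensatory column pairs.

    Every tree leaf must have an OrientedPair and all pairs must share
    one length.  A compensatory call is a branch carrying substitution
    events on both sides at columns (i, L-1-i), classified by the
    complementarity of the paired bases before vs after the branch.
    """
    t = _load_tree(tree)
    leaves = [n._cid for n in t.leaf_node_iter()]
    missing = [s for s in leaves if s not in pairs]
    if missing:
        raise ValueError(f"no oriented pair for tree leaves: {missing}")
    lengths = {len(p) for p in pairs.values()}
    if len(lengths) != 1:
        raise ValueError(f"pairs have unequal lengths: {sorted(lengths)}")
    length = lengths.pop()
    multi = sum(1 for n in t.preorder_node_iter() if len(n.child_nodes()) > 2)

    # Reconstruct every column of both sides.
    node_ids = [n._cid for n in t.preorder_node_iter()]
    anc: dict[str, dict[str, list[str]]] = {
        side: {nid: [] for nid in node_ids} for side in ("C", "D")
    }
    for side in ("C", "D"):
        for col in range(length):
            leaf_states = {
                sp: (pairs[sp].seq_c if side == "C" else pairs[sp].seq_d)[col]
                for sp in leaves
            }
            assigned = fitch_states(t, leaf_states)
            for nid in node_ids:
                anc[side][nid].append(assigned[nid])

    events: list[SubstitutionEvent] = []
    by_branch: dict[str, dict[str, dict[int, SubstitutionEvent]]] = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        nid, pid = node._cid, node.parent_node._cid
        for side in ("C", "D"):
            for col in range(length):
                frm, to = anc[side][pid][col], anc[side][nid][col]
                if frm != to:
                    ev = SubstitutionEvent(nid, side, col, frm, to)
                    events.append(ev)
                    by_branch.setdefault(nid, {"C": {}, "D": {}})[side][col] = ev

    calls: list[CompensatoryCall] = []
    for node in t.preorder_node_iter():
        if node.parent_node is None or node._cid not in by_branch:
            continue
        nid, pid = node._cid, node.parent_node._cid
        branch_events = by_branch[nid]
        for c_col, ev_c in sorted(branch_events["C"].items()):
            d_col = length - 1 - c_col
            ev_d = branch_events["D"].get(d_col)
            if ev_d is None:
                continue
            before = is_wc_pair(anc["C"][pid][c_col], anc["D"][pid][d_col], allow_wobble)
            after = is_wc_pair(anc["C"][nid][c_col], anc["D"][nid][d_col], allow_wobble)
            if before and after:
                call_class = "retention"
            elif before and not after:
                call_class = "loss"
            elif not before and after:
                call_class = "gain"
            else:
                continue  # non-complementary before and after: not compensatory
            calls.append(CompensatoryCall(nid, c_col, d_col, call_class, (ev_c, ev_d)))

    return CompensatoryResult(
        events=events,
        calls=calls,
        ancestral_c={nid: "".join(anc["C"][nid]) for nid in node_ids},
        ancestral_d={nid: "".join(anc["D"][nid]) for nid in node_ids},
        multifurcations=multi,
    )


def parsimony_score(tree: str | dendropy.Tree, leaf_states: dict[str, str]) -> int:
    """Number of state changes implied by the Fitch assignment for one character."""
    t = _load_tree(tree)
    assigned = fitch_states(t, leaf_states)
    changes = 0
    for node in t.preorder_node_iter():
        if node.parent_node is not None and assigned[node._cid] != assigned[node.parent_node._cid]:
            changes += 1
    return changes
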