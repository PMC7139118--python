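"""Complementarity scoring, orientation inference, Fitch-based event detection."""

import itertools

import dendropy
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cneduo.complementarity import (
    OrientedPair,
    complementarity_profile,
    detect_compensatory_events,
    fitch_states,
    infer_orientation,
    parsimony_score,
    revcomp,
    _label_tree,
)
from cneduo.io_formats import GenomicInterval, TranscriptModel
from cneduo.synthetic import (
    SimulationConfig,
    simulate_ancestral_cluster,
    simulate_wgd_and_divergence,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestRevcomp:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("NGA", "TCN")]
    )
    def test_examples(self, seq, expected):
        assert revcomp(seq) == expected

    @settings(deadline=None)
    @given(dna)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


class TestProfile:
    def test_perfect_complement_scores_one(self):
        pair = OrientedPair("x", "ACGTACGTAC", revcomp("ACGTACGTAC"))
        prof = complementarity_profile(pair)
        assert prof.score == 1.0 and all(prof.columns)

    def test_self_identical_homopolymer_scores_zero(self):
        prof = complementarity_profile(OrientedPair("x", "AAAA", "AAAA"))
        assert prof.score == 0.0 and not any(prof.columns)

    def test_six_mer_worked_example(self):
        """seq_c=ACGTAC vs seq_d=GTACGA: 5/6 complementary, only column 0 not."""
        pair = OrientedPair("x", "ACGTAC", "GTACGA")
        prof = complementarity_profile(pair)
        # brute-force per-column oracle
        expected = [
            {(a, b)} <= {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
            for a, b in zip("ACGTAC", reversed("GTACGA"))
        ]
        assert list(prof.columns) == expected
        assert prof.score == pytest.approx(5 / 6)
        assert prof.columns[0] is False and all(prof.columns[1:])

    @settings(deadline=None)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=40))
    def test_revcomp_partner_always_scores_one(self, seq):
        assert complementarity_profile(OrientedPair("x", seq, revcomp(seq))).score == 1.0

    @settings(deadline=None)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=40),
           st.text(alphabet="ACGT", min_size=4, max_size=40))
    def test_symmetry(self, a, b):
        if len(a) != len(b):
            b = (b * len(a))[: len(a)]
        s1 = complementarity_profile(OrientedPair("x", a, b)).score
        s2 = complementarity_profile(OrientedPair("x", b, a)).score
        assert s1 == pytest.approx(s2)

    def test_score_invariant_under_paired_complement_preserving_substitution(self):
        seq = "ACGTACGTACGT"
        pair = OrientedPair("x", seq, revcomp(seq))
        base = complementarity_profile(pair).score
        # substitute column 2 on C and the paired column on D, keeping pairing
        c = list(pair.seq_c)
        d = list(pair.seq_d)
        c[2] = "G"
        d[len(seq) - 3] = "C"
        assert complementarity_profile(OrientedPair("x", "".join(c), "".join(d))).score == base

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            OrientedPair("x", "ACGT", "ACG")

    def test_wobble_flag(self):
        pair = OrientedPair("x", "G", "G")  # G:G never pairs; G:T only with wobble
        assert complementarity_profile(pair).score == 0.0
        wob = OrientedPair("x", "G", "T")
        assert complementarity_profile(wob, allow_wobble=False).score == 0.0
        assert complementarity_profile(wob, allow_wobble=True).score == 1.0


class TestOrientation:
    def _tx(self, strand, start=100, end=300, gene="hostX", seq="chr1"):
        return TranscriptModel(
            f"{gene}.t1", gene, GenomicInterval(seq, start, end, strand),
            (GenomicInterval(seq, start, end, strand),), "noncoding",
        )

    def test_overlapping_transcript_is_annotated(self):
        hit = GenomicInterval("chr1", 150, 182)
        strand, prov = infer_orientation(hit, [self._tx("-")], "c11")
        assert (strand, prov) == ("-", "annotated")

    def test_flank_rule_antisense_to_gene11(self):
        hit = GenomicInterval("chr1", 500, 532)
        gene11 = self._tx("+", 100, 300, gene="gene_c11")
        strand, prov = infer_orientation(hit, [gene11], "c11")
        assert (strand, prov) == ("-", "inferred")

    def test_both_strand_overlap_is_error(self):
        hit = GenomicInterval("chr1", 150, 182)
        with pytest.raises(ValueError, match="both strands"):
            infer_orientation(hit, [self._tx("-"), self._tx("+", gene="other")], "c11")

    def test_ledger_orientation_recovered_in_noiseless_simulation(self):
        cfg = SimulationConfig(seed=4, substitution_rate=0.0,
                               omit_host_transcript_in=("mouse",))
        clade = simulate_wgd_and_divergence(simulate_ancestral_cluster(cfg), cfg)
        for (sp, cl), iv in clade.ledger.cne_intervals.items():
            pattern = "c11" if cl == "C" else "d11"
            strand, prov = infer_orientation(iv, clade.annotations[sp], pattern)
            assert strand == clade.ledger.host_orientation[(sp, cl)]
            assert prov == ("inferred" if sp == "mouse" else "annotated")


def exhaustive_min_changes(tree_str: str, leaf_states: dict[str, str]) -> int:
    """Oracle: enumerate all internal-state assignments, minimize changes."""
    tree = dendropy.Tree.get(data=tree_str, schema="newick")
    _label_tree(tree)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    states = sorted(set(leaf_states.values()))
    best = None
    for combo in itertools.product(states, repeat=len(internal)):
        assign = {n._cid: s for n, s in zip(internal, combo)}
        assign.update(leaf_states)
        changes = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                changes += assign[node._cid] != assign[node.parent_node._cid]
        best = changes if best is None else min(best, changes)
    return best


class TestFitch:
    TREES = [
        "((A,B),(C,D));",
        "(((A,B),C),(D,E));",
        "((A,(B,(C,D))),(E,F));",
        "((A,B,C),(D,E));",  # multifurcation
    ]

    @pytest.mark.parametrize("tree", TREES)
    @pytest.mark.parametrize("pattern", ["AAAA", "AGAG", "AACC", "ACGT", "GGGA", "TTAA"])
    def test_matches_exhaustive_enumeration(self, tree, pattern):
        leaves = [c for c in "ABCDEF" if c + "," in tree or c + ")" in tree]
        leaf_states = {lf: pattern[i % len(pattern)] for i, lf in enumerate(leaves)}
        assert parsimony_score(tree, leaf_states) == exhaustive_min_changes(tree, leaf_states)

    def test_identical_leaves_no_events(self):
        pairs = {sp: OrientedPair(sp, "ACGTACGT", revcomp("ACGTACGT"))
                 for sp in ["A", "B", "C", "D"]}
        res = detect_compensatory_events(pairs, "((A,B),(C,D));")
        assert res.events == [] and res.calls == []

    def test_four_taxon_retention_call_on_shared_ancestor_branch(self):
        """A->G on C side (col 3) and T->C on D side (col L-4) in leaves A,B only:
        one retention call on the (A,B)-ancestor branch."""
        base_c = "TTTTTTATTTTT"  # column 3 = A
        base_d = revcomp(base_c)  # perfect complement; d column L-4 pairs with c column 3
        L = len(base_c)
        derived_c = base_c[:3] + "G" + base_c[4:]
        d_col = L - 4
        derived_d = base_d[:d_col] + "C" + base_d[d_col + 1:]
        pairs = {
            "A": OrientedPair("A", derived_c, derived_d),
            "B": OrientedPair("B", derived_c, derived_d),
            "C": OrientedPair("C", base_c, base_d),
            "D": OrientedPair("D", base_c, base_d),
        }
        res = detect_compensatory_events(pairs, "((A,B),(C,D));")
        assert len(res.calls) == 1
        call = res.calls[0]
        assert call.call_class == "retention"
        assert call.c_column == 3 and call.d_column == L - 4
        # the branch is the ancestor of exactly {A,B}
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        _label_tree(tree)
        ab = tree.mrca(taxon_labels=["A", "B"])
        assert call.branch == ab._cid

    def test_missing_leaf_pair_is_error(self):
        pairs = {"A": OrientedPair("A", "ACGT", revcomp("ACGT"))}
        with pytest.raises(ValueError, match="no oriented pair"):
            detect_compensatory_events(pairs, "((A,B),(C,D));")

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_planted_events_recovered_exactly_in_noiseless_limit(self, k):
        cfg = SimulationConfig(seed=20 + k, substitution_rate=0.0, n_compensatory_events=k)
        clade = simulate_wgd_and_divergence(simulate_ancestral_cluster(cfg), cfg)
        res = detect_compensatory_events(clade.pairs, clade.tree)
        truth = {(e.branch, e.c_column, e.d_column, e.event_class)
                 for e in clade.ledger.events}
        found = {(c.branch, c.c_column, c.d_column, c.call_class) for c in res.calls}
        assert len(truth) == k
        assert found == truth
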