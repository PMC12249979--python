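import itertools

import numpy as np
import pytest

from raresyn.ancestry import (
    AA20,
    call_apomorphies,
    discrete_gamma_rates,
    f81_transition_matrix,
    reconstruct_states,
)
from raresyn.io_core import Alignment, tree_from_string


def enumeration_posteriors(tree, aln, pi, alpha=None, ncat=4):
    """Marginal posteriors by explicit summation over all internal-node
    labelings, independent of the message-passing implementation."""
    rates = discrete_gamma_rates(alpha, ncat) if alpha else np.array([1.0])
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    post = {}
    for col in range(aln.length):
        acc = {id(n): np.zeros(20) for n in internal}
        tot = 0.0
        for rate in rates:
            M = {
                id(n): f81_transition_matrix(n.edge.length or 0.0, pi, rate)
                for n in nodes
            }
            for assign in itertools.product(range(20), repeat=len(internal)):
                amap = dict(zip([id(n) for n in internal], assign))
                p = pi[amap[id(tree.seed_node)]] / len(rates)
                for n in nodes:
                    if n is tree.seed_node:
                        continue
                    ps = amap[id(n.parent_node)]
                    if n.is_leaf():
                        ch = aln.row(n.taxon.label)[col]
                        if ch in AA20:
                            p *= M[id(n)][ps, AA20.index(ch)]
                    else:
                        p *= M[id(n)][ps, amap[id(n)]]
                tot += p
                for n in internal:
                    acc[id(n)][amap[id(n)]] += p
        for n in internal:
            post.setdefault(id(n), []).append(acc[id(n)] / tot)
    return {k: np.array(v) for k, v in post.items()}


UNIFORM = np.full(20, 0.05)


class TestMLMarginal:
    def test_invariant_column_is_certain_everywhere(self):
        # short branches: hidden double substitutions are negligible and the
        # shared state is recovered with posterior ~1 at every node
        tree = tree_from_string("((A:0.05,B:0.05):0.05,C:0.05);")
        aln = Alignment("g", ["A", "B", "C"], ["L", "L", "L"])
        st = reconstruct_states(tree, aln, "ml-marginal", frequencies=UNIFORM)
        for node, i in st.node_index.items():
            if not node.is_leaf():
                assert st.posteriors[i, 0, AA20.index("L")] > 0.999
                assert st.assigned_state(node, 0) == "L"

    def test_majority_state_wins_at_root(self):
        tree = tree_from_string("((A:0.2,B:0.2):0.2,C:0.2);")
        aln = Alignment("g", ["A", "B", "C"], ["L", "V", "V"])
        st = reconstruct_states(tree, aln, "ml-marginal", frequencies=UNIFORM)
        assert st.assigned_state(tree.seed_node, 0) == "V"

    @pytest.mark.parametrize("alpha", [None, 0.6])
    @pytest.mark.parametrize(
        "newick,rows",
        [
            ("((A:0.3,B:0.5):0.4,(C:0.2,D:0.7):0.1);", ["LV-W", "VVXW", "VWLW", "LWLW"]),
            ("((A:0.1,B:0.9):0.2,(C:0.4,(D:0.3,E:0.3):0.2):0.5);",
             ["LVW", "VVW", "VWF", "LWW", "SWW"]),
        ],
    )
    def test_matches_enumeration_oracle(self, newick, rows, alpha):
        tree = tree_from_string(newick)
        labels = sorted({l.taxon.label for l in tree.leaf_node_iter()})
        aln = Alignment("g", labels, rows)
        st = reconstruct_states(
            tree, aln, "ml-marginal", frequencies=UNIFORM, gamma_alpha=alpha
        )
        oracle = enumeration_posteriors(tree, aln, UNIFORM, alpha)
        for node, i in st.node_index.items():
            if not node.is_leaf():
                np.testing.assert_allclose(
                    st.posteriors[i], oracle[id(node)], atol=1e-10
                )

    def test_random_columns_match_enumeration(self):
        rng = np.random.default_rng(5)
        tree = tree_from_string("((A:0.3,B:0.6):0.2,(C:0.4,D:0.1):0.3,E:0.8);")
        labels = ["A", "B", "C", "D", "E"]
        for _ in range(3):
            rows = ["".join(rng.choice(list(AA20 + "X-"), size=4)) for _ in labels]
            aln = Alignment("g", labels, rows)
            pi = rng.dirichlet(np.ones(20) * 5)
            st = reconstruct_states(tree, aln, "ml-marginal", frequencies=pi)
            oracle = enumeration_posteriors(tree, aln, pi)
            for node, i in st.node_index.items():
                if not node.is_leaf():
                    np.testing.assert_allclose(
                        st.posteriors[i], oracle[id(node)], atol=1e-10
                    )

    def test_posteriors_normalized(self, quartet_tree, quartet_alignment):
        st = reconstruct_states(quartet_tree, quartet_alignment, "ml-marginal")
        np.testing.assert_allclose(st.posteriors.sum(axis=2), 1.0, atol=1e-9)

    def test_leaf_missing_from_alignment_rejected(self, quartet_tree):
        aln = Alignment("g", ["A", "B", "C"], ["L", "L", "L"])
        with pytest.raises(ValueError, match="absent from alignment"):
            reconstruct_states(quartet_tree, aln, "ml-marginal")


class TestFitch:
    def test_two_pass_sets(self):
        tree = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        aln = Alignment("g", ["A", "B", "C", "D"], ["L", "V", "V", "V"])
        st = reconstruct_states(tree, aln, "fitch")
        root = tree.seed_node
        i = st.node_index[root]
        states = {AA20[j] for j in np.where(st.state_sets[i, 0])[0]}
        assert states == {"V"}

    def test_wildcard_leaves_do_not_constrain(self):
        tree = tree_from_string("((A:1,B:1):1,C:1);")
        aln = Alignment("g", ["A", "B", "C"], ["W", "-", "X"])
        st = reconstruct_states(tree, aln, "fitch")
        assert st.assigned_state(tree.seed_node, 0) == "W"


class TestApomorphyCalls:
    def _planted_fixture(self):
        # group (A,B,C) fixed derived W; outside (D,E,F) ancestral S, nested
        # so the node one deeper than the clade root is not the tree root
        tree = tree_from_string(
            "((((A:0.2,B:0.2):0.1,C:0.3):0.4,D:0.5):0.1,(E:0.3,F:0.3):0.2);"
        )
        aln = Alignment(
            "g", ["A", "B", "C", "D", "E", "F"],
            ["WL", "WL", "WL", "SL", "SL", "SL"],
        )
        return tree, aln

    @pytest.mark.parametrize("mode", ["fitch", "ml-marginal"])
    def test_planted_synapomorphy_called_exactly(self, mode):
        tree, aln = self._planted_fixture()
        st = reconstruct_states(tree, aln, mode, frequencies=UNIFORM)
        calls = call_apomorphies(st, tree, "grp", ["A", "B", "C"])
        assert [(c.column, c.derived, c.ancestral) for c in calls] == [(0, "W", "S")]
        if mode == "ml-marginal":
            assert calls[0].confidence > 0.9

    def test_invariant_alignment_yields_no_calls(self):
        tree = tree_from_string("(((A:1,B:1):1,C:1):1,D:1);")
        aln = Alignment("g", ["A", "B", "C", "D"], ["LL", "LL", "LL", "LL"])
        st = reconstruct_states(tree, aln, "fitch")
        assert call_apomorphies(st, tree, "grp", ["A", "B", "C"]) == []

    def test_equal_clade_and_parent_state_yields_no_call(self):
        tree, aln = self._planted_fixture()
        # outside also W: state identical at clade root and parent
        aln2 = Alignment("g", aln.sequence_ids, ["WL"] * 6)
        st = reconstruct_states(tree, aln2, "fitch")
        assert call_apomorphies(st, tree, "grp", ["A", "B", "C"]) == []

    def test_fitch_ambiguity_suppresses_call(self):
        tree = tree_from_string("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        # group split W/W/S: Fitch clade root is {W} (wins 2:1), but parent
        # becomes ambiguous {W,S}; no call either way
        aln = Alignment("g", ["A", "B", "C", "D", "E"], ["W", "W", "S", "S", "W"])
        st = reconstruct_states(tree, aln, "fitch")
        assert call_apomorphies(st, tree, "grp", ["A", "B", "C"]) == []

    def test_non_monophyletic_clade_names_intruders(self):
        tree, aln = self._planted_fixture()
        st = reconstruct_states(tree, aln, "fitch")
        with pytest.raises(ValueError, match="intruding.*'B'"):
            call_apomorphies(st, tree, "grp", ["A", "C"])

    def test_p_min_floor_blocks_weak_ml_calls(self):
        tree, aln = self._planted_fixture()
        st = reconstruct_states(tree, aln, "ml-marginal", frequencies=UNIFORM)
        assert call_apomorphies(st, tree, "grp", ["A", "B", "C"], p_min=0.999999) == []

    def test_fitch_calls_subset_of_ml_calls_on_clean_data(self, small_dataset):
        from raresyn.pipeline import ancestry_tree

        data = small_dataset
        rng = np.random.default_rng(0)
        sub = ancestry_tree(data.tree, data.group_def, data.db, 20, rng)
        labels = [l.taxon.label for l in sub.leaf_node_iter()]
        grp = sorted(data.group_def.members)
        aln = data.alignments["atp6"]
        aln_sub = Alignment("atp6", labels, [aln.row(s) for s in labels])
        st_f = reconstruct_states(sub, aln_sub, "fitch")
        st_m = reconstruct_states(sub, aln_sub, "ml-marginal")
        fitch_cols = {
            (c.column, c.derived)
            for c in call_apomorphies(st_f, sub, "grp", grp)
        }
        ml_cols = {
            (c.column, c.derived)
            for c in call_apomorphies(st_m, sub, "grp", grp, p_min=0.5)
        }
        assert fitch_cols <= ml_cols
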