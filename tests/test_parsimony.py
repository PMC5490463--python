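"""Fitch scoring, search, ensemble indices and ACCTRAN mapping.

Every scored quantity is checked against an independent oracle: exhaustive
enumeration over internal-state assignments (conftest.brute_force_length),
dendropy's Fitch implementation, or exact branch-and-bound.
"""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paleophylo as pp
from paleophylo.parsimony_core import (
    NoSynapomorphyError,
    TaxonMismatchError,
    UndefinedStatisticsError,
    character_max_steps,
    character_min_steps,
)

from conftest import brute_force_length, random_matrix, random_topology


class TestFitchScore:
    def test_constant_character_zero_steps(self):
        m = pp.read_matrix("xread 1 4 A 0 B 0 C 0 D 0 ;", "tnt")
        t = pp.read_tree("((A,B),(C,D));")
        assert pp.fitch_score(t, m).length == 0

    @pytest.mark.parametrize(
        "newick,expected",
        [("((A,B),(C,D));", 1), ("((A,C),(B,D));", 2)],
    )
    def test_four_taxon_binary_character(self, newick, expected):
        m = pp.read_matrix("xread 1 4 A 0 B 0 C 1 D 1 ;", "tnt")
        t = pp.read_tree(newick)
        assert pp.fitch_score(t, m).length == expected
        assert brute_force_length(t, m) == expected

    def test_steps_lower_bound_k_minus_one(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        m = random_matrix(rng, taxa, 20, n_states=4)
        t = random_topology(rng, taxa)
        steps = pp.fitch_score(t, m).per_character_steps
        for ci in range(m.n_characters):
            k = character_min_steps(m, ci)
            assert steps[ci] >= k

    def test_tip_without_matrix_row_raises(self):
        m = pp.read_matrix("xread 1 3 A 0 B 1 C 1 ;", "tnt")
        t = pp.read_tree("((A,B),(C,D));")
        with pytest.raises(TaxonMismatchError):
            pp.fitch_score(t, m)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_matches_exhaustive_enumeration_small_trees(self, seed):
        """Fitch equals brute-force enumeration on trees of <= 6 tips."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        taxa = [f"t{i}" for i in range(n)]
        m = random_matrix(rng, taxa, int(rng.integers(1, 8)),
                          n_states=int(rng.integers(2, 4)), missing_prob=0.15)
        t = random_topology(rng, taxa)
        assert pp.fitch_score(t, m).length == brute_force_length(t, m)

    def test_length_invariant_under_rerooting(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        m = random_matrix(rng, taxa, 12, n_states=3)
        t = random_topology(rng, taxa)
        base = pp.fitch_score(t, m).length
        for label in taxa:
            assert pp.fitch_score(t.reroot_above(label), m).length == base

    def test_agrees_with_dendropy_fitch(self, rng):
        """Independent cross-check against dendropy's Fitch downpass."""
        taxa = [f"t{i}" for i in range(9)]
        m = random_matrix(rng, taxa, 25, n_states=3)
        t = random_topology(rng, taxa)
        nexus = pp.write_matrix(m, "nexus")
        dmat = dendropy.StandardCharacterMatrix.get(data=nexus, schema="nexus")
        dtree = dendropy.Tree.get(
            data=pp.write_tree(t), schema="newick",
            taxon_namespace=dmat.taxon_namespace,
        )
        dtree.encode_bipartitions()
        from dendropy.model.parsimony import fitch_down_pass

        score = fitch_down_pass(
            dtree.postorder_node_iter(),
            taxon_state_sets_map=dmat.taxon_state_sets_map(gaps_as_missing=True),
        )
        assert pp.fitch_score(t, m).length == score


class TestTreeStatistics:
    def test_homoplasy_free_matrix_ci_one(self):
        m = pp.read_matrix("xread 3 4 A 000 B 100 C 110 D 111 ;", "tnt")
        t = pp.read_tree("(A,(B,(C,D)));")
        st_ = pp.tree_statistics(t, m)
        assert st_.ci == 1.0
        assert st_.hi == 0.0

    def test_hand_computed_binary_character(self):
        # 0,0,1,1 on ((A,C),(B,D)): M=1, S=2, G=2 -> ci=0.5, ri=0
        m = pp.read_matrix("xread 1 4 A 0 B 0 C 1 D 1 ;", "tnt")
        t = pp.read_tree("((A,C),(B,D));")
        st_ = pp.tree_statistics(t, m)
        assert st_.ci == 0.5
        assert st_.ri == 0.0
        assert st_.rc == 0.0
        assert st_.hi == 0.5

    def test_min_max_step_bounds(self):
        m = pp.read_matrix("xread 2 5 A 00 B 00 C 01 D 11 E {01}1 ;", "tnt")
        # char 0: {01} on a binary character is full ambiguity -> unscored;
        # scored cells 0,0,0,1 give min 1 and max 4 - 3 = 1
        assert character_min_steps(m, 0) == 1
        assert character_max_steps(m, 0) == 1
        assert character_min_steps(m, 1) == 1
        assert character_max_steps(m, 1) == 2

    def test_constant_matrix_raises(self):
        m = pp.read_matrix("xread 2 4 A 00 B 00 C 00 D 00 ;", "tnt")
        t = pp.read_tree("((A,B),(C,D));")
        with pytest.raises(UndefinedStatisticsError):
            pp.tree_statistics(t, m)

    def test_uninformative_convention_changes_ci(self):
        # char 1 is an autapomorphy: included in CI under the default
        m = pp.read_matrix("xread 2 4 A 00 B 00 C 10 D 11 ;", "tnt")
        t = pp.read_tree("((A,C),(B,D));")
        with_u = pp.tree_statistics(t, m, include_uninformative=True)
        without = pp.tree_statistics(t, m, include_uninformative=False)
        assert with_u.ci != without.ci
        assert with_u.includes_uninformative
        # informative-only CI for the single informative character: 1/2
        assert without.ci == 0.5


class TestExactSearch:
    def test_four_taxon_compatible_matrix_recovers_topology(self):
        m = pp.read_matrix("xread 2 4 A 00 B 00 C 11 D 11 ;", "tnt")
        trees, length = pp.branch_and_bound(m)
        assert length == 2
        expected = pp.read_tree("((A,B),(C,D));")
        assert any(t.same_unrooted_topology(expected) for t in trees)

    def test_three_taxa_single_topology(self):
        m = pp.read_matrix("xread 2 3 A 00 B 01 C 11 ;", "tnt")
        trees, _ = pp.branch_and_bound(m)
        assert len(trees) == 1

    def test_guard_refuses_large_inputs(self, rng):
        taxa = [f"t{i}" for i in range(13)]
        m = random_matrix(rng, taxa, 5)
        with pytest.raises(ValueError, match="heuristic"):
            pp.branch_and_bound(m)

    @pytest.mark.parametrize("seed", [3, 17])
    def test_heuristic_matches_branch_and_bound(self, seed):
        cfg = pp.SimulationConfig(seed=seed, n_taxa=8, n_characters=15,
                                  n_states=3, change_rate=0.06)
        tree = pp.simulate_tree(cfg)
        mat, _ = pp.simulate_characters(tree, cfg)
        _, exact_len = pp.branch_and_bound(mat)
        res = pp.heuristic_search(mat, pp.SearchConfig(replicates=3, seed=1))
        assert res.best_length == exact_len

    def test_heuristic_never_beaten_by_user_tree(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        m = random_matrix(rng, taxa, 12, n_states=2)
        res = pp.heuristic_search(m, pp.SearchConfig(replicates=3, seed=2))
        for _ in range(10):
            t = random_topology(rng, taxa)
            assert pp.fitch_score(t, m).length >= res.best_length


class TestHeuristicSearch:
    def test_same_seed_same_result(self, rng):
        taxa = [f"t{i}" for i in range(9)]
        m = random_matrix(rng, taxa, 20, n_states=2)
        cfg = pp.SearchConfig(replicates=3, seed=42)
        a = pp.heuristic_search(m, cfg)
        b = pp.heuristic_search(m, pp.SearchConfig(replicates=3, seed=42))
        assert a.best_length == b.best_length
        assert {frozenset(t.bipartitions()) for t in a.best_trees} == {
            frozenset(t.bipartitions()) for t in b.best_trees
        }

    def test_homoplasy_free_recovery_20_taxa(self):
        cfg = pp.SimulationConfig(seed=11, n_taxa=20, n_characters=100,
                                  homoplasy_free=True)
        tree = pp.simulate_tree(cfg)
        mat, _ = pp.simulate_characters(tree, cfg)
        res = pp.heuristic_search(mat, pp.SearchConfig(replicates=2, seed=5))
        assert any(t.same_unrooted_topology(tree) for t in res.best_trees)
        assert pp.tree_statistics(res.best_trees[0], mat).ci == 1.0

    def test_strict_consensus_contains_only_shared_clades(self):
        t1 = pp.read_tree("((A,B),(C,(D,E)));")
        t2 = pp.read_tree("((A,B),((C,D),E));")
        cons = pp.strict_consensus([t1, t2])
        clades = cons.clades()
        assert frozenset(["A", "B"]) in clades
        assert frozenset(["C", "D", "E"]) in clades
        assert frozenset(["D", "E"]) not in clades


class TestAcctran:
    def test_single_change_on_expected_branch(self):
        m = pp.read_matrix("xread 1 4 A 0 B 0 C 1 D 1 ;", "tnt")
        t = pp.read_tree("(A,(B,(C,D)));")  # rooted on A
        states, changes = pp.acctran_optimize(t, m)
        assert len(changes) == 1
        cd_node = t.mrca(["C", "D"])
        assert changes[0].node_id == cd_node.id
        assert (changes[0].from_state, changes[0].to_state) == ("0", "1")

    def test_constant_character_no_changes(self):
        m = pp.read_matrix("xread 1 4 A 0 B 0 C 0 D 0 ;", "tnt")
        t = pp.read_tree("((A,B),(C,D));")
        _, changes = pp.acctran_optimize(t, m)
        assert changes == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_change_steps_sum_to_tree_length(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        taxa = [f"t{i}" for i in range(n)]
        m = random_matrix(rng, taxa, int(rng.integers(2, 10)),
                          n_states=int(rng.integers(2, 4)), missing_prob=0.1)
        t = random_topology(rng, taxa)
        _, changes = pp.acctran_optimize(t, m)
        assert sum(c.steps for c in changes) == pp.fitch_score(t, m).length


class TestSynapomorphyClassification:
    def test_unique_reconstruction_is_unambiguous(self):
        m = pp.read_matrix("xread 1 4 A 0 B 0 C 1 D 1 ;", "tnt")
        t = pp.read_tree("(A,(B,(C,D)));")
        cd = t.mrca(["C", "D"])
        assert pp.classify_synapomorphy(cd.id, 0, t, m) == "unambiguous"

    def test_missing_data_makes_placement_ambiguous(self):
        m = pp.read_matrix("xread 1 4 A 0 B ? C 1 D 1 ;", "tnt")
        t = pp.read_tree("(A,(B,(C,D)));")
        _, changes = pp.acctran_optimize(t, m)
        (change,) = changes
        assert pp.classify_synapomorphy(change.node_id, 0, t, m) == "ambiguous"

    def test_no_change_at_node_raises(self):
        m = pp.read_matrix("xread 1 4 A 0 B 0 C 1 D 1 ;", "tnt")
        t = pp.read_tree("(A,(B,(C,D)));")
        bcd = t.mrca(["B", "C", "D"])
        with pytest.raises(NoSynapomorphyError):
            pp.classify_synapomorphy(bcd.id, 0, t, m)

    def test_table_classification_matches_mpr_enumeration(self, rng):
        """Forced-change verdicts agree with brute-force MPR enumeration."""
        import itertools

        taxa = [f"t{i}" for i in range(6)]
        for trial in range(5):
            m = random_matrix(rng, taxa, 4, n_states=2, missing_prob=0.2)
            t = random_topology(rng, taxa)
            records = pp.synapomorphy_table(t, m)
            for rec in records:
                forced = _change_in_every_mpr(t, m, rec.node_id, rec.char_index)
                assert (rec.ambiguity == "unambiguous") == forced


def _change_in_every_mpr(tree, matrix, node_id, char_index):
    """Brute force: does every minimum-length internal assignment change
    state on the branch above node_id?"""
    import itertools

    one = matrix.subset_characters([char_index])
    char = one.characters[0]
    alpha = char.state_alphabet
    internals = tree.internal_nodes(include_root=True)
    taxon_row = {t: i for i, t in enumerate(one.taxa)}
    assignments = []
    for assign in itertools.product(range(len(alpha)), repeat=len(internals)):
        states = {n.id: a for n, a in zip(internals, assign)}
        length = 0.0
        changed = False
        for node in tree.preorder():
            if node.parent is None:
                continue
            ps = states[node.parent.id]
            if node.is_leaf:
                cell = one.cells[taxon_row[node.label]][0]
                length += min(float(ps != alpha.index(s)) for s in cell)
            else:
                length += float(ps != states[node.id])
                if node.id == node_id and ps != states[node.id]:
                    changed = True
        # leaf target node: change judged on its own branch
        if any(n.id == node_id and n.is_leaf for n in tree.preorder()):
            raise AssertionError("synapomorphy records must be internal")
        assignments.append((length, changed))
    best = min(l for l, _ in assignments)
    return all(ch for l, ch in assignments if l == best)
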