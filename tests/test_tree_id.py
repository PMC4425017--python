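"""Neighbor joining, bootstrap supports and monophyly scoring."""

import numpy as np
import pytest

from barcodeval import (
    SimulationConfig,
    bootstrap_supports,
    distance_matrix,
    nj_tree,
    read_newick_with_supports,
    score_monophyly,
    simulate_dataset,
)
from barcodeval.exceptions import (
    TreeConsistencyError,
    UndefinedDistanceError,
    ValidationError,
)
from barcodeval.tree_id import SupportTree, _neighbor_joining, _nj_splits

from conftest import RandomAdditiveTree, make_aln, make_dm


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # three-point equations: la = (dab + dac - dbc)/2, etc.
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        root = _neighbor_joining(D)
        lengths = {ch.leaf_id: bl for ch, bl in root.children}
        assert lengths[0] == pytest.approx(0.1)
        assert lengths[1] == pytest.approx(0.2)
        assert lengths[2] == pytest.approx(0.4)

    def test_quartet_matches_four_point_condition(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            tree = RandomAdditiveTree(4, rng)
            D = tree.distance_matrix()
            sums = {
                frozenset([1]): D[0, 1] + D[2, 3],  # split 01|23 -> side {1}
                frozenset([2]): D[0, 2] + D[1, 3],
                frozenset([3]): D[0, 3] + D[1, 2],
            }
            # the four-point condition: the true split has the smallest sum
            best = min(sums, key=sums.get)
            others = [v for k, v in sums.items() if k != best]
            if min(others) - sums[best] < 1e-9:
                continue  # degenerate quartet, no unique split
            # key {k} means taxon 0 pairs with k; canonical side excludes 0
            true_split = frozenset(range(4)) - best - {0}
            assert _nj_splits(D) == {true_split}

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(5, 13))
            tree = RandomAdditiveTree(n, rng)
            assert _nj_splits(tree.distance_matrix()) == tree.splits()

    def test_agrees_with_dendropy_on_generic_matrices(self):
        # tie-free random matrices: the NJ tree is unique, so an independent
        # implementation must produce the identical bipartition set
        import io

        import dendropy

        rng = np.random.default_rng(42)
        for _ in range(5):
            n = int(rng.integers(5, 10))
            D = rng.uniform(0.05, 1.0, size=(n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            species = [f"S_{i}" for i in range(n)]
            dm = make_dm(species, D)
            ours = nj_tree(dm)

            pdm_csv = ["," + ",".join(ours.taxa)]
            for i, t in enumerate(ours.taxa):
                pdm_csv.append(t + "," + ",".join(str(x) for x in D[i]))
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO("\n".join(pdm_csv)), delimiter=","
            )
            ref_st = SupportTree(
                taxa=ours.taxa,
                species_of=ours.species_of,
                tree=pdm.nj_tree(),
                scale="bootstrap",
            )
            assert ours.splits() == ref_st.splits()

    def test_undefined_distances_rejected(self):
        vals = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        dm = make_dm(["X", "Y", "Z"], vals)
        with pytest.raises(UndefinedDistanceError):
            nj_tree(dm)

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            D = rng.uniform(0.0, 1.0, size=(n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            root = _neighbor_joining(D)
            stack = [root]
            while stack:
                node = stack.pop()
                for ch, bl in node.children:
                    assert bl >= 0.0
                    stack.append(ch)


class TestBootstrap:
    @staticmethod
    def _two_clean_species():
        return make_aln(
            [
                ("X_a", "x1", "A" * 30),
                ("X_a", "x2", "A" * 30),
                ("Y_b", "y1", "A" * 20 + "G" * 10),
                ("Y_b", "y2", "A" * 20 + "G" * 10),
            ]
        )

    def test_clean_split_gets_full_support(self):
        aln = self._two_clean_species()
        st = bootstrap_supports(aln, n_replicates=50, seed=1, min_overlap=1)
        (split,) = st.splits()
        assert st.support_of(split) == 100.0

    def test_same_seed_same_supports(self, rng):
        aln, _ = simulate_dataset(SimulationConfig(n_species=5, seed=9))
        s1 = bootstrap_supports(aln, n_replicates=30, seed=4)
        s2 = bootstrap_supports(aln, n_replicates=30, seed=4)
        assert s1.supports == s2.supports
        assert s1.as_newick() == s2.as_newick()

    def test_supports_bounded_and_topology_unchanged(self):
        aln, _ = simulate_dataset(SimulationConfig(n_species=5, seed=10))
        dm = distance_matrix(aln)
        plain = nj_tree(dm)
        st = bootstrap_supports(aln, n_replicates=25, seed=5)
        assert st.splits() == plain.splits()
        assert all(0.0 <= v <= 100.0 for v in st.supports.values())
        assert set(st.supports) == st.splits()


class TestScoreMonophyly:
    def test_hand_example(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((X_a|x1,X_a|x2)95,(Y_b|y1,Z_c|z1)50);\n")
        st = read_newick_with_supports(p, scale="bootstrap")
        rep = score_monophyly(st, support_cutoff=80)
        assert rep.per_species["X_a"]["monophyletic"]
        assert rep.per_species["X_a"]["supported"]
        assert not rep.per_species["Y_b"]["identified"]  # singleton
        assert rep.pct_correct_individuals == pytest.approx(50.0)

    def test_cutoff_above_all_supports_scores_zero(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((X_a|x1,X_a|x2)60,(Y_b|y1,Y_b|y2)70);\n")
        st = read_newick_with_supports(p, scale="bootstrap")
        rep = score_monophyly(st, support_cutoff=75)
        assert rep.pct_correct_individuals == 0.0

    def test_cutoff_is_strict(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((X_a|x1,X_a|x2)80,(Y_b|y1,Z_c|z1)50);\n")
        st = read_newick_with_supports(p, scale="bootstrap")
        rep = score_monophyly(st, support_cutoff=80)
        assert not rep.per_species["X_a"]["supported"]  # 80 is not > 80

    def test_cutoff_monotonicity(self):
        aln, _ = simulate_dataset(SimulationConfig(n_species=6, seed=2))
        st = bootstrap_supports(aln, n_replicates=40, seed=3)
        pcts = [
            score_monophyly(st, support_cutoff=c).pct_correct_individuals
            for c in (0, 20, 40, 60, 80, 99, 100)
        ]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))

    def test_singleton_modes(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((X_a|x1,X_a|x2)95,(Y_b|y1,Z_c|z1)50);\n")
        st = read_newick_with_supports(p, scale="bootstrap")
        incl = score_monophyly(st, singleton_mode="count_incorrect")
        excl = score_monophyly(st, singleton_mode="exclude")
        assert incl.pct_correct_individuals == pytest.approx(50.0)
        assert excl.pct_correct_individuals == pytest.approx(100.0)

    def test_invariant_to_rerooting(self):
        aln, _ = simulate_dataset(SimulationConfig(n_species=5, seed=21))
        st = bootstrap_supports(aln, n_replicates=30, seed=6)
        base = score_monophyly(st)

        rerooted_tree = st.tree.clone(depth=1)
        leaf = next(rerooted_tree.leaf_node_iter())
        rerooted_tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
        st2 = SupportTree(
            taxa=st.taxa,
            species_of=st.species_of,
            tree=rerooted_tree,
            scale=st.scale,
            supports=st.supports,
        )
        rep2 = score_monophyly(st2)
        assert rep2.pct_correct_individuals == base.pct_correct_individuals
        assert rep2.per_species == base.per_species

    def test_leaf_coverage_checked(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((X_a|x1,X_a|x2)95,(Y_b|y1,Z_c|z1)50);\n")
        st = read_newick_with_supports(p)
        with pytest.raises(TreeConsistencyError):
            score_monophyly(st, expected_labels=["X_a|x1", "X_a|x2", "Y_b|y1"])


class TestNewickIO:
    def test_posterior_tree_parsed(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A_a|a,B_b|b)0.99,(C_c|c,D_d|d)0.40);\n")
        st = read_newick_with_supports(p, scale="posterior")
        assert len(st.supports) == 2
        assert sorted(v for v in st.supports.values()) == [0.40, 0.99]

    def test_wrong_scale_bounds_error(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A_a|a,B_b|b)95,(C_c|c,D_d|d)40);\n")
        with pytest.raises(ValidationError, match="scale"):
            read_newick_with_supports(p, scale="posterior")

    def test_missing_supports_warn_and_score_zero(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((X_a|x1,X_a|x2),(Y_b|y1,Y_b|y2)90);\n")
        with pytest.warns(UserWarning, match="support"):
            st = read_newick_with_supports(p, scale="bootstrap")
        rep = score_monophyly(st, support_cutoff=80)
        assert rep.per_species["X_a"]["monophyletic"]
        assert not rep.per_species["X_a"]["supported"]

    def test_round_trip_is_stable(self, tmp_path):
        aln, _ = simulate_dataset(SimulationConfig(n_species=5, seed=33))
        st = bootstrap_supports(aln, n_replicates=20, seed=7)
        p1 = tmp_path / "a.nwk"
        st.write(p1)
        back = read_newick_with_supports(p1, scale="bootstrap")
        p2 = tmp_path / "b.nwk"
        back.write(p2)
        assert p1.read_text() == p2.read_text()
        assert back.splits() == st.splits()
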