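"""Alignment, similarity, distances, neighbor joining, bootstrap, Newick."""

import numpy as np
import pytest

from laccmine.comparative import (
    DistanceMatrix,
    alignment_score,
    bootstrap_support,
    cherry_support,
    distance_matrix,
    global_align,
    is_cherry,
    nj_tree,
    percent_similarity,
    progressive_msa,
    read_newick,
    similarity_matrix,
    tree_bipartitions,
    write_newick,
)
from laccmine.errors import NumericalError, ValidationError

from _oracles import best_ls_topology, edge_bipartitions, exhaustive_global_score, random_additive_tree

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestGlobalAlign:
    def test_identical_sequences(self):
        p = global_align("MKVLH", "MKVLH")
        assert p.identities == 5 and p.compared_columns == 5
        assert "-" not in p.aligned[0] + p.aligned[1]
        assert percent_similarity(p) == 100.0

    def test_insertion_excluded_from_compared_columns(self):
        p = global_align("ACDEFG", "ACDAAAEFG")
        assert (p.identities, p.compared_columns) == (6, 6)
        assert percent_similarity(p) == 100.0

    def test_score_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(6):
            a = "".join(AA20[i] for i in rng.integers(20, size=rng.integers(3, 9)))
            b = "".join(AA20[i] for i in rng.integers(20, size=rng.integers(3, 9)))
            assert alignment_score(a, b) == pytest.approx(exhaustive_global_score(a, b))

    def test_symmetry_of_similarity(self):
        a, b = "MKVLHWWH", "MKVIHWH"
        assert percent_similarity(global_align(a, b)) == percent_similarity(global_align(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            global_align("", "MK")


class TestSimilarityMatrix:
    def test_symmetric_with_unit_diagonal(self):
        sim = similarity_matrix([("a", "MKVLH"), ("b", "MKVIH"), ("c", "WWWWC")])
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 100.0)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValidationError):
            similarity_matrix([("a", "MKVLH"), ("a", "MKVIH")])


class TestDistanceMatrix:
    def test_identical_rows_are_zero(self):
        dm = distance_matrix([("a", "MKV"), ("b", "MKV"), ("c", "MKV")])
        assert np.allclose(dm.values, 0.0)

    def test_saturated_rows_hit_one_and_break_poisson(self):
        rows = [("a", "AAAA"), ("b", "CCCC"), ("c", "DDDD")]
        dm = distance_matrix(rows, model="p")
        assert dm.values[0, 1] == pytest.approx(1.0)
        with pytest.raises(NumericalError):
            distance_matrix(rows, model="poisson")

    def test_hand_computed_pairwise_deletion(self):
        rows = [("a", "AAAA"), ("b", "AAAT"), ("c", "A-TT")]
        dm = distance_matrix(rows)
        assert dm.values[0, 1] == pytest.approx(0.25)
        assert dm.values[0, 2] == pytest.approx(2 / 3)
        assert dm.values[1, 2] == pytest.approx(1 / 3)

    def test_requires_three_rows(self):
        with pytest.raises(ValidationError):
            distance_matrix([("a", "MK"), ("b", "MK")])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(names=("a", "b", "c"),
                            values=np.array([[0, 2.0, 3.0], [2.0, 0, 5.0], [3.0, 5.0, 0]]))
        tree = nj_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 0.0, "b": 2.0, "c": 3.0})

    def test_additive_four_taxa_recovered_exactly(self):
        # tree ((a:1,b:2):0.5,c:0.7,d:0.9) with the internal edge 0.5
        names = ("a", "b", "c", "d")
        d = np.array(
            [
                [0.0, 3.0, 2.2, 2.4],
                [3.0, 0.0, 3.2, 3.4],
                [2.2, 3.2, 0.0, 1.6],
                [2.4, 3.4, 1.6, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(names=names, values=d))
        assert tree_bipartitions(tree) == {frozenset({"a", "b"})}
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 0.7, "d": 0.9})

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_matches_least_squares_brute_force_on_additive_matrices(self, n_taxa):
        for seed in range(3):
            rng = np.random.default_rng(100 * n_taxa + seed)
            names = [f"t{i}" for i in range(n_taxa)]
            edges, _, d = random_additive_tree(rng, names)
            nj = nj_tree(DistanceMatrix(names=tuple(names), values=d))
            assert tree_bipartitions(nj) == edge_bipartitions(edges, names)
            assert tree_bipartitions(nj) == best_ls_topology(names, d)

    def test_negative_lengths_clamped_to_zero(self):
        # strongly non-additive matrix provokes negative NJ branches
        d = np.array(
            [
                [0.0, 0.1, 1.0, 1.0, 0.9],
                [0.1, 0.0, 0.2, 1.0, 1.0],
                [1.0, 0.2, 0.0, 0.3, 1.0],
                [1.0, 1.0, 0.3, 0.0, 0.1],
                [0.9, 1.0, 1.0, 0.1, 0.0],
            ]
        )
        names = tuple("abcde")
        clamped = nj_tree(DistanceMatrix(names=names, values=d), clamp_negative=True)
        assert all(e.length >= 0 for e in clamped.preorder_edge_iter() if e.length is not None)
        free = nj_tree(DistanceMatrix(names=names, values=d), clamp_negative=False)
        assert any(e.length < 0 for e in free.preorder_edge_iter() if e.length is not None)

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(names=("a", "b"), values=np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            nj_tree(dm)


class TestBootstrap:
    msa4 = [("a", "MKVLHAAA"), ("a2", "MKVLHAAA"), ("b", "WWDCHAAA"), ("c", "WWDCYSAA")]

    def test_duplicated_taxon_pair_gets_full_support(self):
        tree = bootstrap_support(self.msa4, reps=100, seed=1)
        assert is_cherry(tree, "a", "a2")
        assert cherry_support(tree, "a", "a2") == pytest.approx(100.0)

    def test_single_replicate_supports_are_binary(self):
        tree = bootstrap_support(self.msa4, reps=1, seed=3)
        sups = [n.support for n in tree.preorder_node_iter() if hasattr(n, "support")]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_supports_invariant_under_taxon_reordering(self):
        msa = [("a", "MKVLHAAA"), ("b", "MKVLHAAC"), ("c", "WWDCHAAA"), ("d", "WWDCYSAA")]
        t1 = bootstrap_support(msa, reps=100, seed=7)
        t2 = bootstrap_support(list(reversed(msa)), reps=100, seed=7)

        def support_map(tree):
            out = {}
            for n in tree.preorder_node_iter():
                if hasattr(n, "support"):
                    out[frozenset(lf.taxon.label for lf in n.leaf_iter())] = n.support
            return out

        m1, m2 = support_map(t1), support_map(t2)
        universe = frozenset("abcd")
        canon = lambda m: {
            min(k, universe - k, key=lambda s: (len(s), tuple(sorted(s)))): v
            for k, v in m.items()
        }
        assert canon(m1) == canon(m2)


class TestNewick:
    def _random_tree(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"t{i}" for i in range(6)]
        _, _, d = random_additive_tree(rng, names)
        return nj_tree(DistanceMatrix(names=tuple(names), values=d))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_topology_lengths_labels(self, tmp_path, seed):
        tree = self._random_tree(seed)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and not node.is_leaf():
                node.label = "87"
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert tree_bipartitions(back) == tree_bipartitions(tree)
        orig = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        redo = {lf.taxon.label: lf.edge.length for lf in back.leaf_node_iter()}
        for k in orig:
            assert redo[k] == pytest.approx(orig[k], abs=1e-6)
        labels = [n.label for n in back.preorder_node_iter()
                  if n.parent_node is not None and not n.is_leaf()]
        assert labels and all(l == "87" for l in labels)

    def test_malformed_newick_raises(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a:1,b:2;\n")
        with pytest.raises(ValidationError):
            read_newick(p)


class TestProgressiveMsa:
    def test_degapping_recovers_inputs(self):
        seqs = [("a", "MKVLHWCDE"), ("b", "MKVHWCDE"), ("c", "MKVLHAAAWCDE")]
        msa = progressive_msa(seqs)
        assert len({len(s) for _, s in msa}) == 1
        assert {n: s.replace("-", "") for n, s in msa} == dict(seqs)

    def test_identical_pair_aligns_gap_free_with_each_other(self):
        seqs = [("a", "MKVLHWCDE"), ("b", "MKVLHWCDE"), ("c", "WWWWHHHHH")]
        msa = dict(progressive_msa(seqs))
        assert msa["a"] == msa["b"]
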