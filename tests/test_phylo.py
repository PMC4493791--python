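"""K2P distances, Neighbor-Joining, bootstrap, rooting and locus partition."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hd1panel.phylo import (
    Clade,
    DistanceMatrix,
    PhyloTree,
    SaturationError,
    bootstrap_support,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    partition_loci,
    root_with_outgroup,
)


def _tree_distances(tree: PhyloTree) -> dict:
    out = {}

    def walk(node):
        if node.is_leaf:
            return {node.name: 0.0}
        subs = []
        for c in node.children:
            sub = walk(c)
            for k in sub:
                sub[k] += c.branch_length or 0.0
            subs.append(sub)
        merged = {}
        for s1, s2 in itertools.combinations(subs, 2):
            for a in s1:
                for b in s2:
                    out[frozenset((a, b))] = s1[a] + s2[b]
        for s in subs:
            merged.update(s)
        return merged

    walk(tree.root)
    return out


def _random_additive(rng, n):
    """A random binary tree; returns (labels, matrix of its path distances)."""
    nodes = [Clade(name=f"L{i}") for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        for k in (i, j):
            nodes[k].branch_length = float(rng.uniform(0.05, 2.0))
        merged = Clade(children=[nodes[i], nodes[j]])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    dists = _tree_distances(PhyloTree(root=nodes[0]))
    labels = [f"L{i}" for i in range(n)]
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = dists[frozenset((labels[a], labels[b]))]
    return labels, m


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_ten_transitions_five_transversions(self):
        a = "A" * 85 + "G" * 10 + "A" * 5
        b = "A" * 85 + "A" * 10 + "C" * 5
        expected = -0.5 * math.log(0.75 * math.sqrt(0.90))
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_differences_inside_gap_columns_ignored(self):
        a = "ACGT" + "----" + "ACGT"
        b = "ACGT" + "GGGG" + "ACGT"
        assert k2p_distance(a, b) == 0.0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 10, "G" * 10)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_zero_iff_identical(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        b = list(a)
        k = int(rng.integers(0, 12))
        idx = rng.choice(n, size=k, replace=False)
        for i in idx:
            b[i] = "ACGT"[(("ACGT".index(b[i])) + 1) % 4]
        b = "".join(b)
        assert k2p_distance(a, b) == pytest.approx(k2p_distance(b, a))
        assert (k2p_distance(a, b) == 0.0) == (a == b)

    def test_monotone_in_transition_fraction_at_fixed_q(self):
        def d(p):
            return -0.5 * math.log((1 - 2 * p - 0.05) * math.sqrt(1 - 0.1))

        values = [d(p) for p in (0.01, 0.05, 0.10, 0.20)]
        assert values == sorted(values)

    def test_matrix_matches_pairwise(self):
        seqs = ["ACGTAAGG", "ACGTAAGA", "ACCTAAGA"]
        dm = k2p_matrix(["a", "b", "c"], seqs)
        assert dm.d[0, 1] == pytest.approx(k2p_distance(seqs[0], seqs[1]))
        assert dm.d[0, 2] == pytest.approx(k2p_distance(seqs[0], seqs[2]))


class TestNeighborJoining:
    def test_three_taxa_unique_solution(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {lf.name: lf.branch_length for lf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_generating_tree_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> distances below
        labels = ["A", "B", "C", "D"]
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(labels, m))
        dists = _tree_distances(tree)
        for i, a in enumerate(labels):
            for j in range(i + 1, 4):
                assert dists[frozenset((a, labels[j]))] == pytest.approx(m[i, j])
        assert frozenset([frozenset("AB"), frozenset("CD")]) in tree.bipartitions()

    def test_additive_matrices_reproduced_to_1e9(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            n = int(rng.integers(4, 9))
            labels, m = _random_additive(rng, n)
            tree = nj_tree(DistanceMatrix(labels, m))
            dists = _tree_distances(tree)
            for i in range(n):
                for j in range(i + 1, n):
                    assert abs(dists[frozenset((labels[i], labels[j]))] - m[i, j]) < 1e-9

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(11)
        labels, m = _random_additive(rng, 6)
        tree = nj_tree(DistanceMatrix(labels, m))
        perm = list(rng.permutation(6))
        labels_p = [labels[i] for i in perm]
        m_p = m[np.ix_(perm, perm)]
        tree_p = nj_tree(DistanceMatrix(labels_p, m_p))
        assert tree.bipartitions() == tree_p.bipartitions()

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


class TestBootstrap:
    def _alignment(self):
        rng = np.random.default_rng(5)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        from hd1panel.simulate import mutate_k2p

        a = mutate_k2p(base, 0.02, 2.0, np.random.default_rng(1))
        c = mutate_k2p(base, 0.25, 2.0, np.random.default_rng(2))
        d = mutate_k2p(c, 0.02, 2.0, np.random.default_rng(3))
        return ["a1", "a2", "c1", "c2"], [a, a, c, d]

    def test_strong_pairing_supported_at_100(self):
        labels, seqs = self._alignment()
        tree = bootstrap_support(labels, seqs, replicates=100, seed=0)
        supports = [
            node.support
            for node in _internal_nodes(tree.root)
            if node.support is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_same_seed_identical_supports(self):
        labels, seqs = self._alignment()
        t1 = bootstrap_support(labels, seqs, replicates=50, seed=9)
        t2 = bootstrap_support(labels, seqs, replicates=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_bounds(self):
        labels, seqs = self._alignment()
        tree = bootstrap_support(labels, seqs, replicates=40, seed=3)
        for node in _internal_nodes(tree.root):
            if node.support is not None:
                assert 0.0 <= node.support <= 100.0

    def test_requires_four_sequences(self):
        with pytest.raises(ValueError, match="at least 4"):
            bootstrap_support(["a", "b", "c"], ["AC", "AC", "AC"], 10, 0)


def _internal_nodes(node):
    if not node.is_leaf:
        yield node
        for c in node.children:
            yield from _internal_nodes(c)


class TestRootingAndPartition:
    def _tree(self):
        labels = ["A", "B", "C", "D", "OUT"]
        m = np.array(
            [
                [0.0, 0.1, 0.5, 0.5, 1.0],
                [0.1, 0.0, 0.5, 0.5, 1.0],
                [0.5, 0.5, 0.0, 0.1, 1.0],
                [0.5, 0.5, 0.1, 0.0, 1.0],
                [1.0, 1.0, 1.0, 1.0, 0.0],
            ]
        )
        return nj_tree(DistanceMatrix(labels, m))

    def test_root_children_outgroup_and_ingroup(self):
        rooted = root_with_outgroup(self._tree(), "OUT")
        names = {
            frozenset(lf.name for lf in child.leaves())
            for child in rooted.root.children
        }
        assert frozenset(["OUT"]) in names
        assert frozenset(["A", "B", "C", "D"]) in names

    def test_rooting_twice_idempotent(self):
        rooted = root_with_outgroup(self._tree(), "OUT")
        again = root_with_outgroup(rooted, "OUT")
        assert rooted.to_newick() == again.to_newick()

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="not found"):
            root_with_outgroup(self._tree(), "nope")

    def test_partition_matches_construction(self):
        rooted = root_with_outgroup(self._tree(), "OUT")
        a, b, conc = partition_loci(rooted, marker_ids={"C", "D"})
        assert {a, b} == {frozenset("AB"), frozenset("CD")}
        assert conc == 1.0

    def test_concordance_symmetric_in_clade_naming(self):
        rooted = root_with_outgroup(self._tree(), "OUT")
        _, _, conc_cd = partition_loci(rooted, marker_ids={"C", "D"})
        _, _, conc_ab = partition_loci(rooted, marker_ids={"A", "B"})
        assert conc_cd == conc_ab == 1.0

    def test_two_leaf_ingroup_splits_to_singletons(self):
        labels = ["A", "B", "OUT"]
        m = np.array([[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]], float)
        rooted = root_with_outgroup(nj_tree(DistanceMatrix(labels, m)), "OUT")
        a, b, _ = partition_loci(rooted)
        assert {a, b} == {frozenset("A"), frozenset("B")}


class TestHighDivergencePanel:
    def test_two_locus_panel_partition_concordance_is_one(self, small_panel):
        from hd1panel.pipeline import reference_anchored_alignment

        records = list(small_panel.alleles) + [small_panel.outgroup]
        labels, rows = reference_anchored_alignment(
            small_panel.gene_model.reference_sequence, records
        )
        tree = nj_tree(k2p_matrix(labels, rows))
        rooted = root_with_outgroup(tree, small_panel.outgroup[0])
        truth_b = {
            aid for aid, t in small_panel.truth.alleles.items()
            if t.locus.value == "Hd1b"
        }
        a, b, conc = partition_loci(rooted, truth_b)
        assert conc == 1.0
        pseudo = b if len(truth_b & b) >= len(truth_b & a) else a
        assert pseudo == truth_b
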