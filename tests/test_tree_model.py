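"""Subpopulation trees: additive edges, coancestry, simulation, fitting."""

import numpy as np
import pytest

import popassoc as pa
from popassoc.tree_model import (
    SubpopTree,
    additive_edges,
    edges_from_deltas,
    from_newick,
    to_newick,
)


def _chain_tree():
    # root T -> A -> B
    return SubpopTree(
        parent=np.array([-1, 0, 1]),
        names=["T", "A", "B"],
        f_edge=np.array([0.0, 0.2, 0.1]),
    )


def _random_tree(K, rng):
    """Random binary tree with distinct node depths."""
    theta = None
    parent = [-1]
    names = ["root"]
    f_edge = [0.0]
    leaves = [0]
    while len(leaves) < K:
        w = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            parent.append(w)
            names.append(f"n{len(parent) - 1}")
            f_edge.append(float(rng.uniform(0.02, 0.2)))
            leaves.append(len(parent) - 1)
    tree = SubpopTree(
        parent=np.array(parent), names=names, f_edge=np.array(f_edge)
    )
    return additive_edges(tree)


class TestAdditiveEdges:
    def test_root_child_delta_equals_f(self):
        tree = SubpopTree(
            parent=np.array([-1, 0]), names=["T", "S"],
            f_edge=np.array([0.0, 0.3]),
        )
        out = additive_edges(tree)
        assert out.delta[1] == pytest.approx(0.3)
        assert out.f_total[1] == pytest.approx(0.3)

    def test_chain_substitution(self):
        out = additive_edges(_chain_tree())
        assert out.delta[2] == pytest.approx(0.1 * (1 - 0.2))
        assert out.f_total[2] == pytest.approx(0.28)

    def test_roundtrip_f_delta_f(self):
        rng = np.random.default_rng(0)
        tree = _random_tree(10, rng)
        back = edges_from_deltas(tree.parent, tree.names, tree.delta)
        np.testing.assert_allclose(back.f_edge[1:], tree.f_edge[1:],
                                   atol=1e-12)
        np.testing.assert_allclose(back.f_total, tree.f_total, atol=1e-12)

    def test_f_total_monotone_on_paths(self):
        tree = _random_tree(8, np.random.default_rng(1))
        for w in range(1, tree.n_nodes):
            assert tree.f_total[w] >= tree.f_total[tree.parent[w]] - 1e-15

    def test_invalid_f_rejected(self):
        tree = _chain_tree()
        tree.f_edge = np.array([0.0, 1.5, 0.1])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            additive_edges(tree)


class TestTreeCoancestry:
    def test_star_tree(self):
        K = 4
        F = np.array([0.1, 0.2, 0.3, 0.4])
        tree = SubpopTree(
            parent=np.array([-1, 0, 0, 0, 0]),
            names=["T"] + [f"S{u}" for u in range(K)],
            f_edge=np.concatenate([[0.0], F]),
        )
        theta, names = pa.tree_coancestry(additive_edges(tree))
        np.testing.assert_allclose(np.diag(theta), F)
        np.testing.assert_allclose(theta - np.diag(F), 0.0)

    def test_caterpillar_hand_values(self):
        # ((A,B),C): internal AB ancestor delta 0.1, leaf deltas 0.05
        tree = edges_from_deltas(
            parent=np.array([-1, 0, 1, 1, 0]),
            names=["T", "AB", "A", "B", "C"],
            delta=np.array([0.0, 0.1, 0.05, 0.05, 0.05]),
        )
        theta, names = pa.tree_coancestry(tree)
        i = {nm: k for k, nm in enumerate(names)}
        assert theta[i["A"], i["B"]] == pytest.approx(0.1)
        assert theta[i["A"], i["C"]] == pytest.approx(0.0)
        assert theta[i["A"], i["A"]] == pytest.approx(0.15)

    def test_matches_common_ancestor_enumeration(self):
        tree = _random_tree(8, np.random.default_rng(2))
        theta, names = pa.tree_coancestry(tree)
        leaves = tree.leaves()
        # brute-force: walk ancestor sets for each pair
        def ancestors(w):
            out = set()
            while w != -1:
                out.add(int(w))
                w = tree.parent[w] if w != 0 else -1
            return out

        for a, u in enumerate(leaves):
            for b, v in enumerate(leaves):
                common = ancestors(u) & ancestors(v) - {0}
                expected = sum(tree.delta[w] for w in common)
                assert theta[a, b] == pytest.approx(expected, abs=1e-12)

    def test_psd(self):
        tree = _random_tree(10, np.random.default_rng(3))
        theta, _ = pa.tree_coancestry(tree)
        assert np.linalg.eigvalsh(theta).min() > -1e-12


class TestSubpopCoancestry:
    def test_single_individual_groups_identity(self):
        theta = np.array([[0.1, 0.02], [0.02, 0.3]])
        out, names = pa.subpop_coancestry(theta, ["a", "b"])
        np.testing.assert_allclose(out, theta)

    def test_block_constant_exact(self):
        block = np.array([[0.2, 0.05], [0.05, 0.3]])
        theta = np.kron(block, np.ones((3, 3)))
        labels = ["a"] * 3 + ["b"] * 3
        out, _ = pa.subpop_coancestry(theta, labels)
        np.testing.assert_allclose(out, block)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(4)
        theta = rng.random((20, 20))
        theta = (theta + theta.T) / 2
        labels = rng.choice(list("abcd"), 20)
        out, names = pa.subpop_coancestry(theta, labels)
        for a, la in enumerate(names):
            for b, lb in enumerate(names):
                ia = np.flatnonzero(labels == la)
                ib = np.flatnonzero(labels == lb)
                vals = [theta[j, k] for j in ia for k in ib]
                assert out[a, b] == pytest.approx(np.mean(vals))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="labels length"):
            pa.subpop_coancestry(np.eye(3), ["a", "b"])


class TestFitTree:
    def test_exact_recovery_from_true_coancestry(self):
        true = _random_tree(8, np.random.default_rng(5))
        theta, names = pa.tree_coancestry(true)
        fit = pa.fit_tree(theta, names)
        theta_fit, names_fit = pa.tree_coancestry(fit)
        # same leaf set; coancestry reproduced exactly => same topology+delta
        order = [names_fit.index(nm) for nm in names]
        np.testing.assert_allclose(
            theta_fit[np.ix_(order, order)], theta, atol=1e-6
        )
        assert abs(fit.delta0) < 1e-6
        assert _topology_signature(fit) == _topology_signature(true)

    def test_star_tree_input(self):
        F = np.array([0.1, 0.2, 0.3, 0.4])
        theta = np.diag(F)
        fit = pa.fit_tree(theta, ["a", "b", "c", "d"])
        leaves = fit.leaves()
        by_name = {fit.names[w]: fit.delta[w] for w in leaves}
        for nm, f in zip(["a", "b", "c", "d"], F):
            assert by_name[nm] == pytest.approx(f, abs=1e-6)
        internal = [w for w in range(1, fit.n_nodes) if w not in leaves]
        assert all(fit.delta[w] < 1e-6 for w in internal)

    def test_fit_deterministic_under_ties(self):
        theta = np.diag([0.1, 0.1, 0.1])
        a = pa.fit_tree(theta)
        b = pa.fit_tree(theta)
        assert a.names == b.names
        np.testing.assert_array_equal(a.parent, b.parent)


def _topology_signature(tree):
    """Frozen set of leaf-name clades, ignoring internal node labels."""
    leaves = set(tree.leaves().tolist())
    children = tree.children()

    def clade(w):
        if not children[w]:
            return frozenset([tree.names[w]])
        return frozenset().union(*(clade(c) for c in children[w]))

    return frozenset(clade(w) for w in range(tree.n_nodes))


class TestGenotypeDraws:
    def test_zero_drift_tree(self):
        tree = _random_tree(4, np.random.default_rng(6))
        tree.f_edge = np.zeros(tree.n_nodes)
        G, p_leaf = pa.draw_tree_genotypes(tree, 50, 500, maf_min=0.0, rng=0)
        np.testing.assert_allclose(p_leaf, p_leaf[:, :1] @ np.ones((1, 4)))
        # genotype means track 2 p_anc
        resid = G.dosages.mean(axis=1) - 2 * p_leaf[:, 0]
        assert np.abs(resid).mean() < 0.05

    def test_two_leaf_fst(self):
        """Hudson-style FST between two leaves with f_total 0.2 each."""
        tree = edges_from_deltas(
            parent=np.array([-1, 0, 0]),
            names=["T", "A", "B"],
            delta=np.array([0.0, 0.2, 0.2]),
        )
        n_per, m = 100, 5000
        G, p_leaf = pa.draw_tree_genotypes(tree, n_per, m, maf_min=0.0, rng=1)
        pA = G.dosages[:, :n_per].mean(axis=1) / 2
        pB = G.dosages[:, n_per:].mean(axis=1) / 2
        num = (pA - pB) ** 2 - (
            pA * (1 - pA) / (2 * n_per - 1) + pB * (1 - pB) / (2 * n_per - 1)
        )
        den = pA * (1 - pB) + pB * (1 - pA)
        fst = num.sum() / den.sum()
        assert abs(fst - 0.2) < 0.02

    def test_maf_filter_enforced(self):
        tree = _random_tree(5, np.random.default_rng(7))
        G, _ = pa.draw_tree_genotypes(tree, 20, 2000, maf_min=0.01, rng=2)
        assert G.maf().min() >= 0.01


def test_recovery_from_estimated_coancestry(admix_model_200):
    """Topology and delta recovered from genotype-based coancestry estimates."""
    rng = np.random.default_rng(30)
    true = _random_tree(8, rng)
    labels_per = 30
    hits = 0
    delta_errs = []
    reps = 20
    for _ in range(reps):
        G, _ = pa.draw_tree_genotypes(true, labels_per, 20_000, rng=rng)
        labels = np.repeat(true.leaf_names(), labels_per)
        phi = pa.corrected_kinship(G, labels=labels)
        theta_i = pa.coancestry_from_kinship(phi)
        theta_s, names = pa.subpop_coancestry(theta_i, labels)
        fit = pa.fit_tree(theta_s, names)
        if _topology_signature(fit) == _topology_signature(true):
            hits += 1
            fit_thetas, fit_names = pa.tree_coancestry(fit)
            order = [fit_names.index(nm) for nm in true.leaf_names()]
            true_thetas, _ = pa.tree_coancestry(true)
            delta_errs.append(np.sqrt(np.mean(
                (fit_thetas[np.ix_(order, order)] - true_thetas) ** 2
            )))
    assert hits >= 0.9 * reps
    assert np.mean(delta_errs) < 0.01


def test_newick_roundtrip():
    tree = _random_tree(6, np.random.default_rng(8))
    back = from_newick(to_newick(tree))
    theta_a, names_a = pa.tree_coancestry(tree)
    theta_b, names_b = pa.tree_coancestry(back)
    order = [names_b.index(nm) for nm in names_a]
    np.testing.assert_allclose(theta_b[np.ix_(order, order)], theta_a,
                               atol=1e-9)
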