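"""Subpopulation-tree genotype simulation and tree fitting from coancestry.

A rooted tree relates K subpopulations (the leaves) to an ancestral
population T (the root).  Each non-root node carries an edge inbreeding
coefficient f (drift along the edge) which determines an *additive edge*
delta and a cumulative total inbreeding f_total:

    f_total(w) = f_total(parent) + delta(w),
    delta(w)   = f_edge(w) * (1 - f_total(parent)).

Coancestry between two subpopulations is the sum of delta over their common
ancestors, so coancestry grows monotonically with the depth of the MRCA.
Fitting inverts this: topology by WPGMA hierarchical clustering on
max(coancestry) - coancestry, edge lengths by non-negative least squares on
the common-ancestor design, with a non-negative intercept delta0 absorbing
small estimation biases.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import nnls

from popassoc._util import as_rng, uniform_p_anc_sampler
from popassoc.data_io import GenotypeMatrix


@dataclass
class SubpopTree:
    """Rooted subpopulation tree in parent-pointer form.

    Nodes are indexed 0..n_nodes-1 in a topological order (parents before
    children); ``parent[root] == -1``.  Leaves carry subpopulation names.
    Any of ``f_edge`` / ``delta`` / ``f_total`` may be None until filled by
    :func:`additive_edges` or its inverse.
    """

    parent: np.ndarray
    names: list[str]  # per node; internal nodes may have synthetic names
    f_edge: np.ndarray | None = None
    delta: np.ndarray | None = None
    f_total: np.ndarray | None = None
    delta0: float = 0.0

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        n = self.parent.size
        if len(self.names) != n:
            raise ValueError("names length mismatch")
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        if np.any(self.parent[1:] >= np.arange(1, n)) or self.parent[0] != -1:
            raise ValueError(
                "nodes must be topologically ordered with the root first"
            )

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return 0

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for w in range(1, self.n_nodes):
            ch[self.parent[w]].append(w)
        return ch

    def leaves(self) -> np.ndarray:
        has_child = np.zeros(self.n_nodes, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~has_child)

    def leaf_names(self) -> list[str]:
        return [self.names[w] for w in self.leaves()]

    def ancestor_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_nodes): entry [w, v] true if w is an
        ancestor-or-self of v."""
        n = self.n_nodes
        anc = np.eye(n, dtype=bool)
        for v in range(1, n):  # topological order: parent rows already done
            anc[:, v] |= anc[:, self.parent[v]]
        return anc


def additive_edges(tree: SubpopTree) -> SubpopTree:
    """Fill delta and f_total from per-edge inbreeding coefficients."""
    if tree.f_edge is None:
        raise ValueError("tree.f_edge must be set")
    f_edge = np.asarray(tree.f_edge, dtype=float)
    if np.any((f_edge[1:] < 0) | (f_edge[1:] > 1)):
        raise ValueError("edge inbreeding coefficients must lie in [0, 1]")
    n = tree.n_nodes
    f_total = np.zeros(n)
    delta = np.zeros(n)
    for w in range(1, n):
        fp = f_total[tree.parent[w]]
        delta[w] = f_edge[w] * (1.0 - fp)
        f_total[w] = fp + delta[w]
    return SubpopTree(
        parent=tree.parent.copy(),
        names=list(tree.names),
        f_edge=f_edge.copy(),
        delta=delta,
        f_total=f_total,
        delta0=tree.delta0,
    )


def edges_from_deltas(
    parent: np.ndarray, names: list[str], delta: np.ndarray, delta0: float = 0.0
) -> SubpopTree:
    """Inverse map: recover edge inbreeding from additive edges.

    delta0 acts as an extra edge above the root for the conversion (shifting
    every f_total by delta0) but is stored separately so simulation can
    ignore it.
    """
    tree = SubpopTree(parent=parent, names=names, delta=np.asarray(delta, float),
                      delta0=delta0)
    n = tree.n_nodes
    f_total = np.zeros(n)
    f_edge = np.zeros(n)
    f_total[0] = delta0
    for w in range(1, n):
        fp = f_total[tree.parent[w]]
        f_total[w] = fp + tree.delta[w]
        f_edge[w] = tree.delta[w] / (1.0 - fp) if fp < 1.0 else np.nan
    tree.f_edge = f_edge
    tree.f_total = f_total
    return tree


def tree_coancestry(tree: SubpopTree) -> tuple[np.ndarray, list[str]]:
    """Subpopulation coancestry: sums of delta over common ancestors (+delta0)."""
    if tree.delta is None:
        raise ValueError("tree.delta must be set (run additive_edges)")
    anc = tree.ancestor_matrix()
    leaves = tree.leaves()
    # indicator I[w, u]: node w is an ancestor-or-self of leaf u (root excluded
    # from the sum: it has no additive edge)
    ind = anc[:, leaves].astype(float)
    ind[tree.root, :] = 0.0
    theta = ind.T @ (tree.delta[:, None] * ind) + tree.delta0
    return (theta + theta.T) / 2.0, [tree.names[w] for w in leaves]


def draw_tree_genotypes(
    tree: SubpopTree,
    n_per_subpop: int | np.ndarray,
    m: int,
    p_anc_sampler=None,
    maf_min: float = 0.01,
    rng: np.random.Generator | int | None = None,
    max_redraw_rounds: int = 1000,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw genotypes by evolving allele frequencies down the tree.

    Frequencies drift along each edge by a Balding–Nichols draw with that
    edge's inbreeding coefficient; individuals of each leaf subpopulation
    draw Binomial(2, p_leaf).  Loci with sample MAF < ``maf_min`` are redrawn
    wholesale from the ancestral distribution.  Returns the genotypes and the
    (m, K) matrix of leaf allele frequencies.
    """
    from popassoc._util import balding_nichols

    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    if tree.f_edge is None:
        raise ValueError("tree.f_edge must be set")
    rng = as_rng(rng)
    if p_anc_sampler is None:
        p_anc_sampler = uniform_p_anc_sampler()
    leaves = tree.leaves()
    K = leaves.size
    counts = np.broadcast_to(np.asarray(n_per_subpop, dtype=int), (K,))
    if np.any(counts < 1):
        raise ValueError("need at least one individual per subpopulation")
    n = int(counts.sum())
    leaf_of_ind = np.repeat(np.arange(K), counts)

    def draw_block(size: int):
        p_anc = np.asarray(p_anc_sampler(size, rng), dtype=float)
        p_node = np.empty((tree.n_nodes, size))
        p_node[tree.root] = p_anc
        for w in range(1, tree.n_nodes):
            p_node[w] = balding_nichols(
                p_node[tree.parent[w]], float(tree.f_edge[w]), rng
            )
        p_leaf = p_node[leaves].T  # (size, K)
        x = rng.binomial(2, p_leaf[:, leaf_of_ind]).astype(np.int8)
        return p_leaf, x

    p_leaf, x = draw_block(m)
    for _ in range(max_redraw_rounds):
        p_samp = x.mean(axis=1) / 2.0
        maf = np.minimum(p_samp, 1.0 - p_samp)
        bad = maf < maf_min
        if not bad.any():
            break
        idx = np.flatnonzero(bad)
        p_leaf[idx], x[idx] = draw_block(idx.size)
    else:
        raise RuntimeError(
            f"loci below MAF {maf_min} remained after {max_redraw_rounds} rounds"
        )

    names = [tree.names[w] for w in leaves]
    G = GenotypeMatrix(
        dosages=x,
        locus_ids=[f"snp{i}" for i in range(m)],
        individual_ids=[
            f"{names[u]}-{j}" for u, c in enumerate(counts) for j in range(c)
        ],
    )
    return G, p_leaf


def subpop_coancestry(
    theta_indiv: np.ndarray, labels: np.ndarray | list
) -> tuple[np.ndarray, list[str]]:
    """Average individual coancestry within subpopulation blocks.

    The input must be on the coancestry scale (inbreeding on the diagonal);
    the u = v block average includes the diagonal self terms.
    """
    theta = np.asarray(theta_indiv, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != theta.shape[0]:
        raise ValueError("labels length mismatch")
    uniq = [str(u) for u in dict.fromkeys(labels)]  # first-appearance order
    groups = [np.flatnonzero(labels == u) for u in uniq]
    if any(g.size == 0 for g in groups):
        raise ValueError("empty subpopulation")
    K = len(uniq)
    out = np.empty((K, K))
    for a in range(K):
        for b in range(a, K):
            out[a, b] = out[b, a] = theta[np.ix_(groups[a], groups[b])].mean()
    return out, uniq


def _wpgma(dist: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """WPGMA hierarchical clustering, returning a parent-pointer tree.

    Merge heights halve the pair distance; ties are broken by the
    lexicographically smallest (creation-order) cluster index pair, making
    the fit deterministic.
    """
    K = dist.shape[0]
    d = {}
    clusters = list(range(K))  # cluster ids, id < K => leaf u
    for a in range(K):
        for b in range(a + 1, K):
            d[(a, b)] = dist[a, b]
    # build child lists; assign final indices at the end
    children: dict[int, tuple[int, int]] = {}
    next_id = K
    while len(clusters) > 1:
        best = min(
            (pair for pair in d if pair[0] in clusters and pair[1] in clusters),
            key=lambda pr: (d[pr], pr),
        )
        a, b = best
        new = next_id
        next_id += 1
        children[new] = (a, b)
        for c in clusters:
            if c in (a, b):
                continue
            key = (min(a, c), max(a, c))
            key2 = (min(b, c), max(b, c))
            d[(min(new, c), max(new, c))] = (d[key] + d[key2]) / 2.0
        clusters = [c for c in clusters if c not in (a, b)] + [new]
    root_id = clusters[0]

    # relabel into topological (root-first) parent-pointer arrays
    n_nodes = next_id  # == 2K - 1
    order: list[int] = []
    stack = [root_id]
    while stack:
        c = stack.pop()
        order.append(c)
        if c in children:
            stack.extend(children[c])
    remap = {c: i for i, c in enumerate(order)}
    parent = np.full(n_nodes, -1, dtype=int)
    out_names = [""] * n_nodes
    for c in order:
        if c in children:
            out_names[remap[c]] = f"node{remap[c]}"
        else:
            out_names[remap[c]] = names[c]
    for c, (x, y) in children.items():
        parent[remap[x]] = remap[c]
        parent[remap[y]] = remap[c]
    return parent, out_names


def fit_tree(
    theta_subpop: np.ndarray, names: list[str] | None = None
) -> SubpopTree:
    """Fit topology and edge lengths to a subpopulation coancestry matrix.

    Topology: WPGMA on d(u, v) = max(theta) - theta_uv.  Edge lengths: NNLS
    on the common-ancestor indicator design with a non-negative intercept
    delta0 (an extra shared edge absorbing estimation bias); edge inbreeding
    is then recovered by inverting the additive-edge relation, treating
    delta0 as a root-adjacent edge excluded from simulation.
    """
    theta = np.asarray(theta_subpop, dtype=float)
    K = theta.shape[0]
    if theta.ndim != 2 or theta.shape[1] != K or K < 2:
        raise ValueError("theta must be square with K >= 2")
    if not np.allclose(theta, theta.T, atol=1e-8):
        raise ValueError("theta must be symmetric")
    if names is None:
        names = [f"S{u + 1}" for u in range(K)]
    dist = theta.max() - theta
    parent, node_names = _wpgma(dist, list(names))
    tree = SubpopTree(parent=parent, names=node_names)

    anc = tree.ancestor_matrix()
    leaves = tree.leaves()
    leaf_name_order = [node_names[w] for w in leaves]
    col_of_name = {nm: i for i, nm in enumerate(names)}
    # design rows: unordered subpopulation pairs incl. u == v
    rows = []
    targets = []
    non_root = np.arange(1, tree.n_nodes)
    for ia in range(K):
        for ib in range(ia, K):
            u, v = leaves[ia], leaves[ib]
            common = anc[:, u] & anc[:, v]
            rows.append(np.concatenate(([1.0], common[non_root].astype(float))))
            targets.append(
                theta[col_of_name[node_names[u]], col_of_name[node_names[v]]]
            )
    A = np.asarray(rows)
    b = np.asarray(targets)
    coef, _ = nnls(A, b)
    delta0 = float(coef[0])
    delta = np.zeros(tree.n_nodes)
    delta[non_root] = coef[1:]
    return edges_from_deltas(parent, node_names, delta, delta0=delta0)


def to_newick(tree: SubpopTree) -> str:
    """Newick string with additive edges (delta) as branch lengths."""
    if tree.delta is None:
        raise ValueError("tree.delta must be set")
    children = tree.children()

    def render(w: int) -> str:
        if not children[w]:
            label = tree.names[w]
        else:
            label = "(" + ",".join(render(c) for c in children[w]) + ")"
        if w == tree.root:
            return label
        return f"{label}:{tree.delta[w]:.10g}"

    return render(tree.root) + ";"


def from_newick(newick: str, delta0: float = 0.0) -> SubpopTree:
    """Parse a newick string whose branch lengths are additive edges."""
    dt = dendropy.Tree.get(data=newick, schema="newick")
    nodes = [nd for nd in dt.preorder_node_iter()]
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    names: list[str] = []
    delta = np.zeros(len(nodes))
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            delta[i] = float(nd.edge.length or 0.0)
        names.append(
            str(nd.taxon.label) if nd.taxon is not None else f"node{i}"
        )
    return edges_from_deltas(parent, names, delta, delta0=delta0)
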