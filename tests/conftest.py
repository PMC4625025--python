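import numpy as np
import pytest

from mipscan.io import (
    load_table1,
    load_table2,
    load_table3_profiles,
    load_table3_rules,
)
from mipscan.template import load_positions, load_template


@pytest.fixture(scope="session")
def gene_models():
    return load_table1()


@pytest.fixture(scope="session")
def profiles():
    return load_table2()


@pytest.fixture(scope="session")
def substrate_rules():
    return {r.substrate: r for r in load_table3_rules()}


@pytest.fixture(scope="session")
def sdp_observations():
    return load_table3_profiles()


@pytest.fixture(scope="session")
def template():
    return load_template()


@pytest.fixture(scope="session")
def positions():
    return load_positions()


def random_additive_tree(n_leaves, rng):
    """Random unrooted binary topology with random branch lengths.

    Returns (edges, lengths, leaves) where edges connect integer node ids,
    leaves are ids 0..n_leaves-1 and internal nodes count upward.
    """
    leaves = list(range(n_leaves))
    internal = n_leaves
    edges = [(internal, leaves[0]), (internal, leaves[1]), (internal, leaves[2])]
    internal += 1
    for leaf in leaves[3:]:
        i = rng.integers(len(edges))
        u, v = edges.pop(i)
        w = internal
        internal += 1
        edges.extend([(u, w), (w, v), (w, leaf)])
    lengths = {e: float(rng.uniform(0.5, 2.0)) for e in edges}
    return edges, lengths, leaves


def tree_distances(edges, lengths, leaves):
    """Leaf-to-leaf path-length matrix of an edge-weighted tree."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_edge(*e, weight=lengths[e])
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nx.shortest_path_length(
                g, leaves[i], leaves[j], weight="weight")
    return d


def tree_splits(edges, leaves):
    """Non-trivial bipartitions of the leaf set, one per internal edge.

    Each split is normalised as the frozenset of the side not containing
    the smallest leaf id/name.
    """
    import networkx as nx

    leafset = set(leaves)
    anchor = min(leaves)
    splits = set()
    for e in edges:
        g = nx.Graph()
        for other in edges:
            if other != e:
                g.add_edge(*other)
        g.add_nodes_from(e)
        side = nx.node_connected_component(g, e[0]) if e[0] in g else {e[0]}
        part = frozenset(leafset & side)
        if anchor in part:
            part = frozenset(leafset - part)
        if 1 < len(part) < len(leafset) - 1:
            splits.add(part)
    return splits


def treenode_splits(tree):
    """Non-trivial bipartitions of a skbio TreeNode (by tip name)."""
    tips = {t.name for t in tree.tips()}
    anchor = min(tips)
    splits = set()
    for node in tree.non_tips(include_self=False):
        part = frozenset(t.name for t in node.tips())
        if anchor in part:
            part = frozenset(tips - part)
        if 1 < len(part) < len(tips) - 1:
            splits.add(part)
    return splits


def best_leastsquares_topology(dm_array, leaf_names, rng_unused=None):
    """Brute-force topology fit: enumerate all unrooted binary topologies,
    fit branch lengths by non-negative least squares, return the splits of
    the topology with the smallest residual."""
    from itertools import combinations

    from scipy.optimize import nnls

    n = len(leaf_names)
    topologies = _enumerate_topologies(n)
    pairs = list(combinations(range(n), 2))
    target = np.array([dm_array[i, j] for i, j in pairs])
    best = None
    for edges in topologies:
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(edges)
        edge_index = {frozenset(e): k for k, e in enumerate(edges)}
        a = np.zeros((len(pairs), len(edges)))
        for row, (i, j) in enumerate(pairs):
            path = nx.shortest_path(g, i, j)
            for u, v in zip(path, path[1:]):
                a[row, edge_index[frozenset((u, v))]] = 1.0
        x, _ = nnls(a, target)
        sse = float((((a @ x) - target) ** 2).sum())
        cand = (sse, tree_splits(edges, list(range(n))))
        if best is None or cand[0] < best[0]:
            best = cand
    # map integer leaves to names
    return {frozenset(leaf_names[i] for i in part) for part in best[1]}


def _enumerate_topologies(n_leaves):
    """All unrooted binary topologies on leaves 0..n-1 (3 for n=4, 15 for n=5)."""
    base = [[(n_leaves, 0), (n_leaves, 1), (n_leaves, 2)]]
    next_internal = n_leaves + 1
    for leaf in range(3, n_leaves):
        grown = []
        for edges in base:
            for i in range(len(edges)):
                u, v = edges[i]
                w = next_internal
                new_edges = edges[:i] + edges[i + 1:] + [(u, w), (w, v),
                                                         (w, leaf)]
                grown.append(new_edges)
        base = grown
        next_internal += 1
    return base
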