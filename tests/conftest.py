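"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from nsltp import default_grammar, load_family_fixture
from nsltp.phylo_lite import TreeNode


@pytest.fixture(scope="session")
def fixture_rows():
    return load_family_fixture()


@pytest.fixture(scope="session")
def grammar():
    return default_grammar()


# ---------------------------------------------------------------------------
# Brute-force ECM oracle: enumerate every 8-subset of cysteine positions and
# keep those satisfying the C/C/CC/CXC/C/C arrangement, the spacing bounds,
# and cysteine-free spacer segments. Independent of the scanner's shortcut
# (consecutive cysteines).

def brute_force_scan(mature: str, bounds) -> list[tuple[int, ...]]:
    cys = [i for i, aa in enumerate(mature) if aa == "C"]
    hits = []
    for p in itertools.combinations(cys, 8):
        if p[3] != p[2] + 1 or p[5] != p[4] + 2:
            continue
        spacings = (p[1] - p[0] - 1, p[2] - p[1] - 1, p[4] - p[3] - 1,
                    p[6] - p[5] - 1, p[7] - p[6] - 1)
        if any(not (lo <= s <= hi) for s, (lo, hi) in zip(spacings, bounds)):
            continue
        segments = (mature[p[0] + 1:p[1]], mature[p[1] + 1:p[2]],
                    mature[p[3] + 1:p[4]], mature[p[4] + 1:p[5]],
                    mature[p[5] + 1:p[6]], mature[p[6] + 1:p[7]])
        if any("C" in seg for seg in segments):
            continue
        hits.append(tuple(i + 1 for i in p))
    return sorted(hits)


# ---------------------------------------------------------------------------
# Random unrooted binary trees with branch lengths, for NJ consistency
# checks: leaf-pair path distances on a tree form an additive matrix.

def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random tree by sequential edge splitting; returns (D, leaf_ids)."""
    g = nx.Graph()
    internal = n_leaves  # internal node ids start above the leaves
    g.add_edge(0, internal, length=rng.uniform(0.1, 1.0))
    g.add_edge(1, internal, length=rng.uniform(0.1, 1.0))
    g.add_edge(2, internal, length=rng.uniform(0.1, 1.0))
    next_internal = internal + 1
    for leaf in range(3, n_leaves):
        u, v = list(g.edges)[rng.integers(0, g.number_of_edges())]
        length = g.edges[u, v]["length"]
        split = rng.uniform(0.2, 0.8)
        g.remove_edge(u, v)
        w = next_internal
        next_internal += 1
        g.add_edge(u, w, length=length * split)
        g.add_edge(v, w, length=length * (1 - split))
        g.add_edge(leaf, w, length=rng.uniform(0.1, 1.0))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(n_leaves):
            D[i, j] = dist[i][j]
    ids = [f"t{i}" for i in range(n_leaves)]
    return D, ids


def tree_leaf_distances(tree: TreeNode) -> dict[frozenset, float]:
    """Path length between every leaf pair of a TreeNode tree."""
    dists: dict[frozenset, float] = {}

    def walk(node: TreeNode) -> list[tuple[str, float]]:
        if node.is_leaf():
            return [(node.name, 0.0)]
        per_child = []
        for child, length in node.children:
            per_child.append([(n, d + length) for n, d in walk(child)])
        for a, b in itertools.combinations(range(len(per_child)), 2):
            for n1, d1 in per_child[a]:
                for n2, d2 in per_child[b]:
                    dists[frozenset((n1, n2))] = d1 + d2
        return [item for sub in per_child for item in sub]

    walk(tree)
    return dists
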