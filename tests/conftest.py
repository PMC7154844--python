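"""Shared fixtures and helpers: engineered matrices and random trees."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from splkit.expression import ExpressionMatrix


def matrix_from_membership(
    membership: list[tuple[str, list[str]]], groups: list[str]
) -> ExpressionMatrix:
    """Build a one-sample-per-group 0/1 matrix from explicit memberships.

    ``membership`` lists ``(transcript_id, groups_it_is_expressed_in)``.
    """
    samples = [f"{g}_s1" for g in groups]
    gmap = {f"{g}_s1": g for g in groups}
    data = np.zeros((len(membership), len(groups)))
    ids = []
    for i, (tid, present) in enumerate(membership):
        ids.append(tid)
        for g in present:
            data[i, groups.index(g)] = 1.0
    return ExpressionMatrix(pd.DataFrame(data, index=ids, columns=samples), gmap)


@pytest.fixture
def age_venn_matrix() -> ExpressionMatrix:
    """A four-age matrix engineered to the published membership partition.

    81 expressed transcripts: group-specific 3/3/3/14, all four ages 29,
    plus multi-age cells chosen so per-age totals are 42/47/53/64.
    """
    groups = ["age5", "age12", "age18", "age25"]
    cells = [
        (["age5"], 3),
        (["age12"], 3),
        (["age18"], 3),
        (["age25"], 14),
        (groups, 29),
        (["age12", "age18", "age25"], 7),
        (["age5", "age18", "age25"], 2),
        (["age5", "age12"], 8),
        (["age18", "age25"], 12),
    ]
    membership = []
    k = 0
    for present, count in cells:
        for _ in range(count):
            membership.append((f"t{k:03d}", present))
            k += 1
    return matrix_from_membership(membership, groups)


TISSUES = [
    "fiber_root", "leg_root", "main_root_epiderm", "main_root_cortex",
    "rhizome", "arm_root", "stem", "leaf_peduncle", "leaflet_pedicel",
    "leaf_blade", "fruit_peduncle", "fruit_pedicel", "fruit_flesh", "seed",
]


@pytest.fixture
def tissue_breadth_matrix() -> ExpressionMatrix:
    """A 14-tissue matrix with 96 expressed transcripts: 16 ubiquitous,
    9 single-tissue (5 fruit pedicel, 2 leaflet pedicel, 1 fruit peduncle,
    1 main root cortex) and 71 in exactly two tissues."""
    membership: list[tuple[str, list[str]]] = []
    k = 0
    for _ in range(16):
        membership.append((f"t{k:03d}", list(TISSUES)))
        k += 1
    singles = (
        ["fruit_pedicel"] * 5
        + ["leaflet_pedicel"] * 2
        + ["fruit_peduncle"]
        + ["main_root_cortex"]
    )
    for tis in singles:
        membership.append((f"t{k:03d}", [tis]))
        k += 1
    for i in range(71):
        pair = [TISSUES[i % 14], TISSUES[(i + 1) % 14]]
        membership.append((f"t{k:03d}", pair))
        k += 1
    return matrix_from_membership(membership, TISSUES)


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree as (edges, leaf names); edges weighted > 0.

    Returns a networkx Graph whose leaf nodes are the taxon names, suitable
    for deriving an additive distance matrix.
    """
    import networkx as nx

    g = nx.Graph()
    leaves = [f"L{i}" for i in range(n_taxa)]
    # start from a 3-star, attach remaining leaves to random edges
    center = "I0"
    internal = 1
    for leaf in leaves[:3]:
        g.add_edge(center, leaf, weight=float(rng.uniform(0.1, 1.0)))
    for leaf in leaves[3:]:
        u, v = list(g.edges)[rng.integers(g.number_of_edges())]
        w = g.edges[u, v]["weight"]
        g.remove_edge(u, v)
        mid = f"I{internal}"
        internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, leaf, weight=float(rng.uniform(0.1, 1.0)))
    return g, leaves


def tree_leaf_distances(g, leaves) -> np.ndarray:
    import networkx as nx

    n = len(leaves)
    d = np.zeros((n, n))
    sp = dict(nx.all_pairs_dijkstra_path_length(g))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sp[leaves[i]][leaves[j]]
    return d


def tree_splits(g, leaves) -> set[frozenset[str]]:
    """Nontrivial bipartitions induced by internal edges of a leaf-labelled tree."""
    import networkx as nx

    leafset = set(leaves)
    canon = set()
    for u, v in list(g.edges):
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(set(nx.node_connected_component(h, u)) & leafset)
        if 1 < len(side) < len(leafset) - 1:
            other = frozenset(leafset - side)
            canon.add(min((side, other), key=lambda x: sorted(x)))
    return canon


def phylotree_splits(tree) -> set[frozenset[str]]:
    """Splits of a splkit PhyloTree, canonicalized like :func:`tree_splits`."""
    g = tree.as_graph()
    leafset = set(tree.leaf_names)
    name = {n: d.get("name") for n, d in g.nodes(data=True)}
    import networkx as nx

    canon = set()
    for u, v in list(g.edges):
        h = g.copy()
        h.remove_edge(u, v)
        side = {name[x] for x in nx.node_connected_component(h, u)} & leafset
        if 1 < len(side) < len(leafset) - 1:
            other = frozenset(leafset - side)
            canon.add(min((frozenset(side), other), key=lambda x: sorted(x)))
    return canon
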