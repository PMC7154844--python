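"""Distance-based phylogeny and clade/group assignment.

Family classification proceeds from an SBP-domain protein alignment: pairwise
p-distances, a neighbor-joining (Saitou–Nei) tree, and nearest-reference
group assignment (the A1–A3 / B1–B3 style grouping of plant SPL families)
with a monophyly report under midpoint rooting. NJ exactly recovers additive
distance matrices, which is what makes the construction testable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import AlignIO, Phylo
from Bio.Phylo.BaseTree import Clade, Tree

__all__ = [
    "PhyloTree",
    "p_distance_matrix",
    "neighbor_joining",
    "assign_groups",
    "patristic_distances",
]


@dataclass
class PhyloTree:
    """An (effectively unrooted) tree with branch lengths, Newick-serializable."""

    tree: Tree

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.get_terminals()]

    def n_branches(self) -> int:
        # every non-root clade carries one branch
        return sum(1 for c in self.tree.find_clades() if c is not self.tree.root)

    def to_newick(self) -> str:
        buf = io.StringIO()
        Phylo.write(self.tree, buf, "newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(Phylo.read(io.StringIO(text), "newick"))

    def as_graph(self) -> nx.Graph:
        """Undirected graph of clades weighted by branch length."""
        g = nx.Graph()
        for clade in self.tree.find_clades(order="level"):
            g.add_node(id(clade), name=clade.name)
            for child in clade.clades:
                bl = child.branch_length if child.branch_length is not None else 0.0
                g.add_node(id(child), name=child.name)
                g.add_edge(id(clade), id(child), weight=float(bl))
        return g


def p_distance_matrix(
    alignment: Sequence[tuple[str, str]] | str | Path,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances over gap-free columns of a protein alignment.

    ``alignment`` may be a path to an aligned FASTA or a list of
    ``(name, sequence)`` pairs of equal length. For each pair, columns where
    either sequence has a gap (``-`` or ``.``) are skipped; the distance is
    the fraction of differing remaining columns. A pair with no comparable
    columns raises, naming the pair.
    """
    if isinstance(alignment, (str, Path)):
        aln = AlignIO.read(str(alignment), "fasta")
        pairs = [(rec.id, str(rec.seq).upper()) for rec in aln]
    else:
        pairs = [(n, s.upper()) for n, s in alignment]
    if len(pairs) < 3:
        raise ValueError("need at least 3 sequences")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise ValueError("alignment is ragged: unequal sequence lengths")
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence names")
    seqs = np.array([list(s) for _, s in pairs])
    gap = (seqs == "-") | (seqs == ".")
    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                raise ValueError(f"no comparable columns between {names[i]} and {names[j]}")
            diff = int((seqs[i, ok] != seqs[j, ok]).sum())
            d[i, j] = d[j, i] = diff / total
    return d, names


def neighbor_joining(
    d: np.ndarray, names: Sequence[str] | None = None
) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion is joined (ties broken
    by the smallest (i, j) index pair in the current ordering); branch
    lengths follow the standard formulas, with negative lengths clamped to
    zero and the deficit moved to the sister branch. The final three nodes
    attach to an unresolved root, giving 2n−3 branches for n leaves.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if names is None:
        names = [f"t{i}" for i in range(n)]
    names = list(names)

    nodes: list[Clade] = [Clade(name=nm) for nm in names]
    dm = d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties by smallest (i, j)
        best = np.unravel_index(np.argmin(q), q.shape)
        i, j = min(best), max(best)
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dm[i, j] - li
        if li < 0:
            lj += -li
            li = 0.0
        elif lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = float(li)
        child_j.branch_length = float(lj)
        new = Clade(clades=[child_i, child_j])
        dk = 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_dm = np.zeros((m - 1, m - 1))
        new_dm[:-1, :-1] = dm[np.ix_(keep, keep)]
        new_dm[-1, :-1] = dk[keep]
        new_dm[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new]
        dm = new_dm

    # resolve the last three around an unrooted center
    a, b, c = nodes
    la = 0.5 * (dm[0, 1] + dm[0, 2] - dm[1, 2])
    lb = 0.5 * (dm[0, 1] + dm[1, 2] - dm[0, 2])
    lc = 0.5 * (dm[0, 2] + dm[1, 2] - dm[0, 1])
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.branch_length = float(max(length, 0.0))
    root = Clade(clades=[a, b, c])
    return PhyloTree(Tree(root=root, rooted=False))


def patristic_distances(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """All-pairs path-length distances between leaves."""
    g = tree.as_graph()
    leaves = {id(t): t.name for t in tree.tree.get_terminals()}
    names = list(leaves.values())
    idx = list(leaves.keys())
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    n = len(idx)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = lengths[idx[i]][idx[j]]
    return d, names


def assign_groups(
    tree: PhyloTree, references: Mapping[str, str]
) -> dict[str, dict]:
    """Assign each unlabeled leaf the group of its nearest reference leaf.

    Nearness is patristic (path-length) distance; ties are broken by the
    lexicographically smallest reference leaf name and flagged ambiguous.
    The result maps each query leaf to ``{"group", "nearest_ref",
    "distance", "ambiguous"}``, plus a ``"__monophyly__"`` entry reporting,
    per group, whether its leaves are monophyletic under midpoint rooting.
    Every group must have at least one reference present in the tree.
    """
    leaf_names = set(tree.leaf_names)
    groups = sorted(set(references.values()))
    for g in groups:
        if not any(leaf in leaf_names for leaf, gr in references.items() if gr == g):
            raise ValueError(f"group {g!r} has no reference leaf in the tree")

    d, names = patristic_distances(tree)
    pos = {nm: i for i, nm in enumerate(names)}
    refs = sorted(r for r in references if r in leaf_names)
    queries = [nm for nm in names if nm not in references]

    out: dict[str, dict] = {}
    for q in queries:
        dists = [(d[pos[q], pos[r]], r) for r in refs]
        dmin = min(dist for dist, _ in dists)
        tied = sorted(r for dist, r in dists if abs(dist - dmin) < 1e-12)
        winner = tied[0]
        out[q] = {
            "group": references[winner],
            "nearest_ref": winner,
            "distance": float(dmin),
            "ambiguous": len({references[r] for r in tied}) > 1,
        }

    rooted = Phylo.read(io.StringIO(tree.to_newick()), "newick")
    rooted.root_at_midpoint()
    mono: dict[str, bool] = {}
    for g in groups:
        members = [
            t for t in rooted.get_terminals()
            if references.get(t.name) == g or out.get(t.name, {}).get("group") == g
        ]
        mono[g] = bool(rooted.is_monophyletic(members)) if members else False
    out["__monophyly__"] = mono
    return out
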