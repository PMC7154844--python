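"""Spearman co-expression networks, p-value ladders and subsampling nulls.

The survey's central bespoke procedure: all-pairs Spearman rank correlation
over a transcript set, an undirected graph keeping pairs with p at or below
a significance threshold, and two ways of judging the resulting network
against chance — a *ladder* of increasingly strict thresholds compared with
a size-matched set of unknown background transcripts, and a *subsampling*
scheme that rebuilds the network from random two-thirds subsets (20
replicates by default) of the focal set and of background controls.

Conventions, chosen to match how such networks are reported:

* A transcript with no surviving edge at a threshold is **not** a node;
  node counts therefore fall as the threshold tightens.
* p-values are raw (no multiple-testing correction): the procedure
  thresholds raw p from 0.05 down to 1e-8. This is a real statistical
  caveat — at alpha 0.05 about 5% of independent pairs connect — and is why
  the negative controls exist.
* The p-value of a correlation uses the t approximation
  ``t = rho * sqrt((n-2) / (1-rho^2))`` with n−2 degrees of freedom; an
  exact rank-permutation p is available for small sample counts.
* Zero-variance transcripts have no defined rank correlation and are
  dropped with a warning before the correlation pass.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "CoexpressionGraph",
    "LadderResult",
    "SubsampleSummary",
    "spearman_rho",
    "rho_pvalue",
    "exact_rho_pvalue",
    "correlation_pass",
    "build_network",
    "average_connectivity",
    "mcl_cluster",
    "pvalue_ladder",
    "subsample_null",
    "graph_to_edge_tsv",
    "plot_ladder",
]


@dataclass
class CoexpressionGraph:
    """Thresholded Spearman graph; nodes are transcripts with ≥ 1 edge."""

    graph: nx.Graph
    alpha: float
    dropped: tuple[str, ...] = ()  # zero-variance transcripts excluded upstream

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class LadderResult:
    """Node/edge counts of focal and control networks along an alpha ladder."""

    alphas: tuple[float, ...]
    focal_nodes: tuple[int, ...]
    focal_edges: tuple[int, ...]
    control_nodes: tuple[int, ...]
    control_edges: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alphas,
                "focal_nodes": self.focal_nodes,
                "focal_edges": self.focal_edges,
                "control_nodes": self.control_nodes,
                "control_edges": self.control_edges,
            }
        )


@dataclass
class SubsampleSummary:
    """Replicate statistics of subsampled focal and control networks."""

    k: int
    reps: int
    alphas: tuple[float, ...]
    focal_node_mean: tuple[float, ...]
    focal_node_sd: tuple[float, ...]
    focal_edge_mean: tuple[float, ...]
    focal_edge_sd: tuple[float, ...]
    control_node_mean: tuple[float, ...]
    control_node_sd: tuple[float, ...]
    control_edge_mean: tuple[float, ...]
    control_edge_sd: tuple[float, ...]
    focal_counts: np.ndarray = field(repr=False, default=None)  # (reps, alphas, 2)
    control_counts: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alphas,
                "focal_node_mean": self.focal_node_mean,
                "focal_node_sd": self.focal_node_sd,
                "focal_edge_mean": self.focal_edge_mean,
                "focal_edge_sd": self.focal_edge_sd,
                "control_node_mean": self.control_node_mean,
                "control_node_sd": self.control_node_sd,
                "control_edge_mean": self.control_edge_mean,
                "control_edge_sd": self.control_edge_sd,
            }
        )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks. A zero-variance vector has no defined rank
    correlation; NaN is returned with a warning (such transcripts are
    excluded from graphs upstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        warnings.warn("zero-variance input: Spearman rho undefined")
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def rho_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho at sample size n (t approximation)."""
    if n < 4:
        raise ValueError("n must be >= 4")
    if not np.isfinite(rho) or abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def exact_rho_pvalue(rho: float, n: int) -> float:
    """Exact permutation p for distinct ranks, feasible for n ≤ 8.

    Enumerates all n! rank permutations and counts |rho_perm| ≥ |rho| (with
    a numeric guard at the boundary).
    """
    if n > 8:
        raise ValueError("exact enumeration is limited to n <= 8")
    base = np.arange(1, n + 1, dtype=float)
    target = abs(rho) - 1e-12
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        r = float(np.corrcoef(base, base[list(perm)])[0, 1])
        total += 1
        if abs(r) >= target:
            hits += 1
    return hits / total


def _pvalues_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return p


def correlation_pass(
    matrix: ExpressionMatrix, transcripts: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[str, ...]]:
    """All-pairs Spearman rho and p over a transcript set, one pass.

    Zero-variance transcripts are dropped with a warning; the returned
    tuple is ``(rho_df, p_df, dropped_ids)``.
    """
    missing = set(transcripts) - set(matrix.values.index)
    if missing:
        raise KeyError(f"transcripts not in matrix: {sorted(missing)[:5]}")
    sub = matrix.values.loc[list(transcripts)]
    n = sub.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    var = sub.to_numpy().std(axis=1)
    dropped = tuple(sub.index[var == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance transcripts")
        sub = sub.loc[var > 0]
    ids = list(sub.index)
    if len(ids) < 2:
        return (
            pd.DataFrame(index=ids, columns=ids, dtype=float),
            pd.DataFrame(index=ids, columns=ids, dtype=float),
            dropped,
        )
    ranks = np.apply_along_axis(stats.rankdata, 1, sub.to_numpy())
    rho = np.corrcoef(ranks)
    np.fill_diagonal(rho, 1.0)
    p = _pvalues_from_rho(rho, n)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
        dropped,
    )


def _graph_from_pass(
    rho: pd.DataFrame, p: pd.DataFrame, alpha: float
) -> nx.Graph:
    g = nx.Graph()
    ids = list(rho.index)
    pv = p.to_numpy()
    rv = rho.to_numpy()
    ii, jj = np.where(np.triu(pv <= alpha, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(ids[i], ids[j], rho=float(rv[i, j]), p=float(pv[i, j]))
    return g


def build_network(
    matrix: ExpressionMatrix, transcripts: Sequence[str], alpha: float = 0.05
) -> CoexpressionGraph:
    """Threshold the all-pairs Spearman correlations at ``alpha``.

    Fewer than two usable transcripts yield an empty graph rather than an
    error (the subsampling machinery hits this regularly at tight alphas).
    """
    rho, p, dropped = correlation_pass(matrix, transcripts)
    if len(rho) < 2:
        return CoexpressionGraph(nx.Graph(), alpha, dropped)
    return CoexpressionGraph(_graph_from_pass(rho, p, alpha), alpha, dropped)


def average_connectivity(graph: CoexpressionGraph | nx.Graph) -> float:
    """Mean node degree, 2·|edges| / |nodes|."""
    g = graph.graph if isinstance(graph, CoexpressionGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("average connectivity is undefined on an empty graph")
    return 2.0 * g.number_of_edges() / g.number_of_nodes()


def mcl_cluster(
    graph: CoexpressionGraph | nx.Graph,
    inflation: float = 2.0,
    *,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[set[str]], bool]:
    """Markov clustering of an undirected graph.

    Column-stochastic adjacency with self-loops, alternated expansion
    (matrix squaring) and inflation (elementwise power + renormalization)
    with pruning of entries below ``prune``, until the maximum column change
    drops below ``tol`` or ``max_iter`` is hit. Clusters are the connected
    components of the converged matrix's support; every node lands in
    exactly one cluster. Returns ``(clusters, converged)``; on hitting the
    iteration cap the current clustering is returned with ``converged``
    False.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    g = graph.graph if isinstance(graph, CoexpressionGraph) else graph
    nodes = list(g.nodes)
    if not nodes:
        raise ValueError("cannot cluster an empty graph")
    a = nx.to_numpy_array(g, nodelist=nodes)
    np.fill_diagonal(a, 1.0)  # self-loops stabilize the random walk
    m = a / a.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = m @ m  # expansion
        m = np.power(m, inflation)  # inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL hit the iteration cap before converging")

    support = nx.Graph()
    support.add_nodes_from(range(len(nodes)))
    ii, jj = np.where(m > 0)
    for i, j in zip(ii, jj):
        if i != j:
            support.add_edge(i, j)
    clusters = [
        {nodes[i] for i in comp} for comp in nx.connected_components(support)
    ]
    clusters.sort(key=lambda c: (-len(c), sorted(c)[0]))
    return clusters, converged


def pvalue_ladder(
    matrix: ExpressionMatrix,
    focal_ids: Sequence[str],
    control_ids: Sequence[str],
    alphas: Sequence[float],
) -> LadderResult:
    """Node/edge counts of focal and control networks along an alpha ladder.

    Thresholds must be strictly decreasing; both sets share one correlation
    pass each, re-thresholded per alpha. Counts are non-increasing along
    the ladder by construction.
    """
    alphas = list(alphas)
    if any(a2 >= a1 for a1, a2 in zip(alphas, alphas[1:])):
        raise ValueError("alphas must be strictly decreasing")
    if set(focal_ids) & set(control_ids):
        raise ValueError("focal and control sets overlap")

    out: dict[str, list[int]] = {
        "focal_nodes": [], "focal_edges": [], "control_nodes": [], "control_edges": []
    }
    for label, ids in (("focal", focal_ids), ("control", control_ids)):
        rho, p, _ = correlation_pass(matrix, ids)
        for a in alphas:
            if len(rho) < 2:
                g = nx.Graph()
            else:
                g = _graph_from_pass(rho, p, a)
            out[f"{label}_nodes"].append(g.number_of_nodes())
            out[f"{label}_edges"].append(g.number_of_edges())
    return LadderResult(
        alphas=tuple(alphas),
        focal_nodes=tuple(out["focal_nodes"]),
        focal_edges=tuple(out["focal_edges"]),
        control_nodes=tuple(out["control_nodes"]),
        control_edges=tuple(out["control_edges"]),
    )


def subsample_null(
    matrix: ExpressionMatrix,
    focal_ids: Sequence[str],
    control_pool: Sequence[str],
    alphas: Sequence[float],
    fraction: float = 2.0 / 3.0,
    reps: int = 20,
    seed: int = 0,
) -> SubsampleSummary:
    """Replicated subsampled networks for focal transcripts and controls.

    Per replicate, ``floor(fraction * |focal|)`` focal transcripts are drawn
    without replacement together with an equal-sized draw from the control
    pool; networks are built across the alpha ladder and node/edge counts
    recorded. Means and standard deviations (population, over replicates)
    are reported per alpha per set.
    """
    from .simulate import named_rng

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    focal_ids = list(focal_ids)
    control_pool = list(control_pool)
    k = int(math.floor(fraction * len(focal_ids)))
    if k < 2:
        raise ValueError("subsample size below 2; increase fraction or focal set")
    if len(control_pool) < k:
        raise ValueError("control pool smaller than the subsample size")

    rng = named_rng(seed, "subsample_null")
    alphas = list(alphas)
    focal_counts = np.zeros((reps, len(alphas), 2))
    control_counts = np.zeros((reps, len(alphas), 2))
    for r in range(reps):
        f_draw = list(rng.choice(focal_ids, size=k, replace=False))
        c_draw = list(rng.choice(control_pool, size=k, replace=False))
        for arr, ids in ((focal_counts, f_draw), (control_counts, c_draw)):
            rho, p, _ = correlation_pass(matrix, ids)
            for ai, a in enumerate(alphas):
                g = _graph_from_pass(rho, p, a) if len(rho) >= 2 else nx.Graph()
                arr[r, ai, 0] = g.number_of_nodes()
                arr[r, ai, 1] = g.number_of_edges()

    def _stats(arr: np.ndarray, idx: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
        return (
            tuple(arr[:, :, idx].mean(axis=0)),
            tuple(arr[:, :, idx].std(axis=0)),
        )

    fn_m, fn_s = _stats(focal_counts, 0)
    fe_m, fe_s = _stats(focal_counts, 1)
    cn_m, cn_s = _stats(control_counts, 0)
    ce_m, ce_s = _stats(control_counts, 1)
    return SubsampleSummary(
        k=k,
        reps=reps,
        alphas=tuple(alphas),
        focal_node_mean=fn_m,
        focal_node_sd=fn_s,
        focal_edge_mean=fe_m,
        focal_edge_sd=fe_s,
        control_node_mean=cn_m,
        control_node_sd=cn_s,
        control_edge_mean=ce_m,
        control_edge_sd=ce_s,
        focal_counts=focal_counts,
        control_counts=control_counts,
    )


def graph_to_edge_tsv(graph: CoexpressionGraph, path) -> None:
    """Edge list as TSV: idA, idB, rho, p."""
    with open(path, "w") as fh:
        fh.write("idA\tidB\trho\tp\n")
        for u, v, d in sorted(graph.graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['rho']:.6g}\t{d['p']:.6g}\n")


def plot_ladder(ladder: LadderResult, path=None):
    """Simple node/edge ladder curves for focal vs control sets."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    x = -np.log10(np.asarray(ladder.alphas))
    ax1.plot(x, ladder.focal_nodes, "o-", label="focal")
    ax1.plot(x, ladder.control_nodes, "s--", label="control")
    ax1.set_xlabel("-log10 p threshold")
    ax1.set_ylabel("nodes")
    ax1.legend()
    ax2.plot(x, ladder.focal_edges, "o-", label="focal")
    ax2.plot(x, ladder.control_edges, "s--", label="control")
    ax2.set_xlabel("-log10 p threshold")
    ax2.set_ylabel("edges")
    ax2.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
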