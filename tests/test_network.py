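"""Spearman correlation, thresholded networks, MCL, ladders and subsampling."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splkit.expression import ExpressionMatrix
from splkit.network import (
    average_connectivity,
    build_network,
    correlation_pass,
    exact_rho_pvalue,
    graph_to_edge_tsv,
    mcl_cluster,
    pvalue_ladder,
    rho_pvalue,
    spearman_rho,
    subsample_null,
)
from splkit.simulate import SimulationConfig, simulate_expression


def _matrix(values: np.ndarray, prefix="t") -> ExpressionMatrix:
    ids = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"g_s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=ids, columns=samples),
        {s: "g" for s in samples},
    )


class TestSpearmanRho:
    def test_self_correlation(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)

    def test_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_rank_pearson_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        # heavy ties: integer-valued data
        x = rng.integers(0, 5, size=50).astype(float)
        y = rng.integers(0, 5, size=50).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pytest.skip("degenerate draw")
        # independent oracle: average ranks computed by sorting, then Pearson
        def avg_ranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                ranks[order[i : j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        expected = np.sum((rx - rx.mean()) * (ry - ry.mean())) / np.sqrt(
            np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2)
        )
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestRhoPvalue:
    def test_boundaries(self):
        assert rho_pvalue(0.0, 10) == pytest.approx(1.0)
        assert rho_pvalue(1.0, 5) == 0.0
        assert rho_pvalue(-1.0, 12) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rho_pvalue(0.5, 3)

    @pytest.mark.parametrize("n,tol", [(6, 0.03), (7, 0.02)])
    def test_t_approximation_close_to_exact_enumeration(self, n, tol):
        # independent oracle: enumerate all n! rank permutations; mid-p
        # (half-weight on ties) is the standard continuity correction when
        # comparing a discrete permutation law with a continuous
        # approximation. At n = 6 the discrete law is coarse enough that the
        # t approximation deviates up to 0.029 at |rho| ~ 0.14, hence the
        # wider band there; from n = 7 on it is within 0.02 everywhere.
        base = np.arange(1, n + 1, dtype=float)
        counts: dict[float, int] = {}
        for p in itertools.permutations(range(n)):
            r = round(abs(float(np.corrcoef(base, base[list(p)])[0, 1])), 10)
            counts[r] = counts.get(r, 0) + 1
        total = sum(counts.values())
        for r in sorted(counts):
            gt = sum(c for rr, c in counts.items() if rr > r + 1e-9)
            exact_mid = (gt + 0.5 * counts[r]) / total
            assert rho_pvalue(r, n) == pytest.approx(exact_mid, abs=tol)

    def test_exact_option_agrees_with_enumeration(self):
        assert exact_rho_pvalue(1.0, 5) == pytest.approx(2 / 120)
        assert exact_rho_pvalue(0.0, 4) == pytest.approx(1.0, abs=0.2)


class TestBuildNetwork:
    def test_planted_block_is_connected(self):
        cfg = SimulationConfig(
            n_spl=12,
            n_background=0,
            n_samples_per_group={"g": 40},
            block_spec=[(6, 0.95)],
            dropout_rate=0.0,
            seed=7,
        )
        matrix, truth = simulate_expression(cfg)
        block = list(truth[truth.block_id == "block1"].index)
        g = build_network(matrix, matrix.transcript_ids, alpha=0.05)
        sub = g.graph.subgraph(block)
        assert sub.number_of_nodes() == 6
        assert nx.is_connected(sub)

    def test_null_edge_rate_matches_alpha(self):
        alpha, m, reps = 0.05, 25, 8
        rates = []
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            matrix = _matrix(rng.lognormal(size=(m, 30)))
            g = build_network(matrix, matrix.transcript_ids, alpha)
            rates.append(g.n_edges / (m * (m - 1) / 2))
        n_pairs = reps * m * (m - 1) // 2
        se = np.sqrt(alpha * (1 - alpha) / n_pairs)
        assert abs(np.mean(rates) - alpha) < 3 * se + 0.01

    def test_alpha_zero_gives_no_edges(self):
        rng = np.random.default_rng(1)
        matrix = _matrix(rng.random((8, 10)))
        g = build_network(matrix, matrix.transcript_ids, alpha=0.0)
        # only perfectly correlated pairs (p = 0) could survive
        assert all(abs(d["rho"]) == 1.0 for _, _, d in g.graph.edges(data=True))

    def test_isolated_transcripts_are_not_nodes(self):
        rng = np.random.default_rng(2)
        matrix = _matrix(rng.random((10, 12)))
        g = build_network(matrix, matrix.transcript_ids, alpha=1e-8)
        for node in g.graph.nodes:
            assert g.graph.degree(node) >= 1

    def test_zero_variance_dropped_with_warning(self):
        vals = np.vstack([np.ones(10), np.random.default_rng(3).random((4, 10))])
        matrix = _matrix(vals)
        with pytest.warns(UserWarning, match="zero-variance"):
            g = build_network(matrix, matrix.transcript_ids, 0.05)
        assert "t0" in g.dropped

    def test_edge_tsv_export(self, tmp_path):
        rng = np.random.default_rng(4)
        matrix = _matrix(rng.lognormal(size=(6, 20)))
        g = build_network(matrix, matrix.transcript_ids, 0.5)
        p = tmp_path / "edges.tsv"
        graph_to_edge_tsv(g, p)
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "idA\tidB\trho\tp"
        assert len(lines) - 1 == g.n_edges


class TestAverageConnectivity:
    @pytest.mark.parametrize(
        "nodes,edges,expected",
        [(96, 527, 10.979), (90, 409, 9.089)],
    )
    def test_published_network_sizes(self, nodes, edges, expected):
        g = nx.cycle_graph(nodes)  # no isolates
        extra = (
            (i, (i + k) % nodes)
            for k in range(2, nodes)
            for i in range(nodes)
        )
        for u, v in extra:
            if g.number_of_edges() == edges:
                break
            g.add_edge(u, v)
        assert g.number_of_edges() == edges
        assert round(average_connectivity(g), 3) == expected

    def test_triangle(self):
        assert average_connectivity(nx.complete_graph(3)) == 2.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            average_connectivity(nx.Graph())

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_identity(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnm_random_graph(20, int(rng.integers(1, 60)), seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() == 0:
            pytest.skip("all isolates")
        degs = sum(d for _, d in g.degree())
        assert degs == 2 * g.number_of_edges()
        assert average_connectivity(g) == degs / g.number_of_nodes()


class TestMCL:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        clusters, converged = mcl_cluster(g, 2.0)
        assert converged
        assert sorted(sorted(c) for c in clusters) == [
            [0, 1, 2, 3, 4],
            [5, 6, 7, 8, 9],
        ]

    def test_single_clique(self):
        clusters, _ = mcl_cluster(nx.complete_graph(6), 2.0)
        assert len(clusters) == 1 and clusters[0] == set(range(6))

    def test_barbell_splits_at_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        clusters, _ = mcl_cluster(g, 2.0)
        assert sorted(sorted(c) for c in clusters) == [
            [0, 1, 2, 3, 4],
            [5, 6, 7, 8, 9],
        ]

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_invariants_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(30, 0.12, seed=seed)
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() == 0:
            pytest.skip("empty")
        clusters, _ = mcl_cluster(g, 2.0)
        all_nodes = [n for c in clusters for n in c]
        assert sorted(all_nodes) == sorted(g.nodes)  # disjoint cover
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for n in comp:
                comp_of[n] = ci
        for c in clusters:
            assert len({comp_of[n] for n in c}) == 1  # never spans components

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.complete_graph(3), 1.0)


class TestLadder:
    def _planted(self, seed):
        cfg = SimulationConfig(
            n_spl=15,
            n_background=40,
            n_samples_per_group={"g": 30},
            block_spec=[(8, 0.9), (5, 0.9)],
            dropout_rate=0.1,
            seed=seed,
        )
        return simulate_expression(cfg)

    def test_counts_non_increasing(self):
        matrix, truth = self._planted(0)
        focal = list(truth[truth.role != "background"].index)
        control = list(truth[truth.role == "background"].index)[: len(focal)]
        ladder = pvalue_ladder(matrix, focal, control, [0.05, 1e-2, 1e-3, 1e-5, 1e-8])
        for series in (ladder.focal_nodes, ladder.focal_edges,
                       ladder.control_nodes, ladder.control_edges):
            assert all(a >= b for a, b in zip(series, series[1:]))

    def test_focal_exceeds_control_at_small_alpha(self):
        wins = 0
        for seed in range(10):
            matrix, truth = self._planted(seed)
            focal = list(truth[truth.role != "background"].index)
            control = list(truth[truth.role == "background"].index)[: len(focal)]
            ladder = pvalue_ladder(matrix, focal, control, [0.05, 1e-3])
            wins += ladder.focal_edges[-1] > ladder.control_edges[-1]
        assert wins >= 9  # sign test: planted structure survives tight alpha

    def test_single_alpha_consistent_with_build(self):
        matrix, truth = self._planted(1)
        focal = list(truth[truth.role != "background"].index)
        control = list(truth[truth.role == "background"].index)[: len(focal)]
        ladder = pvalue_ladder(matrix, focal, control, [0.01])
        g = build_network(matrix, focal, 0.01)
        assert ladder.focal_nodes == (g.n_nodes,)
        assert ladder.focal_edges == (g.n_edges,)

    def test_overlap_rejected(self):
        matrix, truth = self._planted(2)
        ids = matrix.transcript_ids
        with pytest.raises(ValueError, match="overlap"):
            pvalue_ladder(matrix, ids[:5], ids[4:8], [0.05])

    def test_non_decreasing_alphas_rejected(self):
        matrix, truth = self._planted(3)
        ids = matrix.transcript_ids
        with pytest.raises(ValueError, match="decreasing"):
            pvalue_ladder(matrix, ids[:5], ids[10:15], [0.01, 0.05])


class TestSubsampleNull:
    def _planted(self, seed=0):
        cfg = SimulationConfig(
            n_spl=18,
            n_background=40,
            n_samples_per_group={"g": 30},
            block_spec=[(10, 0.9)],
            dropout_rate=0.1,
            seed=seed,
        )
        return simulate_expression(cfg)

    def test_degenerate_full_fraction_equals_build(self):
        matrix, truth = self._planted()
        focal = list(truth[truth.role != "background"].index)
        pool = list(truth[truth.role == "background"].index)
        summary = subsample_null(
            matrix, focal, pool, [0.05], fraction=1.0, reps=1, seed=5
        )
        g = build_network(matrix, focal, 0.05)
        assert summary.focal_node_mean[0] == g.n_nodes
        assert summary.focal_edge_mean[0] == g.n_edges
        assert summary.focal_node_sd[0] == 0.0

    def test_deterministic_under_seed(self):
        matrix, truth = self._planted()
        focal = list(truth[truth.role != "background"].index)
        pool = list(truth[truth.role == "background"].index)
        s1 = subsample_null(matrix, focal, pool, [0.05, 1e-3], reps=5, seed=3)
        s2 = subsample_null(matrix, focal, pool, [0.05, 1e-3], reps=5, seed=3)
        assert s1.focal_edge_mean == s2.focal_edge_mean
        assert s1.control_edge_mean == s2.control_edge_mean

    def test_mean_bounded_by_max_replicate(self):
        matrix, truth = self._planted()
        focal = list(truth[truth.role != "background"].index)
        pool = list(truth[truth.role == "background"].index)
        s = subsample_null(matrix, focal, pool, [0.05], reps=6, seed=1)
        assert s.focal_edge_mean[0] <= s.focal_counts[:, 0, 1].max()

    def test_insufficient_pool_rejected(self):
        matrix, truth = self._planted()
        focal = list(truth[truth.role != "background"].index)
        with pytest.raises(ValueError, match="pool"):
            subsample_null(matrix, focal, focal[:3], [0.05], reps=2, seed=0)
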