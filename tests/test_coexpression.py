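"""Spearman statistics, thresholds, Monte-Carlo null, network, clustering."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from castriage.coexpression import (
    analyze_gene_set,
    build_network,
    cluster_order,
    eligible_universe,
    genome_wide_threshold,
    monte_carlo_test,
    set_coexpression_statistic,
    spearman_matrix,
)
from castriage.simulate import ExpressionSimSpec, simulate_expression
from castriage.types import ExpressionMatrix


def matrix_from(values: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df)


class TestSpearman:
    def test_identical_vectors_have_rho_one(self):
        m = matrix_from({"A": [1, 2, 3, 4], "B": [1, 2, 3, 4]})
        assert spearman_matrix(m).loc["A", "B"] == pytest.approx(1.0)

    def test_reversed_vector_has_rho_minus_one(self):
        m = matrix_from({"A": [1, 2, 3, 4], "B": [4, 3, 2, 1]})
        assert spearman_matrix(m).loc["A", "B"] == pytest.approx(-1.0)

    def test_toy_pairs_match_scipy_oracle(self):
        m = matrix_from({"A": [3, 1, 4, 1.5, 9], "B": [2, 7, 1, 8, 2.5],
                         "C": [5, 5, 3, 0, 1]})
        rho = spearman_matrix(m)
        for a, b in itertools.combinations("ABC", 2):
            expected = stats.spearmanr(m.values.loc[a], m.values.loc[b]).statistic
            assert rho.loc[a, b] == pytest.approx(expected)

    def test_constant_vector_gives_missing_pairs(self):
        m = matrix_from({"A": [1, 2, 3, 4], "B": [5, 5, 5, 5]})
        rho = spearman_matrix(m)
        assert np.isnan(rho.loc["A", "B"])
        assert rho.loc["B", "B"] == 1.0

    def test_fewer_than_three_samples_is_an_error(self):
        m = matrix_from({"A": [1, 2], "B": [2, 1]})
        with pytest.raises(ValueError, match="3 samples"):
            spearman_matrix(m)


class TestGenomeWideThreshold:
    def test_exact_percentile_matches_brute_force_on_ten_genes(self):
        m = simulate_expression(ExpressionSimSpec(n_genes=10, n_samples=50, seed=8))
        threshold, method = genome_wide_threshold(m, quantile=0.95)
        assert method == "exact"
        vals = sorted(
            abs(stats.spearmanr(m.values.iloc[i], m.values.iloc[j]).statistic)
            for i, j in itertools.combinations(range(10), 2)
        )
        k = int(np.ceil(0.95 * len(vals))) - 1
        assert threshold == pytest.approx(vals[k])

    def test_all_equal_correlations_give_that_value(self):
        base = [1.0, 2.0, 3.0, 4.0]
        m = matrix_from({"A": base, "B": base, "C": base})
        threshold, _ = genome_wide_threshold(m, quantile=0.95)
        assert threshold == pytest.approx(1.0)

    def test_quantile_zero_gives_minimum(self):
        m = simulate_expression(ExpressionSimSpec(n_genes=8, n_samples=40, seed=3))
        threshold, _ = genome_wide_threshold(m, quantile=0.0)
        vals = [abs(stats.spearmanr(m.values.iloc[i], m.values.iloc[j]).statistic)
                for i, j in itertools.combinations(range(8), 2)]
        assert threshold == pytest.approx(min(vals))

    def test_sampled_path_approximates_exact(self):
        m = simulate_expression(ExpressionSimSpec(n_genes=120, n_samples=60, seed=5))
        exact, _ = genome_wide_threshold(m, max_pairs=10**7)
        sampled, method = genome_wide_threshold(m, max_pairs=4000, seed=0)
        assert method == "sampled"
        assert abs(exact - sampled) < 0.05


class TestSetStatistic:
    def test_eighteen_gene_set_has_153_pairs(self):
        m = simulate_expression(ExpressionSimSpec(n_genes=30, n_samples=40, seed=2))
        rho = spearman_matrix(m)
        stat = set_coexpression_statistic(rho, m.genes[:18])
        assert stat.n_pairs == 153 and stat.n_missing == 0

    def test_two_gene_set_statistic_is_the_single_pair(self):
        m = matrix_from({"A": [1, 2, 3, 5], "B": [1, 3, 2, 5]})
        rho = spearman_matrix(m)
        stat = set_coexpression_statistic(rho, ["A", "B"])
        assert stat.value == pytest.approx(abs(rho.loc["A", "B"])) and stat.n_pairs == 1

    def test_planted_block_statistic_near_target(self):
        block = {f"GENE{i + 1:05d}": 1 for i in range(18)}
        m = simulate_expression(ExpressionSimSpec(n_genes=100, n_samples=280,
                                                  module_assignments=block,
                                                  within_block_correlation=0.65, seed=1))
        rho = spearman_matrix(m, sorted(block))
        stat = set_coexpression_statistic(rho, sorted(block))
        assert 0.55 <= stat.value <= 0.75

    def test_absent_gene_is_an_error(self):
        m = matrix_from({"A": [1, 2, 3], "B": [3, 2, 1]})
        with pytest.raises(KeyError, match="NOPE"):
            set_coexpression_statistic(spearman_matrix(m), ["A", "NOPE"])


class TestMonteCarlo:
    def test_weak_set_has_large_p(self):
        m = simulate_expression(ExpressionSimSpec(n_genes=300, n_samples=100, seed=11))
        res = monte_carlo_test(m, m.genes[:10], n_iter=400, seed=1)
        assert res.mc_p > 0.05  # nothing planted: no signal

    def test_add_one_estimator_floor(self):
        # a tight planted block never matched by null draws: p hits the floor
        block = {f"GENE{i + 1:05d}": 1 for i in range(8)}
        m = simulate_expression(ExpressionSimSpec(n_genes=60, n_samples=120,
                                                  module_assignments=block,
                                                  within_block_correlation=0.95, seed=4))
        res = monte_carlo_test(m, sorted(block), n_iter=4999, seed=2)
        assert np.sum(res.null_statistics >= res.observed) == 0
        assert res.mc_p == pytest.approx(2e-4)

    def test_identical_seed_reproduces_p_exactly(self):
        m = simulate_expression(ExpressionSimSpec(n_genes=120, n_samples=60, seed=6))
        a = monte_carlo_test(m, m.genes[:6], n_iter=300, seed=17)
        b = monte_carlo_test(m, m.genes[:6], n_iter=300, seed=17)
        assert a.mc_p == b.mc_p

    def test_universe_smaller_than_set_is_an_error(self):
        m = simulate_expression(ExpressionSimSpec(n_genes=5, n_samples=20, seed=1))
        with pytest.raises(ValueError, match="universe"):
            monte_carlo_test(m, m.genes, n_iter=10, seed=0)

    def test_absent_members_error_lists_them(self):
        m = simulate_expression(ExpressionSimSpec(n_genes=10, n_samples=20, seed=1))
        with pytest.raises(KeyError, match="ABSENT"):
            monte_carlo_test(m, ["ABSENT", m.genes[0]], n_iter=10, seed=0)


class TestNetwork:
    def _rho(self):
        m = simulate_expression(ExpressionSimSpec(n_genes=12, n_samples=50, seed=9))
        return spearman_matrix(m)

    def test_threshold_above_one_gives_no_edges(self):
        g = build_network(self._rho(), threshold=1.01)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 12

    def test_threshold_zero_gives_complete_graph(self):
        g = build_network(self._rho(), threshold=0.0)
        assert g.number_of_edges() == 12 * 11 // 2

    def test_edge_count_matches_brute_force(self):
        rho = self._rho()
        t = 0.15
        g = build_network(rho, threshold=t)
        expected = sum(
            1 for i, j in itertools.combinations(range(12), 2)
            if abs(rho.iloc[i, j]) >= t
        )
        assert g.number_of_edges() == expected

    def test_sign_and_provenance_attributes(self):
        rho = pd.DataFrame([[1, -0.9], [-0.9, 1]], index=["A", "B"], columns=["A", "B"])
        g = build_network(rho, gene_sets={"study1": {"A"}}, threshold=0.5)
        assert g.edges["A", "B"]["sign"] == -1
        assert g.nodes["A"]["sources"] == ["study1"]
        assert g.nodes["B"]["sources"] == []


def _brute_force_median_linkage(dist: np.ndarray) -> list[int]:
    """Tiny independent agglomerative median-linkage: returns leaf order."""
    clusters = {i: ([i], dist.copy()) for i in range(len(dist))}
    active = {i: [i] for i in range(len(dist))}
    d = {(i, j): dist[i, j] for i in range(len(dist)) for j in range(len(dist)) if i < j}
    centers = {i: None for i in range(len(dist))}
    # operate on Lance-Williams median update: d(k, i u j) = d(k,i)/2 + d(k,j)/2 - d(i,j)/4
    order = {i: [i] for i in range(len(dist))}
    nxt = len(dist)
    while len(active) > 1:
        (i, j), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merged = order[i] + order[j]
        for k in list(active):
            if k in (i, j):
                continue
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            d[(min(k, nxt), max(k, nxt))] = d[a] / 2 + d[b] / 2 - d[(i, j)] / 4
            del d[a], d[b]
        del d[(i, j)], active[i], active[j], order[i], order[j]
        active[nxt] = merged
        order[nxt] = merged
        nxt += 1
    return order[nxt - 1]


class TestClusterOrder:
    def test_two_perfect_pairs_are_adjacent(self):
        base = list(np.arange(10.0))
        noise = list(np.random.default_rng(0).uniform(0, 1, 10))
        m = matrix_from({"A1": base, "A2": [x * 2 + 1 for x in base],
                         "B1": noise, "B2": [x * 3 + 2 for x in noise]})
        order = cluster_order(spearman_matrix(m))
        pos = {g: i for i, g in enumerate(order)}
        assert abs(pos["A1"] - pos["A2"]) == 1
        assert abs(pos["B1"] - pos["B2"]) == 1

    def test_four_gene_order_matches_hand_run_median_linkage(self):
        rho = pd.DataFrame(
            [[1.0, 0.9, 0.1, 0.2],
             [0.9, 1.0, 0.3, 0.15],
             [0.1, 0.3, 1.0, 0.8],
             [0.2, 0.15, 0.8, 1.0]],
            index=list("ABCD"), columns=list("ABCD"),
        )
        order = cluster_order(rho)
        dist = 1.0 - rho.to_numpy()
        np.fill_diagonal(dist, 0.0)
        expected = [rho.index[i] for i in _brute_force_median_linkage(dist)]
        assert order == expected or order == expected[::-1]

    def test_singleton_set(self):
        m = matrix_from({"A": [1, 2, 3], "B": [1, 3, 2]})
        assert cluster_order(spearman_matrix(m), ["A"]) == ["A"]


class TestEligibleUniverse:
    def test_detection_floor_excludes_silent_genes(self):
        df = pd.DataFrame(
            [[0.0, 0.0, 0.0, 5.0], [1.0, 2.0, 3.0, 4.0]],
            index=["rare", "broad"], columns=["s1", "s2", "s3", "s4"],
        )
        m = ExpressionMatrix(df)
        assert eligible_universe(m, detection_fraction=0.5) == ["broad"]


class TestRankInvariance:
    def test_monotone_transform_leaves_everything_bit_identical(self):
        block = {f"GENE{i + 1:05d}": 1 for i in range(10)}
        spec = ExpressionSimSpec(n_genes=80, n_samples=60, module_assignments=block,
                                 within_block_correlation=0.6, seed=12)
        m = simulate_expression(spec)
        transformed = ExpressionMatrix(np.exp(m.values / 10.0) * 3.0 + 1.0, m.metadata)
        a = analyze_gene_set(m, sorted(block), n_iter=200, seed=3)
        b = analyze_gene_set(transformed, sorted(block), n_iter=200, seed=3)
        assert a.rho.equals(b.rho)
        assert a.threshold == b.threshold
        assert a.set_statistic == b.set_statistic
        assert a.mc_p == b.mc_p
        assert a.edges == b.edges
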