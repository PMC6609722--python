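import numpy as np
import pytest

import ssrimet as sm
from ssrimet.exceptions import ValidationError
from ssrimet.network import (
    bootstrap_network,
    ebic,
    ebic_select,
    graphical_lasso,
    kkt_violation,
    lambda_max,
    make_lambda_grid,
    precision_to_partial_correlations,
    sample_correlation,
    walktrap_communities,
)


def random_spd_correlation(rng, p):
    A = rng.standard_normal((p, 2 * p))
    S = A @ A.T / (2 * p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestSampleCorrelation:
    def test_identical_columns(self, rng):
        x = rng.standard_normal(20)
        S = sample_correlation(np.column_stack([x, x]))
        assert S[0, 1] == pytest.approx(1.0)

    def test_orthogonal_contrasts(self):
        S = sample_correlation(np.array([[1.0, 1.0], [-1.0, 1.0], [0.0, -2.0]]))
        assert S[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        X = rng.standard_normal((40, 5))
        S = sample_correlation(X)
        Xc = X - X.mean(axis=0)
        direct = (Xc.T @ Xc) / np.sqrt(np.outer((Xc**2).sum(0), (Xc**2).sum(0)))
        np.testing.assert_allclose(S, direct, atol=1e-12)

    def test_zero_variance_named(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValidationError, match="V2"):
            sample_correlation(X)


class TestGraphicalLasso:
    def test_full_shrinkage_is_diagonal(self, rng):
        S = random_spd_correlation(rng, 6)
        theta = graphical_lasso(S, lam=lambda_max(S) + 0.01)
        assert np.allclose(theta - np.diag(np.diag(theta)), 0.0)

    def test_zero_penalty_matches_inverse(self, rng):
        S = random_spd_correlation(rng, 6)
        np.testing.assert_allclose(graphical_lasso(S, 0.0), np.linalg.inv(S), atol=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_kkt_conditions(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 12))
        S = random_spd_correlation(rng, p)
        lam = float(rng.uniform(0.02, 0.3))
        theta = graphical_lasso(S, lam)
        assert kkt_violation(theta, S, lam) < 1e-3

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValidationError):
            graphical_lasso(np.eye(3), -0.1)


class TestPartialCorrelations:
    def test_identity_gives_zero(self):
        assert np.all(precision_to_partial_correlations(np.eye(4)) == 0)

    def test_two_by_two_matches_marginal(self):
        theta = np.array([[2.0, -1.0], [-1.0, 2.0]])
        w = precision_to_partial_correlations(theta)
        assert w[0, 1] == pytest.approx(0.5)
        # for two variables the partial equals the marginal correlation
        sigma = np.linalg.inv(theta)
        marg = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
        assert w[0, 1] == pytest.approx(marg)

    def test_strictly_below_one(self, rng):
        for _ in range(5):
            S = random_spd_correlation(rng, 6)
            w = precision_to_partial_correlations(np.linalg.inv(S))
            off = w[~np.eye(6, dtype=bool)]
            assert np.abs(off).max() < 1.0

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValidationError):
            precision_to_partial_correlations(np.diag([1.0, -2.0]))


class TestEbicSelect:
    def test_single_lambda_returned(self, rng):
        X = rng.standard_normal((80, 5))
        net = ebic_select(X, lambda_grid=np.array([0.21]))
        assert net.penalty == pytest.approx(0.21)

    def test_independent_data_near_empty(self):
        spurious = []
        for seed in range(5):
            X = np.random.default_rng(seed).standard_normal((500, 12))
            spurious.append(ebic_select(X).n_edges)
        assert np.median(spurious) <= 2

    def test_gamma_zero_is_denser_or_equal(self, small_processed):
        X = small_processed["t0"]
        grid = make_lambda_grid(sample_correlation(X), 30)
        e_bic = ebic_select(X, lambda_grid=grid, gamma=0.0).n_edges
        e_ebic = ebic_select(X, lambda_grid=grid, gamma=0.5).n_edges
        assert e_bic >= e_ebic

    def test_edge_count_monotone_in_lambda(self, rng):
        X = rng.standard_normal((200, 8)) @ rng.standard_normal((8, 8))
        S = sample_correlation(X)
        counts = []
        for lam in make_lambda_grid(S, 20):
            theta = graphical_lasso(S, lam)
            counts.append(int((np.triu(theta, 1) != 0).sum()))
        # grid is descending in lambda, so counts must be non-decreasing
        # (allow rare single-step solver jitter of one edge)
        diffs = np.diff(counts)
        assert (diffs >= -1).all()
        assert counts[-1] >= counts[0]

    def test_network_invariants(self, small_processed):
        net = ebic_select(small_processed["t0"])
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)
        assert np.abs(net.weights).max() <= 1
        assert net.sample_size == 60
        # support of weights equals support of the precision estimate
        assert np.array_equal(net.weights != 0, ~np.eye(10, dtype=bool) & (net.precision != 0))


class TestBootstrap:
    def test_single_resample_is_that_network(self, small_processed):
        X = small_processed["t0"].values.to_numpy()
        summary = bootstrap_network(X, n_boot=1, lambda_grid=np.array([0.3]), seed=0)
        idx = np.random.default_rng(0).integers(0, 60, size=60)
        net = ebic_select(X[idx], lambda_grid=np.array([0.3]))
        np.testing.assert_allclose(summary.median_weights, net.weights)
        assert np.array_equal(summary.inclusion_frequency, (net.weights != 0).astype(float))

    def test_seed_determinism(self, small_processed):
        a = bootstrap_network(small_processed["t0"], n_boot=5, lambda_grid=np.array([0.3]), seed=4)
        b = bootstrap_network(small_processed["t0"], n_boot=5, lambda_grid=np.array([0.3]), seed=4)
        np.testing.assert_array_equal(a.median_weights, b.median_weights)

    def test_strong_edge_stable_null_edge_rare(self):
        truth = sm.make_precision_matrix(8, 1, within_density=0.07, edge_strength=0.6, seed=3)
        w_true = truth.partial_correlations()
        i, j = np.argwhere(np.triu(w_true, 1) != 0)[0]
        cohort = sm.simulate_cohort(400, truth, seed=5, subject_intercept_sd=0.0)
        proc = sm.preprocess_cohort(cohort)
        S = sample_correlation(proc["t0"])
        summary = bootstrap_network(
            proc["t0"], n_boot=60, lambda_grid=make_lambda_grid(S, 15), seed=6
        )
        assert summary.inclusion_frequency[i, j] >= 0.9
        null = np.triu(w_true, 1) == 0
        null[np.tril_indices(8)] = False
        assert np.median(summary.inclusion_frequency[null]) <= 0.5

    def test_median_zero_where_never_included(self, small_processed):
        summary = bootstrap_network(
            small_processed["t0"], n_boot=10, lambda_grid=np.array([0.5]), seed=1
        )
        assert np.all(summary.median_weights[summary.inclusion_frequency == 0] == 0)


class TestWalktrap:
    def _clique_matrix(self, sizes, weight=0.5):
        p = sum(sizes)
        w = np.zeros((p, p))
        start = 0
        for s in sizes:
            w[start : start + s, start : start + s] = weight
            start += s
        np.fill_diagonal(w, 0.0)
        return w

    def test_disconnected_cliques(self):
        w = self._clique_matrix([4, 4])
        part = walktrap_communities(w)
        labels = part.labels
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        assert part.modularity > 0

    def test_complete_graph_single_community(self):
        w = self._clique_matrix([6])
        part = walktrap_communities(w)
        assert len(set(part.labels.tolist())) == 1

    def test_empty_graph_singletons(self):
        part = walktrap_communities(np.zeros((5, 5)))
        assert sorted(part.labels.tolist()) == list(range(5))
        assert part.modularity == 0.0

    def test_isolated_node_is_singleton(self):
        w = self._clique_matrix([4, 4])
        w2 = np.zeros((9, 9))
        w2[:8, :8] = w
        base = walktrap_communities(w)
        aug = walktrap_communities(w2)
        # the isolated node forms its own community; the clique partition is intact
        assert len(set(aug.labels.tolist())) == len(set(base.labels.tolist())) + 1
        assert (aug.labels[:4] == aug.labels[0]).all()
        assert (aug.labels[4:8] == aug.labels[4]).all()
        assert aug.labels[8] not in set(aug.labels[:8].tolist())


class TestCompareNetworks:
    def test_duplicated_groups_give_null_result(self, rng):
        X_half = rng.standard_normal((40, 5))
        X = np.vstack([X_half, X_half])
        outcome = np.concatenate([np.zeros(40), np.ones(40)])
        res = sm.compare_networks(X, outcome, n_perm=30, seed=0, lambda_grid=np.array([0.2]))
        assert res.stat_structure == pytest.approx(0.0)
        assert res.p_structure == pytest.approx(1.0)

    def test_group_relabeling_invariance(self, rng):
        X = rng.standard_normal((60, 5))
        outcome = rng.standard_normal(60)
        grid = np.array([0.25])
        a = sm.compare_networks(X, outcome, n_perm=20, seed=3, lambda_grid=grid)
        b = sm.compare_networks(X, -outcome, n_perm=20, seed=3, lambda_grid=grid)
        # M and S are symmetric in the two groups; only the group labels swap
        assert a.stat_structure == pytest.approx(b.stat_structure, abs=1e-6)
        assert a.stat_global_strength == pytest.approx(b.stat_global_strength, abs=1e-6)

    def test_planted_differential_edge_detected(self):
        truth = sm.make_precision_matrix(8, 1, within_density=0.0, seed=0)
        truth = sm.GroundTruth(
            precision_matrix=truth.precision_matrix,
            community_labels=truth.community_labels,
            differential_edges=[(1, 4, 0.4, 0.0)],
        )
        cohort = sm.simulate_cohort(600, truth, response_rate=0.5, seed=9,
                                    subject_intercept_sd=0.0)
        proc = sm.preprocess_cohort(cohort)
        outcome = cohort.clinical["hrsd_t8"].to_numpy(dtype=float)
        S = sample_correlation(proc["t0"])
        res = sm.compare_networks(
            proc["t0"], outcome, n_perm=149, seed=10, lambda_grid=make_lambda_grid(S, 20)
        )
        top = res.per_edge.iloc[res.per_edge["diff"].abs().argmax()]
        assert {top["node_a"], top["node_b"]} == {"M02", "M05"}
        assert top["p_adjusted"] < 0.05
        assert res.p_structure < 0.05

    def test_degenerate_split_rejected(self, rng):
        X = rng.standard_normal((30, 4))
        outcome = np.r_[np.zeros(25), np.ones(5)]
        with pytest.raises(ValidationError, match="group"):
            sm.compare_networks(X, outcome, n_perm=10)

    def test_outcome_node_included(self, rng):
        X = rng.standard_normal((60, 4))
        outcome = rng.standard_normal(60)
        res = sm.compare_networks(
            X, outcome, n_perm=5, seed=0, include_outcome_node=True,
            lambda_grid=np.array([0.3]),
        )
        assert res.network_low.node_labels[-1] == "OUTCOME"
        assert res.network_low.weights.shape == (5, 5)


class TestValidateInteraction:
    def test_planted_interaction(self, rng):
        n = 300
        b = rng.standard_normal(n)
        group = rng.integers(0, 2, n).astype(float)
        a = b * group + 0.1 * rng.standard_normal(n)
        coef, p = sm.validate_interaction(a, b, group)
        assert p < 1e-6
        assert coef == pytest.approx(1.0, abs=0.1)

    def test_constant_outcome_returns_nan(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        with pytest.warns(UserWarning):
            coef, p = sm.validate_interaction(a, b, np.ones(50))
        assert np.isnan(coef) and np.isnan(p)

    def test_null_interaction_usually_insignificant(self, rng):
        hits = 0
        for _ in range(20):
            a = rng.standard_normal(200)
            b = rng.standard_normal(200)
            y = rng.standard_normal(200)
            _, p = sm.validate_interaction(a, b, y)
            hits += p < 0.05
        assert hits <= 4


def test_ebic_formula_components(rng):
    # EBIC = -2 loglik + E log n + 4 gamma E log p, with the Gaussian loglik
    S = random_spd_correlation(rng, 4)
    theta = np.linalg.inv(S)
    n, p = 100, 4
    sign, logdet = np.linalg.slogdet(theta)
    loglik = 0.5 * n * (logdet - np.trace(S @ theta) - p * np.log(2 * np.pi))
    E = int((np.triu(theta, 1) != 0).sum())
    expected = -2 * loglik + E * np.log(n) + 4 * 0.5 * E * np.log(p)
    assert ebic(theta, S, n, gamma=0.5) == pytest.approx(expected)
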