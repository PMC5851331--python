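"""Non-negative elastic-net: optimality, augmentation identity, selection."""

import numpy as np
import pytest

from dsnis.connectome import edge_pairs
from dsnis.n2en import (
    N2ENConfig,
    SelectionResult,
    _pgd_solve,
    augment,
    baseline_rank,
    kkt_violation,
    objective,
    rank_edges,
    select_dsnis,
    solve,
)
from helpers import n2en_bruteforce, n2en_nnls_oracle, n2en_objective


def _instance(rng, n=8, M=10):
    return rng.normal(size=(n, M)), rng.normal(size=n)


class TestAugmentation:
    def test_gamma2_zero_pads_with_zero_rows(self, rng):
        X, y = _instance(rng, 4, 3)
        ap = augment(X, y, gamma2=0.0)
        np.testing.assert_allclose(ap.X_star[:4], X)
        np.testing.assert_array_equal(ap.X_star[4:], np.zeros((3, 3)))
        np.testing.assert_array_equal(ap.y_star[4:], 0.0)

    def test_hand_expanded_shapes_and_bottom_block(self, rng):
        X, y = _instance(rng, 2, 3)
        ap = augment(X, y, gamma2=1.0)
        assert ap.X_star.shape == (5, 3) and ap.y_star.shape == (5,)
        np.testing.assert_allclose(ap.X_star[2:], np.eye(3) / np.sqrt(2.0))

    def test_objective_identity_on_random_instances(self, rng):
        # augmented lasso objective == original elastic-net objective after
        # the change of variables a* = sqrt(1+g2) a
        for _ in range(10):
            X, y = _instance(rng)
            g1, g2 = rng.uniform(0, 1), rng.uniform(0, 2)
            a = rng.uniform(0, 1, size=X.shape[1])
            ap = augment(X, y, g2, g1)
            a_star = a / ap.rescale
            lhs = np.sum((ap.y_star - ap.X_star @ a_star) ** 2) + ap.alpha_l1 * a_star.sum()
            assert lhs == pytest.approx(n2en_objective(X, y, a, g1, g2), rel=1e-12)

    def test_linear_term_definition(self, rng):
        X, y = _instance(rng, 5, 4)
        ap = augment(X, y, gamma2=0.5, gamma1=0.3)
        np.testing.assert_allclose(
            ap.b, (ap.alpha_l1 / 2) * np.ones(4) - ap.X_star.T @ ap.y_star
        )


class TestSolver:
    def test_l1_kill_threshold_zeroes_everything(self, rng):
        X, y = _instance(rng)
        g1 = 2.0 * np.max(X.T @ y) + 0.1
        res = solve(X, y, N2ENConfig(gamma1=g1, gamma2=0.0))
        np.testing.assert_array_equal(res.weights, 0.0)

    def test_orthonormal_exact_recovery(self):
        X = np.eye(6)[:, :4]  # orthonormal columns
        y = X[:, 0].copy()
        res = solve(X, y, N2ENConfig(gamma1=0.0, gamma2=0.0, tol=1e-12))
        np.testing.assert_allclose(res.weights, [1, 0, 0, 0], atol=1e-9)

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(15):
            X, y = _instance(rng, n=6, M=6)
            g1, g2 = 0.1, 0.5
            res = solve(X, y, N2ENConfig(gamma1=g1, gamma2=g2, tol=1e-10))
            _, obj_bf = n2en_bruteforce(X, y, g1, g2)
            assert res.objective == pytest.approx(obj_bf, abs=1e-6)

    def test_matches_nnls_oracle_medium_size(self, rng):
        X, y = _instance(rng, n=20, M=40)
        cfg = N2ENConfig(gamma1=0.2, gamma2=1.0, tol=1e-10)
        res = solve(X, y, cfg)
        a_or = n2en_nnls_oracle(X, y, cfg.gamma1, cfg.gamma2)
        assert res.objective == pytest.approx(
            n2en_objective(X, y, a_or, cfg.gamma1, cfg.gamma2), abs=1e-8
        )
        np.testing.assert_allclose(res.weights, a_or, atol=1e-5)

    def test_kkt_conditions_hold(self, rng):
        X, y = _instance(rng, 10, 15)
        cfg = N2ENConfig(gamma1=0.3, gamma2=0.7, tol=1e-10)
        res = solve(X, y, cfg)
        assert kkt_violation(X, y, res.weights, cfg) < 1e-6

    def test_objective_monotone_nonincreasing(self, rng):
        X, y = _instance(rng, 12, 20)
        res = solve(X, y, N2ENConfig(gamma1=0.1, gamma2=0.5))
        assert np.all(np.diff(res.objective_path) <= 1e-10)

    def test_projected_gradient_agrees(self, rng):
        X, y = _instance(rng, 10, 12)
        cfg = N2ENConfig(gamma1=0.2, gamma2=0.8, tol=1e-10)
        res = solve(X, y, cfg)
        a_pgd = _pgd_solve(X, y, cfg)
        assert objective(X, y, a_pgd, cfg) == pytest.approx(res.objective, abs=1e-8)

    def test_unique_optimum_from_warm_state(self, rng):
        # strict convexity for g2>0: objective is invariant to problem
        # permutation (a different coordinate visiting order)
        X, y = _instance(rng, 10, 12)
        cfg = N2ENConfig(gamma1=0.1, gamma2=0.5, tol=1e-12)
        perm = rng.permutation(12)
        res1 = solve(X, y, cfg)
        res2 = solve(X[:, perm], y, cfg)
        assert res1.objective == pytest.approx(res2.objective, abs=1e-8)
        np.testing.assert_allclose(res1.weights[perm], res2.weights, atol=1e-6)

    def test_grouping_identical_columns_equal_weights(self, rng):
        X, y = _instance(rng, 10, 5)
        X = np.column_stack([X, X[:, 0]])  # duplicate the first column
        res = solve(X, y, N2ENConfig(gamma1=0.05, gamma2=1.0, tol=1e-12))
        assert res.weights[0] == pytest.approx(res.weights[-1], abs=1e-6)

    def test_negative_penalties_rejected(self):
        with pytest.raises(ValueError):
            N2ENConfig(gamma1=-0.1)
        with pytest.raises(ValueError):
            N2ENConfig(gamma2=-1.0)

    def test_nonfinite_design_rejected(self, rng):
        X, y = _instance(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            solve(X, y)


class TestSelection:
    def _result(self, weights):
        w = np.asarray(weights, float)
        return SelectionResult(
            weights=w, residual=np.zeros(2), objective=0.0, sweeps=1, converged=True
        )

    def test_zero_solution_gives_empty_table(self):
        res = self._result(np.zeros(6))  # m=4
        assert rank_edges(res).empty

    def test_tie_broken_by_lower_edge_index(self):
        res = self._result([0.5, 0.9, 0.9, 0.0, 0.1, 0.0])
        tab = rank_edges(res)
        assert list(tab.edge_index[:2]) == [1, 2]  # equal weights, lower index first

    def test_sparsity_zero_retains_full_positive_support(self):
        res = self._result([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        sel = select_dsnis(res, 0.0)
        assert sel.retained_edges.size == 6 and sel.sparsity == 0.0

    def test_target_count_rounding(self):
        # s=0.2 on M=4005 edges -> 3204 retained (support permitting)
        assert round((1 - 0.2) * 4005) == 3204
        w = np.linspace(1, 2, 10)
        sel = select_dsnis(self._result(w), 0.2)  # m=5, M=10 -> keep 8
        assert sel.retained_edges.size == 8

    def test_support_limited_retention(self):
        w = np.zeros(10)
        w[[2, 5, 7]] = [3.0, 2.0, 1.0]
        sel = select_dsnis(self._result(w), 0.0)  # target 10 but support is 3
        np.testing.assert_array_equal(sel.retained_edges, [2, 5, 7])
        assert sel.sparsity == pytest.approx(0.7)

    def test_sparsity_one_rejected(self):
        with pytest.raises(ValueError):
            select_dsnis(self._result(np.ones(6)), 1.0)

    def test_retained_sorted_by_descending_weight(self):
        w = np.array([0.2, 0.9, 0.1, 0.5, 0.0, 0.7])
        sel = select_dsnis(self._result(w), 0.0)
        np.testing.assert_array_equal(sel.retained_edges, [1, 5, 3, 0, 2])


class TestRankingExperiments:
    def test_planted_edges_dominate_top10(self, recovery_cohort):
        from dsnis.connectome import build_design

        spec = recovery_cohort.spec
        X, y, _, region_ids = build_design(recovery_cohort.subjects, tau=0.0)
        res = solve(X, y)
        tab = rank_edges(res, region_ids=region_ids, top=10)
        planted = set(recovery_cohort.truth_edges)
        hits = sum(
            (int(a), int(b)) in planted
            for a, b in zip(tab.region_a_id, tab.region_b_id)
        )
        assert hits >= 8

    def test_all_ranked_weights_positive(self, recovery_cohort):
        from dsnis.connectome import build_design

        X, y, _, region_ids = build_design(recovery_cohort.subjects, tau=0.0)
        tab = rank_edges(solve(X, y), region_ids=region_ids)
        assert (tab.weight > 0).all()
        assert (tab.weight.diff().dropna() <= 0).all()  # descending


class TestBaselines:
    def test_identical_groups_give_zero_t(self, rng):
        half = rng.normal(size=(4, 6))
        X = np.vstack([half, half])
        y = np.array([1.0] * 4 + [-1.0] * 4)
        tab = baseline_rank(X, y, "t_test")
        assert np.allclose(tab.weight, 0.0)

    def test_nn_ridge_orthonormal_closed_form(self, rng):
        X = np.linalg.qr(rng.normal(size=(10, 6)))[0]  # orthonormal columns (M=6, m=4)
        y = rng.normal(size=10)
        g2 = 0.7
        tab = baseline_rank(X, y, "nn_ridge", N2ENConfig(gamma2=g2, tol=1e-12))
        want = np.maximum(0.0, X.T @ y) / (1.0 + g2)
        got = np.zeros(6)
        got[tab.edge_index.to_numpy()] = tab.weight.to_numpy()
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_nn_lasso_is_solve_with_gamma2_zero(self, rng):
        X, y = _instance(rng, 10, 6)
        cfg = N2ENConfig(gamma1=0.2, gamma2=5.0)
        tab = baseline_rank(X, y, "nn_lasso", cfg)
        from dataclasses import replace

        direct = rank_edges(solve(X, y, replace(cfg, gamma2=0.0)))
        assert tab.equals(direct)

    def test_unknown_method_rejected(self, rng):
        X, y = _instance(rng)
        with pytest.raises(ValueError):
            baseline_rank(X, y, "pca")


def test_null_cohort_top_edges_at_chance(null_cohort):
    """With no group difference, planted-style enrichment cannot occur: the
    top edges of an N2EN fit on a permuted-label null cohort overlap a random
    reference set consistently with the hypergeometric distribution."""
    from scipy.stats import hypergeom

    from dsnis.connectome import build_design

    X, y, _, region_ids = build_design(null_cohort.subjects, tau=0.0)
    res = solve(X, y)
    top = rank_edges(res, region_ids=region_ids, top=10)
    M = X.shape[1]
    # any fixed 10-edge reference set; chance overlap follows hypergeom(M,10,10)
    pairs = edge_pairs(30, region_ids)
    ref = {tuple(p) for p in pairs[:10]}
    k = sum((int(a), int(b)) in ref for a, b in zip(top.region_a_id, top.region_b_id))
    lo, hi = hypergeom.interval(0.95, M, 10, 10)
    assert lo <= k <= hi
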