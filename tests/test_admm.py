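import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msfsgl as m
from msfsgl.admm import adapt_rho, dual_update, _check_stopping
from msfsgl.state_space import column_index


class TestSoftThreshold:
    def test_scalar(self):
        assert m.soft_threshold(3.0, 1.0) == pytest.approx(2.0)
        assert m.soft_threshold(-3.0, 1.0) == pytest.approx(-2.0)
        assert m.soft_threshold(0.3, 0.5) == 0.0

    def test_zero_maps_to_zero(self):
        assert m.soft_threshold(0.0, 7.0) == 0.0
        np.testing.assert_array_equal(m.soft_threshold(np.zeros(3), 2.0), np.zeros(3))

    def test_vector_shrinkage(self):
        np.testing.assert_allclose(m.soft_threshold(np.array([3.0, 4.0]), 1.0),
                                   [2.4, 3.2])

    def test_block_zeroed_below_threshold(self):
        np.testing.assert_array_equal(m.soft_threshold(np.array([0.3, 0.4]), 1.0),
                                      np.zeros(2))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=6),
           st.floats(0, 30))
    def test_proximal_operator_properties(self, vals, kappa):
        # S_kappa shrinks the norm by exactly kappa (or to zero) and
        # preserves the direction
        a = np.array(vals)
        out = m.soft_threshold(a, kappa)
        norm = np.linalg.norm(a)
        if norm <= kappa:
            np.testing.assert_array_equal(out, np.zeros_like(a))
        else:
            assert np.linalg.norm(out) == pytest.approx(norm - kappa, rel=1e-9)
            np.testing.assert_allclose(out * norm, a * (norm - kappa),
                                       rtol=1e-9, atol=1e-9)


class TestAdaptRho:
    cfg = m.ADMMConfig()

    def test_primal_dominates(self):
        assert adapt_rho(1.0, primal=10.1, dual=1.0, cfg=self.cfg) == 2.0

    def test_dual_dominates(self):
        assert adapt_rho(1.0, primal=1.0, dual=20.0, cfg=self.cfg) == 0.5

    def test_balanced_unchanged(self):
        assert adapt_rho(1.0, primal=1.0, dual=1.1, cfg=self.cfg) == 1.0


class TestDualUpdate:
    def test_unchanged_at_feasibility(self):
        nu = np.array([1.0, -2.0])
        np.testing.assert_array_equal(dual_update(nu, 3.0, nu * 0 + 5, nu * 0 + 5), nu)

    def test_running_sum_at_fixed_rho(self):
        rng = np.random.default_rng(0)
        rho = 2.0
        nu = np.zeros(4)
        gaps = []
        for _ in range(5):
            theta, Kb = rng.normal(size=(2, 4))
            gaps.append(Kb - theta)
            nu = dual_update(nu, rho, theta, Kb)
        np.testing.assert_allclose(nu, rho * np.sum(gaps, axis=0))


class TestStopping:
    def test_zero_residuals_stop(self):
        stop, _, _ = _check_stopping(0.0, 0.0, 1.0, 1.0, 1.0, 16, 36, m.ADMMConfig())
        assert stop

    def test_loosening_eps_rel_preserves_stop(self):
        cfg = m.ADMMConfig()
        args = (0.05, 0.02, 3.0, 3.0, 2.0, 16, 36)
        stop1, _, _ = _check_stopping(*args, cfg)
        stop2, _, _ = _check_stopping(*args, m.ADMMConfig(eps_rel=2 * cfg.eps_rel))
        assert not stop1 or stop2

    def test_strict_mode_uses_printed_scaling(self):
        cfg = m.ADMMConfig(strict_stopping=True)
        _, e1, e2 = _check_stopping(0.0, 0.0, 0.0, 0.0, 0.0, 16, 36, cfg)
        assert e1 == pytest.approx(16 * cfg.eps_abs)
        assert e2 == pytest.approx(36 * cfg.eps_abs)


class TestFit:
    def test_lambda_zero_matches_unpenalized_mle(self, aml_small):
        _, _, design, ps = aml_small
        res = m.fit(design, ps, m.FSGLParams(lam=0.0))
        beta_mle, _ = m.newton_mle(design)
        assert res.converged
        np.testing.assert_allclose(res.beta_hat, beta_mle, atol=1e-3)

    def test_huge_lambda_zeroes_everything(self, aml_small):
        _, _, design, ps = aml_small
        res = m.fit(design, ps, m.FSGLParams(lam=1e5, alpha=1.0, gamma=1.0))
        np.testing.assert_array_equal(res.beta_hat, np.zeros(16))
        assert res.n_selected == 0

    def test_theta_sparse_but_beta_iterate_dense(self, aml_small):
        _, _, design, ps = aml_small
        res = m.fit(design, ps, m.FSGLParams(lam=10.0, alpha=1.0, gamma=1.0))
        assert np.sum(res.beta_hat == 0.0) > 0  # exact zeros in theta
        assert np.all(res.beta_admm != 0.0)  # smooth iterate has none

    def test_fusion_corner_equalizes_similar_pairs(self, aml_small):
        # gamma = 0, large lambda: fused pairs driven together (tight
        # solver tolerances so the residual gap is dominated by the model,
        # not the stopping rule)
        _, _, design, ps = aml_small
        cfg = m.ADMMConfig(eps_abs=1e-6, eps_rel=1e-4, max_iter=2000)
        res = m.fit(design, ps, m.FSGLParams(lam=200.0, alpha=1.0, gamma=0.0), cfg)
        b = res.beta_hat
        Q = 8
        for p in (1, 2):
            for q, q2 in ((3, 7), (4, 8)):
                diff = abs(b[column_index(p, q, Q)] - b[column_index(p, q2, Q)])
                assert diff < 1e-3

    def test_group_corner_joint_selection(self, aml_small):
        # (alpha, gamma) = (0, 1): whole transitions drop out together
        _, _, design, ps = aml_small
        res = m.fit(design, ps, m.FSGLParams(lam=40.0, alpha=0.0, gamma=1.0))
        sel = res.selected.reshape(2, 8)
        dropped = ~sel.any(axis=0)
        assert dropped.any()  # at least one transition fully removed
        for q in range(8):
            assert sel[:, q].all() or not sel[:, q].any()

    def test_penalized_objective_monotone_up_to_slack(self, aml_small):
        _, _, design, ps = aml_small
        res = m.fit(design, ps, m.FSGLParams(lam=5.0, alpha=1.0, gamma=0.5),
                    keep_trace=True)
        obj = np.array(res.trace["objective"])
        # monitored contract: non-increasing after the initial iterations,
        # up to small tolerance slack
        assert np.all(np.diff(obj[2:]) < 1e-2 * (1 + np.abs(obj[2:-1])))
        assert obj[-1] <= obj[0]

    def test_augmented_gradient_matches_finite_differences(self, aml_small):
        from msfsgl.likelihood import _evaluate

        _, _, design, ps = aml_small
        rng = np.random.default_rng(3)
        beta = rng.normal(scale=0.2, size=16)
        theta = rng.normal(size=ps.M)
        u = rng.normal(size=ps.M)
        rho = 1.7
        v = theta - u

        def aug(b):
            r = ps.K @ b - v
            return m.neg_log_partial_likelihood(design, b) + 0.5 * rho * (r @ r)

        _, U, _ = _evaluate(design, beta, order=1)
        grad = -U + rho * (ps.K.T @ (ps.K @ beta - v))
        eps = 1e-6
        fd = np.array([(aug(beta + eps * e) - aug(beta - eps * e)) / (2 * eps)
                       for e in np.eye(16)])
        np.testing.assert_allclose(grad, fd, rtol=1e-5, atol=1e-6)

    def test_no_events_rejected(self, two_state_chart):
        import pandas as pd

        df = pd.DataFrame({"id": [1], "trans": [1], "Tstart": [0.0], "Tstop": [1.0],
                           "status": [0], "x": [1.0]})
        design = m.expand_design(df, two_state_chart)
        ps = m.build_penalty_structure(two_state_chart, P=1)
        with pytest.raises(ValueError, match="no events"):
            m.fit(design, ps, m.FSGLParams(lam=1.0))

    def test_unpenalized_covariate_survives_heavy_penalty(self, aml_small):
        cfg, _, design, _ = aml_small
        ps = m.build_penalty_structure(cfg.chart, P=2, unpenalized={1})
        res = m.fit(design, ps, m.FSGLParams(lam=1e4, alpha=1.0, gamma=1.0))
        b = res.beta_hat.reshape(2, 8)
        assert np.abs(b[0]).max() > 0.1  # X1 effects not thresholded
        np.testing.assert_array_equal(b[1], np.zeros(8))
        assert res.selected.reshape(2, 8)[0].all()
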