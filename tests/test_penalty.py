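import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msfsgl as m
from msfsgl.state_space import column_index


@pytest.fixture(scope="module")
def two_by_two():
    chart = m.StateChart(states=("a", "b", "c"), transitions=((1, 2), (1, 3)),
                         similar_pairs=((1, 2),))
    return m.build_penalty_structure(chart, P=2)


class TestStructure:
    def test_block_counts_two_by_two(self, two_by_two):
        ps = two_by_two
        assert ps.n_lasso == 4 and ps.n_fusion == 2 and ps.M == 10

    def test_first_contrast_couples_covariate_one(self, two_by_two):
        # d1 fuses beta_{1,1} and beta_{1,2}
        np.testing.assert_array_equal(two_by_two.K[4], [1, -1, 0, 0])

    def test_group_matrix_for_transition_one(self, two_by_two):
        q, rows, cols = two_by_two.group_blocks[0]
        assert q == 1
        np.testing.assert_array_equal(two_by_two.K[rows],
                                      [[1, 0, 0, 0], [0, 0, 1, 0]])

    def test_lasso_block_is_identity(self, two_by_two):
        np.testing.assert_array_equal(two_by_two.K[:4], np.eye(4))

    def test_aml_structure_counts(self):
        ps = m.build_penalty_structure(m.aml_state_chart(), P=2)
        assert ps.n_fusion == 4  # two similar pairs x two covariates
        assert ps.M == 16 + 4 + 16

    def test_fusion_rows_sum_to_zero(self):
        ps = m.build_penalty_structure(m.aml_state_chart(), P=3)
        fusion = ps.K[ps.n_lasso:ps.n_lasso + ps.n_fusion]
        np.testing.assert_array_equal(fusion.sum(axis=1), np.zeros(ps.n_fusion))
        assert np.all(np.sort(np.abs(fusion), axis=1)[:, -2:] == 1)

    def test_ktk_psd_and_full_rank_without_unpenalized(self):
        ps = m.build_penalty_structure(m.aml_state_chart(), P=2)
        eigs = np.linalg.eigvalsh(ps.K.T @ ps.K)
        assert eigs.min() >= 1.0 - 1e-12  # lasso block alone contributes identity

    def test_unpenalized_covariate_excluded_from_all_blocks(self):
        chart = m.aml_state_chart()
        ps = m.build_penalty_structure(chart, P=3, unpenalized={2})
        Q = chart.n_transitions
        for q in range(1, Q + 1):
            assert ps.zeta[column_index(2, q, Q)] == 0.0
        assert all(p != 2 for p, _, _ in ps.fusion_rows)
        for q, _, cols in ps.group_blocks:
            assert column_index(2, q, Q) not in cols
            assert len(cols) == 2  # only the penalized covariates
        # group weight follows the penalized group size
        assert ps.group_weights[0] == pytest.approx(np.sqrt(2))

    def test_group_weight_modes(self):
        chart = m.aml_state_chart()
        assert m.build_penalty_structure(chart, P=4).group_weights[0] == pytest.approx(2.0)
        assert m.build_penalty_structure(chart, P=4, group_weight="size").group_weights[0] == 4.0

    def test_invalid_similar_pair_rejected(self):
        chart = m.StateChart(states=("a", "b"), transitions=((1, 2),),
                             similar_pairs=((1, 9),))
        with pytest.raises(ValueError, match="unknown transition"):
            m.build_penalty_structure(chart, P=1)

    def test_triplet_export_blocks(self, two_by_two):
        trip = two_by_two.to_triplets()
        assert set(trip["block"]) == {"lasso", "fusion", "group"}
        assert (trip["block"] == "lasso").sum() == 4


class TestPenaltyValue:
    def test_zero_at_origin(self, two_by_two):
        assert m.penalty_value(np.zeros(4), two_by_two, m.FSGLParams(1.0)) == 0.0

    def test_pure_lasso_single_coefficient(self, two_by_two):
        beta = np.array([2.0, 0.0, 0.0, 0.0])
        h = m.FSGLParams(lam=1.0, alpha=1.0, gamma=1.0)
        assert m.penalty_value(beta, two_by_two, h) == pytest.approx(2.0)

    def test_fusion_term_vanishes_for_equal_pair(self):
        ps = m.build_penalty_structure(m.aml_state_chart(), P=2)
        beta = np.zeros(16)
        beta[column_index(1, 3, 8)] = beta[column_index(1, 7, 8)] = 1.7
        h = m.FSGLParams(lam=1.0, alpha=1.0, gamma=0.0)
        assert m.penalty_value(beta, ps, h) == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_blockwise_identity_with_structure_matrix(self, seed, two_by_two):
        # penalty equals sum over K rows/blocks of multiplier * w * ||K_m beta||
        ps = two_by_two
        rng = np.random.default_rng(seed)
        beta = rng.normal(size=4)
        h = m.FSGLParams(lam=0.7, alpha=0.4, gamma=0.6)
        expected = h.lam * h.alpha * h.gamma * np.abs(ps.K[:4] @ beta) @ ps.zeta
        expected += h.lam * (1 - h.gamma) * np.abs(ps.K[4:6] @ beta).sum()
        for (q, rows, cols), w in zip(ps.group_blocks, ps.group_weights):
            expected += h.lam * (1 - h.alpha) * h.gamma * w * np.linalg.norm(ps.K[rows] @ beta)
        assert m.penalty_value(beta, ps, h) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_convex_and_positively_homogeneous(self, seed, two_by_two):
        rng = np.random.default_rng(seed)
        h = m.FSGLParams(lam=1.3, alpha=0.5, gamma=0.5)
        a, b = rng.normal(size=(2, 4))
        t = rng.uniform()
        pv = lambda v: m.penalty_value(v, two_by_two, h)
        assert pv(t * a + (1 - t) * b) <= t * pv(a) + (1 - t) * pv(b) + 1e-12
        c = rng.uniform(0, 5)
        assert pv(c * a) == pytest.approx(c * pv(a))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=4),
           st.floats(0, 1), st.floats(0, 1))
    def test_nonnegative_and_subadditive(self, vals, alpha, gamma):
        ps = m.build_penalty_structure(
            m.StateChart(states=("a", "b", "c"), transitions=((1, 2), (1, 3)),
                         similar_pairs=((1, 2),)), P=2)
        h = m.FSGLParams(lam=1.0, alpha=alpha, gamma=gamma)
        beta = np.array(vals)
        assert m.penalty_value(beta, ps, h) >= 0.0
        half = m.penalty_value(beta / 2, ps, h)
        assert m.penalty_value(beta, ps, h) <= 2 * half + 1e-9


@pytest.mark.parametrize(
    "alpha,gamma,label",
    [(1.0, 1.0, "global-lasso"), (0.0, 1.0, "group"), (1.0, 0.0, "fusion"),
     (0.0, 0.0, "fusion"), (0.75, 0.5, "mixed")],
)
def test_reduction_mode(alpha, gamma, label):
    assert m.reduction_mode(m.FSGLParams(1.0, alpha, gamma)) == label


@pytest.mark.parametrize("lam,alpha,gamma", [(-1, 1, 1), (1, 2, 1), (1, 1, -0.1)])
def test_hyperparameter_bounds(lam, alpha, gamma):
    with pytest.raises(ValueError):
        m.FSGLParams(lam, alpha, gamma)
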