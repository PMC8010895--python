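"""GLS variance engine: covariance structure, closed-form limits, oracles."""

import numpy as np
import pytest

from crtbaseline import (
    CorrelationParams,
    DesignSpec,
    ObservationGrid,
    TimeEffectSpec,
    build_model_matrices,
    build_observation_grid,
    design_variance,
    gls_variance,
)
from crtbaseline.variance import DegenerateDesignError

from conftest import brute_force_gls_variance, random_corr, random_design

STEP = TimeEffectSpec.step()


class TestCovarianceStructure:
    def test_same_time_and_opposite_ends(self):
        corr = CorrelationParams(rho=0.1, tau=0.4, sigma2=2.0)
        v = corr.covariance(np.array([0.0, 0.0, 1.0]))
        assert v[0, 1] == pytest.approx(2.0 * 0.1)        # same time: rho
        assert v[0, 2] == pytest.approx(2.0 * 0.1 * 0.4)  # ends of trial: tau*rho
        assert np.all(np.diag(v) == 2.0)

    def test_tau_one_is_compound_symmetric(self):
        corr = CorrelationParams(rho=0.07, tau=1.0)
        v = corr.covariance(np.linspace(0.1, 1, 9))
        off = v[~np.eye(9, dtype=bool)]
        np.testing.assert_allclose(off, 0.07)

    def test_positive_definite_across_parameter_range(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 1, 40))
        for rho in [0.0, 0.001, 0.3, 0.9, 0.999]:
            for tau in [0.01, 0.1, 0.5, 1.0]:
                np.linalg.cholesky(CorrelationParams(rho, tau).covariance(t))


class TestClosedFormLimits:
    def test_independence_reduces_to_ols_post_means(self):
        # rho = 0: GLS = OLS and the treatment effect is the post-period
        # between-arm mean difference, so Var = 1/n_post + 1/n_post
        spec = DesignSpec(m=100, crossover=0.5)
        res = design_variance(spec, CorrelationParams(rho=0.0), STEP)
        n_post = np.sum(spec.arrival_times() >= 0.5)  # 51 arrivals at i/100
        assert res.multiplier == pytest.approx(2.0 / n_post, rel=1e-10)

    def test_independence_matches_brute_force_ols(self):
        spec = DesignSpec(m=10, crossover=0.4, closure=0.1)
        grid = build_observation_grid(spec)
        mm = build_model_matrices(grid, CorrelationParams(rho=0.0), STEP, spec.crossover)
        oracle = brute_force_gls_variance(mm.Z, np.eye(mm.n_observations),
                                          mm.treatment_index)
        assert gls_variance(mm).multiplier == pytest.approx(oracle, rel=1e-12)

    def test_parallel_groups_design_effect(self):
        # crossover 0 with tau=1 is a parallel-groups cluster trial:
        # Var = 2 (1 + (m-1) rho) / m
        m, rho = 100, 0.05
        spec = DesignSpec(m=m, crossover=0.0)
        res = design_variance(spec, CorrelationParams(rho=rho, tau=1.0), STEP)
        assert res.multiplier == pytest.approx(2 * (1 + (m - 1) * rho) / m, rel=1e-10)

    def test_worked_example_step_value(self, worked_example_template):
        res = design_variance(worked_example_template(15.0),
                              CorrelationParams(rho=0.05, tau=1.0), STEP)
        assert round(res.multiplier, 3) == 0.060
        assert res.n_retained == 214


class TestOracleEquivalence:
    def test_block_accumulation_equals_monolithic_inverse(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            spec, corr = random_design(rng), random_corr(rng)
            grid = build_observation_grid(spec)
            mm = build_model_matrices(grid, corr, STEP, spec.crossover)
            oracle = brute_force_gls_variance(mm.Z, mm.V, mm.treatment_index)
            assert gls_variance(mm).multiplier == pytest.approx(oracle, rel=1e-10)

    def test_statsmodels_gls_cross_check(self, worked_example_template):
        sm = pytest.importorskip("statsmodels.api")
        spec = worked_example_template(15.0)
        corr = CorrelationParams(rho=0.05, tau=0.5)
        grid = build_observation_grid(spec)
        mm = build_model_matrices(grid, corr, STEP, spec.crossover)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(mm.n_observations)
        fit = sm.GLS(y, mm.Z, sigma=mm.V).fit()
        ti = mm.treatment_index
        assert gls_variance(mm).multiplier == pytest.approx(
            fit.normalized_cov_params[ti, ti], rel=1e-8
        )


class TestScaling:
    def test_sigma2_scales_variance(self, worked_example_template):
        spec = worked_example_template(15.0)
        base = design_variance(spec, CorrelationParams(0.05, 0.5, sigma2=1.0), STEP)
        scaled = design_variance(spec, CorrelationParams(0.05, 0.5, sigma2=4.0), STEP)
        assert scaled.multiplier == pytest.approx(4.0 * base.multiplier, rel=1e-10)

    @pytest.mark.parametrize("rho,tau", [(0.01, 1.0), (0.05, 0.5)])
    def test_monotone_in_cluster_size(self, rho, tau):
        corr = CorrelationParams(rho=rho, tau=tau)
        mults = [
            design_variance(DesignSpec(m=m, crossover=0.5), corr, STEP).multiplier
            for m in (25, 50, 100, 200)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(mults, mults[1:]))


class TestTimeEffectInvariance:
    def test_polynomial_additions_leave_variance_unchanged(self):
        # with the step-at-t* column in the model, adding polynomial time
        # columns of any degree up to 6 does not move the treatment variance
        rng = np.random.default_rng(7)
        for _ in range(10):
            spec = random_design(rng, max_m=20, symmetric=True)
            corr = random_corr(rng)
            base = design_variance(spec, corr, STEP).multiplier
            for degree in range(1, 7):
                aug = design_variance(spec, corr, TimeEffectSpec.step(degree)).multiplier
                assert aug == pytest.approx(base, rel=1e-8)

    def test_polynomial_basis_invariance(self, worked_example_template):
        # raw powers of t versus the internal centred basis give the same
        # treatment variance
        spec = worked_example_template(15.0)
        corr = CorrelationParams(0.05, 0.5)
        internal = design_variance(spec, corr, TimeEffectSpec.polynomial(3)).multiplier
        grid = build_observation_grid(spec)
        from crtbaseline.design import CONTROL, INTERVENTION

        blocks, vs = [], []
        for arm in (CONTROL, INTERVENTION):
            t = grid.times_in(arm)
            Z = np.column_stack([t**k for k in range(4)] + [grid.treated_in(arm)])
            blocks.append(Z)
            vs.append(corr.covariance(t))
        from scipy.linalg import block_diag

        oracle = brute_force_gls_variance(np.vstack(blocks), block_diag(*vs), 4)
        assert internal == pytest.approx(oracle, rel=1e-8)


class TestRankHandling:
    def test_redundant_step_column_dropped_with_warning(self):
        # crossover 0: the post indicator equals the intercept
        spec = DesignSpec(m=10, crossover=0.0)
        grid = build_observation_grid(spec)
        with pytest.warns(UserWarning, match="post"):
            mm = build_model_matrices(grid, CorrelationParams(0.05), STEP, 0.0)
        assert "post" in mm.dropped_columns
        assert mm.columns[-1] == "treatment"

    def test_no_baseline_step_column_dropped(self, worked_example_no_baseline):
        grid = build_observation_grid(worked_example_no_baseline)
        with pytest.warns(UserWarning):
            mm = build_model_matrices(grid, CorrelationParams(0.05), STEP, 3 / 24)
        assert mm.dropped_columns == ("post",)

    def test_untreated_grid_is_degenerate(self):
        grid = ObservationGrid(
            times=np.array([0.25, 0.5, 0.25, 0.5]),
            arm=np.array(["control", "control", "intervention", "intervention"]),
            treated=np.zeros(4, dtype=np.int8),
            n_control=2,
            n_intervention=2,
        )
        with pytest.raises(DegenerateDesignError):
            build_model_matrices(grid, CorrelationParams(0.05), STEP, 0.9)
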