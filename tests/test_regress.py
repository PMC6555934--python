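import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbreg import (
    CEDataset,
    DomainError,
    InsufficientDataError,
    SingularDesignError,
    compute_nb,
    fit_cost,
    fit_effect,
    fit_nb,
    fit_ols,
    incremental_summary,
    residual_cross_covariance,
)
from nbreg.regress import build_design


def _random_ds(seed: int, n_per_arm: int = 30, with_covariates: bool = True):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    tx = np.r_[np.zeros(n_per_arm, int), np.ones(n_per_arm, int)]
    cov = {"age": rng.normal(60, 8, n), "sex": rng.choice(["f", "m"], n)} if with_covariates else None
    return CEDataset.from_arrays(
        tx=tx,
        cost=rng.lognormal(9.5, 0.8, n) + 8000 * tx,
        effect=rng.normal(0.3, 0.15, n) + 0.1 * tx,
        covariates=cov,
        allow_negative_cost=True,
    )


class TestFitOls:
    def test_toy_cost_fit_equals_arm_mean_difference(self, toy_ds):
        assert fit_cost(toy_ds).coef() == pytest.approx(50.0, rel=1e-10)
        assert fit_effect(toy_ds).coef() == pytest.approx(0.5, rel=1e-10)

    def test_constant_outcome_degenerates_cleanly(self, toy_ds):
        X, names = build_design(toy_ds)
        fit = fit_ols(np.full(4, 7.0), X, names)
        assert fit.coef("tx") == pytest.approx(0.0, abs=1e-10)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-18)
        assert fit.p_value("tx") == 1.0

    def test_duplicated_column_raises_naming_culprits(self, toy_ds):
        X, names = build_design(toy_ds, extra=[("tx_copy", toy_ds.tx.astype(float))])
        with pytest.raises(SingularDesignError, match="tx_copy"):
            fit_ols(toy_ds.cost, X, names)

    def test_too_few_rows_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_ols(np.ones(2), np.ones((2, 2)), ["const", "x"])

    def test_covariance_diagonal_matches_se(self):
        fit = fit_cost(_random_ds(1), covariates=["age", "sex"])
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.coef_covariance)), fit.standard_errors, rtol=1e-10
        )
        assert fit.df_resid == fit.n - len(fit.coefficient_names)

    def test_matches_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        ds = _random_ds(2)
        X, names = build_design(ds, ["age", "sex"])
        ours = fit_ols(ds.cost, X, names)
        ref = sm.OLS(ds.cost, X).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, rtol=1e-9)
        np.testing.assert_allclose(ours.standard_errors, ref.bse, rtol=1e-9)
        np.testing.assert_allclose(ours.p_two_sided, ref.pvalues, rtol=1e-8, atol=1e-12)
        assert ours.df_resid == ref.df_resid

    def test_robust_se_matches_statsmodels_hc1(self):
        sm = pytest.importorskip("statsmodels.api")
        ds = _random_ds(3)
        X, names = build_design(ds)
        ours = fit_ols(ds.cost, X, names, robust=True)
        ref = sm.OLS(ds.cost, X).fit(cov_type="HC1")
        np.testing.assert_allclose(ours.standard_errors, ref.bse, rtol=1e-9)


class TestComputeNb:
    def test_wtp_zero_is_negated_cost(self, toy_ds):
        nb = compute_nb(toy_ds, 0.0)
        np.testing.assert_array_equal(nb.values, -toy_ds.cost)

    def test_break_even_patient(self):
        ds = CEDataset.from_arrays(
            tx=[0, 0, 1, 1], cost=[50, 50, 50, 50], effect=[0.5] * 4
        )
        assert compute_nb(ds, 100.0).values[0] == 0.0

    def test_toy_rows_at_wtp_200(self, toy_ds):
        np.testing.assert_allclose(
            compute_nb(toy_ds, 200.0).values, [50.0, 150.0, 100.0, 200.0]
        )

    def test_negative_wtp_rejected(self, toy_ds):
        with pytest.raises(DomainError):
            compute_nb(toy_ds, -1.0)


class TestNbRegression:
    def test_toy_inb_at_200(self, toy_ds):
        assert fit_nb(toy_ds, 200.0).coef() == pytest.approx(50.0, rel=1e-10)

    def test_inb_at_zero_wtp_is_minus_delta_cost(self, toy_ds):
        assert fit_nb(toy_ds, 0.0).coef() == pytest.approx(
            -fit_cost(toy_ds).coef(), rel=1e-12
        )

    def test_inb_vanishes_at_point_icer(self):
        ds = _random_ds(4, with_covariates=False)
        inc = incremental_summary(ds)
        icer_point = inc.delta_cost / inc.delta_effect
        assert fit_nb(ds, icer_point).coef() == pytest.approx(
            0.0, abs=1e-8 * abs(inc.delta_cost)
        )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), wtp=st.floats(0, 1e6))
    def test_linearity_identity_property(self, seed, wtp):
        """b_NB(lambda) = lambda*b_E - b_C for any shared covariate set."""
        ds = _random_ds(seed, n_per_arm=15)
        for covs in ((), ("age", "sex")):
            b_nb = fit_nb(ds, wtp, covs).coef()
            b_e = fit_effect(ds, covs).coef()
            b_c = fit_cost(ds, covs).coef()
            assert b_nb == pytest.approx(
                wtp * b_e - b_c, rel=1e-8, abs=1e-6 * max(1, abs(b_c))
            )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_arm_mean_oracle_property(self, seed):
        """Unadjusted TX coefficients equal arm-mean differences."""
        ds = _random_ds(seed, n_per_arm=10, with_covariates=False)
        for outcome, fitter in (("cost", fit_cost), ("effect", fit_effect)):
            vals = getattr(ds, outcome)
            oracle = vals[ds.tx == 1].mean() - vals[ds.tx == 0].mean()
            assert fitter(ds).coef() == pytest.approx(oracle, rel=1e-10, abs=1e-12)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), wtp=st.floats(0, 5e5))
    def test_variance_composition_property(self, seed, wtp):
        """s2_NB(l) = l^2 s2_E - 2 l s_EC + s2_C with one shared design."""
        ds = _random_ds(seed, n_per_arm=12)
        fc, fe = fit_cost(ds, ["age"]), fit_effect(ds, ["age"])
        s_ec = residual_cross_covariance(fc, fe)
        fnb = fit_nb(ds, wtp, ["age"])
        composed = (
            wtp**2 * fe.residual_variance - 2 * wtp * s_ec + fc.residual_variance
        )
        assert fnb.residual_variance == pytest.approx(
            composed, rel=1e-8, abs=1e-8 * max(1.0, abs(composed))
        )

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_fitted_plus_residuals_reconstruct_outcome(self, seed):
        ds = _random_ds(seed, n_per_arm=10)
        fit = fit_cost(ds, ["age", "sex"])
        np.testing.assert_allclose(
            fit.fitted + fit.residuals, ds.cost, rtol=1e-10
        )

    def test_permuted_labels_center_on_zero(self):
        rng = np.random.default_rng(9)
        ds = _random_ds(10, n_per_arm=50, with_covariates=False)
        effects = []
        for _ in range(200):
            perm = rng.permutation(ds.n)
            shuffled = CEDataset.from_arrays(
                tx=ds.tx[perm], cost=ds.cost, effect=ds.effect,
                allow_negative_cost=True,
            )
            effects.append(fit_effect(shuffled).coef())
        se = np.std(effects) / np.sqrt(len(effects))
        assert abs(np.mean(effects)) < 4 * se + 1e-3
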