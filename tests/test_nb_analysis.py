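import numpy as np
import pytest
from scipy import stats

from nbreg import (
    CEDataset,
    DomainError,
    IncrementalSummary,
    Quadrant,
    extrapolate_inb,
    fieller_ci,
    icer,
    incremental_summary,
    sweep_inb,
)
from tests.conftest import make_bivariate_normal


def _summary(dc, de, se_c=1.0, se_e=1.0, cov=0.0, n=100):
    return IncrementalSummary(
        delta_cost=dc, se_cost=se_c, p_cost=0.5,
        delta_effect=de, se_effect=se_e, p_effect=0.5,
        cov_delta=cov, n=n, df_resid=n - 2,
    )


class TestIncrementalSummary:
    def test_toy_values(self, toy_ds):
        inc = incremental_summary(toy_ds)
        assert inc.delta_cost == pytest.approx(50.0, rel=1e-10)
        assert inc.delta_effect == pytest.approx(0.5, rel=1e-10)

    def test_null_dataset_near_zero(self):
        rng = np.random.default_rng(0)
        n = 4000
        ds = CEDataset.from_arrays(
            tx=np.r_[np.zeros(n, int), np.ones(n, int)],
            cost=rng.lognormal(9, 0.5, 2 * n),
            effect=rng.normal(0.3, 0.1, 2 * n),
        )
        inc = incremental_summary(ds)
        assert abs(inc.delta_cost) < 4 * inc.se_cost
        assert abs(inc.delta_effect) < 4 * inc.se_effect


class TestIcerPolicy:
    @pytest.mark.parametrize(
        "dc, de, expected",
        [(22_210.0, 0.0771, 288_067.0), (30_843.0, 0.1769, 174_353.0)],
    )
    def test_trade_off_ratios_round_to_printed_dollars(self, dc, de, expected):
        est = icer(_summary(dc, de))
        assert est.reportable and est.quadrant is Quadrant.TRADE_OFF
        assert est.ratio == expected
        assert est.ratio_exact == pytest.approx(dc / de)

    def test_dominated_ratio_suppressed(self):
        est = icer(_summary(13_787.0, -0.0172))
        assert est.quadrant is Quadrant.DOMINATED
        assert not est.reportable and est.ratio is None

    def test_dominant_ratio_suppressed(self):
        est = icer(_summary(-500.0, 0.1))
        assert est.quadrant is Quadrant.DOMINANT and est.ratio is None

    def test_cost_saving_less_effective_is_reportable(self):
        est = icer(_summary(-10_000.0, -0.1))
        assert est.quadrant is Quadrant.COST_SAVING_LESS_EFFECTIVE
        assert est.reportable and est.ratio == 100_000.0

    def test_zero_delta_effect_labelled_undefined(self):
        est = icer(_summary(100.0, 0.0))
        assert est.ratio is None and "undefined" in est.label


class TestSweep:
    def test_toy_grid_values(self, toy_ds):
        curve = sweep_inb(toy_ds, [0.0, 100.0, 200.0])
        np.testing.assert_allclose(curve.inb, [-50.0, 0.0, 50.0], atol=1e-9)

    def test_inb_at_zero_equals_minus_delta_cost(self, bivnorm_ds):
        curve = sweep_inb(bivnorm_ds, [0.0, 50_000.0])
        assert curve.inb[0] == pytest.approx(-curve.summary.delta_cost, rel=1e-10)

    def test_line_slope_and_intercept(self, bivnorm_ds):
        curve = sweep_inb(bivnorm_ds, [0.0, 100_000.0, 350_000.0])
        inc = curve.summary
        slopes = np.diff(curve.inb) / np.diff(curve.grid)
        np.testing.assert_allclose(slopes, inc.delta_effect, rtol=1e-8)
        assert curve.inb[0] == pytest.approx(-inc.delta_cost, rel=1e-8)

    def test_zero_crossing_is_point_icer(self, bivnorm_ds):
        curve = sweep_inb(bivnorm_ds, [0.0, 500_000.0])
        inc = curve.summary
        assert curve.zero_crossing * inc.delta_effect - inc.delta_cost == pytest.approx(
            0.0, abs=1e-8 * abs(inc.delta_cost)
        )

    def test_ci_bounds_bracket_estimate_and_match_closed_form_se(self, bivnorm_ds):
        curve = sweep_inb(bivnorm_ds, list(np.linspace(0, 5e5, 11)))
        assert (curve.ci_low <= curve.inb).all() and (curve.inb <= curve.ci_high).all()
        closed = np.array([curve.summary.inb_se(w) for w in curve.grid])
        np.testing.assert_allclose(curve.se, closed, rtol=1e-8)
        # CI width is non-constant in lambda, minimized near the SE minimum
        widths = curve.ci_high - curve.ci_low
        assert widths.max() > widths.min()

    def test_grid_validation(self, toy_ds):
        with pytest.raises(DomainError):
            sweep_inb(toy_ds, [])
        with pytest.raises(DomainError):
            sweep_inb(toy_ds, [100.0, 50.0])
        with pytest.raises(DomainError):
            sweep_inb(toy_ds, [-10.0, 10.0])

    def test_wt_like_crossing_between_100k_and_200k(self):
        """A stratum with dE=0.1769, dC=30,843 turns cost-effective between
        $100k and $200k of willingness to pay (x-intercept ~ $174k)."""
        ds = make_bivariate_normal(seed=21, n_per_arm=2000)
        curve = sweep_inb(ds, [100_000.0, 200_000.0])
        assert curve.inb[0] < 0 < curve.inb[1]
        assert 100_000 < curve.zero_crossing < 200_000


class TestFieller:
    def test_matches_closed_form_quadratic_oracle(self):
        for seed in (11, 23, 47):
            ds = make_bivariate_normal(seed=seed, n_per_arm=400)
            inc = incremental_summary(ds)
            fi = fieller_ci(inc, 0.95)
            tcrit = stats.t.ppf(0.975, inc.df_resid)
            a = inc.delta_effect**2 - tcrit**2 * inc.se_effect**2
            b = -2 * (inc.delta_cost * inc.delta_effect - tcrit**2 * inc.cov_delta)
            c = inc.delta_cost**2 - tcrit**2 * inc.se_cost**2
            disc = b**2 - 4 * a * c
            lo, hi = sorted(
                [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
            )
            assert fi.lower == pytest.approx(lo, rel=1e-6)
            assert fi.upper == pytest.approx(hi, rel=1e-6)
            for lim in (fi.lower, fi.upper):
                assert abs(inc.inb(lim)) / inc.inb_se(lim) == pytest.approx(
                    tcrit, rel=1e-6
                )

    def test_interval_contains_point_icer(self):
        ds = make_bivariate_normal(seed=31, n_per_arm=600)
        inc = incremental_summary(ds)
        fi = fieller_ci(inc)
        assert fi.contains(inc.delta_cost / inc.delta_effect)

    def test_insignificant_effect_gives_unbounded_upper(self):
        ds = make_bivariate_normal(
            seed=41, n_per_arm=60, delta_effect=0.005, effect_sd=0.3
        )
        inc = incremental_summary(ds)
        tcrit = stats.t.ppf(0.975, inc.df_resid)
        assert inc.delta_effect - tcrit * inc.se_effect < 0  # precondition
        fi = fieller_ci(inc)
        assert fi.upper is None

    def test_dominated_line_never_crosses_positive_wtp(self):
        ds = make_bivariate_normal(
            seed=51, n_per_arm=2000, delta_cost=13_787.0, delta_effect=-0.0172
        )
        curve = sweep_inb(ds, [0.0, 500_000.0])
        assert curve.zero_crossing is None
        assert (curve.inb < 0).all()

    def test_degenerate_se_collapses_to_point_icer(self):
        inc = _summary(200.0, 0.5, se_c=0.0, se_e=0.0, cov=0.0)
        fi = fieller_ci(inc)
        assert fi.lower == fi.upper == pytest.approx(400.0)


class TestExtrapolation:
    def test_worked_examples(self):
        assert extrapolate_inb(-13_154.0, 100_000.0, 123_456.0, 0.1769) == -9_005
        assert extrapolate_inb(57_606.0, 500_000.0, 600_000.0, 0.1769) == 75_296

    def test_identity_at_same_wtp(self):
        assert extrapolate_inb(-13_154.0, 100_000.0, 100_000.0, 0.1769) == -13_154

    def test_agrees_with_direct_line_evaluation(self):
        direct = 123_456.0 * 0.1769 - 30_843.0
        via_extrapolation = extrapolate_inb(-13_154.0, 100_000.0, 123_456.0, 0.1769)
        assert abs(direct - via_extrapolation) < 2.0
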