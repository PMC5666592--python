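"""Causal estimators against independent oracles and their invariants."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from vdmr import (
    EstimationError,
    HarmonizedInstrument,
    ivw,
    likelihood_estimate,
    mr_egger,
    rescale_estimate,
    score_subset_estimate,
    wald_ratio,
    weighted_median,
)
from vdmr.estimators import _weighted_median_value
from vdmr.synthetic_data import (
    INSTRUMENT_GAMMA,
    INSTRUMENT_GAMMA_SE,
    SimulationConfig,
    simulate_summary_pair,
)
from vdmr.summary_io import harmonize

from conftest import build_instrument


class TestWaldRatio:
    def test_null_numerator(self):
        inst = build_instrument([4.67], [0.0])
        assert wald_ratio(inst.records[0]).beta == 0.0

    def test_hand_arithmetic(self):
        # outcome log-OR ln(0.95) on the strongest published variant
        inst = build_instrument([4.67], [math.log(0.95)], outcome_se=[0.02])
        est = wald_ratio(inst.records[0])
        assert est.beta == pytest.approx(math.log(0.95) / 4.67, rel=1e-12)
        assert est.se == pytest.approx(0.02 / 4.67, rel=1e-12)
        assert math.exp(25 * est.beta) == pytest.approx(0.760, abs=5e-4)

    def test_doubling_exposure_halves_beta_and_se(self):
        a = wald_ratio(build_instrument([2.0], [0.1]).records[0])
        b = wald_ratio(build_instrument([4.0], [0.1]).records[0])
        assert b.beta == pytest.approx(a.beta / 2)
        assert b.se == pytest.approx(a.se / 2)

    def test_ci_is_wald_type(self):
        est = wald_ratio(build_instrument([2.0], [0.1]).records[0])
        from scipy.stats import norm
        z = norm.ppf(0.975)
        assert est.ci_low == pytest.approx(est.beta - z * est.se)
        assert est.ci_high == pytest.approx(est.beta + z * est.se)


class TestIVW:
    def test_single_variant_reduces_to_wald(self):
        inst = build_instrument([4.67], [0.05], outcome_se=[0.018])
        assert ivw(inst).beta == pytest.approx(wald_ratio(inst.records[0]).beta)
        assert ivw(inst).se == pytest.approx(wald_ratio(inst.records[0]).se)

    def test_symmetric_two_variant_average(self):
        # equal gamma, equal outcome SE -> plain average of the two ratios
        inst = build_instrument([2.0, 2.0], [0.10, 0.04], outcome_se=[0.02, 0.02])
        r1, r2 = 0.10 / 2.0, 0.04 / 2.0
        assert ivw(inst).beta == pytest.approx((r1 + r2) / 2, rel=1e-12)

    @pytest.mark.parametrize("J", [2, 3, 4, 6])
    def test_equals_wls_through_origin(self, J, rng):
        """Independent normal-equations oracle via statsmodels (no constant)."""
        g = rng.uniform(0.5, 5.0, J)
        sy = rng.uniform(0.01, 0.05, J)
        G = rng.normal(0.0, 0.05, J)
        inst = build_instrument(g, G, outcome_se=sy)
        oracle = sm.WLS(G, g[:, None], weights=sy**-2.0).fit().params[0]
        assert ivw(inst).beta == pytest.approx(oracle, abs=1e-10)

    def test_four_variant_published_strength_fixture(self):
        g = np.array(INSTRUMENT_GAMMA)
        sy = np.array([0.015, 0.02, 0.018, 0.025])
        G = np.array([-0.02, -0.01, -0.008, -0.005])
        inst = build_instrument(g, G, outcome_se=sy)
        w = sy**-2.0
        oracle = np.sum(w * g * G) / np.sum(w * g * g)
        est = ivw(inst)
        assert est.beta == pytest.approx(oracle, abs=1e-12)
        assert est.se == pytest.approx(np.sum(w * g * g) ** -0.5, abs=1e-12)

    def test_order_invariance(self, rng):
        g = [4.67, 1.72, 2.11, 0.98]
        G = [-0.02, -0.01, -0.008, -0.005]
        sy = [0.015, 0.02, 0.018, 0.025]
        inst = build_instrument(g, G, outcome_se=sy)
        perm = [2, 0, 3, 1]
        shuffled = build_instrument(
            [g[i] for i in perm], [G[i] for i in perm], outcome_se=[sy[i] for i in perm]
        )
        assert ivw(shuffled).beta == pytest.approx(ivw(inst).beta, rel=1e-14)

    def test_empty_instrument_raises(self):
        with pytest.raises(Exception):
            ivw(HarmonizedInstrument(records=[]))


class TestLikelihood:
    def test_null_outcome_gives_zero(self):
        inst = build_instrument(INSTRUMENT_GAMMA, [0.0] * 4, gamma_se=INSTRUMENT_GAMMA_SE,
                                outcome_se=[0.018] * 4)
        assert likelihood_estimate(inst).beta == pytest.approx(0.0, abs=1e-12)

    def test_nome_limit_equals_ivw(self):
        inst = build_instrument(
            INSTRUMENT_GAMMA, [-0.021, -0.008, -0.009, -0.004],
            gamma_se=[1e-8] * 4, outcome_se=[0.018] * 4,
        )
        lik = likelihood_estimate(inst)
        assert abs(lik.beta - ivw(inst).beta) / abs(ivw(inst).beta) < 1e-4

    def test_nome_approach_is_monotone(self):
        """Shrinking sigma_x moves the MLE monotonically onto IVW."""
        inst0 = build_instrument(
            INSTRUMENT_GAMMA, [-0.021, -0.008, -0.009, -0.004], outcome_se=[0.018] * 4
        )
        target = ivw(inst0).beta
        gaps = []
        for factor in (1.0, 0.3, 0.1, 0.03, 0.01):
            sx = np.array(INSTRUMENT_GAMMA_SE) * factor
            inst = build_instrument(
                INSTRUMENT_GAMMA, [-0.021, -0.008, -0.009, -0.004],
                gamma_se=sx, outcome_se=[0.018] * 4,
            )
            gaps.append(abs(likelihood_estimate(inst).beta - target))
        assert all(a >= b for a, b in zip(gaps, gaps[1:]))

    def test_matches_grid_search_oracle(self):
        """Dense theta grid with the profiled-gamma closed form as oracle."""
        g = np.array(INSTRUMENT_GAMMA)
        sx = np.array(INSTRUMENT_GAMMA_SE)
        sy = np.full(4, 0.018)
        G = np.array([-0.024, -0.007, -0.011, -0.006])
        inst = build_instrument(g, G, gamma_se=sx, outcome_se=sy)
        theta_hat = likelihood_estimate(inst).beta

        def m2ll(th):
            gam = (g / sx**2 + th * G / sy**2) / (1 / sx**2 + th**2 / sy**2)
            return np.sum((g - gam) ** 2 / sx**2 + (G - th * gam) ** 2 / sy**2)

        grid = np.linspace(theta_hat - 0.01, theta_hat + 0.01, 2_000_001)
        oracle = grid[np.argmin([0])]  # placeholder replaced below
        vals = (
            (g[None, :] / sx[None, :] ** 2 + grid[:, None] * G[None, :] / sy[None, :] ** 2)
            / (1 / sx[None, :] ** 2 + grid[:, None] ** 2 / sy[None, :] ** 2)
        )
        m = np.sum(
            (g[None, :] - vals) ** 2 / sx[None, :] ** 2
            + (G[None, :] - grid[:, None] * vals) ** 2 / sy[None, :] ** 2,
            axis=1,
        )
        oracle = grid[np.argmin(m)]
        assert theta_hat == pytest.approx(oracle, abs=1e-6)

    def test_profile_ci_contains_wald_estimate(self):
        inst = build_instrument(
            INSTRUMENT_GAMMA, [-0.024, -0.007, -0.011, -0.006],
            gamma_se=INSTRUMENT_GAMMA_SE, outcome_se=[0.018] * 4,
        )
        est = likelihood_estimate(inst, ci_method="profile")
        assert est.ci_low < est.beta < est.ci_high


class TestMREgger:
    def test_exact_fit_recovers_slope_and_zero_intercept(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = mr_egger(build_instrument(g, 0.01 * g, outcome_se=[0.02] * 4))
        assert res.slope.beta == pytest.approx(0.01, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_two_point_input_rejected(self):
        with pytest.raises(EstimationError):
            mr_egger(build_instrument([1.0, 2.0], [0.01, 0.02]))

    def test_zero_gamma_spread_rejected(self):
        with pytest.raises(EstimationError):
            mr_egger(build_instrument([2.0] * 4, [0.01, 0.02, 0.03, 0.04]))

    def test_matches_wls_oracle_with_intercept(self, rng):
        g = rng.uniform(0.5, 5.0, 5)
        G = rng.normal(0.0, 0.03, 5)
        sy = rng.uniform(0.01, 0.04, 5)
        inst = build_instrument(g, G, outcome_se=sy)
        fit = sm.WLS(G, sm.add_constant(g), weights=sy**-2.0).fit()
        res = mr_egger(inst)
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-12)
        assert res.slope.beta == pytest.approx(fit.params[1], abs=1e-12)

    def test_intercept_t_option_widens_p(self):
        inst = build_instrument(
            [1.0, 2.0, 3.0, 4.0], [0.012, 0.017, 0.035, 0.039], outcome_se=[0.01] * 4
        )
        p_norm = mr_egger(inst, intercept_dist="normal").intercept_pvalue
        p_t = mr_egger(inst, intercept_dist="t").intercept_pvalue
        assert p_t > p_norm

    def test_directional_pleiotropy_recovered_in_mean(self):
        """Monte-Carlo oracle: injected constant pleiotropy 0.02 log-OR."""
        config = SimulationConfig(
            theta=-0.004, seed=77, n_replicates=400,
            pleiotropy_mode="directional", pleiotropy_mean=0.02, pleiotropy_sd=0.0,
        )
        intercepts, slopes = [], []
        for rep in simulate_summary_pair(config):
            inst = harmonize(rep.exposure, rep.outcome)
            res = mr_egger(inst)
            intercepts.append(res.intercept)
            slopes.append(res.slope.beta)
        mc_se = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert np.mean(intercepts) == pytest.approx(0.02, abs=4 * mc_se)
        slope_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(-0.004, abs=4 * slope_se)


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_plain_median(self):
        ratios = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        assert _weighted_median_value(ratios, np.ones(5)) == pytest.approx(
            np.median(ratios), rel=1e-12
        )

    def test_degenerate_spread(self):
        inst = build_instrument([1.0, 2.0, 4.0], [0.01, 0.02, 0.04],
                                gamma_se=[1e-6] * 3, outcome_se=[1e-6] * 3)
        est = weighted_median(inst, bootstrap_reps=200, seed=9)
        assert est.beta == pytest.approx(0.01, rel=1e-9)

    def test_matches_cumulative_weight_scan_oracle(self):
        """Brute-force scan over the interpolation breakpoints."""
        ratios = np.array([0.1, 0.2, 0.4, 0.8])
        weights = np.array([0.1, 0.2, 0.3, 0.4])
        breaks = np.cumsum(weights) - weights / 2  # weights already sum to 1
        # 0.5 falls between breaks[1]=0.2 and breaks[2]=0.45... find bracket
        k = np.searchsorted(breaks, 0.5)
        expected = ratios[k - 1] + (ratios[k] - ratios[k - 1]) * (
            (0.5 - breaks[k - 1]) / (breaks[k] - breaks[k - 1])
        )
        assert _weighted_median_value(ratios, weights) == pytest.approx(expected, abs=1e-15)

    @given(
        st.lists(st.floats(min_value=-2, max_value=2), min_size=3, max_size=9),
        st.lists(st.floats(min_value=0.01, max_value=5), min_size=9, max_size=9),
    )
    def test_always_within_ratio_range(self, ratios, weights):
        r = np.asarray(ratios)
        w = np.asarray(weights[: r.size])
        value = _weighted_median_value(r, w)
        assert r.min() - 1e-12 <= value <= r.max() + 1e-12

    def test_seed_required_and_reproducible(self):
        inst = build_instrument([4.67, 1.72, 2.11], [-0.02, -0.008, -0.01])
        with pytest.raises(ValueError):
            weighted_median(inst)
        a = weighted_median(inst, bootstrap_reps=300, seed=5)
        b = weighted_median(inst, bootstrap_reps=300, seed=5)
        assert a == b

    def test_small_bootstrap_warns(self):
        inst = build_instrument([4.67, 1.72, 2.11], [-0.02, -0.008, -0.01])
        with pytest.warns(UserWarning):
            weighted_median(inst, bootstrap_reps=50, seed=5)


class TestScoreSubsets:
    def test_synthesis_subset_is_ivw_over_the_two_synthesis_snps(
        self, fixture_instrument
    ):
        est = score_subset_estimate(fixture_instrument, "synthesis")
        sub = fixture_instrument.subset(["rs10741657", "rs12785878"])
        assert est.beta == pytest.approx(ivw(sub).beta)
        assert est.method == "score_synthesis"
        assert est.n_variants == 2

    def test_missing_member_raises_with_names(self, fixture_instrument):
        inst = fixture_instrument.subset(["rs2282679", "rs10741657", "rs12785878"])
        with pytest.raises(EstimationError, match="rs6013897"):
            score_subset_estimate(inst, "metabolism")

    def test_scores_agree_without_pleiotropy(self):
        """Synthesis and metabolism estimates agree within 2 pooled SEs."""
        config = SimulationConfig(theta=np.log(0.89) / 25, seed=11, n_replicates=1000)
        agree = 0
        for rep in simulate_summary_pair(config):
            inst = harmonize(rep.exposure, rep.outcome)
            syn = score_subset_estimate(inst, "synthesis")
            met = score_subset_estimate(inst, "metabolism")
            pooled_se = np.hypot(syn.se, met.se)
            agree += abs(syn.beta - met.beta) <= 2 * pooled_se
        assert agree / 1000 >= 0.95


class TestRescale:
    def test_published_unit_conversion(self):
        est = ivw(build_instrument([1.0], [math.log(0.988)], outcome_se=[0.0046]))
        per20_decrease = rescale_estimate(est, 20.0, "decrease")
        assert round(per20_decrease.odds_ratio, 2) == 1.27

    def test_null_effect_unchanged(self):
        est = ivw(build_instrument([1.0], [0.0], outcome_se=[0.01]))
        for direction in ("increase", "decrease"):
            assert rescale_estimate(est, 20.0, direction).odds_ratio == 1.0

    def test_log_or_linear_in_increment(self):
        est = ivw(build_instrument([2.0], [0.01], outcome_se=[0.01]))
        scaled = rescale_estimate(est, 25.0)
        assert math.log(scaled.odds_ratio) == pytest.approx(25 * est.beta, rel=1e-12)

    def test_decrease_swaps_ci_order(self):
        est = ivw(build_instrument([2.0], [0.01], outcome_se=[0.01]))
        dec = rescale_estimate(est, 25.0, "decrease")
        assert dec.ci_low == pytest.approx(-est.ci_high)
        assert dec.ci_high == pytest.approx(-est.ci_low)
        assert dec.ci_low < dec.ci_high

    def test_invalid_increment(self):
        est = ivw(build_instrument([2.0], [0.01], outcome_se=[0.01]))
        with pytest.raises(ValueError):
            rescale_estimate(est, 0.0)
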