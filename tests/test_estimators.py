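"""Core MR estimators: IVW, Egger, weighted median, mode, bidirectional."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from pleiomr import (bidirectional_mr, egger, ivw, mode_estimate,
                     weighted_median)
from pleiomr.estimators import (EstimatorError, available_methods,
                                get_method, register_method)
from pleiomr.pleiosim import ScenarioConfig, make_harmonized, \
    simulate_summary_stats
from pleiomr.sumstats import select_instruments

from conftest import make_harm, make_stats


class TestIvw:
    def test_equal_weight_mean_of_ratios(self):
        h = make_harm([1, 1, 1], [0.1, 0.2, 0.3])
        assert ivw(h).b_xy == pytest.approx(0.2)

    def test_single_iv_rejected_two_identical_ratios_recovered(self):
        with pytest.raises(EstimatorError):
            ivw(make_harm([1.0], [0.3]))
        h = make_harm([0.5, 1.0], [0.15, 0.3])
        assert ivw(h).b_xy == pytest.approx(0.3)

    def test_matches_wls_through_origin(self, random_harm):
        """Dual route: closed form vs statsmodels WLS without intercept."""
        res = ivw(random_harm)
        fit = sm.WLS(random_harm.by, random_harm.bx[:, None],
                     weights=1.0 / random_harm.se_y ** 2).fit()
        assert res.b_xy == pytest.approx(fit.params[0], rel=1e-12)
        # fixed-effect se uses the theoretical (unit) scale
        expected_se = np.sum(random_harm.bx ** 2
                             / random_harm.se_y ** 2) ** -0.5
        assert res.se == pytest.approx(expected_se, rel=1e-12)

    def test_multiplicative_model_never_deflates(self, random_harm):
        fixed = ivw(random_harm, variance_model="fixed")
        mult = ivw(random_harm, variance_model="multiplicative")
        assert mult.se >= fixed.se
        assert mult.b_xy == fixed.b_xy


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harm(bx, 0.05 + 0.3 * bx)
        res = egger(h)
        assert res.b_xy == pytest.approx(0.3, abs=1e-10)
        assert res.intercept == pytest.approx(0.05, abs=1e-10)

    def test_zero_intercept_when_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = egger(make_harm(bx, 0.3 * bx))
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_wls_with_intercept(self, rng):
        k = 6
        bx = rng.normal(0.1, 0.05, k)
        by = 0.02 + 0.25 * bx + rng.normal(0, 0.01, k)
        se_y = rng.uniform(0.008, 0.02, k)
        h = make_harm(bx, by, se_y=se_y)
        res = egger(h)
        flip = np.where(bx < 0, -1.0, 1.0)
        X = sm.add_constant(bx * flip)
        fit = sm.WLS(by * flip, X, weights=1.0 / se_y ** 2).fit()
        assert res.b_xy == pytest.approx(fit.params[1], rel=1e-10)
        assert res.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert res.se == pytest.approx(fit.bse[1], rel=1e-10)
        assert res.p == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_requires_three_instruments_and_variation(self):
        with pytest.raises(EstimatorError):
            egger(make_harm([0.1, 0.2], [0.03, 0.06]))
        with pytest.raises(EstimatorError, match="degenerate"):
            egger(make_harm([0.1, 0.1, -0.1], [0.03, 0.03, -0.03]))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        h = make_harm([1, 1, 1], [1, 2, 3])
        assert weighted_median(h, seed=1).b_xy == pytest.approx(2.0)

    def test_mid_weight_interpolation_oracle(self):
        """Weights (0.5, 0.25, 0.25) on ratios (1,2,3): direct evaluation
        of the mid-weight definition gives 5/3."""
        # equal se_y, so weights proportional to bx^2: bx = (2,1,1)/sqrt
        bx = np.array([np.sqrt(2.0), 1.0, 1.0])
        by = bx * np.array([1.0, 2.0, 3.0])
        h = make_harm(bx, by)
        # oracle: s = cumsum(w) - w/2 = (.25, .625, .875); interpolate at .5
        s = np.array([0.25, 0.625, 0.875])
        expect = 1.0 + (2.0 - 1.0) * (0.5 - s[0]) / (s[1] - s[0])
        res = weighted_median(h, seed=2)
        assert expect == pytest.approx(5.0 / 3.0)
        assert res.b_xy == pytest.approx(expect, rel=1e-12)

    def test_degenerate_ratios_give_zero_se(self):
        h = make_harm([0.5, 1.0, 2.0], [0.15, 0.3, 0.6])
        res = weighted_median(h, seed=3)
        assert res.b_xy == pytest.approx(0.3)
        assert res.se == pytest.approx(0.0)

    def test_seed_mandatory_and_reproducible(self, random_harm):
        with pytest.raises(EstimatorError, match="seed"):
            weighted_median(random_harm)
        a = weighted_median(random_harm, seed=11)
        b = weighted_median(random_harm, seed=11)
        assert a.se == b.se


class TestMode:
    def test_cluster_dominates_single_outlier(self):
        bx = np.ones(4)
        h = make_harm(bx, np.array([0.2, 0.21, 0.19, 5.0]),
                      se_y=np.full(4, 0.05))
        res = mode_estimate(h, seed=4)
        # independent oracle: brute-force grid argmax of the smoothed density
        ratios = np.array([0.2, 0.21, 0.19, 5.0])
        sd = ratios.std(ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25])) / 1.349
        bw = 0.9 * min(sd, iqr) * 4 ** -0.2
        grid = np.linspace(ratios.min() - 2 * bw, ratios.max() + 2 * bw,
                           20001)
        dens = np.exp(-0.5 * ((grid[:, None] - ratios) / bw) ** 2).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        assert res.b_xy == pytest.approx(oracle, abs=bw)
        assert abs(res.b_xy - 0.2) < bw

    def test_identical_ratios_return_common_value(self):
        h = make_harm([1.0, 2.0, 0.5], [0.3, 0.6, 0.15])
        assert mode_estimate(h, seed=5).b_xy == pytest.approx(0.3, abs=1e-6)

    def test_dominant_weight_pulls_weighted_mode(self):
        bx = np.array([10.0, 0.3, 0.4, 0.5, 0.6])
        ratios = np.array([0.7, -2.0, 1.8, 3.5, -0.9])
        h = make_harm(bx, bx * ratios, se_y=np.full(5, 0.05))
        res = mode_estimate(h, weighted=True, seed=6)
        assert abs(res.b_xy - 0.7) < 0.05


class TestEquivariance:
    @given(st.floats(0.2, 5.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_scale_equivariance(self, c):
        """Multiplying bx and se_x by c divides every estimate by c."""
        rng = np.random.default_rng(7)
        k = 8
        bx = rng.normal(0.1, 0.03, k)
        by = 0.3 * bx + rng.normal(0, 0.01, k)
        h1 = make_harm(bx, by)
        h2 = make_harm(c * bx, by, se_x=np.full(k, 0.01 * c))
        for fn, kw in [(ivw, {}), (egger, {}),
                       (weighted_median, {"seed": 1, "n_boot": 50}),
                       (mode_estimate, {"seed": 1, "n_boot": 50})]:
            assert fn(h2, **kw).b_xy == pytest.approx(fn(h1, **kw).b_xy / c,
                                                      rel=1e-6)

    def test_sign_equivariance_and_egger_orientation_invariance(self, rng):
        k = 8
        bx = rng.normal(0.1, 0.05, k)          # mixed signs possible
        by = 0.3 * bx + rng.normal(0, 0.01, k)
        h = make_harm(bx, by)
        h_neg = make_harm(bx, -by)
        for fn, kw in [(ivw, {}), (egger, {}),
                       (weighted_median, {"seed": 2, "n_boot": 50})]:
            assert fn(h_neg, **kw).b_xy == pytest.approx(-fn(h, **kw).b_xy,
                                                         rel=1e-9)
        # flipping the reported effect allele of some IVs leaves Egger alone
        flip = rng.random(k) < 0.5
        s = np.where(flip, -1.0, 1.0)
        h_flip = make_harm(bx * s, by * s)
        assert egger(h_flip).b_xy == pytest.approx(egger(h).b_xy, rel=1e-9)
        assert egger(h_flip).intercept == pytest.approx(egger(h).intercept,
                                                        rel=1e-9)

    def test_weighted_median_within_ratio_range(self, rng):
        for _ in range(20):
            k = rng.integers(3, 12)
            bx = rng.normal(0.1, 0.04, k)
            bx[np.abs(bx) < 0.01] = 0.05
            by = rng.normal(0, 0.05, k)
            res = weighted_median(make_harm(bx, by), seed=8, n_boot=20)
            r = by / bx
            assert r.min() - 1e-12 <= res.b_xy <= r.max() + 1e-12


class TestConsistencyAndRobustness:
    def test_all_estimators_consistent_on_valid_ivs(self):
        """With no invalid instruments the mean estimate over 200
        replicates matches the generative effect within Monte-Carlo
        error."""
        reps = 200
        ests = {m: [] for m in ("ivw", "egger", "weighted_median", "mode")}
        for rep in range(reps):
            cfg = ScenarioConfig(k=30, h2_x=0.1, b_xy=0.15, seed=40_000 + rep)
            e, o, _ = simulate_summary_stats(cfg)
            h = make_harmonized(e, o, select_instruments(e))
            ests["ivw"].append(ivw(h).b_xy)
            ests["egger"].append(egger(h).b_xy)
            ests["weighted_median"].append(
                weighted_median(h, seed=rep, n_boot=20).b_xy)
            ests["mode"].append(mode_estimate(h, seed=rep, n_boot=20).b_xy)
        for m, vals in ests.items():
            vals = np.array(vals)
            mc = vals.std(ddof=1) / np.sqrt(reps)
            assert abs(vals.mean() - 0.15) < 4 * mc + 1e-4, \
                f"{m}: mean {vals.mean():.4f}"

    def test_weighted_median_less_biased_than_ivw_under_directional(self):
        """30% invalid IVs with directional pleiotropy: the weighted
        median is the more robust estimator."""
        reps = 500
        b_ivw, b_wm = [], []
        for rep in range(reps):
            cfg = ScenarioConfig(k=50, pi_invalid=0.3, invalid_var_share=0.3,
                                 pleiotropy="directional", alpha_sd=0.01,
                                 alpha_mean=0.005, rho_dir=0.8, b_xy=0.2,
                                 seed=50_000 + rep)
            e, o, _ = simulate_summary_stats(cfg)
            h = make_harmonized(e, o, select_instruments(e))
            b_ivw.append(ivw(h).b_xy)
            b_wm.append(weighted_median(h, seed=rep, n_boot=8).b_xy)
        bias_ivw = abs(np.mean(b_ivw) - 0.2)
        bias_wm = abs(np.mean(b_wm) - 0.2)
        assert bias_wm < bias_ivw


class TestRegistry:
    def test_builtins_registered(self):
        for m in ("ivw", "egger", "weighted_median", "mode", "gsmr2"):
            assert m in available_methods()

    def test_plugin_contract(self, random_harm):
        from pleiomr.results import MRResult

        def external(h, **kw):
            return MRResult("external", 0.0, 1.0, 1.0, h.k)

        register_method("external_test", external, overwrite=True)
        assert get_method("external_test")(random_harm).method == "external"
        with pytest.raises(EstimatorError, match="unknown method"):
            get_method("nope")


class TestBidirectional:
    def _trait_pair(self, rng, n_x_only=25, n_y_only=25, b=0.3, n=200_000):
        """Panel with exposure-specific and outcome-specific variants:
        forward MR sees b; reverse MR mixes null and 1/b instruments."""
        m = n_x_only + n_y_only
        se = np.full(m, n ** -0.5)
        beta_a = np.zeros(m)
        beta_a[:n_x_only] = np.sqrt(0.5 / n_x_only)
        beta_b = b * beta_a
        beta_b[n_x_only:] = np.sqrt(0.5 / n_y_only)
        bhat_a = beta_a + rng.normal(0, se)
        bhat_b = beta_b + rng.normal(0, se)
        ids = [f"rs{i}" for i in range(m)]

        def mk(bhat):
            p = np.clip(2 * stats.norm.sf(np.abs(bhat / se)),
                        np.nextafter(0, 1), 1)
            return make_stats(ids, ["A"] * m, ["G"] * m, np.full(m, 0.3),
                              bhat, se, p, np.full(m, n))
        return mk(bhat_a), mk(bhat_b)

    def test_forward_recovered_reverse_attenuated(self, rng):
        a, b = self._trait_pair(rng)
        fwd, rev = bidirectional_mr(a, b, method="ivw")
        assert fwd.b_xy == pytest.approx(0.3, abs=0.05)
        # reverse instruments include outcome-specific (null-ratio)
        # variants, so the estimate is pulled well below 1/0.3
        assert rev.n_iv_used > 0
        assert rev.b_xy < 1.5

    def test_same_trait_both_directions_unity(self, rng):
        a, _ = self._trait_pair(rng)
        fwd, rev = bidirectional_mr(a, a, method="ivw")
        assert fwd.b_xy == pytest.approx(1.0, abs=1e-10)
        assert rev.b_xy == pytest.approx(1.0, abs=1e-10)

    def test_no_instrument_direction_marked(self, rng):
        a, _ = self._trait_pair(rng)
        null = make_stats(a.variant_ids, ["A"] * len(a.df),
                          ["G"] * len(a.df), np.full(len(a.df), 0.3),
                          np.full(len(a.df), 1e-4),
                          np.full(len(a.df), 0.01),
                          np.full(len(a.df), 0.99),
                          np.full(len(a.df), 1000))
        fwd, rev = bidirectional_mr(a, null, method="ivw")
        assert rev.note == "no-instrument"
        assert np.isnan(rev.b_xy)
        assert fwd.n_iv_used > 0
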