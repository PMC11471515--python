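"""The five univariable MR estimators and effect-scale conversion."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrmediate.estimators import (
    beta_to_or,
    egger,
    ivw,
    mode_estimate,
    run_all_methods,
    wald_ratios,
    weighted_median,
)
from mrmediate.instruments import InsufficientInstrumentsError

from conftest import make_harmonized


class TestWaldRatios:
    def test_direct_division(self):
        h = make_harmonized([0.2], [0.01], [0.1], [0.02])
        r, se = wald_ratios(h)
        assert r[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.1)

    def test_null_outcome_effect(self):
        h = make_harmonized([0.2], [0.01], [0.0], [0.02])
        assert wald_ratios(h)[0][0] == 0.0

    def test_negative_gamma_sign(self):
        h = make_harmonized([-0.2], [0.01], [0.1], [0.02])
        r, se = wald_ratios(h)
        assert r[0] == pytest.approx(-0.5)
        assert se[0] == pytest.approx(0.1)  # SE uses |gamma|

    def test_zero_gamma_excluded(self):
        h = make_harmonized([0.2, 0.0], [0.01] * 2, [0.1, 0.1], [0.02] * 2)
        r, _ = wald_ratios(h)
        assert len(r) == 1


class TestIVW:
    def test_homogeneous_ratios_fixed_effect(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.01] * 3,
                            [0.05, 0.10, 0.20], [0.01, 0.03, 0.02])
        est = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert est.model == "fixed"

    def test_two_point_hand_computation(self):
        h = make_harmonized([1.0, 1.0], [0.01] * 2, [0.5, 1.5], [1.0, 1.0])
        est = ivw(h)
        assert est.beta == pytest.approx(1.0)
        # Q = (0.5-1)^2 + (1.5-1)^2 = 0.5 < df=1, so fixed-effect SE = 1/sqrt(2)
        assert est.model == "fixed"
        assert est.se == pytest.approx(1.0 / np.sqrt(2.0))

    def test_random_effects_inflation_when_q_exceeds_df(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.01] * 3, [0.0, 1.0, 5.0], [0.1] * 3)
        est = ivw(h)
        assert est.model == "multiplicative-random"
        # SE inflated by sqrt(Q/df) relative to the fixed form
        fixed_se = 1.0 / np.sqrt(np.sum(1.0 / 0.1**2 * np.ones(3)))
        assert est.se > fixed_se

    def test_regression_form_equals_pooled_wald_mean(self, random_harmonized):
        h = random_harmonized
        est = ivw(h)
        r, se_r = wald_ratios(h)
        w = 1.0 / se_r**2
        assert est.beta == pytest.approx(np.sum(w * r) / np.sum(w), abs=1e-12)

    def test_published_or_scale_conversion(self):
        # an IVW estimate of 0.103 (0.026) corresponds to OR 1.108 (1.053-1.166)
        or_, lo, hi = beta_to_or(0.103, 0.026)
        assert round(or_, 3) == 1.108
        assert round(lo, 3) == 1.053

    def test_insufficient_instruments(self):
        h = make_harmonized([0.2], [0.01], [0.1], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        G = 0.02 + 0.4 * g
        h = make_harmonized(g, [0.01] * 4, G, [0.05, 0.02, 0.03, 0.04])
        est = egger(h)
        assert est.beta == pytest.approx(0.4, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.02, abs=1e-10)

    def test_origin_constrained_fit_equals_ivw(self, random_harmonized):
        """Fitting the same weighted regression without the intercept is IVW."""
        h = random_harmonized
        w = 1.0 / h.se_capital_gamma**2
        slope = sm.WLS(h.capital_gamma, h.gamma[:, None], weights=w).fit().params[0]
        assert slope == pytest.approx(ivw(h).beta, abs=1e-9)

    def test_insufficient_instruments(self):
        h = make_harmonized([0.2, 0.3], [0.01] * 2, [0.1, 0.15], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_harmonized([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.5, 0.9], [1.0] * 3)
        assert weighted_median(h, n_boot=0).beta == pytest.approx(0.5)

    def test_interpolation_matches_brute_force_oracle(self, rng):
        """The interpolated weighted median agrees with an independent
        brute-force implementation of the midpoint-cumulative-weight rule."""
        from mrmediate.estimators import _weighted_median_arrays

        def brute_force(ratio, weight):
            order = np.argsort(ratio)
            r, w = np.asarray(ratio)[order], np.asarray(weight)[order]
            w = w / w.sum()
            # midpoint cumulative weight of item i: sum(w[:i]) + w[i]/2
            cum = np.cumsum(w) - w / 2
            if 0.5 <= cum[0]:
                return r[0]
            if 0.5 >= cum[-1]:
                return r[-1]
            i = np.searchsorted(cum, 0.5)
            frac = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
            return r[i - 1] + frac * (r[i] - r[i - 1])

        # hand case: ratios (0, 1), weights (0.25, 0.75) -> 0.75
        assert _weighted_median_arrays(np.array([0.0, 1.0]),
                                       np.array([0.25, 0.75])) == pytest.approx(0.75)
        assert brute_force([0.0, 1.0], [0.25, 0.75]) == pytest.approx(0.75)
        for _ in range(50):
            k = int(rng.integers(2, 12))
            ratio = rng.normal(0, 1, k)
            weight = rng.uniform(0.1, 2.0, k)
            assert _weighted_median_arrays(ratio, weight) == pytest.approx(
                brute_force(ratio, weight), abs=1e-12)

    def test_seeded_bootstrap_reproducible(self, random_harmonized):
        a = weighted_median(random_harmonized, n_boot=100, seed=42)
        b = weighted_median(random_harmonized, n_boot=100, seed=42)
        assert a.se == b.se
        c = weighted_median(random_harmonized, n_boot=100, seed=43)
        assert a.se != c.se


class TestModes:
    def test_dominant_cluster(self):
        h = make_harmonized([1.0] * 4, [0.01] * 4, [0.5, 0.5, 0.5, 3.0], [0.5] * 4)
        for weighted in (True, False):
            est = mode_estimate(h, weighted=weighted, n_boot=0)
            assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_weighting_degenerate_with_equal_weights(self):
        h = make_harmonized([1.0] * 5, [0.01] * 5, [0.2, 0.3, 0.35, 0.8, 0.9], [0.4] * 5)
        a = mode_estimate(h, weighted=True, n_boot=0)
        b = mode_estimate(h, weighted=False, n_boot=0)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_heavier_weighted_cluster_wins(self):
        # bimodal ratios: cluster at 0.2 carries far more inverse-variance weight
        gamma = np.array([1.0] * 3 + [1.0] * 3)
        G = np.array([0.2, 0.21, 0.19, 1.0, 1.01, 0.99])
        seG = np.array([0.05] * 3 + [0.5] * 3)
        h = make_harmonized(gamma, [0.01] * 6, G, seG)
        est = mode_estimate(h, weighted=True, n_boot=0)
        assert est.beta == pytest.approx(0.2, abs=0.05)


class TestSignSymmetry:
    """Flipping the outcome associations negates every estimate (SE unchanged);
    flipping both legs — pure allele relabelling — changes nothing."""

    def _flip(self, h, flip_gamma, flip_capital):
        df = h.df.copy()
        if flip_gamma:
            df["gamma"] = -df["gamma"]
        if flip_capital:
            df["capital_gamma"] = -df["capital_gamma"]
        return type(h)(exposure=h.exposure, outcome=h.outcome, df=df)

    @pytest.mark.parametrize("method,kwargs,se_rel", [
        (ivw, {}, 1e-9),
        (egger, {}, 1e-9),
        # bootstrap SEs match only to Monte-Carlo accuracy under the flip
        (weighted_median, {"n_boot": 400, "seed": 7}, 0.25),
        (mode_estimate, {"weighted": True, "n_boot": 400, "seed": 7}, 0.25),
        (mode_estimate, {"weighted": False, "n_boot": 400, "seed": 7}, 0.25),
    ])
    def test_outcome_flip_negates(self, random_harmonized, method, kwargs, se_rel):
        a = method(random_harmonized, **kwargs)
        b = method(self._flip(random_harmonized, False, True), **kwargs)
        assert b.beta == pytest.approx(-a.beta, abs=1e-9)
        assert b.se == pytest.approx(a.se, rel=se_rel)

    @pytest.mark.parametrize("method,kwargs", [
        (ivw, {}),
        (egger, {}),
        (weighted_median, {"n_boot": 0}),
        (mode_estimate, {"weighted": True, "n_boot": 0}),
    ])
    def test_joint_flip_invariant(self, random_harmonized, method, kwargs):
        a = method(random_harmonized, **kwargs)
        b = method(self._flip(random_harmonized, True, True), **kwargs)
        assert b.beta == pytest.approx(a.beta, abs=1e-9)


class TestBetaToOR:
    @pytest.mark.parametrize("beta,expected", [
        (0.103, 1.108),
        (0.087, 1.091),
        (-0.199, 0.820),
        (0.0, 1.0),
    ])
    def test_published_conversions(self, beta, expected):
        or_, _, _ = beta_to_or(beta, 0.01)
        assert round(or_, 3) == expected

    def test_ci_symmetric_on_log_scale(self):
        or_, lo, hi = beta_to_or(0.0, 0.5)
        assert lo * hi == pytest.approx(1.0)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            beta_to_or(0.1, -0.01)


def test_run_all_methods_returns_five(random_harmonized):
    out = run_all_methods(random_harmonized, n_boot=20, seed=1)
    assert set(out) == {"ivw", "egger", "weighted_median", "weighted_mode", "simple_mode"}
    assert all(np.isfinite(e.beta) for e in out.values())
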