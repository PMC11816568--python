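import numpy as np
import pytest

from mrchain import (
    HarmonizedSet,
    InsufficientInstruments,
    all_methods,
    egger,
    ivw,
    mode_estimate,
    simulate_summary_effects,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrchain.estimators import _weighted_median_point


def _hset(bx, by, sx=0.01, sy=0.01):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    return HarmonizedSet.from_arrays(
        bx, np.full_like(bx, sx), by, np.full_like(by, sy)
    )


def _wls_oracle(x, y, w, intercept):
    """Independent weighted-least-squares route: scaled design + lstsq."""
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.5, 0.01, 0.1, 0.02)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.02 / 0.5)

    def test_zero_outcome_effect(self):
        est = wald_ratio(0.5, 0.01, 0.0, 0.02)
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)

    def test_second_order_limit(self):
        first = wald_ratio(0.5, 0.0, 0.1, 0.02)
        second = wald_ratio(0.5, 1e-12, 0.1, 0.02, second_order=True)
        assert second.se == pytest.approx(first.se, rel=1e-9)
        # away from the limit the second-order se is strictly larger
        assert wald_ratio(0.5, 0.1, 0.1, 0.02, second_order=True).se > first.se


class TestIVW:
    def test_single_snp_equals_wald(self):
        h = _hset([0.5], [0.1], sy=0.02)
        assert ivw(h).beta == pytest.approx(wald_ratio(0.5, 0.01, 0.1, 0.02).beta)
        assert ivw(h, mode="fixed").se == pytest.approx(0.02 / 0.5)

    def test_closed_form_proportional_data(self):
        h = _hset([0.1, 0.2, 0.3], [0.02, 0.04, 0.06], sy=0.01)
        est = ivw(h)
        assert est.beta == pytest.approx(0.2)
        assert est.extra["q"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 21))
            bx = rng.normal(0.1, 0.05, n)
            by = rng.normal(0.02, 0.03, n)
            sy = rng.uniform(0.005, 0.05, n)
            h = HarmonizedSet.from_arrays(bx, np.full(n, 0.01), by, sy)
            beta = ivw(h, mode="fixed").beta
            (oracle,) = _wls_oracle(bx, by, 1.0 / sy**2, intercept=False)
            assert beta == pytest.approx(oracle, abs=1e-8)

    def test_equal_weights_reduce_to_ols_through_origin(self):
        rng = np.random.default_rng(1)
        bx, by = rng.normal(0.1, 0.05, 10), rng.normal(0.03, 0.02, 10)
        h = _hset(bx, by, sy=0.02)
        ols = float(bx @ by / (bx @ bx))
        assert ivw(h).beta == pytest.approx(ols, abs=1e-12)

    def test_random_effects_never_deflates(self):
        h = simulate_summary_effects(n_snp=30, beta_causal=0.2, pleiotropy_frac=1.0,
                                     pleiotropy_sd=0.1, seed=3)
        assert ivw(h, mode="multiplicative_random").se >= ivw(h, mode="fixed").se

    def test_no_snps_raises(self):
        with pytest.raises(InsufficientInstruments):
            ivw(_hset([], []))

    def test_recovers_truth_on_valid_instruments(self):
        h = simulate_summary_effects(n_snp=50, beta_causal=0.2, seed=4)
        est = ivw(h)
        assert abs(est.beta - 0.2) < 3 * est.se


class TestEgger:
    def test_exact_line(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = _hset(bx, 0.05 + 0.2 * bx, sy=0.01)
        est = egger(h)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.extra["intercept"] == pytest.approx(0.05, abs=1e-12)
        assert est.extra["q"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 21))
            bx = rng.uniform(0.02, 0.3, n)  # positive: orientation is a no-op
            by = rng.normal(0.01 + 0.2 * bx, 0.03)
            sy = rng.uniform(0.005, 0.05, n)
            h = HarmonizedSet.from_arrays(bx, np.full(n, 0.01), by, sy)
            est = egger(h)
            intercept, slope = _wls_oracle(bx, by, 1.0 / sy**2, intercept=True)
            assert est.beta == pytest.approx(slope, abs=1e-8)
            assert est.extra["intercept"] == pytest.approx(intercept, abs=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.3, 15)
        by = rng.normal(0.02 + 0.25 * bx, 0.02)
        sy = rng.uniform(0.01, 0.04, 15)
        h = HarmonizedSet.from_arrays(bx, np.full(15, 0.01), by, sy)
        est = egger(h)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(fit.params[0], abs=1e-10)

    def test_too_few_snps(self):
        with pytest.raises(InsufficientInstruments):
            egger(_hset([0.1, 0.2], [0.02, 0.04]))


class TestWeightedMedian:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = weighted_median(_hset(bx, 0.2 * bx), n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_interpolation_against_brute_force(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        est = weighted_median(_hset(bx, by), n_boot=10, seed=0)
        # equal weights 1/3: midpoint cumulative weights (1/6, 3/6, 5/6); 0.5
        # lands exactly on the middle order statistic
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_matches_independent_interpolation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            ratios = rng.normal(0.2, 0.3, n)
            weights = rng.uniform(0.1, 2.0, n)
            # brute-force oracle: walk the sorted ratios accumulating weight
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order] / weights.sum()
            cum = np.cumsum(w) - w / 2
            if 0.5 <= cum[0]:
                expected = r[0]
            elif 0.5 >= cum[-1]:
                expected = r[-1]
            else:
                k = int(np.searchsorted(cum, 0.5)) - 1
                frac = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
                expected = r[k] + frac * (r[k + 1] - r[k])
            assert _weighted_median_point(ratios, weights) == pytest.approx(
                expected, abs=1e-12
            )

    def test_bounded_by_ratio_range(self):
        h = simulate_summary_effects(n_snp=20, beta_causal=0.2, seed=6)
        bx, _, by, _ = h.arrays()
        est = weighted_median(h, n_boot=20, seed=1)
        assert (by / bx).min() <= est.beta <= (by / bx).max()

    def test_robust_to_invalid_instruments(self):
        # 30% of instruments carry big pleiotropy: the median should beat IVW
        # most of the time
        wins = 0
        reps = 200
        for r in range(reps):
            h = simulate_summary_effects(
                n_snp=50, beta_causal=0.2, pleiotropy_frac=0.3,
                pleiotropy_mean=0.1, pleiotropy_sd=0.02, seed=1000 + r,
            )
            wm = weighted_median(h, n_boot=2, seed=r).beta
            iv = ivw(h).beta
            wins += abs(wm - 0.2) < abs(iv - 0.2)
        assert wins / reps >= 0.8


class TestModes:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        est = mode_estimate(_hset(bx, 0.2 * bx), "simple", n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_majority_cluster_wins(self):
        ratios = np.array([0.2] * 7 + [0.8] * 3) + np.linspace(-0.005, 0.005, 10)
        bx = np.full(10, 0.2)
        est = mode_estimate(_hset(bx, ratios * bx), "simple", n_boot=20, seed=0)
        assert abs(est.beta - 0.2) < 0.1

    def test_weighted_variant_downweights_cluster(self):
        # the 0.8 cluster gets near-zero weight via huge outcome SEs
        bx = np.full(10, 0.2)
        ratios = np.array([0.2] * 5 + [0.8] * 5) + np.linspace(-0.005, 0.005, 10)
        sy = np.array([0.01] * 5 + [10.0] * 5)
        h = HarmonizedSet.from_arrays(bx, np.full(10, 0.01), ratios * bx, sy)
        est = mode_estimate(h, "weighted", n_boot=20, seed=0)
        assert abs(est.beta - 0.2) < 0.1

    def test_bounded_by_ratio_range(self):
        h = simulate_summary_effects(n_snp=20, beta_causal=0.2, seed=7)
        bx, _, by, _ = h.arrays()
        for variant in ("simple", "weighted"):
            est = mode_estimate(h, variant, n_boot=10, seed=2)
            r = by / bx
            # grid extends 3 bandwidths past the extremes; the mode of a
            # gaussian mixture still cannot escape the data range by more
            assert r.min() - 0.5 <= est.beta <= r.max() + 0.5


class TestOddsRatio:
    def test_printed_cholesterol_association(self):
        # log(1.334) = 0.2881; with se back-derived from the CI the
        # exponentiated interval reproduces (1.123, 1.584)
        or_value, or_low, or_high = to_odds_ratio(0.2881, 0.0876)
        assert or_value == pytest.approx(1.334, abs=2e-3)
        assert or_low == pytest.approx(1.123, abs=2e-3)
        assert or_high == pytest.approx(1.584, abs=2e-3)

    def test_null_beta(self):
        or_value, or_low, or_high = to_odds_ratio(0.0, 0.1)
        assert or_value == 1.0
        assert or_low * or_high == pytest.approx(1.0)

    def test_log_round_trip(self):
        rng = np.random.default_rng(8)
        for beta in rng.normal(0, 1, 20):
            or_value, _, _ = to_odds_ratio(beta, 0.1)
            assert np.log(or_value) == pytest.approx(beta, abs=1e-14)


class TestSignEquivariance:
    def test_negating_outcome_negates_estimates(self):
        h = simulate_summary_effects(n_snp=25, beta_causal=0.15, seed=9)
        bx, sx, by, sy = h.arrays()
        neg = HarmonizedSet.from_arrays(bx, sx, -by, sy)
        assert ivw(neg).beta == pytest.approx(-ivw(h).beta, abs=1e-12)
        assert ivw(neg).se == pytest.approx(ivw(h).se, abs=1e-12)
        assert egger(neg).beta == pytest.approx(-egger(h).beta, abs=1e-12)
        assert egger(neg).se == pytest.approx(egger(h).se, abs=1e-12)
        assert weighted_median(neg, n_boot=10, seed=3).beta == pytest.approx(
            -weighted_median(h, n_boot=10, seed=3).beta, abs=1e-12
        )
        assert mode_estimate(neg, "simple", n_boot=10, seed=3).beta == pytest.approx(
            -mode_estimate(h, "simple", n_boot=10, seed=3).beta, abs=1e-12
        )


class TestAllMethods:
    def test_five_methods_consistent_on_clean_data(self):
        h = simulate_summary_effects(n_snp=40, beta_causal=0.25, seed=10)
        ests = all_methods(h, n_boot=100, seed=0)
        assert set(ests) == {"ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"}
        for est in ests.values():
            assert abs(est.beta - 0.25) < 3 * est.se
            assert est.ci_low <= est.beta <= est.ci_high
            assert est.or_value == pytest.approx(np.exp(est.beta))
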