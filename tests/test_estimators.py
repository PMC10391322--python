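"""Causal estimators: worked examples, independent oracles, invariances."""

import numpy as np
import pytest
import statsmodels.api as sm

from cytomr import (
    EstimationError,
    HarmonisedSet,
    NotEstimable,
    cochran_q,
    ivw,
    leave_one_out,
    max_loo_deviation,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)

from conftest import random_pairs


def hs_from(bx, sx, by, sy):
    return HarmonisedSet.from_arrays(bx, sx, by, sy)


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)
        assert est.ci_low == pytest.approx(0.2 - 1.959963984540054 * 0.04, abs=1e-9)

    def test_null_numerator(self):
        est = wald_ratio(0.5, 0.05, 0.0, 0.02)
        assert est.beta == 0.0 and est.pvalue == pytest.approx(1.0)

    def test_zero_exposure_beta_is_error(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.05, 0.1, 0.02)

    def test_se_against_parametric_bootstrap(self):
        """First-order SE is accurate for a strong instrument (F >> 10)."""
        bx, sx, by, sy = 0.5, 0.02, 0.1, 0.02
        est = wald_ratio(bx, sx, by, sy)
        rng = np.random.default_rng(123)
        ratios = rng.normal(by, sy, 100_000) / rng.normal(bx, sx, 100_000)
        assert est.se == pytest.approx(np.std(ratios), rel=0.10)


def wls_oracle(bx, by, sy, intercept):
    """Independent weighted-least-squares fit via statsmodels."""
    X = sm.add_constant(bx) if intercept else bx[:, None]
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    se_unscaled = fit.bse / np.sqrt(fit.scale)
    return fit.params, se_unscaled, float(fit.ssr)


class TestIVW:
    def test_perfect_proportionality(self):
        hs = hs_from([0.5, 0.25], [0.05, 0.05], [0.1, 0.05], [0.02, 0.02])
        est = ivw(hs)
        assert est.beta == pytest.approx(0.2, abs=1e-15)
        assert est.q == pytest.approx(0.0, abs=1e-20)

    def test_single_pair_collapses_to_wald(self):
        hs = hs_from([0.5], [0.05], [0.1], [0.02])
        est = ivw(hs)
        ref = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.method == "wald_ratio"
        assert est.beta == ref.beta and est.se == ref.se

    def test_matches_wls_oracle(self, rng):
        for _ in range(20):
            hs = random_pairs(rng, int(rng.integers(3, 10)))
            est = ivw(hs, effects_model="fixed")
            params, se, _ = wls_oracle(hs.beta_exposure, hs.beta_outcome, hs.se_outcome, False)
            assert est.beta == pytest.approx(params[0], abs=1e-10)
            assert est.se == pytest.approx(se[0], abs=1e-10)

    def test_random_effects_inflate_se_only_under_heterogeneity(self):
        hs = hs_from([0.5, 0.25], [0.05, 0.05], [0.1, 0.05], [0.02, 0.02])
        assert ivw(hs, "multiplicative_random").se == ivw(hs, "fixed").se  # Q=0, phi=1
        het = hs_from([0.5, 0.25, 0.4], [0.01] * 3, [0.2, -0.1, 0.05], [0.02] * 3)
        assert ivw(het, "multiplicative_random").se > ivw(het, "fixed").se

    def test_all_zero_exposure_betas_error(self):
        hs = hs_from([0.0, 0.0], [0.1, 0.1], [0.1, 0.2], [0.02, 0.02])
        with pytest.raises(EstimationError):
            ivw(hs)


class TestMREgger:
    def test_exact_line(self):
        bx = np.array([0.2, 0.4, 0.6])
        by = 0.01 + 0.3 * bx
        est = mr_egger(hs_from(bx, [0.01] * 3, by, [0.02] * 3))
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.01, abs=1e-12)

    def test_zero_intercept_when_proportional(self):
        bx = np.array([0.2, 0.4, 0.6])
        est = mr_egger(hs_from(bx, [0.01] * 3, 0.25 * bx, [0.02] * 3))
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_wls_oracle(self, rng):
        for _ in range(20):
            hs = random_pairs(rng, int(rng.integers(3, 10)))
            est = mr_egger(hs)
            flip = np.sign(hs.beta_exposure)
            bx, by = hs.beta_exposure * flip, hs.beta_outcome * flip
            params, se_unscaled, rss = wls_oracle(bx, by, hs.se_outcome, True)
            scale = max(1.0, np.sqrt(rss / (len(bx) - 2)))
            assert est.egger_intercept == pytest.approx(params[0], abs=1e-10)
            assert est.beta == pytest.approx(params[1], abs=1e-10)
            assert est.se == pytest.approx(se_unscaled[1] * scale, abs=1e-10)
            assert est.egger_intercept_se == pytest.approx(se_unscaled[0] * scale, abs=1e-10)

    def test_constant_pleiotropy_offset_recovered_exactly(self):
        # noise-free directional pleiotropy: slope stays true, intercept = offset
        bx = np.array([0.1, 0.3, 0.5, 0.7])
        by = 0.05 + 0.2 * bx
        est = mr_egger(hs_from(bx, [0.01] * 4, by, [0.02] * 4))
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.05, abs=1e-12)

    def test_too_few_variants(self):
        with pytest.raises(NotEstimable):
            mr_egger(hs_from([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.01] * 2))


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        hs = hs_from([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        assert weighted_median_point(hs) == pytest.approx(0.2)

    def test_outlier_robustness(self):
        # outlier carries < 25% of the weight; estimate stays in the valid range
        hs = hs_from([1, 1, 1, 0.5], [0.01] * 4, [0.1, 0.2, 0.3, 5.0], [0.05] * 4)
        assert 0.1 <= weighted_median_point(hs) <= 0.3

    def test_interpolation_hand_value(self):
        # equal weights, ratios (0.1, 0.2, 0.4, 0.5): midpoints (.125,.375,.625,.875)
        # -> interpolate at 0.5 between 0.2 and 0.4 -> 0.3
        hs = hs_from([1, 1, 1, 1], [0.01] * 4, [0.1, 0.2, 0.4, 0.5], [0.05] * 4)
        assert weighted_median_point(hs) == pytest.approx(0.3, abs=1e-12)

    def test_bootstrap_se_is_seeded(self, rng):
        hs = random_pairs(rng, 6)
        a = weighted_median(hs, n_boot=200, seed=9)
        b = weighted_median(hs, n_boot=200, seed=9)
        c = weighted_median(hs, n_boot=200, seed=10)
        assert a.se == b.se and a.beta == c.beta and a.se != c.se

    def test_requires_seed_and_three_variants(self, rng):
        hs = random_pairs(rng, 6)
        with pytest.raises(ValueError):
            weighted_median(hs, seed=None)
        with pytest.raises(NotEstimable):
            weighted_median(random_pairs(rng, 2), seed=1)


class TestCochranQ:
    def test_homogeneous(self):
        hs = hs_from([0.5, 0.25], [0.05] * 2, [0.1, 0.05], [0.02] * 2)
        q, df, p = cochran_q(hs, 0.2)
        assert q == pytest.approx(0.0, abs=1e-20) and p == pytest.approx(1.0)

    def test_closed_form(self):
        # ratios 0 and 0.4, weights 25 each, reference 0.2 -> Q = 2, df = 1
        hs = hs_from([1.0, 1.0], [0.01] * 2, [0.0, 0.4], [0.2, 0.2])
        q, df, p = cochran_q(hs, 0.2)
        assert q == pytest.approx(2.0, abs=1e-12) and df == 1


class TestLeaveOneOut:
    def test_homogeneous_set_is_stable(self):
        bx = np.array([0.5, 0.25, 0.4])
        hs = hs_from(bx, [0.05] * 3, 0.2 * bx, [0.02] * 3)
        full = ivw(hs)
        res = leave_one_out(hs)
        assert len(res) == 3
        assert max_loo_deviation(full, res) == pytest.approx(0.0, abs=1e-12)

    def test_outlier_exclusion_moves_most(self):
        bx = np.array([0.5, 0.25, 0.4, 0.3])
        by = 0.2 * bx
        by[2] = 0.35  # gross outlier ratio
        hs = hs_from(bx, [0.05] * 4, by, [0.02] * 4)
        full = ivw(hs)
        res = leave_one_out(hs)
        deltas = {r.excluded_variant: abs(r.estimate.beta - full.beta) for r in res}
        assert max(deltas, key=deltas.get) == hs.variant_ids[2]

    def test_matches_manual_subsetting(self, rng):
        hs = random_pairs(rng, 6)
        for r in leave_one_out(hs):
            mask = hs.variant_ids != r.excluded_variant
            ref = ivw(hs.subset(mask))
            assert r.estimate.beta == pytest.approx(ref.beta, abs=1e-14)

    def test_too_few_variants(self, rng):
        with pytest.raises(NotEstimable):
            leave_one_out(random_pairs(rng, 2))


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_sign_equivariance(self, seed):
        """Negating all outcome betas negates every estimate, SEs unchanged."""
        hs = random_pairs(np.random.default_rng(seed), 7)
        neg = HarmonisedSet.from_arrays(
            hs.beta_exposure, hs.se_exposure, -hs.beta_outcome, hs.se_outcome
        )
        for fn in (lambda h: ivw(h), lambda h: mr_egger(h)):
            a, b = fn(hs), fn(neg)
            assert b.beta == pytest.approx(-a.beta, abs=1e-12)
            assert b.se == pytest.approx(a.se, rel=1e-9)
        assert weighted_median_point(neg) == pytest.approx(
            -weighted_median_point(hs), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_exposure_orientation_invariance(self, seed):
        """Jointly flipping (bx, by) of any subset leaves estimates unchanged."""
        rng = np.random.default_rng(seed)
        hs = random_pairs(rng, 7)
        flip = rng.choice([-1.0, 1.0], size=7)
        flipped = HarmonisedSet.from_arrays(
            hs.beta_exposure * flip, hs.se_exposure, hs.beta_outcome * flip, hs.se_outcome
        )
        assert ivw(flipped).beta == pytest.approx(ivw(hs).beta, abs=1e-12)
        assert mr_egger(flipped).beta == pytest.approx(mr_egger(hs).beta, abs=1e-12)
        assert weighted_median_point(flipped) == pytest.approx(weighted_median_point(hs), abs=1e-12)
        q1, _, _ = cochran_q(hs, 0.1)
        q2, _, _ = cochran_q(flipped, 0.1)
        assert q1 == pytest.approx(q2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_outcome_scale_equivariance(self, seed):
        c = 3.7
        hs = random_pairs(np.random.default_rng(seed), 6)
        scaled = HarmonisedSet.from_arrays(
            hs.beta_exposure, hs.se_exposure, c * hs.beta_outcome, c * hs.se_outcome
        )
        for fn in (lambda h: ivw(h), lambda h: mr_egger(h)):
            a, b = fn(hs), fn(scaled)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-9)
            assert b.se == pytest.approx(c * a.se, rel=1e-9)

    def test_weighted_median_breakdown(self):
        """Bounded by valid ratios below 50% invalid weight, not above."""
        bx = np.ones(10)
        sy = np.full(10, 0.05)
        by = np.full(10, 0.2)
        shifted = by.copy()
        shifted[:4] += 1.0  # 40% invalid weight
        hs40 = hs_from(bx, [0.01] * 10, shifted, sy)
        assert weighted_median_point(hs40) == pytest.approx(0.2)
        shifted6 = by.copy()
        shifted6[:6] += 1.0  # 60% invalid weight
        hs60 = hs_from(bx, [0.01] * 10, shifted6, sy)
        assert weighted_median_point(hs60) > 0.2 + 0.5
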