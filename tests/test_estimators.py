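import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from cytomr.estimators import (
    IVWEstimator,
    MREggerEstimator,
    WeightedMedianEstimator,
    ivw,
    mr_egger,
    wald_ratio,
    wald_ratios,
    weighted_median,
    weighted_median_point,
)
from cytomr.exceptions import DegenerateInstrumentError, InsufficientInstrumentsError
from cytomr.simulate import exact_line_instruments

from conftest import make_instruments


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        inst = {"snp_id": "rs1", "beta_exp": 0.10, "beta_out": 0.05,
                "se_exp": 0.01, "se_out": 0.02}
        r = wald_ratio(inst)
        assert r.ratio == pytest.approx(0.5)
        assert r.se_ratio == pytest.approx(0.2)
        assert r.weight == pytest.approx(0.2**-2)

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio({"snp_id": "rs1", "beta_exp": 0.0, "beta_out": 0.1,
                        "se_out": 0.01})


class TestIVW:
    def test_homogeneous_ratios_fixed_equals_random(self):
        inst = make_instruments([0.1, 0.2, 0.4], 0.01,
                                [0.05, 0.10, 0.20], [0.01, 0.03, 0.02])
        fe = ivw(inst, mode="fixed")
        re = ivw(inst, mode="multiplicative_random")
        assert fe.beta == pytest.approx(0.5)
        assert re.extra["q"] == pytest.approx(0.0, abs=1e-20)
        assert re.extra["phi"] == 1.0
        assert re.se == fe.se

    def test_matches_brute_force_weighted_mean(self):
        ratios = np.array([0.2, 0.4, 0.9])
        se_ratio = np.array([0.1, 0.1, 0.2])
        bx = np.array([0.2, 0.25, 0.3])
        inst = make_instruments(bx, 0.01, ratios * bx, se_ratio * bx)
        est = ivw(inst, mode="fixed")
        w = se_ratio**-2.0
        expected_beta = sum(w * ratios) / sum(w)
        assert est.beta == pytest.approx(expected_beta, abs=1e-12)
        assert est.se == pytest.approx(sum(w) ** -0.5, abs=1e-12)

    def test_equals_zero_intercept_wls_route(self, random_instruments):
        """Ratio-form IVW and zero-intercept WLS of beta_out on beta_exp
        (weights 1/se_out^2) are algebraically identical."""
        est = ivw(random_instruments, mode="fixed")
        x = random_instruments["beta_exp"].to_numpy()
        y = random_instruments["beta_out"].to_numpy()
        w = random_instruments["se_out"].to_numpy() ** -2.0
        slope = (w * x * y).sum() / (w * x * x).sum()
        assert est.beta == pytest.approx(slope, abs=1e-12)

    def test_single_instrument_insufficient(self):
        inst = make_instruments([0.1], 0.01, [0.05], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            ivw(inst)

    def test_random_effects_never_tighter_than_fixed(self, rng):
        for _ in range(10):
            bx = rng.uniform(0.1, 0.3, 8)
            inst = make_instruments(bx, 0.01, rng.normal(0, 0.05, 8),
                                    rng.uniform(0.005, 0.03, 8))
            assert ivw(inst).se >= ivw(inst, mode="fixed").se


class TestMREgger:
    def test_exact_line_recovered(self):
        est = mr_egger(exact_line_instruments(intercept=0.02, slope=0.4))
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.extra["intercept"] == pytest.approx(0.02, abs=1e-12)
        assert est.extra["sigma2"] == 1.0  # zero residual clamps at 1

    def test_matches_statsmodels_wls(self, rng):
        """Slope, intercept and (inflated) SEs against an independent WLS."""
        bx = rng.uniform(0.1, 0.4, 5)
        by = 0.02 + 0.3 * bx + rng.normal(0, 0.05, 5)
        se_out = rng.uniform(0.02, 0.08, 5)
        inst = make_instruments(bx, 0.01, by, se_out)
        est = MREggerEstimator().fit(inst)
        w = se_out**-2.0
        fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        # statsmodels scales the covariance by RSS/(J-2) without the clamp;
        # apply the same inflation definition for comparison
        resid = by - fit.params[0] - fit.params[1] * bx
        sigma2 = max(1.0, (w * resid**2).sum() / 3)
        cov = np.linalg.inv((sm.add_constant(bx) * w[:, None]).T @ sm.add_constant(bx))
        assert est.beta_ == pytest.approx(fit.params[1], abs=1e-10)
        assert est.intercept_ == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se_ == pytest.approx(math.sqrt(sigma2 * cov[1, 1]), abs=1e-10)
        assert est.intercept_se_ == pytest.approx(
            math.sqrt(sigma2 * cov[0, 0]), abs=1e-10
        )

    def test_orientation_invariance(self, random_instruments):
        est1 = mr_egger(random_instruments)
        flipped = random_instruments.copy()
        flipped.loc[0, "beta_exp"] *= -1
        flipped.loc[0, "beta_out"] *= -1
        est2 = mr_egger(flipped)
        assert est1.beta == pytest.approx(est2.beta, abs=1e-14)
        assert est1.extra["intercept"] == pytest.approx(
            est2.extra["intercept"], abs=1e-14
        )

    def test_two_instruments_insufficient(self):
        inst = make_instruments([0.1, 0.2], 0.01, [0.05, 0.1], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(inst)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        assert weighted_median_point(
            np.array([0.1, 0.2, 0.3]), np.array([1.0, 1.0, 1.0])
        ) == pytest.approx(0.2)

    def test_hand_interpolation_oracle(self):
        # weights (1,1,2)/4 over sorted ratios (0.1,0.2,0.4):
        # p = (0.125, 0.375, 0.75); 0.5 lies between p2 and p3:
        # 0.2 + (0.5-0.375)/(0.75-0.375) * (0.4-0.2) = 0.2 + 0.2/3
        est = weighted_median_point(
            np.array([0.1, 0.2, 0.4]), np.array([1.0, 1.0, 2.0])
        )
        assert est == pytest.approx(0.2 + 0.2 / 3, abs=1e-12)

    def test_bootstrap_se_deterministic_under_seed(self, random_instruments):
        a = weighted_median(random_instruments, n_boot=200, seed=42)
        b = weighted_median(random_instruments, n_boot=200, seed=42)
        assert a.se == b.se and a.beta == b.beta

    def test_two_instruments_insufficient(self):
        inst = make_instruments([0.1, 0.2], 0.01, [0.05, 0.1], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(inst)


class TestSharedInvariants:
    def test_scale_equivariance(self, random_instruments):
        c = 3.7
        scaled = random_instruments.copy()
        scaled["beta_out"] *= c
        scaled["se_out"] *= c
        for fit, fit_scaled in [
            (ivw(random_instruments), ivw(scaled)),
            (mr_egger(random_instruments), mr_egger(scaled)),
            (
                weighted_median(random_instruments, n_boot=0),
                weighted_median(scaled, n_boot=0),
            ),
        ]:
            assert fit_scaled.beta == pytest.approx(c * fit.beta, rel=1e-10)
            if not math.isnan(fit.se):
                assert fit_scaled.se == pytest.approx(c * fit.se, rel=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.permutations(list(range(5))))
    def test_permutation_invariance(self, perm):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.3, 5)
        inst = make_instruments(bx, 0.01, 0.1 * bx + rng.normal(0, 0.02, 5),
                                rng.uniform(0.01, 0.03, 5))
        shuffled = inst.iloc[list(perm)].reset_index(drop=True)
        assert ivw(inst).beta == pytest.approx(ivw(shuffled).beta, abs=1e-14)
        assert mr_egger(inst).beta == pytest.approx(
            mr_egger(shuffled).beta, abs=1e-14
        )
        assert weighted_median(inst, n_boot=0).beta == pytest.approx(
            weighted_median(shuffled, n_boot=0).beta, abs=1e-14
        )

    def test_sklearn_protocol(self):
        est = IVWEstimator(mode="fixed")
        assert est.get_params() == {"mode": "fixed"}
        est.set_params(mode="multiplicative_random")
        inst = make_instruments([0.1, 0.2, 0.3], 0.01,
                                [0.05, 0.1, 0.15], 0.01)
        assert est.fit(inst).beta_ == pytest.approx(0.5)
        wm = WeightedMedianEstimator(n_boot=10, random_state=1)
        assert wm.get_params()["n_boot"] == 10
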