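import numpy as np
import pytest
from scipy import stats

from cytomr.estimators import wald_ratios, ivw
from cytomr.exceptions import CytomrError, InsufficientInstrumentsError
from cytomr.sensitivity import (
    cochran_q,
    f_statistic,
    leave_one_out,
    mr_power,
    per_snp_diagnostics,
    sensitivity_report,
    variance_explained,
)

from conftest import make_instruments


class TestVarianceExplained:
    def test_zero_effect_zero_r2(self):
        assert variance_explained(0.0, 0.01, 0.3, 5000) == 0.0

    def test_matches_independent_transcription(self, rng):
        """Against a literal re-transcription of the printed R2 formula."""
        for _ in range(100):
            beta = rng.normal(0, 0.3)
            se = rng.uniform(1e-3, 0.1)
            eaf = rng.uniform(0.01, 0.99)
            n = int(rng.integers(100, 500_000))
            num = 2.0 * beta**2 * eaf * (1.0 - eaf)
            den = num + 2.0 * se**2 * n * eaf * (1.0 - eaf)
            assert variance_explained(beta, se, eaf, n) == pytest.approx(
                num / den, abs=1e-12
            )

    def test_symmetric_in_allele_frequency(self):
        a = variance_explained(0.1, 0.01, 0.3, 5000)
        b = variance_explained(0.1, 0.01, 0.7, 5000)
        assert a == pytest.approx(b, rel=1e-14)

    def test_monotone_in_effect_size(self):
        r2s = [variance_explained(b, 0.01, 0.3, 5000) for b in (0.05, 0.1, 0.2)]
        assert r2s[0] < r2s[1] < r2s[2]


class TestFStatistic:
    def test_half_r2_n_102_gives_100(self):
        assert f_statistic(0.5, 102) == pytest.approx(100.0)

    def test_zero_r2_zero_f(self):
        assert f_statistic(0.0, 100) == 0.0

    def test_cohort_scale_value(self):
        # exposure-cohort size 8293; oracle = direct substitution
        assert f_statistic(0.01, 8293) == pytest.approx(0.01 * 8291 / 0.99)

    def test_domain_errors(self):
        with pytest.raises(CytomrError):
            f_statistic(1.0, 100)
        with pytest.raises(CytomrError):
            f_statistic(0.1, 2)

    def test_f_increases_with_effect_at_fixed_se(self):
        f = [
            f_statistic(variance_explained(b, 0.01, 0.3, 5000), 5000)
            for b in (0.05, 0.1, 0.2, 0.4)
        ]
        assert all(x < y for x, y in zip(f, f[1:]))


class TestCochranQ:
    def test_identical_ratios_zero_q(self):
        inst = make_instruments([0.1, 0.2], 0.01, [0.05, 0.1], 0.01)
        ratios = wald_ratios(inst)
        q, df, p = cochran_q(ratios, 0.5)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        # ratios {0.1, 0.3}, weights {100, 100}, beta 0.2:
        # Q = 100*(0.1-0.2)^2 + 100*(0.3-0.2)^2 = 2
        import pandas as pd

        ratios = pd.DataFrame(
            {"snp_id": ["a", "b"], "ratio": [0.1, 0.3],
             "se_ratio": [0.1, 0.1], "weight": [100.0, 100.0]}
        )
        q, df, p = cochran_q(ratios, 0.2)
        assert q == pytest.approx(2.0)
        assert p == pytest.approx(float(stats.chi2.sf(2.0, 1)))

    def test_permutation_invariant(self, random_instruments):
        ratios = wald_ratios(random_instruments)
        q1, *_ = cochran_q(ratios, 0.1)
        q2, *_ = cochran_q(ratios.iloc[::-1].reset_index(drop=True), 0.1)
        assert q1 == pytest.approx(q2, rel=1e-14)


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        assert mr_power(10000, 0.02, 0.0) == pytest.approx(0.05, abs=1e-12)

    def test_monotone_in_n_r2_beta(self):
        base = mr_power(10000, 0.02, 0.1)
        assert mr_power(40000, 0.02, 0.1) > base
        assert mr_power(10000, 0.08, 0.1) > base
        assert mr_power(10000, 0.02, 0.2) > base
        assert mr_power(10**8, 0.02, 0.1) > 0.9999

    def test_matches_monte_carlo_rejection_rate(self, rng):
        """Continuous outcome: analytic power vs simulated z-test at the
        same non-centrality, 1e5 draws."""
        n, r2, beta = 10000, 0.02, 0.1
        analytic = mr_power(n, r2, beta)
        nu = abs(beta) * np.sqrt(n * r2)
        z = rng.normal(nu, 1.0, 100_000)
        empirical = float(np.mean(np.abs(z) > stats.norm.ppf(0.975)))
        assert analytic == pytest.approx(empirical, abs=0.01)

    def test_binary_needs_case_fraction(self):
        with pytest.raises(CytomrError):
            mr_power(10000, 0.02, 0.1, trait_type="binary")
        p = mr_power(10000, 0.02, 0.3, trait_type="binary", case_fraction=0.2)
        assert 0.05 < p < 1.0


class TestLeaveOneOut:
    def test_identical_ratios_all_equal_full(self):
        bx = np.array([0.1, 0.2, 0.4])
        inst = make_instruments(bx, 0.01, 0.5 * bx, 0.01)
        loo = leave_one_out(inst)
        assert len(loo) == 3
        assert np.allclose(loo["beta"], 0.5)
        assert not loo["sign_change"].any()

    def test_planted_outlier_shifts_only_its_drop(self):
        bx = np.full(6, 0.2)
        by = np.full(6, 0.02)
        by[3] = 0.2  # one wildly discordant ratio
        inst = make_instruments(bx, 0.01, by, 0.01)
        loo = leave_one_out(inst)
        drop_out = loo.loc[loo["snp_id"] == "rs3", "beta"].iloc[0]
        others = loo.loc[loo["snp_id"] != "rs3", "beta"]
        assert drop_out == pytest.approx(0.1)  # clean ratio restored
        assert (others > 0.2).all()  # outlier still inside

    def test_insufficient(self):
        inst = make_instruments([0.1, 0.2], 0.01, [0.05, 0.1], 0.01)
        with pytest.raises(InsufficientInstrumentsError):
            leave_one_out(inst)


class TestPerSnpDiagnostics:
    def test_forest_ci_and_funnel_precision(self):
        inst = make_instruments([0.1], 0.01, [0.05], 0.02)
        table = per_snp_diagnostics(inst)
        assert table.loc[0, "ratio"] == pytest.approx(0.5)
        assert table.loc[0, "ci_low"] == pytest.approx(0.5 - 1.96 * 0.2)
        assert table.loc[0, "ci_high"] == pytest.approx(0.5 + 1.96 * 0.2)
        assert table.loc[0, "precision"] == pytest.approx(5.0)

    def test_empty_input_empty_table(self):
        import pandas as pd

        empty = make_instruments([], [], [], [])
        assert len(per_snp_diagnostics(empty)) == 0


class TestReport:
    def test_bundle_fields_consistent(self, random_instruments):
        rep = sensitivity_report(random_instruments)
        assert len(rep.per_snp_r2) == len(random_instruments)
        assert rep.q_df == len(random_instruments) - 1
        assert rep.min_f <= rep.mean_f
        assert 0.0 <= rep.power <= 1.0
        assert len(rep.leave_one_out) == len(random_instruments)
        d = rep.to_dict()
        assert set(d) >= {"q", "power", "egger_intercept"}

    def test_q_decomposition_against_enumeration(self):
        """Full-set Q equals the weighted dispersion summed SNP by SNP
        around the fixed-effect estimate (direct enumeration, J=5)."""
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.1, 0.3, 5)
        inst = make_instruments(bx, 0.01, 0.1 * bx + rng.normal(0, 0.02, 5),
                                rng.uniform(0.01, 0.03, 5))
        ratios = wald_ratios(inst)
        beta_fe = ivw(inst, mode="fixed").beta
        q, _, _ = cochran_q(ratios, beta_fe)
        manual = sum(
            w * (r - beta_fe) ** 2
            for r, w in zip(ratios["ratio"], ratios["weight"])
        )
        assert q == pytest.approx(manual, rel=1e-12)
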