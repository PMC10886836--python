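"""Repeated-measures statistics, paired tests, power inversions."""

import numpy as np
import pingouin as pg
import pytest
from scipy import stats as sps

from mstate import (ConfigurationError, InvalidInputError,
                    UndefinedResultError, bonferroni_posthoc, friedman,
                    gate_bands, omnibus_repeated_measures, paired_test,
                    power_paired_t, power_rm_anova, required_n_paired_t,
                    required_n_rm_anova, rm_anova_oneway)
from oracles import anova_rm_brute_force, friedman_exact_p


class TestRmAnova:
    def test_identical_conditions_give_f_zero(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova_oneway(x)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_gg_epsilon_bounds_m3(self, rng):
        for _ in range(10):
            x = rng.standard_normal((8, 3))
            res = rm_anova_oneway(x)
            assert 0.5 - 1e-9 <= res.extra["epsilon_gg"] <= 1.0 + 1e-9

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal((6, 3)) + rng.standard_normal(3)
            res = rm_anova_oneway(x)
            f_oracle, df_oracle, p_oracle = anova_rm_brute_force(x)
            assert res.statistic == pytest.approx(f_oracle, abs=1e-8)
            assert res.extra["df_uncorrected"] == df_oracle
            assert res.extra["p_uncorrected"] == pytest.approx(p_oracle, abs=1e-8)

    def test_matches_pingouin(self, rng):
        import pandas as pd

        x = rng.standard_normal((10, 3)) + np.array([0.0, 0.3, 0.6])
        long = pd.DataFrame({
            "y": x.ravel(),
            "cond": np.tile(np.arange(3), 10),
            "subj": np.repeat(np.arange(10), 3),
        })
        res = rm_anova_oneway(x)
        pg_res = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert res.statistic == pytest.approx(float(pg_res["F"][0]), abs=1e-8)

    def test_permutation_p_agrees(self, rng):
        # condition-label permutations within subjects give a reference p
        x = rng.standard_normal((6, 3)) + np.array([0.0, 0.5, 1.0])
        res = rm_anova_oneway(x)
        f_obs = res.statistic
        count = 0
        reps = 2000
        prng = np.random.default_rng(0)
        for _ in range(reps):
            xp = np.array([row[prng.permutation(3)] for row in x])
            count += anova_rm_brute_force(xp)[0] >= f_obs - 1e-12
        p_perm = count / reps
        se = np.sqrt(p_perm * (1 - p_perm) / reps) + 1e-3
        assert abs(res.extra["p_uncorrected"] - p_perm) < max(4 * se, 0.02)

    def test_f_equals_t_squared_for_two_conditions(self, rng):
        x = rng.standard_normal((12, 2)) + np.array([0.0, 0.4])
        res = rm_anova_oneway(x)
        t = paired_test(x[:, 0], x[:, 1], mode="t")
        assert res.statistic == pytest.approx(t.statistic**2, abs=1e-8)
        assert res.p_value == pytest.approx(t.p_value, abs=1e-8)

    def test_correction_rule_dispatch(self):
        # strongly non-spherical data: correction applied, GG vs HF by the
        # 0.75 threshold on the GG epsilon
        rng = np.random.default_rng(4)
        base = rng.standard_normal(40)
        x = np.column_stack([base + rng.standard_normal(40) * 0.01,
                             base + rng.standard_normal(40) * 0.01,
                             rng.standard_normal(40) * 5])
        res = rm_anova_oneway(x)
        if res.extra["mauchly_p"] < 0.05:
            expected = "HF" if res.extra["epsilon_gg"] > 0.75 else "GG"
            assert res.correction == expected
            df1, df2 = res.df
            assert df1 <= x.shape[1] - 1 + 1e-9

    def test_missing_cells_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            rm_anova_oneway(x)


class TestFriedman:
    def test_perfect_concordance_closed_form(self):
        # every subject ranks conditions identically: chi2 = n(m-1) = 2n
        n = 20
        x = np.tile([1.0, 2.0, 3.0], (n, 1)) + np.random.default_rng(0).normal(
            0, 0.01, size=(n, 3))
        x = np.tile([1.0, 2.0, 3.0], (n, 1))
        res = friedman(x)
        assert res.statistic == pytest.approx(2 * n, abs=1e-9)

    def test_equal_values_zero_statistic(self):
        res = friedman(np.ones((6, 3)))
        assert res.statistic == 0.0

    def test_exact_p_matches_enumeration_oracle(self, rng):
        x = rng.standard_normal((5, 3))
        res = friedman(x, method="exact")
        assert res.p_value == pytest.approx(friedman_exact_p(x), abs=1e-12)

    def test_approx_matches_scipy(self, rng):
        x = rng.standard_normal((10, 4))
        res = friedman(x)
        chi2, p = sps.friedmanchisquare(*(x[:, j] for j in range(4)))
        assert res.statistic == pytest.approx(chi2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


class TestPairedTest:
    def test_identical_samples_t_branch(self):
        x = np.arange(5.0)
        res = paired_test(x, x, mode="t")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_identical_samples_wilcoxon_undefined(self):
        x = np.arange(5.0)
        with pytest.raises(UndefinedResultError):
            paired_test(x, x, mode="wilcoxon")

    def test_constant_nonzero_differences_undefined(self):
        x = np.arange(5.0)
        with pytest.raises(UndefinedResultError):
            paired_test(x + 1.0, x, mode="t")

    def test_hand_computed_t_and_dz(self):
        y = np.zeros(3)
        x = np.array([1.0, 2.0, 3.0])
        res = paired_test(x, y, mode="t")
        assert res.effect_size == pytest.approx(2.0, abs=1e-12)
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res.df == 2

    def test_wilcoxon_exact_all_positive_n6(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = paired_test(x, np.zeros(6), mode="wilcoxon")
        assert res.p_value == pytest.approx(2 / 2**6, abs=1e-12)
        assert res.effect_size == pytest.approx(1.0)  # all ranks positive

    def test_auto_dispatch_normality(self, rng):
        x = rng.standard_normal(30)
        res = paired_test(x + 0.2, x - rng.standard_normal(30) * 0.5, mode="auto")
        assert res.test_name in ("paired_t", "wilcoxon")
        heavy = sps.cauchy.rvs(size=50, random_state=7)
        res2 = paired_test(heavy, np.zeros(50), mode="auto")
        assert res2.test_name == "wilcoxon"

    def test_type_one_error_calibration(self):
        # paired-t branch on null Gaussian data rejects at ~alpha
        rng = np.random.default_rng(99)
        n, reps, alpha = 10, 100_000, 0.05
        x = rng.standard_normal((reps, n))
        # vectorized identical computation cross-checked against paired_test
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        crit = sps.t.ppf(1 - alpha / 2, n - 1)
        rate = np.mean(np.abs(t) > crit)
        assert 0.045 <= rate <= 0.055
        # the vectorized statistic equals paired_test's on sampled rows
        for i in range(0, reps, reps // 7):
            res = paired_test(x[i], np.zeros(n), mode="t")
            assert res.statistic == pytest.approx(t[i], abs=1e-10)


class TestBonferroni:
    def test_three_conditions_three_pairs(self, rng):
        x = rng.standard_normal((8, 3))
        out = bonferroni_posthoc(x, ("neg", "neu", "pos"), mode="t")
        assert len(out) == 3
        for res in out:
            assert res.correction == "Bonferroni"
            assert res.p_value == pytest.approx(
                min(1.0, res.extra["p_raw"] * 3), abs=1e-12)

    def test_clipping_at_one(self, rng):
        x = rng.standard_normal((8, 3))
        out = bonferroni_posthoc(x, mode="t")
        raw = [r.extra["p_raw"] for r in out]
        if max(raw) > 1 / 3:
            assert max(r.p_value for r in out) == 1.0


class TestPower:
    def test_paired_t_group_size_medium_effect(self):
        assert required_n_paired_t(0.5, 0.05, 0.8, two_sided=True) == 34

    def test_rm_anova_group_size_medium_effect(self):
        assert required_n_rm_anova(0.25, 0.05, 0.8, m=3, rho=0.5, eps=1.0) == 28

    def test_required_n_monotone_in_effect_size(self):
        ns = [required_n_paired_t(d) for d in (0.2, 0.4, 0.6, 0.8)]
        assert ns == sorted(ns, reverse=True)

    def test_required_n_monotone_in_rho(self):
        ns = [required_n_rm_anova(0.25, rho=r) for r in (0.3, 0.5, 0.7)]
        assert ns == sorted(ns, reverse=True)

    @pytest.mark.parametrize("d", [0.3, 0.5, 0.8])
    def test_exact_inversion_paired_t(self, d):
        n = required_n_paired_t(d)
        assert power_paired_t(n, d) >= 0.8
        assert power_paired_t(n - 1, d) < 0.8

    @pytest.mark.parametrize("f", [0.2, 0.25, 0.4])
    def test_exact_inversion_rm_anova(self, f):
        n = required_n_rm_anova(f)
        assert power_rm_anova(n, f, 3) >= 0.8
        assert power_rm_anova(n - 1, f, 3) < 0.8

    def test_monte_carlo_power_at_returned_n(self):
        # simulated paired samples at d = 0.5: empirical power near 0.8
        n = required_n_paired_t(0.5)
        rng = np.random.default_rng(5)
        reps = 100_000
        x = rng.standard_normal((reps, n)) + 0.5
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        crit = sps.t.ppf(0.975, n - 1)
        power = np.mean(np.abs(t) > crit)
        assert 0.79 <= power <= 0.83

    def test_monte_carlo_power_rm_anova(self):
        # compound-symmetric data at f = 0.25, rho = 0.5: power near 0.8
        n = required_n_rm_anova(0.25)
        m, rho, sigma = 3, 0.5, 1.0
        # between-condition means with effect size f: sd of means = f*sigma
        offsets = np.array([-1.0, 0.0, 1.0])
        offsets *= 0.25 / np.sqrt(np.mean(offsets**2))
        rng = np.random.default_rng(11)
        reps = 10_000
        rejections = 0
        subj = rng.standard_normal((reps, n, 1)) * np.sqrt(rho)
        eps = rng.standard_normal((reps, n, m)) * np.sqrt(1 - rho)
        x = subj + eps + offsets[None, None, :]
        for r in range(reps):
            f_val, _, p = anova_rm_brute_force(x[r])
            rejections += p < 0.05
        assert 0.76 <= rejections / reps <= 0.84


class TestGateBands:
    def test_seventy_percent_pattern(self):
        included, report = gate_bands(
            {"theta": 0.77, "alpha": 0.76, "beta": 0.62, "gamma": 0.55})
        assert included == ["theta", "alpha"]
        assert report["excluded"] == ["beta", "gamma"]

    def test_all_retained(self):
        included, _ = gate_bands({"theta": 0.9, "alpha": 0.8})
        assert included == ["theta", "alpha"]

    def test_boundary_retained(self):
        included, _ = gate_bands({"theta": 0.70})
        assert included == ["theta"]


class TestOmnibusGate:
    def test_normal_data_uses_anova(self, rng):
        x = rng.standard_normal((15, 3))
        res = omnibus_repeated_measures(x)
        assert res.test_name == "rm_anova_oneway"

    def test_heavy_tailed_data_uses_friedman(self):
        x = sps.cauchy.rvs(size=(15, 3), random_state=3)
        res = omnibus_repeated_measures(x)
        assert res.test_name == "friedman"


class TestValidation:
    @pytest.mark.parametrize("call", [
        lambda: required_n_paired_t(-0.5),
        lambda: required_n_rm_anova(0.25, rho=1.0),
        lambda: required_n_rm_anova(0.25, m=1),
        lambda: paired_test([1.0, 2.0], [1.0, 2.0]),
    ])
    def test_bad_inputs_rejected(self, call):
        with pytest.raises((ConfigurationError, InvalidInputError)):
            call()
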