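"""Cohort statistics: summaries, rank tests, permutation dispersion, survivor fit."""

import numpy as np
import pytest

from rdnacn.cohort_stats import (
    bin_dispersion_profile,
    cohort_report,
    describe,
    dispersion_permutation_test,
    fit_survivor_model,
    ks_test,
    mann_whitney,
    regression_cn_age,
)
from rdnacn.cohort_synth import CohortConfig, generate_cohort


def _pair_sample(mean, sd, n=100):
    """n values with exactly the requested mean and ddof=1 SD (paired offsets)."""
    d = sd / np.sqrt(n / (n - 1) * 2 * (n // 2) / n)
    base = np.array([mean - d, mean + d] * (n // 2))
    return base


class TestDescribe:
    def test_exact_moments_of_constructed_sample(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = describe(x)
        assert s.n == 5
        assert s.mean == 3.0
        assert s.median == 3.0
        assert s.sd == pytest.approx(np.sqrt(2.5))
        assert s.min == 1.0 and s.max == 5.0

    def test_published_cv_values_follow_from_moments(self):
        # CV = SD/mean: 110/419 -> 0.26, 63/396 -> 0.16
        x = _pair_sample(419.0, 110.0)
        assert describe(x).rounded_cv() == 0.26
        y = _pair_sample(396.0, 63.0)
        assert describe(y).rounded_cv() == 0.16

    def test_degenerate_sample_flagged(self):
        s = describe(np.full(10, 400.0))
        assert s.degenerate and s.cv == 0.0

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            describe(np.array([1.0]))


class TestRankTests:
    def test_mann_whitney_exact_small_sample(self):
        # fully separated samples of 3 and 3: U = 0 or 9, p = 0.1 exactly
        r = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert r.p_value == pytest.approx(0.1)

    def test_identical_samples_not_significant(self):
        x = np.arange(50, dtype=float)
        assert mann_whitney(x, x).p_value == pytest.approx(1.0, abs=0.01)
        assert ks_test(x, x).p_value == pytest.approx(1.0)

    def test_disjoint_samples_rejected_by_ks(self):
        x = np.linspace(0, 1, 60)
        y = np.linspace(10, 11, 60)
        r = ks_test(x, y)
        assert r.statistic == 1.0 and r.p_value < 1e-10

    def test_type_i_error_calibrated(self, rng):
        # both tests should reject ~5% of null datasets at alpha = 0.05
        for test in (mann_whitney, ks_test):
            rejections = sum(
                test(rng.normal(size=40), rng.normal(size=40)).p_value < 0.05
                for _ in range(400)
            )
            assert 4 <= rejections <= 40  # binomial(400, .05): central range

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
        with pytest.raises(ValueError):
            ks_test([1.0], [])


class TestDispersionPermutation:
    def test_seeded_result_reproducible(self, rng):
        x, y = rng.normal(0, 2, 40), rng.normal(0, 1, 40)
        a = dispersion_permutation_test(x + 10, y + 10, n_perm=999, seed=5)
        b = dispersion_permutation_test(x + 10, y + 10, n_perm=999, seed=5)
        assert a == b

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(120):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(400, 100, 30), rng.normal(400, 100, 30)
            ps.append(dispersion_permutation_test(x, y, n_perm=999, seed=seed).p_value)
        ps = np.array(ps)
        assert 0.01 < (ps < 0.1).mean() < 0.25
        assert np.mean(ps) == pytest.approx(0.5, abs=0.12)

    def test_detects_variance_narrowing_in_default_cohorts(self):
        df = generate_cohort(CohortConfig(seed=3))
        ne = df[df.cohort == "NE"].cn_true.to_numpy()
        e = df[df.cohort == "E"].cn_true.to_numpy()
        for stat in ("cv_diff", "range_diff"):
            t = dispersion_permutation_test(ne, e, stat, n_perm=1999, seed=0)
            assert t.observed > 0  # NE more dispersed
            assert t.p_value <= 0.01

    def test_addone_convention_bounds_p(self, rng):
        x, y = rng.normal(0, 5, 25) + 100, rng.normal(0, 1, 25) + 100
        t = dispersion_permutation_test(x, y, n_perm=999, seed=0)
        assert t.p_value >= 1 / 1000

    def test_bad_arguments_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="999"):
            dispersion_permutation_test(x, x, n_perm=10)
        with pytest.raises(ValueError, match="statistic"):
            dispersion_permutation_test(x, x, statistic="iqr_diff")


class TestBinnedProfile:
    def test_bin_widths_and_counts(self):
        df = generate_cohort(CohortConfig(seed=1))
        prof = bin_dispersion_profile(df)
        assert set(prof.cohort) == {"NE", "E"}
        assert prof.n.sum() == len(df)
        # 5-year NE bins over ages 17-71 -> at most 11 bins; 2-year E bins -> 10
        assert (prof[prof.cohort == "NE"].n > 0).all()
        assert len(prof[prof.cohort == "E"]) <= 10

    def test_small_bins_flagged(self):
        df = generate_cohort(CohortConfig(seed=1, n_ne=12, n_e=6))
        prof = bin_dispersion_profile(df)
        assert prof.loc[prof.n < 5, "small"].all()

    def test_missing_columns_rejected(self):
        df = generate_cohort(CohortConfig(seed=1)).drop(columns=["age"])
        with pytest.raises(ValueError, match="age"):
            bin_dispersion_profile(df)


class TestRegression:
    def test_exact_line_recovered(self):
        import pandas as pd

        ages = np.arange(20, 70)
        df = pd.DataFrame({"age": ages, "cn_true": 500.0 - 2.0 * ages})
        slope, intercept, p = regression_cn_age(df)
        assert slope == pytest.approx(-2.0)
        assert intercept == pytest.approx(500.0)
        assert p < 1e-10

    def test_no_age_trend_within_ne_group(self):
        # the generator draws CN independently of age inside NE
        df = generate_cohort(CohortConfig(seed=4))
        slope, _, p = regression_cn_age(df[df.cohort == "NE"])
        assert p > 0.01

    def test_too_few_points_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            regression_cn_age(pd.DataFrame({"age": [20, 30], "cn_true": [400, 410]}))


class TestSurvivorFit:
    def test_hard_bounds_recovered_to_within_ten_copies(self):
        errs = []
        for seed in range(60):
            df = generate_cohort(CohortConfig(seed=seed))
            fit = fit_survivor_model(
                df[df.cohort == "NE"].cn_true, df[df.cohort == "E"].cn_true, mode="hard"
            )
            errs.append((abs(fit.lower - 272.0), abs(fit.upper - 541.0)))
        errs = np.array(errs)
        assert errs.mean(axis=0).max() < 10.0

    def test_predicted_summary_narrower_than_ne(self):
        df = generate_cohort(CohortConfig(seed=2))
        ne = df[df.cohort == "NE"].cn_true.to_numpy()
        fit = fit_survivor_model(ne, df[df.cohort == "E"].cn_true, mode="hard")
        assert fit.predicted_cv < describe(ne).cv
        assert fit.ks_p > 0.01  # model-consistent data should fit

    def test_soft_fit_runs_and_brackets_hard_bounds(self):
        df = generate_cohort(CohortConfig(seed=6))
        fit = fit_survivor_model(
            df[df.cohort == "NE"].cn_true, df[df.cohort == "E"].cn_true, mode="soft"
        )
        assert fit.scale is not None and fit.scale > 0
        assert 200 < fit.lower < fit.upper < 711

    def test_no_selection_case_gives_wide_bounds(self):
        df = generate_cohort(CohortConfig(seed=7, e_mode="none"))
        fit = fit_survivor_model(
            df[df.cohort == "NE"].cn_true, df[df.cohort == "E"].cn_true, mode="hard"
        )
        # without selection the E extremes approach the NE support
        assert fit.lower < 272.0 - 10 or fit.upper > 541.0 + 10

    def test_small_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_survivor_model(rng.normal(size=10), rng.normal(size=100))


class TestReport:
    def test_report_json_serialisable_and_complete(self):
        import json

        df = generate_cohort(CohortConfig(seed=0))
        rep = cohort_report(df, n_perm=999)
        s = json.dumps(rep)
        assert '"NE"' in s and '"E"' in s
        assert set(rep) >= {
            "groups", "mean_tests", "dispersion_tests", "survivor_fit",
            "cn_vs_age", "binned_dispersion",
        }
        assert rep["groups"]["NE"]["n"] == 525
        assert rep["dispersion_tests"]["cv_diff"]["p"] <= 0.05
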