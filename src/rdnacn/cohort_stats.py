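"""Cohort-level analysis of rDNA copy-number distributions.

Implements the descriptive and inferential toolkit used to contrast the
non-elderly and elderly groups: summaries with the coefficient of
variation, Mann-Whitney and Kolmogorov-Smirnov two-sample tests, a
label-permutation test for dispersion statistics (the published dispersion
p-value's exact construction is unstated, so the permutation test here is
this package's own, documented construction), age-binned range/CV profiles,
copy-number-vs-age regression, and the survivor-truncation model fit that
formalises the hypothesis that only mid-range copy numbers survive to the
elderly ages.

Standard tests delegate to scipy.stats; the permutation machinery and the
survivor-bound estimator are implemented here. Two-sided p-values
throughout; the study's significance threshold was p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_synth import NECopyNumberModel, SoftSurvivorParams


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of one copy-number sample."""

    n: int
    min: float
    max: float
    mean: float
    sd: float
    median: float
    cv: float
    degenerate: bool = False

    def rounded_cv(self, digits: int = 2) -> float:
        """CV rounded for presentation (kept exact internally)."""
        return round(self.cv, digits)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float


@dataclass(frozen=True)
class DispersionTest:
    """Permutation test of a dispersion contrast between two groups."""

    statistic_name: str
    observed: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class SurvivorFit:
    """Fitted survivor-selection model mapping the NE to the E distribution."""

    mode: str
    lower: float
    upper: float
    scale: float | None
    predicted_mean: float
    predicted_sd: float
    predicted_cv: float
    ks_statistic: float
    ks_p: float


def describe(values: np.ndarray) -> GroupSummary:
    """Exact sample statistics (SD with ddof=1); CV = SD/mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(values.std(ddof=1))
    mean = float(values.mean())
    return GroupSummary(
        n=int(values.size),
        min=float(values.min()),
        max=float(values.max()),
        mean=mean,
        sd=sd,
        median=float(np.median(values)),
        cv=sd / mean if mean else np.nan,
        degenerate=sd == 0.0,
    )


def mann_whitney(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the smaller sample has at most 8
    observations and there are no cross-sample ties; otherwise the normal
    approximation with tie correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if min(x.size, y.size) <= 8 and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def ks_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (exact for tiny samples)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="auto")
    return TestResult(float(res.statistic), float(res.pvalue))


def _dispersion_stat(name: str, x: np.ndarray, y: np.ndarray) -> float:
    if name == "cv_diff":
        return float(x.std(ddof=1) / x.mean() - y.std(ddof=1) / y.mean())
    if name == "range_diff":
        return float(np.ptp(x) - np.ptp(y))
    raise ValueError("statistic must be 'cv_diff' or 'range_diff'")


def dispersion_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    statistic: str = "cv_diff",
    n_perm: int = 9999,
    seed: int = 0,
) -> DispersionTest:
    """Pooled label-permutation test of a dispersion contrast.

    The observed statistic (CV or range difference between the groups) is
    compared against its permutation null; the two-sided p-value uses the
    add-one convention p = (1 + #{|T*| >= |T|}) / (n_perm + 1).
    """
    if n_perm < 999:
        raise ValueError("use at least 999 permutations")
    x, y = np.asarray(x, float), np.asarray(y, float)
    observed = _dispersion_stat(statistic, x, y)
    pooled = np.concatenate([x, y])
    nx = x.size
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(_dispersion_stat(statistic, perm[:nx], perm[nx:])) >= abs(observed):
            exceed += 1
    return DispersionTest(statistic, observed, (1 + exceed) / (n_perm + 1), n_perm, seed)


def bin_dispersion_profile(
    cohort: pd.DataFrame,
    ne_bin_width: int = 5,
    e_bin_width: int = 2,
    cn_col: str = "cn_true",
    min_n: int = 5,
) -> pd.DataFrame:
    """Per-age-bin range and CV of copy number, by cohort.

    NE ages are binned in 5-year intervals and E ages in 2-year intervals;
    each row reports the bin's mean age, n, range and CV, and bins with
    fewer than ``min_n`` subjects are flagged ``small``. Empty bins are
    omitted.
    """
    if "age" not in cohort or cn_col not in cohort:
        raise ValueError(f"cohort table needs 'age' and '{cn_col}' columns")
    rows = []
    for label, width in (("NE", ne_bin_width), ("E", e_bin_width)):
        sub = cohort[cohort["cohort"] == label]
        if sub.empty:
            continue
        start = int(sub["age"].min())
        bins = ((sub["age"] - start) // width).astype(int)
        for b, grp in sub.groupby(bins):
            if grp.empty:
                continue
            vals = grp[cn_col].to_numpy(dtype=float)
            rows.append(
                dict(
                    cohort=label,
                    mean_age=float(grp["age"].mean()),
                    n=len(grp),
                    cn_range=float(np.ptp(vals)) if len(vals) > 1 else 0.0,
                    cn_cv=float(vals.std(ddof=1) / vals.mean()) if len(vals) > 1 else np.nan,
                    small=len(grp) < min_n,
                )
            )
    return pd.DataFrame(rows).sort_values(["cohort", "mean_age"]).reset_index(drop=True)


def regression_cn_age(
    cohort: pd.DataFrame, cn_col: str = "cn_true"
) -> tuple[float, float, float]:
    """OLS of copy number on age: (slope, intercept, two-sided slope p)."""
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects for regression")
    res = stats.linregress(cohort["age"].to_numpy(float), cohort[cn_col].to_numpy(float))
    return float(res.slope), float(res.intercept), float(res.pvalue)


def fit_survivor_model(
    ne_values: np.ndarray,
    e_values: np.ndarray,
    mode: str = "hard",
) -> SurvivorFit:
    """Fit the survivor-selection model from observed NE and E samples.

    Hard mode: the truncation-bound MLE is the E sample minimum/maximum,
    de-biased by the expected extreme spacing (the first and last order-
    statistic gaps): lower = x(1) - (x(2) - x(1)), upper = x(n) + (x(n) -
    x(n-1)). Soft mode: logistic survival weights fitted so the reweighted
    NE sample matches the E mean and SD. Both report the predicted E
    summary and a Kolmogorov-Smirnov goodness-of-fit of model vs observed E.
    """
    ne = np.sort(np.asarray(ne_values, float))
    e = np.sort(np.asarray(e_values, float))
    if ne.size < 30 or e.size < 30:
        raise ValueError("need at least 30 values in each group")

    if mode == "hard":
        lower = e[0] - (e[1] - e[0])
        upper = e[-1] + (e[-1] - e[-2])
        scale = None
        survivors = ne[(ne >= lower) & (ne <= upper)]
    elif mode == "soft":
        from scipy.optimize import least_squares

        def resid(x: np.ndarray) -> np.ndarray:
            w = SoftSurvivorParams(*x).weight(ne)
            wt = w / w.sum()
            m = float(np.sum(wt * ne))
            s = float(np.sqrt(np.sum(wt * (ne - m) ** 2)))
            return np.array([m - e.mean(), s - e.std(ddof=1)])

        sol = least_squares(
            resid, x0=np.array([np.quantile(ne, 0.1), np.quantile(ne, 0.85), 20.0]),
            bounds=([ne[0], np.median(ne), 1.0], [np.median(ne), ne[-1], 150.0]),
        )
        lower, upper, scale = map(float, sol.x)
        params = SoftSurvivorParams(lower, upper, scale)
        rng = np.random.default_rng(0)
        w = params.weight(ne)
        survivors = rng.choice(ne, size=max(e.size * 20, 2000), p=w / w.sum())
    else:
        raise ValueError("mode must be 'hard' or 'soft'")

    if survivors.size < 2:
        raise RuntimeError("fitted selection leaves too few survivors")
    pred = describe(survivors)
    ks = ks_test(survivors, e)
    return SurvivorFit(
        mode=mode, lower=float(lower), upper=float(upper), scale=scale,
        predicted_mean=pred.mean, predicted_sd=pred.sd, predicted_cv=pred.cv,
        ks_statistic=ks.statistic, ks_p=ks.p_value,
    )


def cohort_report(
    cohort: pd.DataFrame,
    cn_col: str = "cn_true",
    n_perm: int = 1999,
    seed: int = 0,
) -> dict:
    """JSON-serialisable analysis report for a two-group cohort table."""
    ne = cohort.loc[cohort["cohort"] == "NE", cn_col].to_numpy(float)
    e = cohort.loc[cohort["cohort"] == "E", cn_col].to_numpy(float)
    out: dict = {"groups": {}}
    for label, vals in (("NE", ne), ("E", e)):
        if vals.size >= 2:
            s = describe(vals)
            out["groups"][label] = {
                "n": s.n, "min": s.min, "max": s.max, "mean": s.mean,
                "sd": s.sd, "median": s.median, "cv": s.cv,
            }
    if ne.size and e.size:
        mw, ks = mann_whitney(ne, e), ks_test(ne, e)
        out["mean_tests"] = {
            "mann_whitney": {"U": mw.statistic, "p": mw.p_value},
            "ks": {"D": ks.statistic, "p": ks.p_value},
        }
        out["dispersion_tests"] = {}
        for statname in ("cv_diff", "range_diff"):
            t = dispersion_permutation_test(ne, e, statname, n_perm=n_perm, seed=seed)
            out["dispersion_tests"][statname] = {"observed": t.observed, "p": t.p_value}
        fit = fit_survivor_model(ne, e, mode="hard")
        out["survivor_fit"] = {
            "mode": fit.mode, "lower": fit.lower, "upper": fit.upper,
            "predicted_mean": fit.predicted_mean, "predicted_sd": fit.predicted_sd,
            "predicted_cv": fit.predicted_cv, "ks_p": fit.ks_p,
        }
    slope, intercept, p = regression_cn_age(cohort, cn_col)
    out["cn_vs_age"] = {"slope": slope, "intercept": intercept, "p": p}
    out["binned_dispersion"] = bin_dispersion_profile(cohort, cn_col=cn_col).to_dict("records")
    return out
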