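"""Synthetic leukocyte cohorts with the observed age-group structure.

The study population is 651 adults split into a non-elderly group
(NE, n = 525, ages 17-71) and an elderly group (E, n = 126, ages 72-91; 72
is the mean-lifetime age used as the cut). The published NE copy-number
facts pin five constraints: support 200-711, mean 419, SD 110, median 410,
10% below 272 and 15% above 541. No single named parametric family honours
all of them, so NE copy numbers are drawn through a monotone piecewise-
linear quantile function that passes exactly through the five printed
quantile anchors, with four free interior/tail knots solved (once, at
generator construction) so the distribution's mean and SD match the printed
moments.

The elderly group is modelled as survivors of the NE distribution: either
hard truncation at the printed E-group support bounds [272, 541], or a soft
pair of logistic survival weights whose parameters can be fitted to the
E-group mean/SD. Methylation groups (1M/2M/3M) and true hypermethylated
fractions are assigned with age-group-specific probabilities matching the
40 + 40 sample survey: 20 of 40 NE samples vs 4 of 40 E samples carrying
2M/3M rDNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

NE_AGE_RANGE = (17, 71)
E_AGE_RANGE = (72, 91)
#: printed NE quantile anchors: (probability, copy number)
NE_ANCHORS = ((0.0, 200.0), (0.10, 272.0), (0.50, 410.0), (0.85, 541.0), (1.0, 711.0))
NE_MEAN, NE_SD = 419.0, 110.0
E_MEAN, E_SD = 396.0, 63.0
#: E-group survivor bounds (printed E support)
SURVIVOR_BOUNDS = (272.0, 541.0)

#: methylation-group probabilities: NE 50/20/30 (20 of 40 carriers),
#: E 90/5/5 (4 of 40 carriers)
MYTHYL_PROBS = {
    "NE": {"1M": 0.50, "2M": 0.20, "3M": 0.30},
    "E": {"1M": 0.90, "2M": 0.05, "3M": 0.05},
}
#: true hypermethylated-fraction support per group
F_HYPER_RANGES = {"1M": (0.0, 0.02), "2M": (0.05, 0.12), "3M": (0.13, 0.30)}


class GeneratorConstructionError(RuntimeError):
    """The quantile constraints cannot be satisfied by a monotone function."""


class NECopyNumberModel:
    """Quantile-matched NE copy-number distribution.

    Free knots sit at probabilities 0.05, 0.30, 0.70 and 0.93; they are
    solved so that the piecewise-linear quantile function reproduces the
    target mean and SD while staying monotone between the printed anchors.
    """

    _FREE_U = (0.05, 0.30, 0.70, 0.93)

    def __init__(
        self,
        anchors: Sequence[tuple[float, float]] = NE_ANCHORS,
        mean: float = NE_MEAN,
        sd: float = NE_SD,
    ):
        self.anchors = tuple(anchors)
        self.target_mean = mean
        self.target_sd = sd
        self._solve()

    @staticmethod
    def _moments(u: np.ndarray, q: np.ndarray) -> tuple[float, float]:
        du = np.diff(u)
        q0, q1 = q[:-1], q[1:]
        m1 = float(np.sum(du * (q0 + q1) / 2.0))
        m2 = float(np.sum(du * (q0 * q0 + q0 * q1 + q1 * q1) / 3.0))
        return m1, float(np.sqrt(max(m2 - m1 * m1, 0.0)))

    def _solve(self) -> None:
        au = np.array([a[0] for a in self.anchors])
        aq = np.array([a[1] for a in self.anchors])
        free_u = np.array(self._FREE_U)
        all_u = np.sort(np.concatenate([au, free_u]))
        is_free = np.isin(all_u, free_u)

        lo = np.interp(free_u, au, aq) * 0 + np.array(
            [np.max(aq[au < u]) for u in free_u]
        )
        hi = np.array([np.min(aq[au > u]) for u in free_u])
        x0 = np.interp(free_u, au, aq)

        def build(x: np.ndarray) -> np.ndarray:
            q = np.interp(all_u, au, aq)
            q[is_free] = x
            return q

        def resid(x: np.ndarray) -> np.ndarray:
            m, s = self._moments(all_u, build(x))
            # light pull toward the linear interpolant keeps the shape smooth
            return np.concatenate(
                [[m - self.target_mean, s - self.target_sd], 0.01 * (x - x0) / 100.0]
            )

        sol = least_squares(
            resid, x0, bounds=(lo + 1e-6, hi - 1e-6), xtol=1e-14, ftol=1e-14
        )
        q = build(sol.x)
        m, s = self._moments(all_u, q)
        if abs(m - self.target_mean) > 0.05 or abs(s - self.target_sd) > 0.05:
            raise GeneratorConstructionError(
                f"quantile solver missed the moment targets (mean {m:.2f}, sd {s:.2f})"
            )
        if np.any(np.diff(q) < 0):
            raise GeneratorConstructionError("solved quantile function is not monotone")
        self.knots_u = all_u
        self.knots_q = q
        self.mean, self.sd = m, s

    def quantile(self, u: np.ndarray | float) -> np.ndarray | float:
        return np.interp(u, self.knots_u, self.knots_q)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be at least 1")
        return self.quantile(rng.uniform(size=n))


@dataclass(frozen=True)
class SoftSurvivorParams:
    """Smoothed double-truncation survival weights.

    ``w(cn) = logistic((cn - lower)/scale) * logistic((upper - cn)/scale)``.
    """

    lower: float = SURVIVOR_BOUNDS[0]
    upper: float = SURVIVOR_BOUNDS[1]
    scale: float = 20.0

    def weight(self, cn: np.ndarray) -> np.ndarray:
        cn = np.asarray(cn, dtype=float)
        a = 1.0 / (1.0 + np.exp(-(cn - self.lower) / self.scale))
        b = 1.0 / (1.0 + np.exp(-(self.upper - cn) / self.scale))
        return a * b


def fit_soft_survivor(
    model: NECopyNumberModel | None = None,
    target_mean: float = E_MEAN,
    target_sd: float = E_SD,
) -> SoftSurvivorParams:
    """Fit logistic survival weights so survivors of the NE distribution
    reproduce the E-group mean and SD."""
    model = model or NECopyNumberModel()
    u = np.linspace(0.0005, 0.9995, 2000)
    cn = np.asarray(model.quantile(u))

    def resid(x: np.ndarray) -> np.ndarray:
        w = SoftSurvivorParams(*x).weight(cn)
        wt = w / w.sum()
        m = float(np.sum(wt * cn))
        s = float(np.sqrt(np.sum(wt * (cn - m) ** 2)))
        return np.array([m - target_mean, s - target_sd])

    sol = least_squares(
        resid, x0=np.array([272.0, 541.0, 20.0]),
        bounds=([200.0, 410.0, 1.0], [410.0, 711.0, 120.0]),
    )
    return SoftSurvivorParams(*sol.x)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings (defaults reproduce the study conditions)."""

    n_ne: int = 525
    n_e: int = 126
    seed: int = 0
    e_mode: str = "hard"  # "hard" | "soft" | "none"
    survivor_bounds: tuple[float, float] = SURVIVOR_BOUNDS
    soft_params: SoftSurvivorParams = field(default_factory=SoftSurvivorParams)
    meth_probs: dict = field(default_factory=lambda: {g: dict(p) for g, p in MYTHYL_PROBS.items()})
    keep_sex_ratio: bool = True  # 545 male : 106 female overall

    def __post_init__(self) -> None:
        for grp, probs in self.meth_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"methylation probabilities for {grp} must sum to 1")
        if self.e_mode not in ("hard", "soft", "none"):
            raise ValueError("e_mode must be 'hard', 'soft' or 'none'")


def sample_ne_cn(
    n: int, model: NECopyNumberModel | None = None, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw NE-group copy numbers from the quantile-matched preset."""
    model = model or NECopyNumberModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return model.sample(n, rng)


def sample_e_cn(
    n: int,
    ne_pool: np.ndarray | None = None,
    mode: str = "hard",
    bounds: tuple[float, float] = SURVIVOR_BOUNDS,
    soft_params: SoftSurvivorParams | None = None,
    seed: int | np.random.Generator = 0,
    model: NECopyNumberModel | None = None,
) -> np.ndarray:
    """Draw elderly-group copy numbers as survivors of the NE distribution.

    ``mode='hard'`` keeps only values inside ``bounds``; ``mode='soft'``
    accepts with the logistic survival weight; ``mode='none'`` applies no
    selection (null model). If ``ne_pool`` is given survivors are resampled
    from it, otherwise fresh NE draws are generated as needed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    model = model or NECopyNumberModel()
    if ne_pool is not None and len(ne_pool) == 0:
        raise ValueError("ne_pool must be non-empty")

    def draw(k: int) -> np.ndarray:
        if ne_pool is not None:
            return rng.choice(np.asarray(ne_pool, dtype=float), size=k, replace=True)
        return model.sample(k, rng)

    out: list[float] = []
    guard = 0
    while len(out) < n:
        batch = draw(max(4 * (n - len(out)), 16))
        if mode == "hard":
            keep = batch[(batch >= bounds[0]) & (batch <= bounds[1])]
        elif mode == "soft":
            w = (soft_params or SoftSurvivorParams()).weight(batch)
            keep = batch[rng.uniform(size=len(batch)) < w]
        else:
            keep = batch
        out.extend(keep.tolist())
        guard += 1
        if guard > 1000:
            raise RuntimeError("survivor acceptance region too small; check parameters")
    return np.array(out[:n])


def assign_methylation_group(
    cohort_label: str,
    n: int,
    probs: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Assign 1M/2M/3M labels and true hypermethylated fractions.

    Fractions are drawn uniformly within the band consistent with each
    group: 1M 0-0.02, 2M 0.05-0.12, 3M 0.13-0.30.
    """
    if probs is None:
        if cohort_label not in MYTHYL_PROBS:
            raise ValueError(f"unknown cohort label {cohort_label!r}")
        probs = MYTHYL_PROBS[cohort_label]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    groups = rng.choice(list(probs), size=n, p=list(probs.values()))
    f_hyper = np.array(
        [rng.uniform(*F_HYPER_RANGES[g]) for g in groups]
    )
    return pd.DataFrame({"meth_group_true": groups, "f_hyper_true": f_hyper})


def generate_cohort(config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Generate the full subject table.

    Columns: id, cohort (NE/E), age, sex, cn_true, f_hyper_true,
    meth_group_true. All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    model = NECopyNumberModel()

    frames = []
    for label, n, ages in (("NE", config.n_ne, NE_AGE_RANGE), ("E", config.n_e, E_AGE_RANGE)):
        if label == "NE" or config.e_mode == "none":
            cn = model.sample(n, rng) if label == "NE" else sample_e_cn(
                n, mode="none", seed=rng, model=model
            )
        else:
            cn = sample_e_cn(
                n, mode=config.e_mode, bounds=config.survivor_bounds,
                soft_params=config.soft_params, seed=rng, model=model,
            )
        age = rng.integers(ages[0], ages[1] + 1, size=n)
        if config.keep_sex_ratio:
            sex = rng.choice(["M", "F"], size=n, p=(545 / 651, 106 / 651))
        else:
            sex = rng.choice(["M", "F"], size=n)
        meth = assign_methylation_group(label, n, config.meth_probs.get(label), seed=rng)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{label}{i:04d}" for i in range(n)],
                    "cohort": label,
                    "age": age,
                    "sex": sex,
                    "cn_true": cn,
                    "f_hyper_true": meth["f_hyper_true"].to_numpy(),
                    "meth_group_true": meth["meth_group_true"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
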