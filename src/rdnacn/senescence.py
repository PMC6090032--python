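"""Replicative senescence of fibroblast lines losing hypermethylated rDNA.

Cultured skin fibroblasts exhaust their division capacity after a line-
specific number of passages. In lines whose genomes carry hypermethylated
rDNA copies (methylation group 3M), the total copy number falls between
passage 5 and the final passage while the methylation index M drops into
the 1M band; lines without hypermethylated copies keep both unchanged. The
mechanism modelled here is that *only* hypermethylated copies are lost:
each such copy survives a passage with probability 1 - lambda (independent
Bernoulli thinning, i.e. geometric decay of the hypermethylated pool),
while active and low-methylated copies are never touched.

Only the endpoints (passage 5 and the final passage) were observed, so the
per-passage loss rate is an assumption; the default is chosen so the
expected hypermethylated fraction at the final passage of even the
shortest-lived line (45 passages) is below 0.01, i.e. loss is essentially
complete, matching the endpoint observations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .methylation_index import (
    RetentionModel,
    classify_M,
    compute_M,
    estimate_hyper_fraction,
)
from .repeat_model import GenomeRDNA, RepeatUnitMap

#: per-copy, per-passage loss probability of hypermethylated copies;
#: (1 - 0.1)^40 ~ 0.015, so a 3M line (f ~ 0.3) ends below f = 0.005
DEFAULT_LOSS_RATE = 0.10
#: passage at which lines were first characterised
START_PASSAGE = 5
#: share of non-hypermethylated copies that are transcriptionally active
ACTIVE_SHARE = 0.45


@dataclass(frozen=True)
class CellLineState:
    """One fibroblast line at one passage."""

    line: str
    donor_age: int
    passage: int
    final_passage: int
    n_hyper: int
    n_other: int
    m: float

    @property
    def cn_total(self) -> int:
        return self.n_hyper + self.n_other

    @property
    def f_hyper(self) -> float:
        return self.n_hyper / self.cn_total if self.cn_total else 0.0


@dataclass(frozen=True)
class PassageTrajectory:
    """States from passage 5 to the final passage, under loss rate lambda."""

    states: tuple[CellLineState, ...]
    loss_rate: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                line=s.line, passage=s.passage, cn_total=s.cn_total,
                n_hyper=s.n_hyper, f_hyper=s.f_hyper, m=s.m,
            )
            for s in self.states
        )


@dataclass(frozen=True)
class PassageComparison:
    """Passage-5 vs final-passage contrast with measurement-noise intervals."""

    line: str
    cn_start: float
    cn_final: float
    delta_cn: float
    cn_changed: bool
    m_start: float
    m_final: float
    delta_m: float
    m_changed: bool
    final_group: str


def _genome(n_hyper: int, n_other: int) -> GenomeRDNA:
    cn = n_hyper + n_other
    f_h = n_hyper / cn
    rest = 1.0 - f_h
    return GenomeRDNA(cn, ACTIVE_SHARE * rest, (1.0 - ACTIVE_SHARE) * rest, f_h)


def _state(
    line: str, donor_age: int, passage: int, final_passage: int,
    n_hyper: int, n_other: int, unit: RepeatUnitMap, retention: RetentionModel,
) -> CellLineState:
    m = compute_M(_genome(n_hyper, n_other), unit, retention)
    return CellLineState(line, donor_age, passage, final_passage, n_hyper, n_other, m)


def init_line(
    name: str,
    donor_age: int,
    cn_leukocyte: float,
    m_leukocyte: float,
    retention: RetentionModel,
    unit: RepeatUnitMap,
    final_passage: int | None = None,
) -> CellLineState:
    """Passage-5 state of a line from its donor's leukocyte measurements.

    The passage-5 copy number is set equal to the leukocyte copy number (the
    two did not differ at passage 5) and the hypermethylated copy count is
    obtained by inverting the leukocyte methylation index through the
    retention model.
    """
    if m_leukocyte < 1.0 - 1e-9:
        raise ValueError("M must be at least 1")
    if final_passage is None:
        final_passage = int(name.rsplit("-", 1)[-1])
    f_hat, _, _ = estimate_hyper_fraction(m_leukocyte, retention=retention, unit=unit)
    n_hyper = int(round(cn_leukocyte * f_hat))
    n_other = int(round(cn_leukocyte)) - n_hyper
    return _state(name, donor_age, START_PASSAGE, final_passage, n_hyper, n_other, unit, retention)


def simulate_passages(
    state: CellLineState,
    unit: RepeatUnitMap,
    retention: RetentionModel,
    loss_rate: float = DEFAULT_LOSS_RATE,
    seed: int = 0,
) -> PassageTrajectory:
    """Simulate from the state's passage to the final passage.

    Per passage each hypermethylated copy is lost independently with
    probability ``loss_rate``; all other copies are conserved exactly. The
    methylation index is recomputed from the fraction composition at every
    passage.
    """
    if not 0.0 <= loss_rate <= 1.0:
        raise ValueError("loss_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    states = [state]
    n_hyper = state.n_hyper
    for passage in range(state.passage + 1, state.final_passage + 1):
        if n_hyper and loss_rate:
            n_hyper = int(rng.binomial(n_hyper, 1.0 - loss_rate))
        states.append(
            _state(
                state.line, state.donor_age, passage, state.final_passage,
                n_hyper, state.n_other, unit, retention,
            )
        )
    return PassageTrajectory(tuple(states), loss_rate)


def compare_passages(
    trajectory: PassageTrajectory,
    cn_se: float = 40.0,
    m_se: float = 0.2,
    z: float = 1.0,
) -> PassageComparison:
    """Contrast the first and last states of a trajectory.

    A quantity is called "changed" when its measurement intervals
    (value +- z x SE, with the SEs typical of the assay) do not overlap.
    """
    if len(trajectory.states) < 2:
        raise ValueError("trajectory must span at least two passages")
    first, last = trajectory.states[0], trajectory.states[-1]
    d_cn = last.cn_total - first.cn_total
    d_m = last.m - first.m
    return PassageComparison(
        line=first.line,
        cn_start=first.cn_total, cn_final=last.cn_total, delta_cn=d_cn,
        cn_changed=abs(d_cn) > 2 * z * cn_se,
        m_start=first.m, m_final=last.m, delta_m=d_m,
        m_changed=abs(d_m) > 2 * z * m_se,
        final_group=classify_M(last.m),
    )


def load_cell_lines() -> pd.DataFrame:
    """The packaged table of the five fibroblast lines' starting parameters."""
    ref = importlib.resources.files("rdnacn").joinpath("data/fibroblast_lines.yaml")
    doc = yaml.safe_load(ref.read_text())
    return pd.DataFrame(doc["lines"])


def simulate_study(
    unit: RepeatUnitMap,
    retention: RetentionModel,
    loss_rate: float = DEFAULT_LOSS_RATE,
    seed: int = 0,
    lines: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the five-line senescence experiment end to end.

    Returns one row per line with the passage-5 and final-passage copy
    number and methylation index, the change calls, and the final group.
    """
    lines = load_cell_lines() if lines is None else lines
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in lines.iterrows():
        st = init_line(
            rec["name"], int(rec["donor_age"]), float(rec["cn_leukocyte"]),
            float(rec["m_leukocyte"]), retention, unit,
            final_passage=int(rec["final_passage"]),
        )
        traj = simulate_passages(
            st, unit, retention, loss_rate, seed=int(rng.integers(2**31))
        )
        cmp = compare_passages(
            traj, cn_se=float(rec["cn_leukocyte_se"]), m_se=float(rec["m_leukocyte_se"])
        )
        rows.append(
            dict(
                line=cmp.line, final_passage=int(rec["final_passage"]),
                cn_p5=cmp.cn_start, cn_final=cmp.cn_final, delta_cn=cmp.delta_cn,
                cn_changed=cmp.cn_changed, m_p5=round(cmp.m_start, 3),
                m_final=round(cmp.m_final, 3), m_changed=cmp.m_changed,
                start_group=classify_M(cmp.m_start), final_group=cmp.final_group,
            )
        )
    return pd.DataFrame(rows)
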