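"""The methylation index M and the 1M/2M/3M classification.

M is the ratio of dot-hybridization signals of a (HpaII + Csp6I) digest to a
(MspI + Csp6I) digest of the same DNA, probed in the ETS-18S region. MspI
cuts every CCGG, so its digest reduces all copies to small fragments.
HpaII is blocked on hypermethylated copies, which therefore stay as large
Csp6I-only fragments. Because small restriction fragments contribute less
hybridization signal per base than large ones (they are retained less
efficiently on the membrane), the HpaII digest of a genome carrying
hypermethylated copies gives a *stronger* signal, and M rises above 1.

The retention mechanism is modelled explicitly as a logistic weight in
log-fragment-length. Under the three-fraction model the index is affine in
the hypermethylated fraction f:

    M = M0 + f * (g - M0),    g = S_uncut / S_cut,

where g (the "gain") is the per-copy signal ratio of a Csp6I-only spectrum
to a fully CCGG-cut spectrum and M0 ~ 1 is the index of a genome with no
hypermethylated copies. The default retention midpoint is calibrated so
that f = 0.30 (the largest hypermethylated content observed) maps to
M = 2.9, the top of the observed 3M range; this places f ~ 0.10 near the
middle of the 2M range. Empirical group bands: 1M 1.02-1.2, 2M 1.3-1.7,
3M 1.8-2.9; classification thresholds sit in the gaps (1.3 and 1.8), with
boundary values assigned to the higher group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .repeat_model import (
    FractionSpectrum,
    GenomeRDNA,
    RepeatUnitMap,
    digest_genome,
    genome_from_hyper,
    probe_overlap,
)

DEFAULT_PROBE = "p(ETS-18S)"
#: group thresholds: M < 1.3 -> 1M, 1.3 <= M < 1.8 -> 2M, M >= 1.8 -> 3M
GROUP_THRESHOLDS = (1.3, 1.8)
#: M at the top of the 3M band, reached at f_hyper = 0.30
_M_MAX, _F_MAX = 2.9, 0.30


class ModelError(ValueError):
    """Degenerate retention model (no signal or gain <= 1)."""


@dataclass(frozen=True)
class RetentionModel:
    """Membrane retention weight as a logistic function of log fragment length.

    ``weight(L) = L^k / (L^k + l50^k)`` with midpoint ``l50`` (bp, the
    half-retention length) and steepness ``k`` per log-unit. Weights lie in
    (0, 1] and increase with length, so large Csp6I-only fragments hybridize
    more efficiently than the small fragments of a complete CCGG digest.
    """

    l50: float
    steepness: float = 4.0

    def __post_init__(self) -> None:
        if self.l50 <= 0 or self.steepness <= 0:
            raise ValueError("l50 and steepness must be positive")

    def weight(self, length: float | np.ndarray) -> float | np.ndarray:
        ratio = np.asarray(length, dtype=float) / self.l50
        w = ratio**self.steepness
        out = w / (w + 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MethylationCall:
    """One sample's methylation call."""

    m: float
    group: str
    f_hat: float
    f_lo: float
    f_hi: float


def dot_signal(
    spectra: list[FractionSpectrum],
    probe: str,
    retention: RetentionModel,
    unit: RepeatUnitMap,
) -> float:
    """Hybridization signal of a digest: copy-weighted, retention-weighted
    probe overlap summed over all fragments of all fractions."""
    total = 0.0
    for spec in spectra:
        for frag in spec.fragments:
            ov = probe_overlap(unit, frag, probe)
            if ov:
                total += spec.copies * ov * retention.weight(frag.length)
    return total


def _fraction_signal(
    unit: RepeatUnitMap, retention: RetentionModel, f_hyper: float,
    enzymes: tuple[str, ...], probe: str,
) -> float:
    genome = genome_from_hyper(1.0, f_hyper)
    return dot_signal(digest_genome(unit, genome, enzymes, rng_seed=0), probe, retention, unit)


def compute_M(
    genome: GenomeRDNA,
    unit: RepeatUnitMap,
    retention: RetentionModel,
    rng_seed: int = 0,
    probe: str = DEFAULT_PROBE,
) -> float:
    """Closed-form methylation index: ratio of (HpaII+Csp6I) to (MspI+Csp6I)
    hybridization signals under the fraction model (no membrane noise)."""
    num = dot_signal(
        digest_genome(unit, genome, ("HpaII", "Csp6I"), rng_seed=rng_seed),
        probe, retention, unit,
    )
    den = dot_signal(
        digest_genome(unit, genome, ("MspI", "Csp6I"), rng_seed=rng_seed),
        probe, retention, unit,
    )
    if den <= 0:
        raise ModelError("zero denominator signal: degenerate retention or probe")
    return num / den


def alt_index(
    genome: GenomeRDNA,
    unit: RepeatUnitMap,
    retention: RetentionModel,
    rng_seed: int = 0,
    probe: str = DEFAULT_PROBE,
) -> float:
    """Control ratio with a Csp6I-only numerator: signal(Csp6I)/signal(MspI+Csp6I).

    Always at least as large as M, since a Csp6I-only digest retains every
    fragment the HpaII digest retains, merged or larger.
    """
    num = dot_signal(
        digest_genome(unit, genome, ("Csp6I",), rng_seed=rng_seed),
        probe, retention, unit,
    )
    den = dot_signal(
        digest_genome(unit, genome, ("MspI", "Csp6I"), rng_seed=rng_seed),
        probe, retention, unit,
    )
    if den <= 0:
        raise ModelError("zero denominator signal")
    return num / den


def gain(
    unit: RepeatUnitMap,
    retention: RetentionModel,
    probe: str = DEFAULT_PROBE,
) -> float:
    """Per-copy signal gain g of an uncut (Csp6I-only) spectrum over a fully
    CCGG-cut spectrum; the slope of M in f_hyper is g - M0."""
    s_uncut = _fraction_signal(unit, retention, 1.0, ("HpaII", "Csp6I"), probe)
    s_cut = _fraction_signal(unit, retention, 1.0, ("MspI", "Csp6I"), probe)
    if s_cut <= 0:
        raise ModelError("fully cut spectrum has zero probe signal")
    return s_uncut / s_cut


def calibrate_retention(
    unit: RepeatUnitMap,
    probe: str = DEFAULT_PROBE,
    steepness: float = 4.0,
    m_at_fmax: float = _M_MAX,
    f_max: float = _F_MAX,
) -> RetentionModel:
    """Solve for the retention midpoint l50 so that a genome with the maximal
    hypermethylated fraction reaches the top of the 3M band.

    Root-finds M(f_max) = m_at_fmax in log10(l50) over [50 bp, 50 kb].
    """
    genome = genome_from_hyper(400.0, f_max)

    def objective(log_l50: float) -> float:
        model = RetentionModel(10.0**log_l50, steepness)
        return compute_M(genome, unit, model, probe=probe) - m_at_fmax

    lo, hi = math.log10(50.0), math.log10(5e4)
    if objective(lo) * objective(hi) > 0:
        raise ModelError("retention calibration target unreachable with this site table")
    log_l50 = brentq(objective, lo, hi, xtol=1e-10)
    return RetentionModel(10.0**log_l50, steepness)


def default_retention(unit: RepeatUnitMap) -> RetentionModel:
    """The calibrated default retention model for a unit map."""
    return calibrate_retention(unit)


def classify_M(m: float) -> str:
    """Assign the 1M/2M/3M group from an M value (boundaries go up)."""
    if m <= 0:
        raise ValueError("M must be positive")
    if m < GROUP_THRESHOLDS[0]:
        return "1M"
    if m < GROUP_THRESHOLDS[1]:
        return "2M"
    return "3M"


def estimate_hyper_fraction(
    m: float,
    retention: RetentionModel | None = None,
    unit: RepeatUnitMap | None = None,
    gain_value: float | None = None,
    m_uncertainty: float = 0.0,
    probe: str = DEFAULT_PROBE,
) -> tuple[float, float, float]:
    """Invert M to an estimated hypermethylated fraction with an interval.

    With an explicit ``gain_value`` g the simple inversion
    ``f = (M - 1)/(g - 1)`` is used. Given the retention model and unit map
    instead, the exact affine forward model is inverted:
    ``f = (M - M0)/(M1 - M0)`` with M0 = M(f=0) and M1 = M(f=1), which also
    absorbs the small promoter-methylation offset of fraction-2 copies.
    Results are clipped to [0, 1]; the interval propagates ``m_uncertainty``.
    """
    if m_uncertainty < 0:
        raise ValueError("m_uncertainty must be non-negative")

    if gain_value is not None:
        if gain_value <= 1.0:
            raise ModelError("gain must exceed 1")
        m0, m1 = 1.0, gain_value
    else:
        if retention is None or unit is None:
            raise ValueError("provide either gain_value or (retention, unit)")
        m0 = compute_M(genome_from_hyper(1.0, 0.0), unit, retention, probe=probe)
        m1 = compute_M(genome_from_hyper(1.0, 1.0), unit, retention, probe=probe)
        if m1 <= m0:
            raise ModelError("forward model is not increasing in f_hyper")

    def invert(mv: float) -> float:
        return float(np.clip((mv - m0) / (m1 - m0), 0.0, 1.0))

    return invert(m), invert(m - m_uncertainty), invert(m + m_uncertainty)


def compute_M_membrane(
    genome: GenomeRDNA,
    unit: RepeatUnitMap,
    retention: RetentionModel,
    noise=None,
    rng_seed: int = 0,
    n_replicates: int = 3,
    dots_per_digest: int = 4,
    probe: str = DEFAULT_PROBE,
) -> tuple[float, float]:
    """Methylation index measured through simulated dot-blot membranes.

    Each of ``n_replicates`` independent experiments renders one membrane
    carrying ``dots_per_digest`` dots of the (HpaII+Csp6I) hydrolysate and
    of the (MspI+Csp6I) hydrolysate, plus standards and a lambda control;
    the index of one experiment is the ratio of the floor-corrected mean
    integral intensities of the two digests. Returns the mean M over the
    replicate experiments and its standard error (index values are
    conventionally reported as the average of three experiments).
    """
    from .dot_quantifier import locate_dots, measure_dot
    from .membrane_sim import DEFAULT_NOISE, ROLE_LAMBDA, render_membrane, standard_layout

    if noise is None:
        noise = DEFAULT_NOISE
    ng = 100.0
    num_sig = dot_signal(
        digest_genome(unit, genome, ("HpaII", "Csp6I"), rng_seed=0), probe, retention, unit
    )
    den_sig = dot_signal(
        digest_genome(unit, genome, ("MspI", "Csp6I"), rng_seed=0), probe, retention, unit
    )
    if den_sig <= 0:
        raise ModelError("zero denominator signal")
    signals = {"hpaii_csp": num_sig / ng, "mspi_csp": den_sig / ng}
    layout = standard_layout(list(signals), replicates=dots_per_digest, ng=ng)

    rng = np.random.default_rng(rng_seed)
    m_values = []
    for _ in range(n_replicates):
        membrane = render_membrane(
            layout, signals, noise, rng_seed=int(rng.integers(2**31))
        )
        measured = [
            measure_dot(membrane, stub, layout)
            for stub in locate_dots(membrane, layout)
        ]
        floor = np.mean(
            [m.integral for m in measured if m.role == ROLE_LAMBDA and m.usable]
        )
        means = {}
        for sid in signals:
            reps = [
                m.integral - floor
                for m in measured
                if m.sample_id == sid and m.usable
            ]
            if not reps:
                raise ModelError(f"no usable replicate dots for {sid}")
            means[sid] = float(np.mean(reps))
        if means["mspi_csp"] <= 0:
            raise ModelError("non-positive denominator after floor correction")
        m_values.append(means["hpaii_csp"] / means["mspi_csp"])
    m_arr = np.array(m_values)
    se = float(m_arr.std(ddof=1) / np.sqrt(len(m_arr))) if len(m_arr) > 1 else float("nan")
    return float(m_arr.mean()), se


def call_sample(
    m: float,
    retention: RetentionModel,
    unit: RepeatUnitMap,
    m_uncertainty: float = 0.0,
    probe: str = DEFAULT_PROBE,
) -> MethylationCall:
    """Full methylation call: group plus inverted hypermethylated fraction."""
    f_hat, f_lo, f_hi = estimate_hyper_fraction(
        m, retention=retention, unit=unit, m_uncertainty=m_uncertainty, probe=probe
    )
    return MethylationCall(m, classify_M(m), f_hat, f_lo, f_hi)
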