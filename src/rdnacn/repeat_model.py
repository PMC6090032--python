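"""Model of the human ribosomal DNA repeat unit and methylation-sensitive digestion.

The diploid human genome carries roughly 400 tandem copies of a ~43-kb rDNA
unit. Each unit holds a 13.3-kb region coding for the 18S/5.8S/28S rRNAs plus
a long intergenic spacer. Copies fall into three methylation fractions:

* fraction 1 — transcriptionally active, CpG-hypomethylated;
* fraction 2 — inactive, methylated at some promoter CpG sites only;
* fraction 3 — hypermethylated over the whole unit (heterochromatic).

Methylation-sensitive restriction analysis (MSRA) distinguishes the fractions:
HpaII cuts CCGG only when the internal cytosine is unmethylated, MspI cuts
CCGG regardless, and Csp6I (GT^AC) is methylation-insensitive. This module
performs that digestion in silico on a coordinate map of one repeat unit.

Coordinate convention
---------------------
Positions are integers relative to the transcription start (TSS at 0);
upstream positions are negative. Interval length is ``end - start``, which
reproduces the published probe lengths: the p(28S) probe spans 8289..10702
(2413 bp) and the p(ETS-18S) probe spans -515..5321 (5836 bp ~ 5.8 kb).
The unit is digested as a circle (tandem-array context): the last and first
segments of a digest are joined into one wrap-around fragment.

The default restriction-site table is schematic: the published map shows the
site positions only graphically, so the defaults are a plausible placement
that yields four large Csp6I fragments detected by the two probes. Every
downstream computation depends only on the site table, which is fully
user-overridable (TSV or FASTA motif scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ENZYMES = ("Csp6I", "HpaII", "MspI")

#: fraction labels, keyed by the conventional 1/2/3 numbering
FRACTIONS = {1: "active", 2: "low_methylated", 3: "hypermethylated"}

DEFAULT_UNIT_LENGTH = 43_000
DEFAULT_UNIT_START = -2_000            # upstream of the TSS, inside the IGS
DEFAULT_CODING_REGION = (0, 13_300)    # 18S/5.8S/28S transcribed region
DEFAULT_PROMOTER = (-200, 100)

#: schematic Csp6I (GTAC) positions; the first four inter-site intervals
#: downstream of -1500 are the probe-detected "fragments 1-4"
_DEFAULT_CSP6I = (
    -1500, 1000, 4500, 7800, 12000, 16000, 21000, 27000, 34000, 39000,
)

#: schematic CCGG positions (HpaII/MspI); -150 lies in the promoter window,
#: flanked closely by CpG-island neighbours so that promoter-only methylation
#: (fraction 2) merges just a short stretch
_DEFAULT_CCGG = (
    -800, -220, -150, -50, 120, 500, 1700, 2600, 3500, 4300, 5100, 6200, 7000,
    8700, 9500, 10300, 11300, 13500, 15000, 18000, 23000, 30000, 36000, 40000,
)

DEFAULT_PROBE_WINDOWS = {
    "p(ETS-18S)": (-515, 5321),
    "p(28S)": (8289, 10702),
    "oligo(18S)": (4000, 4030),
    "oligo(28S)": (9500, 9530),
}


class CoordinateError(ValueError):
    """A position or interval lies outside the repeat unit."""


@dataclass(frozen=True)
class RestrictionSite:
    """One cut site in the unit.

    ``cpg_linked`` marks CCGG sites whose internal cytosine can be methylated
    (this is what makes HpaII digestion methylation-dependent).
    """

    enzyme: str
    position: int
    cpg_linked: bool = False

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}; expected one of {ENZYMES}")


@dataclass(frozen=True)
class Fragment:
    """A digest fragment. ``end`` may exceed the unit end for the wrap-around
    fragment of a circular digest; :func:`probe_overlap` handles the split."""

    start: int
    end: int
    probe_hits: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatUnitMap:
    """Coordinate map of one rDNA repeat unit (see module docstring)."""

    unit_length: int = DEFAULT_UNIT_LENGTH
    unit_start: int = DEFAULT_UNIT_START
    tss_offset: int = 0
    coding_region: tuple[int, int] = DEFAULT_CODING_REGION
    probe_windows: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PROBE_WINDOWS)
    )
    sites: tuple[RestrictionSite, ...] = ()

    @property
    def unit_end(self) -> int:
        return self.unit_start + self.unit_length

    def __post_init__(self) -> None:
        if self.unit_length <= 0:
            raise ValueError("unit_length must be positive")
        lo, hi = self.unit_start, self.unit_end
        for name, (a, b) in self.probe_windows.items():
            if b - a < 30:
                raise ValueError(f"probe window {name} shorter than 30 bp")
            if a < lo or b > hi:
                raise CoordinateError(f"probe window {name} outside unit [{lo}, {hi})")
        c0, c1 = self.coding_region
        if c0 < lo or c1 > hi:
            raise CoordinateError("coding region outside unit")
        seen: set[tuple[str, int]] = set()
        ccgg = {s.position for s in self.sites if s.enzyme in ("HpaII", "MspI")}
        for s in self.sites:
            if not (lo <= s.position < hi):
                raise CoordinateError(f"site {s.enzyme}@{s.position} outside unit [{lo}, {hi})")
            key = (s.enzyme, s.position)
            if key in seen:
                raise ValueError(f"duplicate site {key}")
            seen.add(key)
            if s.enzyme == "Csp6I" and s.position in ccgg:
                raise ValueError(f"Csp6I site at CCGG position {s.position}")
        # HpaII and MspI recognise the same CCGG motif
        hpa = sorted(s.position for s in self.sites if s.enzyme == "HpaII")
        msp = sorted(s.position for s in self.sites if s.enzyme == "MspI")
        if hpa != msp:
            raise ValueError("HpaII and MspI site positions must coincide (both cut CCGG)")

    def positions(self, enzyme: str) -> list[int]:
        if enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {enzyme!r}")
        return sorted(s.position for s in self.sites if s.enzyme == enzyme)

    @property
    def ccgg_positions(self) -> list[int]:
        return self.positions("HpaII")

    def methylatable_positions(self) -> list[int]:
        return sorted(
            s.position for s in self.sites if s.enzyme == "HpaII" and s.cpg_linked
        )

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "unit_length": self.unit_length,
            "unit_start": self.unit_start,
            "tss_offset": self.tss_offset,
            "coding_region": list(self.coding_region),
            "probe_windows": {k: list(v) for k, v in self.probe_windows.items()},
            "sites": [
                {"enzyme": s.enzyme, "position": s.position, "cpg_linked": s.cpg_linked}
                for s in self.sites
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RepeatUnitMap":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            unit_length=doc["unit_length"],
            unit_start=doc["unit_start"],
            tss_offset=doc.get("tss_offset", 0),
            coding_region=tuple(doc["coding_region"]),
            probe_windows={k: tuple(v) for k, v in doc["probe_windows"].items()},
            sites=tuple(
                RestrictionSite(d["enzyme"], int(d["position"]), bool(d.get("cpg_linked", False)))
                for d in doc["sites"]
            ),
        )


@dataclass(frozen=True)
class MethylationProfile:
    """Per-CCGG-site methylation probabilities for one rDNA fraction.

    ``site_methylation`` maps CCGG position -> probability that the internal
    cytosine is methylated (blocking HpaII) in a copy of this fraction.
    """

    fraction: int
    site_methylation: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError("fraction must be 1, 2 or 3")
        for pos, p in self.site_methylation.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"methylation probability at {pos} outside [0, 1]")

    @property
    def name(self) -> str:
        return FRACTIONS[self.fraction]


@dataclass(frozen=True)
class GenomeRDNA:
    """One genome's rDNA array: copy count and fraction composition."""

    cn_total: float
    f_active: float
    f_low: float
    f_hyper: float

    def __post_init__(self) -> None:
        if self.cn_total <= 0:
            raise ValueError("cn_total must be positive")
        fr = (self.f_active, self.f_low, self.f_hyper)
        if any(f < 0 for f in fr):
            raise ValueError("fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def fractions(self) -> dict[int, float]:
        return {1: self.f_active, 2: self.f_low, 3: self.f_hyper}


def genome_from_hyper(cn_total: float, f_hyper: float, active_share: float = 0.45) -> GenomeRDNA:
    """Build a genome given the hypermethylated fraction alone.

    The non-hypermethylated remainder is split between active and
    low-methylated copies with ``active_share`` of it active (the active
    fraction is typically 30-50% of all copies).
    """
    if not 0.0 <= f_hyper <= 1.0:
        raise ValueError("f_hyper outside [0, 1]")
    rest = 1.0 - f_hyper
    return GenomeRDNA(cn_total, active_share * rest, (1.0 - active_share) * rest, f_hyper)


# ---------------------------------------------------------------------------
# profiles


def fraction_profile(
    unit: RepeatUnitMap,
    fraction: int,
    promoter: tuple[int, int] = DEFAULT_PROMOTER,
    promoter_methylation: float = 1.0,
) -> MethylationProfile:
    """Default methylation profile of one fraction over the unit's CCGG sites.

    Fraction 1: unmethylated everywhere. Fraction 2: methylated at promoter
    CCGG sites only (probability ``promoter_methylation``). Fraction 3:
    methylated at every methylatable site.
    """
    probs: dict[int, float] = {}
    methylatable = set(unit.methylatable_positions())
    for pos in unit.ccgg_positions:
        if pos not in methylatable:
            probs[pos] = 0.0
        elif fraction == 1:
            probs[pos] = 0.0
        elif fraction == 2:
            probs[pos] = promoter_methylation if promoter[0] <= pos < promoter[1] else 0.0
        else:
            probs[pos] = 1.0
    return MethylationProfile(fraction, probs)


# ---------------------------------------------------------------------------
# construction


def build_default_unit(
    site_config: pd.DataFrame | Sequence[tuple[str, int, bool]] | None = None,
) -> RepeatUnitMap:
    """Build the repeat-unit map with the documented (schematic) site table.

    ``site_config`` may be a DataFrame with columns enzyme/position/cpg_linked
    or an iterable of such rows; it replaces the default table entirely. An
    empty table is allowed and means an uncuttable unit.
    """
    if site_config is None:
        sites = [RestrictionSite("Csp6I", p) for p in _DEFAULT_CSP6I]
        for p in _DEFAULT_CCGG:
            sites.append(RestrictionSite("HpaII", p, cpg_linked=True))
            sites.append(RestrictionSite("MspI", p, cpg_linked=True))
    else:
        if isinstance(site_config, pd.DataFrame):
            rows = list(
                site_config[["enzyme", "position", "cpg_linked"]].itertuples(index=False)
            )
        else:
            rows = list(site_config)
        sites = [RestrictionSite(str(e), int(p), bool(c)) for e, p, c in rows]
    return RepeatUnitMap(sites=tuple(sites))


def load_site_table(path: str | Path) -> pd.DataFrame:
    """Read a site table TSV with columns enzyme, position, cpg_linked."""
    df = pd.read_csv(path, sep="\t")
    missing = {"enzyme", "position", "cpg_linked"} - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return df


def save_site_table(unit: RepeatUnitMap, path: str | Path) -> None:
    pd.DataFrame(
        [(s.enzyme, s.position, s.cpg_linked) for s in unit.sites],
        columns=["enzyme", "position", "cpg_linked"],
    ).to_csv(path, sep="\t", index=False)


def unit_from_fasta(path: str | Path, tss_offset: int = 0) -> RepeatUnitMap:
    """Build a unit map by motif-scanning a user-supplied repeat-unit FASTA.

    GTAC matches become Csp6I sites and CCGG matches become HpaII/MspI sites
    (all CCGG sites are treated as methylatable). Coordinates are shifted so
    that ``tss_offset`` (0-based position in the FASTA) maps to 0.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper()
    sites: list[RestrictionSite] = []
    for motif, enzymes in (("GTAC", ("Csp6I",)), ("CCGG", ("HpaII", "MspI"))):
        start = 0
        while (i := seq.find(motif, start)) != -1:
            for enz in enzymes:
                sites.append(
                    RestrictionSite(enz, i - tss_offset, cpg_linked=(motif == "CCGG"))
                )
            start = i + 1
    return RepeatUnitMap(
        unit_length=len(seq),
        unit_start=-tss_offset,
        coding_region=(
            max(DEFAULT_CODING_REGION[0], -tss_offset),
            min(DEFAULT_CODING_REGION[1], len(seq) - tss_offset),
        ),
        probe_windows={
            k: v
            for k, v in DEFAULT_PROBE_WINDOWS.items()
            if v[0] >= -tss_offset and v[1] <= len(seq) - tss_offset
        },
        sites=tuple(sites),
    )


# ---------------------------------------------------------------------------
# digestion


def probe_overlap(unit: RepeatUnitMap, fragment: Fragment, probe: str) -> int:
    """Base pairs of overlap between a fragment and a probe window.

    Handles the wrap-around fragment of a circular digest by measuring the
    window against both the fragment itself and its copy shifted one unit
    length downstream.
    """
    try:
        a, b = unit.probe_windows[probe]
    except KeyError:
        raise ValueError(f"unknown probe {probe!r}") from None
    total = 0
    for shift in (0, unit.unit_length):
        lo = max(fragment.start, a + shift)
        hi = min(fragment.end, b + shift)
        if hi > lo:
            total += hi - lo
    return total


def _annotate(unit: RepeatUnitMap, start: int, end: int) -> Fragment:
    frag = Fragment(start, end)
    hits = frozenset(
        name for name in unit.probe_windows if probe_overlap(unit, frag, name) > 0
    )
    return replace(frag, probe_hits=hits)


def digest(
    unit: RepeatUnitMap,
    profile: MethylationProfile,
    enzymes: Iterable[str],
    rng_seed: int | np.random.Generator = 0,
) -> list[Fragment]:
    """Digest one rDNA copy with the given enzyme set.

    Csp6I and MspI cut at every one of their sites. HpaII cuts a CCGG site
    only if the copy's sampled methylation state there is unmethylated
    (one Bernoulli draw per site from the profile's probability, seeded).
    Fragments tile the circularised unit; each is annotated with the probe
    windows it overlaps.
    """
    enzymes = set(enzymes)
    if not enzymes:
        raise ValueError("enzyme set must be non-empty")
    unknown = enzymes - set(ENZYMES)
    if unknown:
        raise ValueError(f"unknown enzymes: {sorted(unknown)}")
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, int) else rng_seed

    cuts: set[int] = set()
    if "Csp6I" in enzymes:
        cuts.update(unit.positions("Csp6I"))
    if "MspI" in enzymes:
        cuts.update(unit.ccgg_positions)
    if "HpaII" in enzymes:
        for pos in unit.ccgg_positions:
            p_meth = profile.site_methylation.get(pos, 0.0)
            methylated = p_meth > 0 and rng.random() < p_meth
            if not methylated:
                cuts.add(pos)

    if not cuts:
        return [_annotate(unit, unit.unit_start, unit.unit_end)]

    ordered = sorted(cuts)
    frags = [
        _annotate(unit, a, b) for a, b in zip(ordered[:-1], ordered[1:])
    ]
    # circular wrap: last cut to first cut (one unit length around)
    frags.append(_annotate(unit, ordered[-1], ordered[0] + unit.unit_length))
    return frags


@dataclass(frozen=True)
class FractionSpectrum:
    """Digest outcome for one methylation fraction, with its copy weight."""

    fraction: int
    copies: float
    fragments: tuple[Fragment, ...]

    @property
    def name(self) -> str:
        return FRACTIONS[self.fraction]


def digest_genome(
    unit: RepeatUnitMap,
    genome: GenomeRDNA,
    enzymes: Iterable[str],
    rng_seed: int = 0,
    promoter_methylation: float = 1.0,
) -> list[FractionSpectrum]:
    """Digest a whole genome's rDNA array, fraction by fraction.

    Returns one representative fragment spectrum per fraction together with
    the number of copies carrying it; the weights sum to ``cn_total``.
    """
    rng = np.random.default_rng(rng_seed)
    spectra = []
    for fraction, share in genome.fractions.items():
        if share == 0.0:
            continue  # absent fractions leave no signal on a membrane
        profile = fraction_profile(unit, fraction, promoter_methylation=promoter_methylation)
        frags = digest(unit, profile, enzymes, rng_seed=rng)
        spectra.append(
            FractionSpectrum(fraction, genome.cn_total * share, tuple(frags))
        )
    return spectra
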