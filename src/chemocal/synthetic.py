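"""Synthetic emulation of the study's NIR spectra and GC-IMS volatile profiles.

The real instrument data behind the storage-deterioration study are not
deposited, so every downstream stage is exercised on a generator that
reproduces the *statistical structure* the analysis assumes:

* seven coix-seed samples — raw ``S`` plus processed material stored 2, 4,
  12, 29, 46 and 56 months (``P2`` .. ``P56``);
* 50 diffuse-reflectance NIR spectra per sample (5 subsamples x 10 scans) on
  either of two instrument grids (900-1700 nm / 228 points, 1300-2500 nm /
  257 points), built as Beer-Lambert mixtures of Gaussian component bands
  whose concentrations follow smooth storage-month trajectories, degraded by
  per-spectrum multiplicative/additive scatter and white noise;
* a 74-compound GC-IMS peak-volume table (3 replicates per sample) whose
  compound classes follow the storage trends reported for roasted cereal
  volatilomes — aldehydes/acids rise, alcohols fall, ketones dip then
  rebound — with monomer/dimer ion pairs and a deuterated internal standard
  (2-octanol-D) carrying a shared per-injection intensity factor.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import INTERNAL_STANDARD, PeakTable, SpectraSet

# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

DEFAULT_SAMPLE_LABELS = ("S", "P2", "P4", "P12", "P29", "P46", "P56")
DEFAULT_STORAGE_MONTHS = (2, 4, 12, 29, 46, 56)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of the storage experiment.

    The raw sample ``S`` is unprocessed and carries months=0 for plotting
    only; storage months apply to the processed samples.
    """

    sample_labels: Sequence[str] = DEFAULT_SAMPLE_LABELS
    storage_months: Sequence[int] = DEFAULT_STORAGE_MONTHS
    n_subsamples: int = 5
    n_scans_per_subsample: int = 10
    n_gcims_replicates: int = 3
    seed: int = 20250901

    def __post_init__(self) -> None:
        labels = list(self.sample_labels)
        months = list(self.storage_months)
        if len(labels) != len(months) + 1:
            raise ValueError(
                "expected one unprocessed label plus one label per storage duration"
            )
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("storage months must be strictly increasing")
        if min(self.n_subsamples, self.n_scans_per_subsample, self.n_gcims_replicates) < 1:
            raise ValueError("counts must be positive")

    @property
    def processed_labels(self) -> list:
        return list(self.sample_labels[1:])

    @property
    def raw_label(self) -> str:
        return self.sample_labels[0]

    def months_of(self, label: str) -> float:
        if label == self.raw_label:
            return 0.0
        return float(self.storage_months[self.processed_labels.index(label)])

    def is_processed(self, label: str) -> bool:
        return label != self.raw_label

    @property
    def n_spectra_per_sample(self) -> int:
        return self.n_subsamples * self.n_scans_per_subsample


def true_index(design: StudyDesign) -> pd.Series:
    """Ground-truth deterioration score used for parameter-recovery tests.

    Linear in storage months, scaled so the processed samples span exactly
    6 dimensionless units between the first and last storage durations.
    """
    m = np.array([design.months_of(s) for s in design.sample_labels], dtype=float)
    lo, hi = design.storage_months[0], design.storage_months[-1]
    values = 6.0 * (m - lo) / (hi - lo)
    return pd.Series(values, index=list(design.sample_labels), name="true_index")


# ---------------------------------------------------------------------------
# NIR spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: center and width in nm, peak amplitude in AU."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("band width and amplitude must be positive")


@dataclass(frozen=True)
class Component:
    """A latent chemical component: its bands plus a concentration trajectory.

    ``trajectory(months, processed)`` returns the (dimensionless) relative
    concentration multiplying every band of the component.
    """

    name: str
    bands: tuple
    trajectory: Callable[[float, bool], float]


def _logistic(m: float, m0: float, tau: float) -> float:
    return 1.0 / (1.0 + math.exp(-(m - m0) / tau))


# Default trajectories.  Oxidation is monotone nondecreasing in months (the
# invariant every region-recovery test relies on); the lipid substrate is
# consumed; carbohydrate/protein background and water are stable; the
# roasting component exists only in processed material and fades slowly.

def _traj_lipid(m: float, processed: bool) -> float:
    return 1.0 - 0.30 * (1.0 - math.exp(-m / 25.0))


def _traj_oxidation(m: float, processed: bool) -> float:
    base = _logistic(m, 20.0, 10.0) - _logistic(0.0, 20.0, 10.0)
    return 0.15 + base / (1.0 - _logistic(0.0, 20.0, 10.0))


def _traj_background(m: float, processed: bool) -> float:
    return 1.0


def _traj_water(m: float, processed: bool) -> float:
    return 1.0


def _traj_roast(m: float, processed: bool) -> float:
    return math.exp(-m / 80.0) if processed else 0.0


def _long_wave_components() -> tuple:
    """Component bands for the 1300-2500 nm instrument.

    Oxidation-product bands sit inside 1300-1500 and 1800-2000 nm — the
    first overtone / combination regions of O-H and C=O groups formed by
    lipid oxidation — so the long-wave grid carries the stronger
    deterioration signal.
    """
    return (
        Component("water", (Band(1440, 70, 0.42), Band(1905, 80, 0.50)), _traj_water),
        Component(
            "lipid",
            (Band(1725, 40, 0.26), Band(2310, 45, 0.30), Band(1395, 50, 0.12)),
            _traj_lipid,
        ),
        Component(
            "oxidation",
            (Band(1450, 45, 0.12), Band(1920, 50, 0.16)),
            _traj_oxidation,
        ),
        Component(
            "background",
            (Band(2100, 120, 0.34), Band(1580, 100, 0.20)),
            _traj_background,
        ),
        Component("roast", (Band(2200, 60, 0.12), Band(1680, 40, 0.08)), _traj_roast),
    )


def _short_wave_components() -> tuple:
    """Component bands for the 900-1700 nm instrument (second overtones;
    weaker oxidation amplitudes than the long-wave grid)."""
    return (
        Component("water", (Band(970, 40, 0.25), Band(1440, 60, 0.36)), _traj_water),
        Component(
            "lipid", (Band(1210, 40, 0.20), Band(1390, 45, 0.10)), _traj_lipid
        ),
        Component(
            "oxidation", (Band(1160, 35, 0.05), Band(1415, 45, 0.06)), _traj_oxidation
        ),
        Component(
            "background", (Band(1100, 80, 0.20), Band(1585, 90, 0.15)), _traj_background
        ),
        Component("roast", (Band(1000, 40, 0.05), Band(1650, 40, 0.05)), _traj_roast),
    )


@dataclass(frozen=True)
class SpectralGeneratorConfig:
    """Parameters of the Beer-Lambert band-mixture spectra generator.

    scatter_slope_sd / scatter_offset_sd are the dispersions of the
    per-spectrum multiplicative (1+s) and additive offset scatter terms;
    noise_sd is additive white noise in absorbance units.
    subsample_variance_fraction splits the scatter variance between the
    subsample level and the scan level (0.5 = equal split).
    """

    wavelengths: np.ndarray
    components: tuple
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.002
    subsample_variance_fraction: float = 0.5
    emit_reflectance: bool = False
    name: str = "custom"

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", grid)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if self.noise_sd < 0 or self.scatter_slope_sd < 0 or self.scatter_offset_sd < 0:
            raise ValueError("noise and scatter dispersions must be nonnegative")
        if not 0.0 <= self.subsample_variance_fraction <= 1.0:
            raise ValueError("subsample_variance_fraction must lie in [0, 1]")

    @classmethod
    def short_wave(cls, **overrides) -> "SpectralGeneratorConfig":
        """900-1700 nm, 228 points (handheld short-wave instrument)."""
        return cls(
            wavelengths=np.linspace(900.0, 1700.0, 228),
            components=_short_wave_components(),
            name="short_wave",
            **overrides,
        )

    @classmethod
    def long_wave(cls, **overrides) -> "SpectralGeneratorConfig":
        """1300-2500 nm, 257 points (handheld long-wave instrument)."""
        return cls(
            wavelengths=np.linspace(1300.0, 2500.0, 257),
            components=_long_wave_components(),
            name="long_wave",
            **overrides,
        )

    def pure_spectrum(self, months: float, processed: bool) -> np.ndarray:
        """Noise-free band mixture for one sample condition."""
        grid = self.wavelengths
        out = np.zeros_like(grid)
        for comp in self.components:
            c = comp.trajectory(months, processed)
            if c == 0.0:
                continue
            for band in comp.bands:
                out += (
                    c
                    * band.amplitude
                    * np.exp(-0.5 * ((grid - band.center) / band.width) ** 2)
                )
        return out


def generate_spectra(
    design: StudyDesign,
    config: SpectralGeneratorConfig,
    seed: int | None = None,
) -> SpectraSet:
    """Simulate the full acquisition: one spectrum per (sample, subsample, scan).

    Each spectrum is the sample's pure band mixture distorted by a
    multiplicative slope, an additive offset (both split between subsample-
    and scan-level contributions) and white noise. Deterministic given seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    f_sub = math.sqrt(config.subsample_variance_fraction)
    f_scan = math.sqrt(1.0 - config.subsample_variance_fraction)

    rows = []
    spectra = []
    for label in design.sample_labels:
        months = design.months_of(label)
        processed = design.is_processed(label)
        pure = config.pure_spectrum(months, processed)
        for sub in range(1, design.n_subsamples + 1):
            slope_sub = rng.normal(0.0, config.scatter_slope_sd * f_sub)
            offset_sub = rng.normal(0.0, config.scatter_offset_sd * f_sub)
            for scan in range(1, design.n_scans_per_subsample + 1):
                slope = slope_sub + rng.normal(0.0, config.scatter_slope_sd * f_scan)
                offset = offset_sub + rng.normal(0.0, config.scatter_offset_sd * f_scan)
                noise = (
                    rng.normal(0.0, config.noise_sd, size=pure.size)
                    if config.noise_sd > 0
                    else 0.0
                )
                spectra.append(pure * (1.0 + slope) + offset + noise)
                rows.append(
                    {
                        "sample": label,
                        "processed": processed,
                        "months": months,
                        "subsample": sub,
                        "scan": scan,
                    }
                )
    absorbance = np.vstack(spectra)
    if config.emit_reflectance:
        absorbance = np.power(10.0, -absorbance)
    return SpectraSet(config.wavelengths, absorbance, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# GC-IMS peak table
# ---------------------------------------------------------------------------

DEFAULT_CLASS_COUNTS = {
    "aldehyde": 19,
    "alcohol": 18,
    "ketone": 13,
    "ester": 9,
    "acid": 6,
    "pyrazine": 3,
    "furan": 2,
    "other": 4,
}

DEFAULT_TREND_FAMILIES = {
    "aldehyde": "rise",
    "alcohol": "fall",
    "ketone": "dip_rebound",
    "ester": "late_rise",
    "acid": "rise",
    "pyrazine": "processing_pulse",
    "furan": "rise",
    "other": "flat",
}

# Processing multiplier ranges per class: roasting creates Maillard volatiles
# (pyrazines, furans, aldehydes) and destroys part of the raw grain aroma
# (alcohols, esters).
_PROCESSING_RANGES = {
    "aldehyde": (1.3, 2.2),
    "alcohol": (0.35, 0.8),
    "ketone": (0.9, 1.5),
    "ester": (0.5, 0.9),
    "acid": (1.0, 1.5),
    "pyrazine": (3.0, 8.0),
    "furan": (2.0, 5.0),
    "other": (0.8, 1.2),
}


@dataclass(frozen=True)
class VolatileGeneratorConfig:
    """Parameters of the volatile-compound (GC-IMS) generator.

    replicate_cv is the relative SD of the multiplicative replicate noise;
    injection_effect_sd the log-scale SD of the per-injection factor shared
    by every compound (and the internal standard) of one replicate;
    dimer_fraction the share of compounds emitted as monomer+dimer pairs.
    """

    class_counts: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    trend_families: dict = field(default_factory=lambda: dict(DEFAULT_TREND_FAMILIES))
    dimer_fraction: float = 0.3
    dimer_ratio_range: tuple = (0.25, 0.6)
    replicate_cv: float = 0.05
    injection_effect_sd: float = 0.15
    internal_standard_volume: float = 1000.0
    n_compounds: int = 74

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != self.n_compounds:
            raise ValueError(
                f"compound class counts sum to {sum(self.class_counts.values())}, "
                f"expected {self.n_compounds}"
            )
        if self.replicate_cv < 0 or self.injection_effect_sd < 0:
            raise ValueError("replicate_cv and injection_effect_sd must be nonnegative")
        if not 0.0 <= self.dimer_fraction <= 1.0:
            raise ValueError("dimer_fraction must lie in [0, 1]")
        missing = set(self.class_counts) - set(self.trend_families)
        if missing:
            raise ValueError(f"no trend family for classes: {sorted(missing)}")


def _make_trend(family: str, rng: np.random.Generator) -> Callable[[float], float]:
    """Draw one smooth trend curve g(months) from the named family; g(0) = 1."""
    if family == "rise":
        amp = rng.uniform(1.5, 4.0)
        m0 = rng.uniform(10.0, 30.0)
        tau = rng.uniform(5.0, 15.0)
        base = _logistic(0.0, m0, tau)
        return lambda m: 1.0 + amp * (_logistic(m, m0, tau) - base) / (1.0 - base)
    if family == "late_rise":
        amp = rng.uniform(1.5, 4.0)
        m0 = rng.uniform(32.0, 45.0)
        tau = rng.uniform(4.0, 10.0)
        base = _logistic(0.0, m0, tau)
        return lambda m: 1.0 + amp * (_logistic(m, m0, tau) - base) / (1.0 - base)
    if family == "fall":
        tau = rng.uniform(15.0, 40.0)
        floor = rng.uniform(0.1, 0.3)
        return lambda m: floor + (1.0 - floor) * math.exp(-m / tau)
    if family == "dip_rebound":
        depth = rng.uniform(0.2, 0.5)
        m_dip = rng.uniform(10.0, 25.0)
        width = rng.uniform(8.0, 15.0)
        slope = rng.uniform(0.3, 0.8)
        return lambda m: (
            1.0
            - depth * math.exp(-0.5 * ((m - m_dip) / width) ** 2)
            + depth * math.exp(-0.5 * (m_dip / width) ** 2)
            + slope * m / 56.0
        )
    if family == "processing_pulse":
        tau = rng.uniform(30.0, 60.0)
        return lambda m: math.exp(-m / tau)
    if family == "flat":
        return lambda m: 1.0
    raise ValueError(f"unknown trend family {family!r}")


def generate_peak_table(
    design: StudyDesign,
    config: VolatileGeneratorConfig,
    seed: int | None = None,
) -> PeakTable:
    """Simulate the GC-IMS census: 74 compounds (+ internal standard) x
    7 samples x 3 replicates.

    Volume(compound, sample, replicate) =
        base x processing_factor^[processed] x trend(months)
             x injection_factor(sample, replicate) x replicate noise.

    The injection factor is shared by all compounds of one replicate,
    including the internal standard, so internal-standard normalization
    cancels it exactly.
    """
    rng = np.random.default_rng(
        (design.seed if seed is None else seed) + 104729  # offset: decouple from spectra
    )

    compounds = []  # (name, cas, form, class, base, proc_factor, trend)
    idx = 0
    for cls_name, count in config.class_counts.items():
        family = config.trend_families[cls_name]
        lo, hi = _PROCESSING_RANGES.get(cls_name, (0.8, 1.2))
        n_dimer = int(round(config.dimer_fraction * count))
        for i in range(count):
            idx += 1
            name = f"{cls_name}_{i + 1:02d}"
            cas = f"SYN-{idx:04d}-0"
            base = 10.0 ** rng.uniform(2.0, 4.0)
            proc = rng.uniform(lo, hi)
            trend = _make_trend(family, rng)
            compounds.append((name, cas, "M", cls_name, base, proc, trend))
            if i < n_dimer:
                ratio = rng.uniform(*config.dimer_ratio_range)
                compounds.append(
                    (name + "-D", cas, "D", cls_name, base * ratio, proc, trend)
                )

    labels = list(design.sample_labels)
    n_rep = design.n_gcims_replicates
    injection = {
        (label, rep): math.exp(rng.normal(0.0, config.injection_effect_sd))
        if config.injection_effect_sd > 0
        else 1.0
        for label in labels
        for rep in range(1, n_rep + 1)
    }

    rows = []
    for name, cas, form, cls_name, base, proc, trend in compounds:
        for label in labels:
            months = design.months_of(label)
            expected = base * trend(months)
            if design.is_processed(label):
                expected *= proc
            for rep in range(1, n_rep + 1):
                noise = (
                    math.exp(rng.normal(0.0, config.replicate_cv))
                    if config.replicate_cv > 0
                    else 1.0
                )
                rows.append(
                    {
                        "compound": name,
                        "cas": cas,
                        "form": form,
                        "compound_class": cls_name,
                        "sample": label,
                        "replicate": rep,
                        "volume": expected * injection[(label, rep)] * noise,
                    }
                )

    # internal standard: constant expected volume, same injection factor
    for label in labels:
        for rep in range(1, n_rep + 1):
            noise = (
                math.exp(rng.normal(0.0, config.replicate_cv))
                if config.replicate_cv > 0
                else 1.0
            )
            rows.append(
                {
                    "compound": INTERNAL_STANDARD,
                    "cas": "SYN-IS-0",
                    "form": "M",
                    "compound_class": "internal_standard",
                    "sample": label,
                    "replicate": rep,
                    "volume": config.internal_standard_volume
                    * injection[(label, rep)]
                    * noise,
                }
            )

    return PeakTable(pd.DataFrame(rows))
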