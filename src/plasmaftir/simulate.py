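"""Synthetic plasma ATR-FTIR cohort generator.

Emulates the statistical structure of a two-class (healthy control vs multiple
sclerosis) plasma mid-infrared cohort: absorbance built as a sum of Gaussian
bands at literature-assigned wavenumbers, subject-level lognormal amplitude
variation, disease effects injected as per-band multiplicative factors
(ester C=O and CH bands up, amide I down in MS), a smooth random polynomial
baseline, replicate-level multiplicative gain, and additive white noise.

The defaults mirror the emulated study design: 40 HC and 45 MS subjects, up to
five replicate spectra each, a 4000-900 cm^-1 grid whose spacing (900/620
cm^-1) gives exactly 621 points in the 1800-900 cm^-1 fingerprint cut, EDSS
split 32 mild : 13 moderate/severe and disease onset split 27 short : 18 long.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpectraSet

__all__ = [
    "BandModel",
    "CohortConfig",
    "default_band_library",
    "evaluate_band",
    "generate_subject_spectra",
    "generate_cohort",
]

GAUSS_AREA_FACTOR = math.sqrt(math.pi / (4.0 * math.log(2.0)))


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band.

    ``class_multiplier_MS`` scales the band amplitude for MS subjects
    (1.0 = no disease effect).
    """

    center: float
    fwhm: float
    base_amplitude: float
    class_multiplier_MS: float = 1.0
    assignment_label: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        if self.class_multiplier_MS <= 0:
            raise ValueError("class_multiplier_MS must be > 0")

    @property
    def area(self) -> float:
        """Analytic area amplitude * fwhm * sqrt(pi / (4 ln 2))."""
        return self.base_amplitude * self.fwhm * GAUSS_AREA_FACTOR


def default_band_library(
    ms_multipliers: dict[float, float] | None = None,
) -> list[BandModel]:
    """Plasma band library: centers from standard biofluid assignments.

    Amplitudes and widths are generator parameters chosen to resemble a
    typical plasma absorbance spectrum (amide I dominant, weak lipid ester
    band); they are not measured values.  ``ms_multipliers`` overrides the
    default disease-effect multipliers, keyed by band center.
    """
    # (center, fwhm, amplitude, default MS multiplier, assignment)
    table = [
        (1740.0, 25.0, 0.060, 1.15, "ester C=O stretch (lipids)"),
        (1650.0, 45.0, 0.500, 0.95, "amide I (C=O stretch)"),
        (1633.0, 30.0, 0.250, 1.00, "amide I beta-sheet shoulder"),
        (1547.0, 45.0, 0.330, 1.00, "amide II (N-H bend / C-N stretch)"),
        (1510.0, 25.0, 0.070, 1.00, "tyrosine ring"),
        (1468.0, 18.0, 0.090, 1.00, "CH2 bending (lipids)"),
        (1453.0, 20.0, 0.110, 1.08, "CH2/CH3 bending"),
        (1405.0, 25.0, 0.100, 1.00, "COO- symmetric stretch"),
        (1340.0, 25.0, 0.045, 1.00, "CH2 wagging"),
        (1262.0, 35.0, 0.060, 1.00, "amide III / PO2- asym"),
        (1210.0, 35.0, 0.050, 1.00, "PO2- asymmetric stretch"),
        (966.0, 20.0, 0.030, 1.00, "C-C / PO2- symmetric"),
        (920.0, 20.0, 0.020, 1.00, "glucose / ribose region"),
        (3016.0, 20.0, 0.015, 1.12, "olefinic =C-H stretch (unsat. lipids)"),
        (2960.0, 22.0, 0.095, 1.00, "CH3 asymmetric stretch"),
        (2927.0, 24.0, 0.120, 1.10, "CH2 asymmetric stretch"),
        (2872.0, 22.0, 0.050, 1.00, "CH3 symmetric stretch"),
        (2852.0, 20.0, 0.045, 1.00, "CH2 symmetric stretch"),
        (2832.0, 18.0, 0.015, 1.00, "CH stretch shoulder"),
    ]
    ms_multipliers = ms_multipliers or {}
    return [
        BandModel(c, w, a, ms_multipliers.get(c, m), label)
        for c, w, a, m, label in table
    ]


@dataclass
class CohortConfig:
    """Cohort-level generator settings; defaults state the emulated design."""

    n_HC: int = 40
    n_MS: int = 45
    replicates_per_subject: int = 5
    grid_min: float = 900.0
    grid_max: float = 4000.0
    spacing: float = 900.0 / 620.0  # fingerprint cut -> 621 points
    band_library: list[BandModel] = field(default_factory=default_band_library)
    subject_cv: float = 0.10
    baseline_poly_degree: int = 3
    baseline_scale: float = 0.01
    gain_cv: float = 0.05
    noise_sd: float = 0.002
    edss_mild_fraction: float = 32.0 / 45.0
    onset_short_fraction: float = 27.0 / 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_HC < 0 or self.n_MS < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not 1 <= self.replicates_per_subject <= 5:
            raise ValueError("replicates_per_subject must be in [1, 5]")
        if self.spacing <= 0 or self.grid_min >= self.grid_max:
            raise ValueError("invalid grid settings")
        if min(self.subject_cv, self.gain_cv, self.noise_sd) < 0:
            raise ValueError("variation parameters must be >= 0")
        if self.baseline_poly_degree < 0:
            raise ValueError("baseline_poly_degree must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(math.floor((self.grid_max - self.grid_min) / self.spacing + 1e-9)) + 1
        return self.grid_min + self.spacing * np.arange(n)


def evaluate_band(band: BandModel, grid: np.ndarray, amplitude: float) -> np.ndarray:
    """Sample amplitude * exp(-4 ln2 (v - center)^2 / fwhm^2) on the grid."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    grid = np.asarray(grid, dtype=float)
    z = (grid - band.center) / band.fwhm
    return amplitude * np.exp(-4.0 * math.log(2.0) * z * z)


def _lognormal_unit_median(rng: np.random.Generator, cv: float, size=None):
    """Lognormal factor with median 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_subject_spectra(
    config: CohortConfig, class_label: str, rng: np.random.Generator
) -> np.ndarray:
    """Replicate spectra for one subject, shape (replicates, n_wavenumbers).

    Per-band subject amplitude = base * (MS multiplier if MS) * lognormal(cv);
    each replicate = gain * (band sum + baseline) + white noise.  The
    lognormal subject factor is shared across a subject's replicates.
    """
    grid = config.grid()
    is_ms = class_label == "MS"
    clean = np.zeros_like(grid)
    for band in config.band_library:
        amp = band.base_amplitude * (band.class_multiplier_MS if is_ms else 1.0)
        amp *= _lognormal_unit_median(rng, config.subject_cv)
        clean += evaluate_band(band, grid, amp)
    # smooth per-subject drift: random polynomial on a [-1, 1]-mapped axis
    coeffs = rng.standard_normal(config.baseline_poly_degree + 1)
    x = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    baseline = config.baseline_scale * np.polyval(coeffs, x)
    clean = clean + baseline
    reps = []
    for _ in range(config.replicates_per_subject):
        gain = _lognormal_unit_median(rng, config.gain_cv)
        noise = (
            rng.normal(0.0, config.noise_sd, size=grid.size)
            if config.noise_sd > 0
            else 0.0
        )
        reps.append(gain * clean + noise)
    return np.asarray(reps)


# onset-time histogram (years, coarse study bins): (lo, hi, weight)
_ONSET_BINS_SHORT = [(1.0, 5.0, 0.377), (6.0, 10.0, 0.222)]
_ONSET_BINS_LONG = [(11.0, 15.0, 0.200), (16.0, 20.0, 0.111),
                    (24.0, 35.0, 0.066), (47.0, 47.0, 0.022)]


def _draw_from_bins(rng: np.random.Generator, bins) -> float:
    w = np.array([b[2] for b in bins])
    lo, hi, _ = bins[rng.choice(len(bins), p=w / w.sum())]
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def generate_cohort(config: CohortConfig | None = None) -> SpectraSet:
    """Generate a full synthetic cohort as a :class:`SpectraSet`.

    Deterministic under ``config.seed``.  MS subjects receive EDSS scores
    (uniform within the mild 0.5-3.0 or moderate/severe 3.5-7.0 range, counts
    set by ``edss_mild_fraction``) and onset times drawn from the coarse study
    histogram with the short (<=10 y) : long (>10 y) split fixed by
    ``onset_short_fraction``; both stay missing for HC subjects.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    n_mild = int(round(config.edss_mild_fraction * config.n_MS))
    n_short = int(round(config.onset_short_fraction * config.n_MS))
    mild_flags = np.zeros(config.n_MS, dtype=bool)
    mild_flags[:n_mild] = True
    rng.shuffle(mild_flags)
    short_flags = np.zeros(config.n_MS, dtype=bool)
    short_flags[:n_short] = True
    rng.shuffle(short_flags)

    rows, meta = [], []
    for cls, n in (("HC", config.n_HC), ("MS", config.n_MS)):
        for i in range(n):
            sid = f"{cls}{i + 1:03d}"
            if cls == "MS":
                edss = (
                    float(rng.uniform(0.5, 3.0))
                    if mild_flags[i]
                    else float(rng.uniform(3.5, 7.0))
                )
                onset = _draw_from_bins(
                    rng, _ONSET_BINS_SHORT if short_flags[i] else _ONSET_BINS_LONG
                )
            else:
                edss, onset = np.nan, np.nan
            reps = generate_subject_spectra(config, cls, rng)
            for r, spec in enumerate(reps, start=1):
                rows.append(spec)
                meta.append(
                    dict(
                        subject_id=sid,
                        replicate=r,
                        class_label=cls,
                        edss=edss,
                        onset_years=onset,
                    )
                )
    matrix = (
        np.asarray(rows) if rows else np.empty((0, grid.size))
    )
    return SpectraSet(
        grid,
        matrix,
        pd.DataFrame(meta, columns=["subject_id", "replicate", "class_label",
                                    "edss", "onset_years"]),
        provenance=[f"simulate(seed={config.seed})"],
    )
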