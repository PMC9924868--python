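"""Peak intensities, band areas and lipid/protein ratio biomarkers.

Ratios are computed from baseline-corrected, vector-normalized absorbance
spectra (not derivatives); all three ratios are invariant to an overall
positive scaling of a spectrum, so the normalization cancels.

Named ratios
------------
``lipid_protein_intensity``
    I(1453) / I(1650): CH2/CH3 bending over amide I.
``lipid_protein_area``
    A(2800-3050) / (A(amide I) + A(amide II)): CH-stretch area over the
    protein amide area.  Amide integration windows default to 1600-1700
    (amide I) and 1500-1600 cm^-1 (amide II), bracketing the 1650 and 1547
    peaks.
``lipid_oxidation``
    I(1739) / I(1468): ester C=O over CH2 bending, an oxidized-lipid marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SpectraSet

__all__ = [
    "PeakSpec",
    "BandAreaSpec",
    "DEFAULT_PEAKS",
    "DEFAULT_AREAS",
    "peak_intensity",
    "band_area",
    "compute_ratios",
]


@dataclass(frozen=True)
class PeakSpec:
    """Named peak: maximum within ``center +- search_halfwidth`` cm^-1.

    ``search_halfwidth = 0`` reads the nearest grid point instead.
    """

    name: str
    center: float
    search_halfwidth: float = 5.0

    def __post_init__(self) -> None:
        if self.search_halfwidth < 0:
            raise ValueError("search_halfwidth must be >= 0")


@dataclass(frozen=True)
class BandAreaSpec:
    """Named integration interval [lo, hi] in cm^-1 (trapezoidal area)."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("band area requires lo < hi")


# 1739 and 1740 label the same ester C=O band in the source assignments.
DEFAULT_PEAKS = {
    "ester_CO": PeakSpec("ester_CO", 1739.0),
    "amide_I": PeakSpec("amide_I", 1650.0),
    "amide_II": PeakSpec("amide_II", 1547.0),
    "ch2_bend_1468": PeakSpec("ch2_bend_1468", 1468.0),
    "ch_bend_1453": PeakSpec("ch_bend_1453", 1453.0),
    "olefinic_3013": PeakSpec("olefinic_3013", 3013.0),
    "ch2_asym_2927": PeakSpec("ch2_asym_2927", 2927.0),
}

DEFAULT_AREAS = {
    "high_region": BandAreaSpec("high_region", 2800.0, 3050.0),
    "amide_I": BandAreaSpec("amide_I", 1600.0, 1700.0),
    "amide_II": BandAreaSpec("amide_II", 1500.0, 1600.0),
}


def peak_intensity(
    wavenumbers: np.ndarray, absorbance: np.ndarray, peak: PeakSpec
) -> float:
    """Maximum absorbance in the closed search window around the peak.

    With a zero half-width the value at the nearest grid point is returned;
    ties between equal maxima break toward the lower wavenumber.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if peak.search_halfwidth == 0:
        return float(y[np.argmin(np.abs(wn - peak.center))])
    lo, hi = peak.center - peak.search_halfwidth, peak.center + peak.search_halfwidth
    mask = (wn >= lo) & (wn <= hi)
    if not mask.any():
        raise ValueError(
            f"peak window [{lo:g}, {hi:g}] for {peak.name!r} misses the grid"
        )
    window = y[mask]
    return float(window[np.argmax(window)])  # argmax: first (lowest-wn) maximum


def band_area(
    wavenumbers: np.ndarray, absorbance: np.ndarray, spec: BandAreaSpec
) -> float:
    """Trapezoidal integral of absorbance over [lo, hi] on the ascending grid."""
    wn = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    mask = (wn >= spec.lo) & (wn <= spec.hi)
    if not mask.any():
        raise ValueError(f"band interval [{spec.lo:g}, {spec.hi:g}] misses the grid")
    return float(np.trapezoid(y[mask], wn[mask]))


def compute_ratios(
    data: SpectraSet,
    peaks: dict[str, PeakSpec] | None = None,
    areas: dict[str, BandAreaSpec] | None = None,
) -> pd.DataFrame:
    """Per-subject feature table of peak intensities, areas and named ratios.

    Requires one row per subject (replicates already averaged) on a grid
    covering 900-1800 cm^-1; the area ratio additionally needs 2800-3050.
    A non-positive ratio denominator raises, naming the subject.
    """
    peaks = dict(DEFAULT_PEAKS, **(peaks or {}))
    areas = dict(DEFAULT_AREAS, **(areas or {}))
    wn = data.wavenumbers
    has_high = wn.max() >= areas["high_region"].lo

    records = []
    for i in range(data.n_spectra):
        y = data.intensities[i]
        rec: dict[str, object] = {
            "subject_id": data.meta.loc[i, "subject_id"],
            "class_label": data.meta.loc[i, "class_label"],
        }
        for name, pk in peaks.items():
            lo = pk.center - pk.search_halfwidth
            if lo > wn.max() or pk.center + pk.search_halfwidth < wn.min():
                rec[f"I_{name}"] = np.nan
                continue
            rec[f"I_{name}"] = peak_intensity(wn, y, pk)
        for name, ar in areas.items():
            in_grid = ar.lo <= wn.max() and ar.hi >= wn.min()
            rec[f"A_{name}"] = band_area(wn, y, ar) if in_grid else np.nan
        sid = rec["subject_id"]

        def _ratio(num, den, label):
            if np.isnan(num) or np.isnan(den):
                return np.nan
            if den <= 0:
                raise ValueError(
                    f"degenerate spectrum for subject {sid!r}: "
                    f"non-positive denominator in {label}"
                )
            return num / den

        rec["lipid_protein_intensity"] = _ratio(
            rec["I_ch_bend_1453"], rec["I_amide_I"], "I(1453)/I(1650)"
        )
        rec["lipid_protein_area"] = _ratio(
            rec["A_high_region"],
            rec["A_amide_I"] + rec["A_amide_II"],
            "A_HR/(A_amideI+A_amideII)",
        ) if has_high else np.nan
        rec["lipid_oxidation"] = _ratio(
            rec["I_ester_CO"], rec["I_ch2_bend_1468"], "I(1739)/I(1468)"
        )
        records.append(rec)
    return pd.DataFrame(records)
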