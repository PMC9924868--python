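"""Spectral preprocessing chain.

Stages, in the order the pipeline applies them: replicate averaging, region
cut (fingerprint 1800-900 cm^-1 or high 3050-2800 cm^-1), rubber-band
(lower-convex-hull) baseline correction, then either vector normalization
(absorbance track) or Savitzky-Golay second derivative followed by vector
normalization (derivative track).

Each stage is a scikit-learn style transformer operating on an (n_spectra,
n_wavenumbers) matrix with an associated ascending wavenumber grid; the
module-level functions are thin wrappers over them for single spectra and
:class:`~plasmaftir.io.SpectraSet` objects.  None of the stages learn
parameters from data, so ``fit`` is a no-op and there is no leakage concern
in cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SpectraSet

__all__ = [
    "RegionSpec",
    "PreprocessConfig",
    "RegionCutter",
    "RubberbandBaseline",
    "VectorNormalizer",
    "SavitzkyGolayDerivative",
    "cut_region",
    "rubberband_baseline",
    "vector_normalize",
    "savgol_second_derivative",
    "average_replicates",
    "class_mean_sd",
    "run_preprocess",
]

# Relative slack on region boundaries so float grids built by accumulation
# (900 + k*step) are cut reproducibly at nominal interval edges.
_EDGE_RTOL = 1e-9

REGION_BOUNDS = {"fingerprint": (900.0, 1800.0), "high": (2800.0, 3050.0)}


@dataclass(frozen=True)
class RegionSpec:
    """Closed wavenumber interval [lo, hi] in cm^-1."""

    name: str = "fingerprint"
    lo: float | None = None
    hi: float | None = None

    def bounds(self) -> tuple[float, float]:
        if self.lo is not None and self.hi is not None:
            lo, hi = self.lo, self.hi
        elif self.name in REGION_BOUNDS:
            lo, hi = REGION_BOUNDS[self.name]
        else:
            raise ValueError(
                f"region {self.name!r} needs explicit lo/hi "
                f"(known names: {sorted(REGION_BOUNDS)})"
            )
        if lo > hi:
            raise ValueError("region lo must be <= hi")
        return float(lo), float(hi)


@dataclass
class PreprocessConfig:
    region: RegionSpec = field(default_factory=RegionSpec)
    do_baseline: bool = True
    do_vector_norm: bool = True
    derivative: str = "second"  # {"none", "second"}
    sg_window: int = 13
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.derivative not in ("none", "second"):
            raise ValueError("derivative must be 'none' or 'second'")
        if self.sg_window % 2 == 0 or self.sg_window < 5:
            raise ValueError("sg_window must be an odd integer >= 5")
        if not (0 <= self.sg_polyorder < self.sg_window):
            raise ValueError("sg_polyorder must satisfy 0 <= polyorder < window")
        if self.derivative == "second" and self.sg_polyorder < 2:
            raise ValueError("second derivative requires sg_polyorder >= 2")


# ---------------------------------------------------------------------------
# core numerics
# ---------------------------------------------------------------------------

def _region_mask(wavenumbers: np.ndarray, lo: float, hi: float) -> np.ndarray:
    tol = _EDGE_RTOL * max(1.0, abs(lo), abs(hi))
    mask = (wavenumbers >= lo - tol) & (wavenumbers <= hi + tol)
    if not mask.any():
        raise ValueError(f"region [{lo}, {hi}] does not intersect the grid")
    return mask


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain lower hull of the points (x_i, y_i), x ascending."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # keep only right turns: pop k if it lies on/above chord j->i
            if (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j]) <= 0.0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def _rubberband_one(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    idx = _lower_hull_indices(x, y)
    return np.interp(x, x[idx], y[idx])


def _savgol_d2(matrix: np.ndarray, spacing: float, window: int, polyorder: int):
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window > matrix.shape[-1]:
        raise ValueError("Savitzky-Golay window exceeds spectrum length")
    # mode="interp" fits the edge polynomial over the first/last window,
    # keeping the output length equal to the input length.
    return savgol_filter(
        matrix, window_length=window, polyorder=polyorder, deriv=2,
        delta=spacing, axis=-1, mode="interp",
    )


# ---------------------------------------------------------------------------
# transformers
# ---------------------------------------------------------------------------

class _StatelessSpectral(BaseEstimator, TransformerMixin):
    """Shared no-op ``fit`` for stateless spectral transformers."""

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class RegionCutter(_StatelessSpectral):
    """Restrict spectra to a closed wavenumber interval.

    Parameters
    ----------
    wavenumbers : array-like
        Ascending grid associated with the input columns.
    region : RegionSpec
        Interval to keep (closed on both ends).
    """

    def __init__(self, wavenumbers=None, region: RegionSpec = RegionSpec()):
        self.wavenumbers = wavenumbers
        self.region = region

    def fit(self, X, y=None):
        super().fit(X, y)
        wn = np.asarray(self.wavenumbers, dtype=float)
        lo, hi = self.region.bounds()
        self.mask_ = _region_mask(wn, lo, hi)
        self.wavenumbers_out_ = wn[self.mask_]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, self.mask_]


class RubberbandBaseline(_StatelessSpectral):
    """Subtract the piecewise-linear lower convex hull of each spectrum.

    The hull (the "rubber band" stretched under the trace) always touches the
    two endpoints and at least them; the corrected spectrum is >= 0 up to
    float round-off and exactly 0 at every contact point.
    """

    def __init__(self, wavenumbers=None):
        self.wavenumbers = wavenumbers

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.size < 2:
            raise ValueError("rubber-band correction needs at least 2 points")
        out = np.empty_like(X)
        for i, row in enumerate(X):
            out[i] = row - _rubberband_one(wn, row)
        return out


class VectorNormalizer(_StatelessSpectral):
    """Scale each spectrum to unit Euclidean norm."""

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot vector-normalize an all-zero spectrum")
        return X / norms


class SavitzkyGolayDerivative(_StatelessSpectral):
    """Savitzky-Golay second derivative in absorbance/(cm^-1)^2.

    ``window`` is the number of smoothing points (odd); coefficients are
    scaled by the grid spacing so polynomial-exactness holds on any uniform
    grid.
    """

    def __init__(self, spacing: float = 1.0, window: int = 13, polyorder: int = 2):
        self.spacing = spacing
        self.window = window
        self.polyorder = polyorder

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _savgol_d2(X, self.spacing, self.window, self.polyorder)


# ---------------------------------------------------------------------------
# functional wrappers (single spectra and SpectraSet)
# ---------------------------------------------------------------------------

def cut_region(
    data: SpectraSet, region: RegionSpec | str
) -> SpectraSet:
    """Keep only wavenumbers inside the closed region interval."""
    if isinstance(region, str):
        region = RegionSpec(name=region)
    lo, hi = region.bounds()
    mask = _region_mask(data.wavenumbers, lo, hi)
    return data.with_matrix(
        data.intensities[:, mask],
        wavenumbers=data.wavenumbers[mask],
        step=f"cut_region({region.name}:{lo:g}-{hi:g})",
    )


def rubberband_baseline(
    wavenumbers: np.ndarray, absorbance: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(baseline, corrected)`` for one spectrum."""
    x = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if x.size < 2:
        raise ValueError("rubber-band correction needs at least 2 points")
    baseline = _rubberband_one(x, y)
    return baseline, y - baseline


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Scale one spectrum to unit Euclidean norm."""
    s = np.asarray(spectrum, dtype=float)
    norm = np.linalg.norm(s)
    if norm == 0:
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return s / norm


def savgol_second_derivative(
    spectrum: np.ndarray, spacing: float, window: int = 13, polyorder: int = 2
) -> np.ndarray:
    """Second derivative of one spectrum via Savitzky-Golay smoothing."""
    return _savgol_d2(np.asarray(spectrum, dtype=float), spacing, window, polyorder)[()]


def average_replicates(data: SpectraSet) -> SpectraSet:
    """Average each subject's replicate spectra into one row per subject.

    Metadata collapse to one record per subject (the replicate column is
    dropped); subjects keep their order of first appearance.  Conflicting
    class labels within a subject raise.
    """
    meta = data.meta
    order = meta["subject_id"].drop_duplicates().tolist()
    rows, recs = [], []
    for sid in order:
        idx = np.flatnonzero((meta["subject_id"] == sid).to_numpy())
        sub = meta.iloc[idx]
        if sub["class_label"].nunique() > 1:
            raise ValueError(f"subject {sid!r} has conflicting class labels")
        rows.append(data.intensities[idx].mean(axis=0))
        rec = sub.iloc[0].to_dict()
        rec.pop("replicate", None)
        recs.append(rec)
    matrix = np.asarray(rows) if rows else np.empty((0, data.wavenumbers.size))
    return SpectraSet(
        data.wavenumbers.copy(),
        matrix,
        pd.DataFrame(recs, columns=[c for c in meta.columns if c != "replicate"]),
        data.provenance + ["average_replicates"],
    )


def class_mean_sd(data: SpectraSet, class_label: str) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample (n-1) standard deviation of one class."""
    idx = np.flatnonzero(data.class_labels == class_label)
    if idx.size == 0:
        raise ValueError(f"no spectra with class label {class_label!r}")
    sub = data.intensities[idx]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1) if idx.size >= 2 else np.zeros_like(mean)
    return mean, sd


def run_preprocess(data: SpectraSet, config: PreprocessConfig) -> SpectraSet:
    """Apply the full chain: average -> cut -> baseline -> (derivative) -> norm."""
    out = average_replicates(data)
    out = cut_region(out, config.region)
    if config.do_baseline:
        rb = RubberbandBaseline(wavenumbers=out.wavenumbers)
        out = out.with_matrix(rb.fit_transform(out.intensities),
                              step="rubberband_baseline")
    if config.derivative == "second":
        sg = SavitzkyGolayDerivative(
            spacing=out.spacing, window=config.sg_window,
            polyorder=config.sg_polyorder,
        )
        out = out.with_matrix(
            sg.fit_transform(out.intensities),
            step=f"savgol_d2(window={config.sg_window},poly={config.sg_polyorder})",
        )
    if config.do_vector_norm:
        out = out.with_matrix(
            VectorNormalizer().fit_transform(out.intensities),
            step="vector_normalize",
        )
    return out
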