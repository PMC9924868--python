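"""Reading, writing and filtering wide-format spectral matrices.

The on-disk dialect is a plain UTF-8 CSV with a mandatory header: the reserved
metadata columns ``subject_id, replicate, class_label, edss, onset_years``
followed by one numeric column per wavenumber (cm^-1).  Missing numeric
metadata (EDSS / onset for healthy controls) is an empty field.  Wavenumber
columns may appear in instrument (descending) or ascending order; internally
the grid is always stored ascending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "META_COLUMNS",
    "CLASS_LABELS",
    "SpectraSet",
    "SpectraFormatError",
    "GridError",
    "read_spectra_csv",
    "write_spectra_csv",
    "subset_by_meta",
]

#: Reserved metadata column names, in canonical order.
META_COLUMNS = ("subject_id", "replicate", "class_label", "edss", "onset_years")

#: Allowed class labels (healthy control / multiple sclerosis).
CLASS_LABELS = ("HC", "MS")

#: Relative tolerance for grid-spacing uniformity.
GRID_UNIFORMITY_RTOL = 1e-6


class SpectraFormatError(ValueError):
    """Malformed spectra CSV: metadata columns, labels or values."""


class GridError(ValueError):
    """Wavenumber grid is not strictly monotonic / uniform within tolerance."""


def _validate_grid(wavenumbers: np.ndarray) -> None:
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.ndim != 1 or wn.size == 0:
        raise GridError("wavenumber grid must be a non-empty 1-D array")
    if not np.all(np.isfinite(wn)):
        raise GridError("wavenumber grid contains non-finite values")
    if wn.size >= 2:
        steps = np.diff(wn)
        if np.any(steps <= 0):
            raise GridError("wavenumber grid must be strictly ascending")
        step = steps.mean()
        if np.any(np.abs(steps - step) > GRID_UNIFORMITY_RTOL * abs(step)):
            raise GridError(
                "wavenumber grid spacing is not uniform within "
                f"{GRID_UNIFORMITY_RTOL:g} relative tolerance"
            )


@dataclass
class SpectraSet:
    """A matrix of spectra with per-row subject metadata.

    Parameters
    ----------
    wavenumbers : ndarray, shape (p,)
        Strictly ascending, uniform wavenumber grid in cm^-1.
    intensities : ndarray, shape (n, p)
        Absorbance (or derivative) values, one spectrum per row.
    meta : DataFrame, n rows
        Columns ``subject_id`` (str), ``replicate`` (int >= 1),
        ``class_label`` ({HC, MS}), ``edss`` (float in [0, 10] or NaN),
        ``onset_years`` (float >= 0 or NaN).
    provenance : list of str
        Ordered record of the processing steps applied so far.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        _validate_grid(self.wavenumbers)
        if self.intensities.shape[0] == 0:
            self.intensities = self.intensities.reshape(0, self.wavenumbers.size)
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise SpectraFormatError(
                f"matrix has {self.intensities.shape[1]} columns but grid has "
                f"{self.wavenumbers.size} wavenumbers"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError("spectral matrix contains non-finite values")
        self.meta = _validate_meta(self.meta, n_rows=self.intensities.shape[0])

    # -- basic accessors -------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def spacing(self) -> float:
        """Nominal grid step in cm^-1 (0 for a single-point grid)."""
        wn = self.wavenumbers
        return float(np.diff(wn).mean()) if wn.size >= 2 else 0.0

    @property
    def subject_ids(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    @property
    def class_labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.wavenumbers.copy(),
            self.intensities.copy(),
            self.meta.copy(),
            list(self.provenance),
        )

    def with_matrix(
        self,
        intensities: np.ndarray,
        wavenumbers: np.ndarray | None = None,
        step: str | None = None,
    ) -> "SpectraSet":
        """Return a new set sharing this metadata with a replaced matrix."""
        wn = self.wavenumbers if wavenumbers is None else wavenumbers
        prov = self.provenance + ([step] if step else [])
        return SpectraSet(wn, intensities, self.meta.reset_index(drop=True), prov)


def _validate_meta(meta: pd.DataFrame, n_rows: int) -> pd.DataFrame:
    meta = pd.DataFrame(meta).reset_index(drop=True)
    # replicate is optional (dropped after averaging); id and class mandatory
    missing = [c for c in ("subject_id", "class_label") if c not in meta.columns]
    if missing:
        raise SpectraFormatError(f"missing metadata column(s): {missing}")
    for col in ("edss", "onset_years"):
        if col not in meta.columns:
            meta[col] = np.nan
    if len(meta) != n_rows:
        raise SpectraFormatError(
            f"metadata has {len(meta)} rows but matrix has {n_rows}"
        )
    meta["subject_id"] = meta["subject_id"].astype(str)
    bad = sorted(set(meta["class_label"]) - set(CLASS_LABELS))
    if bad:
        raise SpectraFormatError(
            f"unknown class label(s) {bad}; allowed labels are {list(CLASS_LABELS)}"
        )
    meta["edss"] = pd.to_numeric(meta["edss"], errors="raise").astype(float)
    meta["onset_years"] = pd.to_numeric(meta["onset_years"], errors="raise").astype(float)
    hc_edss = meta.loc[meta["class_label"] == "HC", "edss"]
    if hc_edss.notna().any():
        raise SpectraFormatError("EDSS values are only defined for MS subjects")
    edss = meta["edss"].dropna()
    if ((edss < 0) | (edss > 10)).any():
        raise SpectraFormatError("EDSS values must lie in [0, 10]")
    onset = meta["onset_years"].dropna()
    if (onset < 0).any():
        raise SpectraFormatError("onset_years must be >= 0")
    if "replicate" in meta.columns:
        meta["replicate"] = pd.to_numeric(meta["replicate"], errors="raise").astype(int)
        if (meta["replicate"] < 1).any():
            raise SpectraFormatError("replicate numbers must be >= 1")
        pairs = meta[["subject_id", "replicate"]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0].tolist()
            raise SpectraFormatError(f"duplicate subject_id/replicate pair: {dup}")
        cols = [c for c in META_COLUMNS if c in meta.columns]
    else:
        if meta["subject_id"].duplicated().any():
            raise SpectraFormatError("duplicate subject_id in replicate-free metadata")
        cols = [c for c in META_COLUMNS if c in meta.columns]
    return meta[cols]


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a wide-format spectra CSV into a validated :class:`SpectraSet`.

    Wavenumber columns are parsed as floats and re-ordered ascending, so files
    written in descending instrument order parse to the same object.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    present_meta = [c for c in META_COLUMNS if c in df.columns]
    if "subject_id" not in present_meta or "class_label" not in present_meta:
        raise SpectraFormatError(
            f"{path.name}: header must contain the reserved metadata columns "
            "'subject_id' and 'class_label'"
        )
    wn_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path.name}: non-numeric wavenumber column: {exc}")
    order = np.argsort(wn)
    matrix = df[wn_cols].to_numpy(dtype=float)[:, order] if len(df) else \
        np.empty((0, len(wn_cols)))
    bad = np.argwhere(~np.isfinite(matrix))
    if bad.size:
        r, c = bad[0]
        raise SpectraFormatError(
            f"{path.name}: non-numeric absorbance at row {r + 1}, "
            f"column {wn[order][c]:g}"
        )
    return SpectraSet(wn[order], matrix, df[present_meta])


def write_spectra_csv(data: SpectraSet, path: str | Path) -> Path:
    """Write a :class:`SpectraSet` to the wide CSV dialect; returns the path."""
    path = Path(path)
    meta = data.meta.copy()
    wide = pd.concat(
        [
            meta,
            pd.DataFrame(
                data.intensities,
                columns=[repr(float(w)) for w in data.wavenumbers],
                index=meta.index,
            ),
        ],
        axis=1,
    )
    wide.to_csv(path, index=False, float_format=None)
    return path


def subset_by_meta(
    data: SpectraSet, predicate: str | Callable[[pd.DataFrame], Sequence[bool]]
) -> SpectraSet:
    """Select rows by a metadata predicate, preserving row order and grid.

    ``predicate`` is either a pandas ``query`` expression over the metadata
    columns (e.g. ``"class_label == 'MS' and edss <= 3"``) or a callable
    mapping the metadata frame to a boolean mask.
    """
    if callable(predicate):
        mask = np.asarray(predicate(data.meta), dtype=bool)
    else:
        try:
            mask = data.meta.eval(predicate)
        except pd.errors.UndefinedVariableError as exc:
            raise SpectraFormatError(f"predicate references unknown field: {exc}")
        mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    return SpectraSet(
        data.wavenumbers.copy(),
        data.intensities[idx],
        data.meta.iloc[idx].reset_index(drop=True),
        list(data.provenance),
    )
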