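"""Test-set evaluation, ROC analysis, permutation significance and
wavenumber-importance profiles.

MS is the positive class throughout: sensitivity = TP/(TP+FN) is disease
detection, specificity = TN/(TN+FP) control recognition.  The empirical ROC
sweeps every distinct score cutoff and its trapezoidal area equals the
Mann-Whitney concordance probability (ties counted 1/2); the smoothed curve
is a binormal fit on rank-transformed scores.  Three importance profiles
match the three classifiers: PLS weighted absolute coefficients, forest OOB
permutation importance (mean decrease in accuracy over trees, normalized by
its standard error), and the per-variable ROC-AUC filter used as the PCA-LDA
surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionMatrix",
    "ROCCurve",
    "ImportanceProfile",
    "confusion_from_predictions",
    "confusion_metrics",
    "roc_auc",
    "smooth_roc",
    "permutation_test_accuracy",
    "importance_pls",
    "importance_rf",
    "importance_rocfilter",
    "evaluate_subgroups",
]

POSITIVE_CLASS = "MS"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class ROCCurve:
    thresholds: np.ndarray      # descending cutoffs
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    smoothed: dict | None = None


@dataclass
class ImportanceProfile:
    wavenumbers: np.ndarray
    importance: np.ndarray      # raw values (RF permutation may be negative)
    method: str

    def display_importance(self) -> np.ndarray:
        """Non-negative transform for plotting (raw values kept as stored)."""
        return np.clip(self.importance, 0.0, None)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber": self.wavenumbers, "importance": self.importance,
             "method": self.method}
        )


def confusion_from_predictions(y_true, y_pred) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == POSITIVE_CLASS
    pred_pos = y_pred == POSITIVE_CLASS
    return ConfusionMatrix(
        tp=int(np.sum(pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
    )


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with MS as the positive class."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("metrics undefined: a class is absent from the test set")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    return sens, spec, acc


def roc_auc(scores, labels) -> ROCCurve:
    """Empirical ROC over all distinct score cutoffs, trapezoidal AUC.

    The AUC equals U/(n1 n0), the probability that a random MS score exceeds
    a random HC score, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == POSITIVE_CLASS
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    sens = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(thresholds, sens, 1.0 - fpr, auc)


def smooth_roc(scores, labels) -> ROCCurve:
    """Binormal smoothed ROC.

    Scores are mapped to normal quantiles of their pooled ranks, per-class
    normal distributions are fitted, and the induced smooth curve is emitted
    with AUC = Phi(dmu / sqrt(s1^2 + s0^2)).  Zero within-class variance
    falls back to the empirical curve (flagged in ``smoothed``).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == POSITIVE_CLASS
    if min(np.unique(scores[y]).size, np.unique(scores[~y]).size) < 2:
        emp = roc_auc(scores, labels)
        emp.smoothed = {"ok": False, "reason": "zero within-class score variance"}
        return emp
    z = norm.ppf((rankdata(scores) - 0.5) / scores.size)
    mu1, s1 = z[y].mean(), z[y].std(ddof=1)
    mu0, s0 = z[~y].mean(), z[~y].std(ddof=1)
    auc = float(norm.cdf((mu1 - mu0) / np.hypot(s1, s0)))
    grid = np.linspace(-4, 4, 201) * max(s0, s1) + (mu0 + mu1) / 2
    grid = grid[::-1]  # descending cutoffs
    sens = norm.sf((grid - mu1) / s1)
    spec = norm.cdf((grid - mu0) / s0)
    return ROCCurve(grid, sens, spec, auc,
                    smoothed={"ok": True, "mu": (mu0, mu1), "sd": (s0, s1)})


def permutation_test_accuracy(
    pipeline, X, y, n_permutations: int = 1000, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """Permutation significance of a classification pipeline's accuracy.

    ``pipeline(X, y)`` must run the full protocol (split, tune, refit, test)
    and return the held-out accuracy.  Labels are permuted at the subject
    level (rows of ``X`` are subjects); the smoothed p-value
    (1 + #{perm >= observed}) / (n_permutations + 1) is never zero.

    Returns ``(p_value, observed_accuracy, permuted_accuracies)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    observed = float(pipeline(X, y))
    permuted = np.empty(n_permutations)
    for i in range(n_permutations):
        permuted[i] = pipeline(X, rng.permutation(y))
    p = (1.0 + np.sum(permuted >= observed)) / (n_permutations + 1.0)
    return float(p), observed, permuted


# ---------------------------------------------------------------------------
# importance profiles
# ---------------------------------------------------------------------------

def _unwrap(model, attr_chain=("estimator",)):
    for attr in attr_chain:
        inner = getattr(model, attr, None)
        if inner is not None:
            model = inner
    return model


def importance_pls(model, wavenumbers) -> ImportanceProfile:
    """Weighted sum of absolute PLS coefficients.

    importance_j = sum_h |b_jh| SSY_h / sum_h SSY_h where b_jh is variable
    j's coefficient contribution from component h and SSY_h the response
    sum of squares that component explains.
    """
    est = _unwrap(model)
    b = est.component_coefficients()           # (p, h)
    ssy = est.response_ss_by_component()       # (h,)
    w = ssy / ssy.sum()
    return ImportanceProfile(
        np.asarray(wavenumbers, dtype=float),
        np.abs(b) @ w,
        "pls_weighted_coeff",
    )


def importance_rf(model, wavenumbers) -> ImportanceProfile:
    """OOB permutation importance, mean decrease in accuracy over trees
    normalized by its standard error.

    For each tree the OOB accuracy is compared before and after permuting
    one predictor's OOB values; variables a tree never splits on contribute
    an exact zero (permuting them cannot change its predictions).
    """
    est = _unwrap(model)
    X, t = est.X_fit_, est.y_fit_
    p = X.shape[1]
    n_trees = len(est.trees_)
    rng = np.random.default_rng(getattr(est, "random_state", 0) + 1)
    diffs = np.zeros((n_trees, p))
    for ti, (tree, oob) in enumerate(zip(est.trees_, est.oob_indices_)):
        if oob.size == 0:
            continue
        Xo, to = X[oob], t[oob]
        base_acc = float((tree.predict(Xo) == to).mean())
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        perm = rng.permutation(oob.size)
        for j in used:
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            acc = float((tree.predict(Xp) == to).mean())
            diffs[ti, j] = base_acc - acc
    mean = diffs.mean(axis=0)
    se = diffs.std(axis=0, ddof=1) / np.sqrt(n_trees)
    importance = np.where(se > 0, mean / np.where(se > 0, se, 1.0), 0.0)
    return ImportanceProfile(
        np.asarray(wavenumbers, dtype=float), importance, "rf_permutation"
    )


def importance_rocfilter(X, y, wavenumbers=None) -> ImportanceProfile:
    """Per-variable single-predictor ROC AUC, folded to max(AUC, 1-AUC).

    Direction-agnostic filter importance; the PCA-LDA surrogate profile.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos = y == POSITIVE_CLASS
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC filter needs both classes present")
    # rank-based Mann-Whitney AUC per column, vectorized
    ranks = np.apply_along_axis(rankdata, 0, X)
    auc = (ranks[pos].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    folded = np.maximum(auc, 1.0 - auc)
    wn = (
        np.asarray(wavenumbers, dtype=float)
        if wavenumbers is not None
        else np.arange(X.shape[1], dtype=float)
    )
    return ImportanceProfile(wn, folded, "roc_auc_filter")


# ---------------------------------------------------------------------------
# subgroup prediction
# ---------------------------------------------------------------------------

SUBGROUPS = {
    "overall": lambda m: m["class_label"] == "MS",
    "edss_mild": lambda m: (m["class_label"] == "MS") & (m["edss"] <= 3.0),
    "edss_moderate_severe": lambda m: (m["class_label"] == "MS") & (m["edss"] > 3.0),
    "onset_short": lambda m: (m["class_label"] == "MS") & (m["onset_years"] <= 10.0),
    "onset_long": lambda m: (m["class_label"] == "MS") & (m["onset_years"] > 10.0),
}


def evaluate_subgroups(y_pred, meta: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity by MS subgroup with a shared specificity.

    Sensitivity is recomputed on the MS test subjects in each subgroup
    (EDSS mild vs moderate/severe, onset short vs long); specificity comes
    from the one HC test set and is therefore identical across rows.  Empty
    subgroups report NaN rather than raising.
    """
    y_pred = np.asarray(y_pred)
    meta = meta.reset_index(drop=True)
    hc = (meta["class_label"] == "HC").to_numpy()
    if hc.sum() == 0:
        specificity = np.nan
    else:
        specificity = float((y_pred[hc] == "HC").mean())
    rows = []
    for name, selector in SUBGROUPS.items():
        mask = selector(meta).to_numpy()
        if mask.sum() == 0:
            sens = np.nan
        else:
            sens = float((y_pred[mask] == "MS").mean())
        rows.append({"subgroup": name, "n_MS": int(mask.sum()),
                     "sensitivity": sens, "specificity": specificity})
    return pd.DataFrame(rows)
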