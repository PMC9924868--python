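"""PCA-LDA, PLS-DA and random-forest classifiers with nested validation.

All three are scikit-learn compatible binary estimators (``fit`` /
``predict`` / ``predict_proba`` / ``decision_function``) over an
(n_subjects, n_wavenumbers) matrix of preprocessed spectra, with MS as the
positive class.  The validation protocol mirrors the emulated study: a
stratified 75/25 subject-level split, 10-times-repeated stratified 5-fold
cross-validation on the training set to pick the tuning parameter by mean
accuracy (number of latent variables for PLS-DA, variables per split for the
forest; PCA-LDA has none — its PC count is fixed by a 95% explained-variance
threshold re-estimated inside every fold), then a refit on the whole
training set and a single evaluation on the held-out 25%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .io import SpectraSet
from .evaluate import confusion_from_predictions, confusion_metrics, roc_auc

__all__ = [
    "POSITIVE_CLASS",
    "SplitPlan",
    "CVScheme",
    "ModelSpec",
    "FittedClassifier",
    "PCALDAClassifier",
    "PLSDAClassifier",
    "RandomForestOOBClassifier",
    "make_model",
    "default_mtry_grid",
    "make_split",
    "tune_and_refit",
    "fit_pca_lda",
    "fit_pls_da",
    "fit_rf",
]

POSITIVE_CLASS = "MS"


def _encode(y) -> np.ndarray:
    """{HC, MS} labels -> {0, 1} with MS positive."""
    y = np.asarray(y)
    out = (y == POSITIVE_CLASS).astype(float)
    if set(np.unique(y)) - {"HC", "MS"}:
        raise ValueError("labels must be 'HC' or 'MS'")
    return out


# ---------------------------------------------------------------------------
# PCA-LDA
# ---------------------------------------------------------------------------

class PCALDAClassifier(BaseEstimator, ClassifierMixin):
    """PCA scores (smallest PC count explaining > ``variance_threshold`` of
    the variance) fed into a two-class LDA with pooled within-class
    covariance, ridge-regularized by ``reg * trace/dim`` on the diagonal.

    ``decision_function`` returns the log posterior odds of MS and
    ``predict_proba`` the corresponding posteriors (empirical class priors).
    """

    def __init__(self, variance_threshold: float = 0.95, reg: float = 1e-8):
        self.variance_threshold = variance_threshold
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        t = _encode(y)
        if min((t == 0).sum(), (t == 1).sum()) < 2:
            raise ValueError("need >= 2 subjects per class")
        self.pca_ = PCA(svd_solver="full").fit(X)
        cum = np.cumsum(self.pca_.explained_variance_ratio_)
        self.n_components_ = int(np.searchsorted(cum, self.variance_threshold) + 1)
        self.n_components_ = min(self.n_components_, cum.size)
        scores = self.pca_.transform(X)[:, : self.n_components_]
        m0 = scores[t == 0].mean(axis=0)
        m1 = scores[t == 1].mean(axis=0)
        r0 = scores[t == 0] - m0
        r1 = scores[t == 1] - m1
        pooled = (r0.T @ r0 + r1.T @ r1) / (scores.shape[0] - 2)
        d = pooled.shape[0]
        # ridge scaled to the scatter; absolute floor covers zero scatter
        # (identical within-class rows, e.g. rank-1 noise-free data)
        ridge = self.reg * (np.trace(pooled) / d) if np.trace(pooled) > 0 else self.reg
        pooled = pooled + np.eye(d) * ridge
        try:
            cov_inv = np.linalg.inv(pooled)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular within-class covariance: {exc}")
        self.coef_ = cov_inv @ (m1 - m0)
        prior1 = t.mean()
        self.intercept_ = (
            -0.5 * (m1 + m0) @ self.coef_ + math.log(prior1 / (1.0 - prior1))
        )
        self.classes_ = np.array(["HC", "MS"])
        self.explained_variance_ = float(cum[self.n_components_ - 1])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        scores = self.pca_.transform(np.asarray(X, dtype=float))
        return scores[:, : self.n_components_] @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return np.where(self.decision_function(X) > 0, "MS", "HC")


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Partial least squares on a {0, 1} class code (PLS1, mean-centered,
    unscaled), thresholded at 0.5.  The continuous predicted response is the
    ranking score for ROC analysis.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        t = _encode(y)
        max_comp = min(X.shape[0] - 1, X.shape[1])
        if not 1 <= self.n_components <= max_comp:
            raise ValueError(
                f"n_components must be in [1, {max_comp}] for this data"
            )
        self.pls_ = PLSRegression(n_components=self.n_components, scale=False)
        self.pls_.fit(X, t)
        self.classes_ = np.array(["HC", "MS"])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel()

    def predict_proba(self, X):
        p1 = np.clip(self.decision_function(X), 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return np.where(self.decision_function(X) > 0.5, "MS", "HC")

    # -- pieces used by the importance profile --------------------------
    def component_coefficients(self) -> np.ndarray:
        """b_jh: variable j's regression-coefficient contribution from
        component h, shape (p, n_components); their sum over h is the full
        PLS coefficient vector."""
        check_is_fitted(self, "pls_")
        rot = self.pls_.x_rotations_            # (p, h)
        q = self.pls_.y_loadings_.ravel()       # (h,)
        return rot * q

    def response_ss_by_component(self) -> np.ndarray:
        """SSY_h: response sum of squares explained by each component."""
        check_is_fitted(self, "pls_")
        t_scores = self.pls_.x_scores_          # (n, h)
        q = self.pls_.y_loadings_.ravel()
        return (t_scores**2).sum(axis=0) * q**2


# ---------------------------------------------------------------------------
# Random forest with explicit OOB bookkeeping
# ---------------------------------------------------------------------------

class RandomForestOOBClassifier(BaseEstimator, ClassifierMixin):
    """Bagged CART trees with per-tree out-of-bag records.

    Trees are grown to purity with the Gini criterion, ``m_try`` candidate
    variables per split, on bootstrap samples drawn here (not inside
    scikit-learn) so each tree's out-of-bag subject indices are retained for
    OOB accuracy and permutation importance.  The MS score is the fraction
    of trees voting MS.
    """

    def __init__(self, m_try: int | None = None, n_trees: int = 500,
                 random_state: int = 0):
        self.m_try = m_try
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        t = _encode(y).astype(int)
        n, p = X.shape
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        m_try = self.m_try or max(1, round(math.sqrt(p)))
        if not 1 <= m_try <= p:
            raise ValueError(f"m_try must be in [1, {p}]")
        rng = np.random.default_rng(self.random_state)
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_indices_: list[np.ndarray] = []
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            seed = int(rng.integers(0, 2**31 - 1))
            tree = DecisionTreeClassifier(
                criterion="gini", max_features=m_try, random_state=seed
            ).fit(X[boot], t[boot])
            self.trees_.append(tree)
            self.oob_indices_.append(oob)
        self.m_try_ = m_try
        self.X_fit_ = X
        self.y_fit_ = t
        self.classes_ = np.array(["HC", "MS"])
        return self

    def _votes(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree in self.trees_:
            votes += tree.predict(X)
        return votes / len(self.trees_)

    def decision_function(self, X):
        return self._votes(X)

    def predict_proba(self, X):
        p1 = self._votes(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return np.where(self._votes(X) > 0.5, "MS", "HC")

    def oob_accuracy(self) -> float:
        """Out-of-bag accuracy from majority vote over each subject's
        OOB trees (subjects never OOB are skipped)."""
        check_is_fitted(self, "trees_")
        n = self.X_fit_.shape[0]
        votes = np.zeros(n)
        counts = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_indices_):
            if oob.size:
                votes[oob] += tree.predict(self.X_fit_[oob])
                counts[oob] += 1
        seen = counts > 0
        pred = (votes[seen] / counts[seen]) > 0.5
        return float((pred == (self.y_fit_[seen] == 1)).mean())


# ---------------------------------------------------------------------------
# split / CV / tuning protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Disjoint subject-level train/test partition."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test subject sets overlap")


@dataclass(frozen=True)
class CVScheme:
    k: int = 5
    repeats: int = 10
    seed: int = 0

    def splitter(self) -> RepeatedStratifiedKFold:
        return RepeatedStratifiedKFold(
            n_splits=self.k, n_repeats=self.repeats, random_state=self.seed
        )


@dataclass
class ModelSpec:
    """Which classifier to build and its tuning grid.

    method: 'pca_lda' (no grid; 0.95 variance threshold fixed),
    'pls_da' (grid over n_components) or 'rf' (grid over m_try).
    """

    method: str
    tuning_grid: tuple = ()
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pca_lda", "pls_da", "rf"):
            raise ValueError("method must be 'pca_lda', 'pls_da' or 'rf'")
        if self.method != "pca_lda" and not self.tuning_grid:
            raise ValueError(f"{self.method} needs a non-empty tuning grid")


@dataclass
class FittedClassifier:
    """A tuned, refit model plus its cross-validation trace."""

    method: str
    estimator: BaseEstimator
    chosen_tuning_value: object
    grid_mean_accuracy: dict
    cv_trace: list = field(default_factory=list)

    def predict(self, X):
        return self.estimator.predict(X)

    def decision_function(self, X):
        return self.estimator.decision_function(X)


def default_mtry_grid(p: int) -> tuple[int, ...]:
    """Forest tuning grid: sqrt(p) plus the region-typical larger value
    (35 for fingerprint-sized p, 165 for high-region-sized p)."""
    vals = {max(1, round(math.sqrt(p)))}
    if p >= 300:
        vals.add(35)
    elif p >= 165:
        vals.add(165)
    return tuple(sorted(vals))


def make_model(spec: ModelSpec, tuning_value=None) -> BaseEstimator:
    if spec.method == "pca_lda":
        return PCALDAClassifier()
    if spec.method == "pls_da":
        return PLSDAClassifier(n_components=int(tuning_value))
    return RandomForestOOBClassifier(
        m_try=int(tuning_value), n_trees=spec.n_trees, random_state=spec.seed
    )


def make_split(
    data: SpectraSet | None = None,
    *,
    subject_ids=None,
    class_labels=None,
    train_fraction: float = 0.75,
    stratified: bool = True,
    seed: int = 0,
) -> SplitPlan:
    """Stratified subject-level 75/25 split, deterministic under ``seed``.

    Accepts either a SpectraSet (replicates allowed; subjects are split, not
    rows) or explicit per-subject id/label arrays.
    """
    if data is not None:
        pairs = (
            data.meta[["subject_id", "class_label"]]
            .drop_duplicates("subject_id")
        )
        subject_ids = pairs["subject_id"].to_numpy()
        class_labels = pairs["class_label"].to_numpy()
    subject_ids = np.asarray(subject_ids)
    class_labels = np.asarray(class_labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    groups = (
        [(lab, subject_ids[class_labels == lab]) for lab in np.unique(class_labels)]
        if stratified
        else [("all", subject_ids)]
    )
    for lab, ids in groups:
        if ids.size < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 subjects")
        ids = ids.copy()
        rng.shuffle(ids)
        n_test = int(round((1.0 - train_fraction) * ids.size))
        n_test = min(max(n_test, 1), ids.size - 1)
        test.extend(ids[:n_test])
        train.extend(ids[n_test:])
    return SplitPlan(tuple(train), tuple(test), train_fraction, seed)


def _fold_metrics(est, X_val, y_val) -> dict:
    pred = est.predict(X_val)
    scores = est.decision_function(X_val)
    cm = confusion_from_predictions(y_val, pred)
    out = {"accuracy": (pred == y_val).mean()}
    try:
        sens, spec, _ = confusion_metrics(cm)
        out["sensitivity"], out["specificity"] = sens, spec
    except ValueError:
        out["sensitivity"] = out["specificity"] = np.nan
    try:
        out["auc"] = roc_auc(scores, y_val).auc
    except ValueError:
        out["auc"] = np.nan
    return out


def tune_and_refit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    spec: ModelSpec,
    cv: CVScheme | None = None,
    record_trace: bool = True,
) -> FittedClassifier:
    """Grid search by mean CV accuracy, then refit on the full training set.

    Every fold refits the estimator from scratch, so data-driven steps
    (centering, PCA, PLS deflation, tree growing) are re-estimated inside
    each fold.  Ties in mean accuracy break toward the smaller (simpler)
    tuning value.  With a single-value grid and ``record_trace=False`` the
    cross-validation loop is skipped entirely (used inside permutation
    nulls, where only the test accuracy matters).
    """
    cv = cv or CVScheme()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    grid = list(spec.tuning_grid) if spec.method != "pca_lda" else [None]
    y_bin = _encode(y_train)

    grid_acc: dict = {}
    fold_metrics: dict = {g: [] for g in grid}
    need_cv = record_trace or len(grid) > 1
    if need_cv:
        folds = list(cv.splitter().split(X_train, y_bin))
        for g in grid:
            for tr, va in folds:
                est = make_model(spec, g).fit(X_train[tr], y_train[tr])
                fold_metrics[g].append(_fold_metrics(est, X_train[va], y_train[va]))
            grid_acc[g] = float(
                np.mean([m["accuracy"] for m in fold_metrics[g]])
            )
        # argmax accuracy; ties -> smallest tuning value (grid order)
        best = max(grid, key=lambda g: (grid_acc[g],))
        for g in grid:
            if grid_acc[g] == grid_acc[best]:
                best = g
                break
    else:
        best = grid[0]
        grid_acc[best] = float("nan")
    final = make_model(spec, best).fit(X_train, y_train)
    return FittedClassifier(
        method=spec.method,
        estimator=final,
        chosen_tuning_value=best,
        grid_mean_accuracy=grid_acc,
        cv_trace=fold_metrics.get(best, []) if record_trace else [],
    )


# -- thin functional wrappers ------------------------------------------------

def fit_pca_lda(X, y, variance_threshold: float = 0.95) -> PCALDAClassifier:
    return PCALDAClassifier(variance_threshold=variance_threshold).fit(X, y)


def fit_pls_da(X, y, n_components: int) -> PLSDAClassifier:
    return PLSDAClassifier(n_components=n_components).fit(X, y)


def fit_rf(X, y, m_try: int | None = None, n_trees: int = 500,
           seed: int = 0) -> RandomForestOOBClassifier:
    return RandomForestOOBClassifier(
        m_try=m_try, n_trees=n_trees, random_state=seed
    ).fit(X, y)
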