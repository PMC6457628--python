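"""Feature selection and the PLS argmax classifier for volume-wise decoding.

Feature selection follows two routes:

* **PLS/sparse-PLS z-score rule** — fit a multi-response PLS of the dummy-coded
  task labels on all voxels, convert each column of the coefficient matrix
  ``B`` (p voxels x q tasks) to z scores, and keep the voxels with z > 3.5 for
  that task.  The union over tasks is the final feature set.
* **GLM t-test rule** — massively univariate OLS of each voxel's time course
  on the HRF-convolved task regressors plus an intercept; voxels whose t value
  for a task exceeds the one-sided p < 0.001 threshold are kept; union over
  tasks.

The classifier refits a PLS regression of the dummy-coded labels on the
selected voxels; a test volume is assigned to the task with the largest
predicted response score (argmax), and accuracy is the fraction of correctly
classified test volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .pls import LabelSet, PLSRegressor, dummy_code, select_n_components
from .sparse import SparsePLSRegressor

__all__ = [
    "NoFeaturesError",
    "NormalizedRun",
    "FeatureMask",
    "DecodingResult",
    "normalize_run",
    "zscore_columns",
    "select_features_z",
    "glm_t_maps",
    "select_features_glm",
    "PLSTaskClassifier",
    "TrainedClassifier",
    "train_plsr_classifier",
    "classify_volume",
    "score",
]

Z_THRESHOLD = 3.5  # the coefficient z-score cut for PLS-based selection
GLM_ALPHA = 0.001  # one-sided uncorrected p cut for GLM-based selection


class NoFeaturesError(RuntimeError):
    """No voxel survived selection; carries per-task max-statistic diagnostics."""

    def __init__(self, message, per_task_max=None):
        super().__init__(message)
        self.per_task_max = per_task_max


@dataclass
class NormalizedRun:
    """A run after the two-pass standardization, with exclusion bookkeeping.

    ``values`` keeps the original voxel count; excluded (zero-variance) voxel
    columns are set to 0 so that feature indices stay aligned across runs.
    """

    values: np.ndarray
    excluded_voxels: np.ndarray

    @property
    def n_volumes(self):
        return self.values.shape[0]

    @property
    def n_voxels(self):
        return self.values.shape[1]


def normalize_run(X) -> NormalizedRun:
    """Standardize each voxel time course, then each volume, in that order.

    Pass 1 maps every voxel's time course to zero mean / unit variance; pass 2
    does the same to every volume's spatial pattern.  Zero-variance voxels are
    excluded (zeroed, indices recorded) with a warning; a zero-variance volume
    after pass 1 is an error.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:  # time x height x width volumes
        X = X.reshape(X.shape[0], -1)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in run")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    excluded = np.flatnonzero(sd == 0)
    if excluded.size:
        warnings.warn(
            f"{excluded.size} constant voxel(s) excluded from normalization",
            UserWarning,
            stacklevel=2,
        )
    keep = sd > 0
    out = np.zeros_like(X)
    out[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    row_mu = out[:, keep].mean(axis=1)
    row_sd = out[:, keep].std(axis=1)
    if np.any(row_sd == 0):
        bad = np.flatnonzero(row_sd == 0)
        raise ValueError(f"volume(s) {bad.tolist()} have zero spatial variance")
    out[:, keep] = (out[:, keep] - row_mu[:, None]) / row_sd[:, None]
    return NormalizedRun(values=out, excluded_voxels=excluded)


def zscore_columns(B: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Per-column z scores (b - mean) / sd; sample sd (ddof=1) by default."""
    B = np.asarray(B, dtype=float)
    sd = B.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"column(s) {bad.tolist()} are constant; no z scores")
    return (B - B.mean(axis=0)) / sd


@dataclass
class FeatureMask:
    """Ordered voxel-index subset with per-task provenance."""

    voxel_indices: np.ndarray
    per_task_sources: dict = field(default_factory=dict)
    selector_name: str = ""
    threshold_used: float = float("nan")

    def __post_init__(self):
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if self.voxel_indices.size == 0:
            raise ValueError("empty feature mask")
        if len(np.unique(self.voxel_indices)) != self.voxel_indices.size:
            raise ValueError("duplicate voxel indices in mask")

    @property
    def size(self):
        return self.voxel_indices.size

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 1:
            return X[self.voxel_indices]
        return X[:, self.voxel_indices]


def _union_mask(per_task, selector_name, threshold, per_task_max):
    nonempty = {t: idx for t, idx in per_task.items() if idx.size}
    if not nonempty:
        raise NoFeaturesError(
            f"no features selected by {selector_name} at threshold {threshold}; "
            f"per-task max statistic: {per_task_max}",
            per_task_max=per_task_max,
        )
    union = np.unique(np.concatenate(list(nonempty.values())))
    return FeatureMask(
        voxel_indices=union,
        per_task_sources={t: idx.copy() for t, idx in per_task.items()},
        selector_name=selector_name,
        threshold_used=threshold,
    )


def select_features_z(
    B: np.ndarray,
    threshold: float = Z_THRESHOLD,
    selector_name: str = "plsr_z",
    fallback_top_m: int | None = None,
) -> FeatureMask:
    """Per task j: voxels with z(B[:, j]) strictly > threshold; union over tasks.

    ``fallback_top_m``, when given, keeps the top-m voxels per task instead of
    erroring if the union would be empty.
    """
    z = zscore_columns(B)
    per_task = {j + 1: np.flatnonzero(z[:, j] > threshold) for j in range(z.shape[1])}
    per_task_max = {j + 1: float(z[:, j].max()) for j in range(z.shape[1])}
    try:
        return _union_mask(per_task, selector_name, threshold, per_task_max)
    except NoFeaturesError:
        if fallback_top_m is None:
            raise
        per_task = {
            j + 1: np.argsort(z[:, j])[::-1][:fallback_top_m]
            for j in range(z.shape[1])
        }
        return _union_mask(per_task, selector_name + "_topm", threshold, per_task_max)


def glm_t_maps(X, design: np.ndarray) -> tuple[np.ndarray, int]:
    """Voxel-wise OLS t statistics for each task regressor.

    Parameters
    ----------
    X : (n, p) run (normalized or raw) — one column per voxel.
    design : (n, q) HRF-convolved task regressors; an intercept column is
        appended internally.

    Returns
    -------
    t : (p, q) t statistics (coefficient / standard error) per task regressor.
    df : residual degrees of freedom, n - rank(design + intercept).
    """
    if hasattr(X, "values"):
        X = X.values
    X = np.asarray(X, dtype=float)
    design = np.asarray(design, dtype=float)
    n = X.shape[0]
    D = np.column_stack([design, np.ones(n)])
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError("rank-deficient design matrix")
    dtd_inv = np.linalg.inv(D.T @ D)
    beta = dtd_inv @ D.T @ X  # (q+1, p)
    resid = X - D @ beta
    df = n - rank
    sigma2 = (resid**2).sum(axis=0) / df
    q = design.shape[1]
    se = np.sqrt(np.outer(np.diag(dtd_inv)[:q], sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:q] / se, 0.0)
    return t.T, df


def select_features_glm(
    t_maps: np.ndarray, df: int, alpha: float = GLM_ALPHA
) -> FeatureMask:
    """Per task: voxels with one-sided p < alpha (positive activation); union."""
    t_maps = np.asarray(t_maps, dtype=float)
    p = stats.t.sf(t_maps, df)
    per_task = {
        j + 1: np.flatnonzero(p[:, j] < alpha) for j in range(t_maps.shape[1])
    }
    per_task_max = {j + 1: float(t_maps[:, j].max()) for j in range(t_maps.shape[1])}
    return _union_mask(per_task, "glm_t", alpha, per_task_max)


class PLSTaskClassifier(ClassifierMixin, BaseEstimator):
    """Multiclass classifier: PLS regression on dummy labels + argmax readout.

    Parameters
    ----------
    n_components : int or "cv"
        Latent components of the underlying PLS fit; ``"cv"`` picks K by
        stratified cross-validation (grid 1..min(max_components, n-1, p)).
    sparse_alpha : float, default=0.0
        If > 0, the underlying fit is the sparse (soft-thresholded) PLS.
    cv, max_components, random_state : CV controls for ``n_components="cv"``.

    A test sample is assigned the class whose predicted response score is
    largest; exact ties go to the smallest class index and are counted in
    ``tie_count_``.
    """

    def __init__(self, n_components="cv", sparse_alpha: float = 0.0,
                 cv: int = 5, max_components: int = 10, random_state: int = 0):
        self.n_components = n_components
        self.sparse_alpha = sparse_alpha
        self.cv = cv
        self.max_components = max_components
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        codes = np.searchsorted(self.classes_, y) + 1  # 1..q
        q = self.classes_.size
        if self.n_components == "cv":
            grid = range(1, min(self.max_components, X.shape[0] - 1, X.shape[1]) + 1)
            k, self.cv_table_ = select_n_components(
                X, codes, k_grid=list(grid), folds=self.cv, seed=self.random_state
            )
        else:
            k = int(self.n_components)
        Y = dummy_code(codes, q)
        cls = (
            SparsePLSRegressor(n_components=k, alpha=self.sparse_alpha)
            if self.sparse_alpha > 0
            else PLSRegressor(n_components=k)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            self.pls_ = cls.fit(X, Y)
        self.n_components_ = self.pls_.n_components_
        self.tie_count_ = 0
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict(X)

    def predict(self, X):
        scores = self.decision_function(X)
        best = np.argmax(scores, axis=1)  # first max -> smallest class index
        ties = (scores == scores.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            self.tie_count_ += int(ties.sum())
            warnings.warn(
                f"{int(ties.sum())} argmax tie(s); assigned smallest task index",
                UserWarning,
                stacklevel=2,
            )
        return self.classes_[best]


@dataclass
class TrainedClassifier:
    """A fitted PLS argmax classifier bound to the feature mask that fed it."""

    model: PLSTaskClassifier
    mask: FeatureMask
    task_names: list

    def predict(self, X_full):
        """Classify volumes given in the full (unmasked) voxel geometry."""
        return self.model.predict(self.mask.apply(np.atleast_2d(X_full)))

    def decision_function(self, X_full):
        return self.model.decision_function(self.mask.apply(np.atleast_2d(X_full)))


def train_plsr_classifier(
    train, labels, mask: FeatureMask, n_components="cv", random_state: int = 0,
    task_names=None,
) -> TrainedClassifier:
    """Fit the argmax PLS classifier on the masked columns of the training run."""
    X = train.values if hasattr(train, "values") else np.asarray(train, dtype=float)
    y = labels.labels if isinstance(labels, LabelSet) else np.asarray(labels)
    clf = PLSTaskClassifier(
        n_components=n_components, random_state=random_state
    ).fit(mask.apply(X), y)
    if task_names is None:
        task_names = [str(c) for c in clf.classes_]
    return TrainedClassifier(model=clf, mask=mask, task_names=list(task_names))


def classify_volume(clf: TrainedClassifier, volume: np.ndarray):
    """Classify one full-geometry volume; returns (task, score vector)."""
    volume = np.asarray(volume, dtype=float)
    if not np.all(np.isfinite(volume)):
        raise ValueError("non-finite values in volume")
    scores = clf.decision_function(volume)[0]
    return clf.predict(volume)[0], scores


@dataclass
class DecodingResult:
    """Predictions vs truth with exact accuracy R = M / N."""

    predicted: np.ndarray
    truth: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted)
        self.truth = np.asarray(self.truth)
        if self.predicted.shape != self.truth.shape:
            raise ValueError("predictions and truth have different lengths")
        if self.predicted.size == 0:
            raise ValueError("empty result")

    @property
    def n_correct(self) -> int:
        return int(np.sum(self.predicted == self.truth))

    @property
    def n_total(self) -> int:
        return int(self.predicted.size)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def score(predictions, truth, **info) -> DecodingResult:
    """Wrap predictions and truth into a :class:`DecodingResult`."""
    return DecodingResult(predicted=predictions, truth=truth, info=info)
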