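"""Multi-response partial least squares regression (NIPALS, projection deflation).

The estimator here extracts latent components sequentially: at stage ``k`` the
direction vector ``r_k`` maximizes ``r' Z_k' Z_k r`` subject to ``||r|| = 1``,
where ``Z_k = Y_k' X_k`` is the cross-covariance of the current residuals and
the residuals are the projections of the centered data onto the orthogonal
complement of the accumulated score matrix ``T``.  The direction matrix that
maps centered predictors straight to scores is recovered as
``W = R (G' R)^{-1}`` with ``G = X' T (T' T)^{-1}``, so that ``T = X_c W`` and
the coefficient matrix is ``B = W Q_Y'`` with ``Q_Y`` the response loadings.

This handles p >> n gracefully: every dense decomposition is on a q x q
matrix (q = number of responses), never p x p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DataMatrix",
    "LabelSet",
    "ComponentExhausted",
    "center_columns",
    "dummy_code",
    "nipals_direction",
    "PLSRegressor",
    "fit_plsr",
    "select_n_components",
]

# relative magnitude below which a cross-covariance is "numerically zero"
_ZTOL = 1e-12


class ComponentExhausted(Exception):
    """Raised internally when no further latent component exists (Z ~ 0)."""


@dataclass
class DataMatrix:
    """An n x p data matrix (volumes x voxels) with stored centering offsets.

    ``column_means`` is None until :func:`center_columns` is applied.
    """

    values: np.ndarray
    column_means: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DataMatrix contains non-finite entries")
        if self.n_volumes < 2 or self.n_voxels < 1:
            raise ValueError("DataMatrix requires n >= 2 volumes and p >= 1 voxels")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelSet:
    """Per-volume task labels (1..q) and their dummy-coded indicator matrix."""

    labels: np.ndarray
    q: int
    indicator: np.ndarray = field(init=False)
    column_means: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.indicator = dummy_code(self.labels, self.q)


def center_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center every column to zero mean; return (centered, offsets)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("cannot center an empty matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite entries; centering refused")
    offsets = matrix.mean(axis=0)
    return matrix - offsets, offsets


def dummy_code(labels: np.ndarray, q: int) -> np.ndarray:
    """0/1 indicator matrix for labels in 1..q; every class must appear.

    Entry (i, j) is 1 iff sample i belongs to class j+1; each row sums to 1.
    """
    labels = np.asarray(labels, dtype=int)
    if q < 2:
        raise ValueError("dummy coding requires q >= 2 classes")
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty 1-D sequence")
    if labels.min() < 1 or labels.max() > q:
        raise ValueError(f"labels must lie in 1..{q}")
    if len(np.unique(labels)) != q:
        missing = sorted(set(range(1, q + 1)) - set(labels.tolist()))
        raise ValueError(f"classes {missing} have no samples (degenerate regression)")
    out = np.zeros((labels.size, q))
    out[np.arange(labels.size), labels - 1] = 1.0
    return out


def nipals_direction(x_resid: np.ndarray, y_resid: np.ndarray) -> np.ndarray:
    """Unit-norm direction maximizing r' Z'Z r for Z = Y_resid' X_resid.

    Computed as the dominant right singular vector of Z via the q x q Gram
    matrix Z Z' (q is small).  Sign fixed so the largest-magnitude entry is
    positive.  Raises :class:`ComponentExhausted` when Z is numerically zero.
    """
    z = y_resid.T @ x_resid
    scale = np.abs(z).max(initial=0.0)
    if scale <= _ZTOL:
        raise ComponentExhausted("cross-covariance is numerically zero")
    gram = z @ z.T
    evals, evecs = linalg.eigh(gram)
    u = evecs[:, -1]
    r = z.T @ u
    nrm = np.linalg.norm(r)
    if nrm <= _ZTOL * scale:
        raise ComponentExhausted("degenerate dominant direction")
    r = r / nrm
    i = np.argmax(np.abs(r))
    if r[i] < 0:
        r = -r
    return r


class PLSRegressor(RegressorMixin, BaseEstimator):
    """Partial least squares regression via projection-deflation NIPALS.

    Parameters
    ----------
    n_components : int, default=2
        Number of latent components K (1 <= K <= min(n-1, p)).  If the
        cross-covariance is exhausted earlier, the model keeps the components
        found and warns.

    Attributes
    ----------
    x_weights_ : (p, K) ndarray
        Raw unit-norm direction vectors R = (r_1, ..., r_K).
    directions_ : (p, K) ndarray
        W = R (G'R)^{-1}; satisfies scores_ = X_centered @ directions_.
    scores_ : (n, K) ndarray
        Latent scores T, mutually orthogonal columns.
    x_loadings_, y_loadings_ : (p, K), (q, K) ndarrays
        Q_X (= G) and Q_Y from regressing X and Y on T.
    coef_ : (p, q) ndarray
        B = W Q_Y'; prediction is (X - x_mean_) @ coef_ + y_mean_.
    n_components_ : int
        Components actually extracted.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    # -- direction extraction, overridden by the sparse subclass ------------
    def _direction(self, x_resid, y_resid, component):
        return nipals_direction(x_resid, y_resid)

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and Y have different numbers of samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("non-finite values in X or Y")
        k_max = min(n - 1, p)
        K = int(self.n_components)
        if not 1 <= K <= k_max:
            raise ValueError(f"n_components must be in 1..{k_max}, got {K}")

        Xc, self.x_mean_ = center_columns(X)
        Yc, self.y_mean_ = center_columns(Y)
        xk, yk = Xc.copy(), Yc.copy()

        rs, ts = [], []
        for k in range(K):
            try:
                r = self._direction(xk, yk, k)
            except ComponentExhausted as exc:
                if k == 0:
                    raise ValueError(f"no extractable component: {exc}") from exc
                warnings.warn(
                    f"component extraction exhausted after {k} of {K} components "
                    f"({exc}); returning a smaller model",
                    UserWarning,
                    stacklevel=2,
                )
                break
            t = xk @ r
            tt = t @ t
            if tt <= _ZTOL:
                if k == 0:
                    raise ValueError("first score vector is numerically zero")
                warnings.warn(
                    f"zero score at component {k + 1}; returning {k} components",
                    UserWarning,
                    stacklevel=2,
                )
                break
            rs.append(r)
            ts.append(t)
            # projection deflation: scores are orthogonal, so subtracting the
            # rank-1 projection of the newest score equals (I - P_T) overall
            xk = xk - np.outer(t, t @ xk) / tt
            yk = yk - np.outer(t, t @ yk) / tt

        R = np.column_stack(rs)
        T = np.column_stack(ts)
        self._finalize(Xc, Yc, R, T)
        return self

    def _finalize(self, Xc, Yc, R, T):
        K = T.shape[1]
        tt = T.T @ T
        G = linalg.solve(tt, T.T @ Xc, assume_a="pos").T  # X' T (T'T)^-1
        QY = linalg.solve(tt, T.T @ Yc, assume_a="pos").T
        M = G.T @ R
        try:
            W = linalg.solve(M.T, R.T).T  # R @ inv(M)
        except linalg.LinAlgError as exc:
            raise ValueError(f"singular G'R matrix; cannot assemble W: {exc}") from exc
        self.x_weights_ = R
        self.directions_ = W
        self.scores_ = T
        self.x_loadings_ = G
        self.y_loadings_ = QY
        self.coef_ = W @ QY.T
        self.n_components_ = K
        # cached for coefficient truncation (cheap prefix re-assembly in CV)
        self._Xc_T_T = Xc.T @ T
        self._Yc_T_T = Yc.T @ T
        self._tt = tt

    def coef_for(self, k: int) -> np.ndarray:
        """Coefficient matrix of the model truncated to its first ``k`` components."""
        check_is_fitted(self, "coef_")
        if not 1 <= k <= self.n_components_:
            raise ValueError(f"k must be in 1..{self.n_components_}")
        if k == self.n_components_:
            return self.coef_
        tt = self._tt[:k, :k]
        G = linalg.solve(tt, self._Xc_T_T[:, :k].T, assume_a="pos").T
        QY = linalg.solve(tt, self._Yc_T_T[:, :k].T, assume_a="pos").T
        R = self.x_weights_[:, :k]
        W = linalg.solve((G.T @ R).T, R.T).T
        return W @ QY.T

    def predict(self, X, n_components: int | None = None):
        """Predicted response scores (X - x_mean_) B + y_mean_; no thresholding."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.coef_.shape[0]}"
            )
        B = self.coef_ if n_components is None else self.coef_for(n_components)
        return (X - self.x_mean_) @ B + self.y_mean_


def fit_plsr(X, Y, n_components: int) -> PLSRegressor:
    """Functional wrapper: fit a :class:`PLSRegressor` and return it."""
    X = X.values if isinstance(X, DataMatrix) else X
    Y = Y.indicator if isinstance(Y, LabelSet) else Y
    return PLSRegressor(n_components=n_components).fit(X, Y)


def select_n_components(
    X,
    labels,
    k_grid=None,
    folds: int = 5,
    seed: int = 0,
):
    """Stratified-CV choice of the number of latent components.

    The loss is the mean squared error between the predicted response scores
    and the 0/1 indicator matrix of the held-out volumes; ties break toward
    the smaller K.

    Returns
    -------
    best_k : int
    table : pandas.DataFrame with columns ``n_components`` and ``cv_mse``.
    """
    import pandas as pd

    X = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if isinstance(labels, LabelSet):
        labels = labels.labels
    labels = np.asarray(labels, dtype=int)
    q = int(labels.max())
    n, p = X.shape
    if k_grid is None:
        k_grid = list(range(1, min(10, n - 1, p) + 1))
    k_grid = sorted(int(k) for k in k_grid)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(labels)[1:]
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify into "
            f"{folds} folds"
        )
    k_hi = max(k_grid)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(len(k_grid))
    n_val = 0
    for tr, va in skf.split(X, labels):
        Ytr = dummy_code(labels[tr], q)
        k_fit = min(k_hi, len(tr) - 1, p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = PLSRegressor(n_components=k_fit).fit(X[tr], Ytr)
        Yva = dummy_code(labels[va], q)
        for i, k in enumerate(k_grid):
            pred = model.predict(X[va], n_components=min(k, model.n_components_))
            sse[i] += np.sum((pred - Yva) ** 2)
        n_val += va.size * q
    mse = sse / n_val
    best_k = k_grid[int(np.argmin(mse))]  # argmin takes the first (smallest K) on ties
    table = pd.DataFrame({"n_components": k_grid, "cv_mse": mse})
    return best_k, table
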