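"""Sparse PLS direction estimation by coordinate-wise soft thresholding.

Each direction vector solves, coordinate by coordinate,

    minimize_r  sum_j [ 1/2 ||Z_j - C r_j||^2 + lambda |r_j| ]

where ``Z = Y_resid' X_resid`` (q x p) is the current cross-covariance and
``C = Y_resid' t`` (q-vector) the covariate built from the current score.
The problem is separable, with the closed-form minimizer

    r_j = soft(C'Z_j, lambda) / (C'C),    soft(a, l) = sign(a) max(|a|-l, 0).

Because the score t itself depends on r, the direction is found by a short
fixed-point iteration started at the unpenalized (dense) direction; with
lambda = 0 the starting point is already the fixed point, so the sparse model
reduces exactly to the plain PLS fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pls import (
    ComponentExhausted,
    DataMatrix,
    LabelSet,
    PLSRegressor,
    center_columns,
    dummy_code,
    nipals_direction,
)

__all__ = [
    "SparseDirectionProblem",
    "soft_threshold",
    "soft_threshold_direction",
    "SparsePLSRegressor",
    "fit_splsr",
    "tune_lambda",
    "first_stage_lambda_max",
    "default_lambda_grid",
]


@dataclass
class SparseDirectionProblem:
    """One stage of the penalized direction problem: Z (q x p), C (q,), lambda."""

    Z: np.ndarray
    C: np.ndarray
    lam: float

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        self.C = np.asarray(self.C, dtype=float).ravel()
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not self.C @ self.C > 0:
            raise ValueError("covariate C is all zero")


def soft_threshold(a, lam: float):
    """sign(a) * max(|a| - lam, 0), elementwise; exact zeros inside the band."""
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def soft_threshold_direction(problem: SparseDirectionProblem) -> np.ndarray:
    """Closed-form coordinate-wise minimizer, rescaled to unit norm.

    Raises :class:`ComponentExhausted` when every coordinate shrinks to zero
    ("empty direction"); the caller decides whether to stop adding components
    or lower lambda.
    """
    cc = problem.C @ problem.C
    r = soft_threshold(problem.C @ problem.Z, problem.lam) / cc
    nrm = np.linalg.norm(r)
    if nrm == 0.0:
        raise ComponentExhausted("empty direction: every coordinate thresholded to 0")
    r = r / nrm
    i = np.argmax(np.abs(r))
    if r[i] < 0:
        r = -r
    return r


class SparsePLSRegressor(PLSRegressor):
    """PLS regression with l1-penalized (soft-thresholded) direction vectors.

    Identical pipeline to :class:`PLSRegressor` — same projection deflation,
    same ``W = R (G'R)^{-1}`` assembly, same coefficients — with the dense
    NIPALS direction replaced by the sparse fixed point.

    Parameters
    ----------
    n_components : int
        Latent components requested; extraction stops early (with a warning)
        if a direction empties out at some stage.
    alpha : float, default=0.0
        The l1 penalty lambda, shared across components.  ``alpha=0``
        reproduces :class:`PLSRegressor` exactly.
    max_iter, tol : fixed-point iteration controls.

    Attributes (in addition to the parent's)
    ----------
    support_ : list of int ndarrays
        Per-component indices of nonzero direction coordinates.
    """

    def __init__(self, n_components: int = 2, alpha: float = 0.0,
                 max_iter: int = 100, tol: float = 1e-10):
        super().__init__(n_components=n_components)
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol

    def _direction(self, x_resid, y_resid, component):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        r = nipals_direction(x_resid, y_resid)  # raises if Z ~ 0
        if self.alpha == 0:
            return r
        z = y_resid.T @ x_resid
        for _ in range(self.max_iter):
            # C = Y_resid' t = Y_resid' X_resid r = Z r, so the whole fixed
            # point runs on the small q x p cross-covariance
            c = z @ r
            if not c @ c > 0:
                raise ComponentExhausted("covariate C vanished")
            try:
                r_new = soft_threshold_direction(
                    SparseDirectionProblem(Z=z, C=c, lam=self.alpha)
                )
            except ComponentExhausted:
                if component == 0:
                    raise ComponentExhausted(
                        "lambda too large: first direction is empty"
                    ) from None
                raise
            if np.linalg.norm(r_new - r) < self.tol:
                r = r_new
                break
            r = r_new
        return r

    def fit(self, X, Y):
        self._supports = []
        try:
            super().fit(X, Y)
        except ValueError as exc:
            if "no extractable component" in str(exc):
                raise ValueError(f"lambda too large for any component: {exc}") from exc
            raise
        self.support_ = [np.flatnonzero(self.x_weights_[:, k])
                         for k in range(self.n_components_)]
        if any(s.size == 0 for s in self.support_):  # pragma: no cover - guarded above
            raise RuntimeError("retained component with empty support")
        return self


def fit_splsr(X, Y, n_components: int, alpha: float, **kw) -> SparsePLSRegressor:
    """Functional wrapper over :class:`SparsePLSRegressor`."""
    X = X.values if isinstance(X, DataMatrix) else X
    Y = Y.indicator if isinstance(Y, LabelSet) else Y
    return SparsePLSRegressor(n_components=n_components, alpha=alpha, **kw).fit(X, Y)


def first_stage_lambda_max(X, Y) -> float:
    """max_j |C'Z_j| at the first stage (smallest lambda emptying the direction)."""
    X = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    Y = Y.indicator if isinstance(Y, LabelSet) else np.asarray(Y, dtype=float)
    xc, _ = center_columns(X)
    yc, _ = center_columns(Y)
    z = yc.T @ xc
    r0 = nipals_direction(xc, yc)
    c = yc.T @ (xc @ r0)
    return float(np.abs(c @ z).max())


def default_lambda_grid(X, Y, n_points: int = 21) -> np.ndarray:
    """{0} plus a geometric ladder up to just below the first-stage lambda_max."""
    lam_max = first_stage_lambda_max(X, Y)
    grid = np.geomspace(1e-3 * lam_max, 0.99 * lam_max, n_points - 1)
    return np.concatenate([[0.0], grid])


def tune_lambda(
    X,
    labels,
    n_components: int,
    lambda_grid=None,
    folds: int = 5,
    seed: int = 0,
):
    """Cross-validated choice of the shared l1 penalty.

    Loss: mean squared error between predicted response scores and the 0/1
    indicator of held-out volumes; ties break toward the *larger* lambda
    (prefer the sparser model).  Grid points whose first direction empties on
    some fold score infinity.

    Returns
    -------
    best_lambda : float
    table : pandas.DataFrame with columns ``lam`` and ``cv_mse``.
    """
    import pandas as pd
    from sklearn.model_selection import StratifiedKFold

    X = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if isinstance(labels, LabelSet):
        labels = labels.labels
    labels = np.asarray(labels, dtype=int)
    q = int(labels.max())
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if lambda_grid is None:
        Y_full = dummy_code(labels, q)
        lambda_grid = default_lambda_grid(X, Y_full)
    lambda_grid = np.asarray(sorted(float(l) for l in lambda_grid))
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(lambda_grid.size)
    n_val = 0
    for tr, va in skf.split(X, labels):
        Ytr = dummy_code(labels[tr], q)
        Yva = dummy_code(labels[va], q)
        k_fit = min(n_components, len(tr) - 1, X.shape[1])
        for i, lam in enumerate(lambda_grid):
            if not np.isfinite(sse[i]):
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    model = SparsePLSRegressor(
                        n_components=k_fit, alpha=lam
                    ).fit(X[tr], Ytr)
                sse[i] += np.sum((model.predict(X[va]) - Yva) ** 2)
            except ValueError:
                sse[i] = np.inf
        n_val += va.size * q
    mse = sse / n_val
    if not np.any(np.isfinite(mse)):
        raise ValueError("every lambda on the grid empties the first direction")
    best = np.flatnonzero(mse == np.nanmin(np.where(np.isfinite(mse), mse, np.nan)))
    best_lambda = float(lambda_grid[best.max()])  # ties -> larger lambda
    table = pd.DataFrame({"lam": lambda_grid, "cv_mse": mse})
    return best_lambda, table
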