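"""PLS1 regression, k-fold cross-validation and calibration metrics.

The latent-variable kernel is a NIPALS PLS1 written so that one pass at
``max_factors`` components yields the regression coefficient vector for
*every* intermediate component count.  Cross-validating the factor count
then costs one decomposition per fold instead of one per (fold, count)
pair, which is what makes the bootstrap loop in :mod:`bosspls.boss`
affordable: it cross-validates thousands of sub-models per run.

For a single response NIPALS and SIMPLS coincide to numerical precision;
the test-suite cross-checks the kernel against scikit-learn's
``PLSRegression``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CVConfig",
    "MetricReport",
    "PLS1",
    "fit_pls",
    "predict",
    "make_folds",
    "rmsecv",
    "rmsecv_curve",
    "rmsep",
    "r_squared",
    "select_n_factors",
]

_EPS = 1e-12


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings for factor selection and RMSECV.

    Five shuffled folds and a cap of 15 latent factors are the defaults
    used throughout the pipeline.
    """

    n_folds: int = 5
    seed: int = 0
    max_factors: int = 15

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.max_factors < 1:
            raise ValueError(f"max_factors must be >= 1, got {self.max_factors}")


@dataclass(frozen=True)
class MetricReport:
    """Calibration/validation figures of merit for one PLS model."""

    rmsecv: float
    rmsep: float
    r2_calibration: float
    r2_validation: float
    n_factors: int
    n_variables: int = 0

    def as_dict(self) -> dict:
        return {
            "rmsecv": self.rmsecv,
            "rmsep": self.rmsep,
            "r2_calibration": self.r2_calibration,
            "r2_validation": self.r2_validation,
            "n_factors": self.n_factors,
            "n_variables": self.n_variables,
        }


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D spectra matrix, got ndim={X.ndim}")
    return X


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_factors: int):
    """NIPALS decomposition of mean-centred data.

    Returns weight matrix W (p, a), loading matrix P (p, a) and y-loadings
    q (a,) for ``a <= n_factors`` effective components.  Extraction stops
    early when the covariance weight vector underflows (rank exhausted).
    """
    n, p = Xc.shape
    Xd = Xc.copy()
    yd = yc.copy()
    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    q = np.empty(n_factors)
    scale0 = None
    a = 0
    for a in range(n_factors):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if scale0 is None:
            scale0 = max(nw, _EPS)
        if nw <= _EPS * scale0 or nw == 0.0:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        pvec = (Xd.T @ t) / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd -= qa * t
        W[:, a] = w
        P[:, a] = pvec
        q[a] = qa
    else:
        a = n_factors
        return W, P, q
    return W[:, :a], P[:, :a], q[:a]


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray, n_factors: int) -> np.ndarray:
    """Coefficient vectors b_a for component counts 1..n_factors, shape (p, n_factors).

    When fewer effective components exist, the path is padded with the last
    attainable coefficient vector (adding exhausted components does not
    change the fit).
    """
    p = W.shape[0]
    a_eff = W.shape[1]
    B = np.zeros((p, n_factors))
    if a_eff == 0:
        return B
    PtW = P.T @ W
    for a in range(1, a_eff + 1):
        B[:, a - 1] = W[:, :a] @ np.linalg.solve(PtW[:a, :a], q[:a])
    if a_eff < n_factors:
        B[:, a_eff:] = B[:, a_eff - 1 : a_eff]
    return B


class PLS1(RegressorMixin, BaseEstimator):
    """Single-response partial least-squares regression.

    Parameters
    ----------
    n_factors : int
        Number of latent variables to extract.  If the data run out of
        rank earlier, the effective count is reduced with a warning.

    Attributes
    ----------
    x_mean_ : ndarray of shape (p,)
        Column means removed before projection.
    y_mean_ : float
        Response mean.
    coef_ : ndarray of shape (p,)
        Regression coefficients in centred space:
        ``y_hat = (X - x_mean_) @ coef_ + y_mean_``.
    n_factors_ : int
        Effective number of latent variables used.
    """

    def __init__(self, n_factors: int = 2):
        self.n_factors = n_factors

    def fit(self, X, y):
        X = _as_2d(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y have incompatible shapes")
        if self.n_factors < 1:
            raise ValueError(f"n_factors must be >= 1, got {self.n_factors}")
        cap = min(n - 1, p)
        if self.n_factors > cap:
            raise ValueError(
                f"n_factors={self.n_factors} exceeds min(N-1, P)={cap}"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        W, P, q = _nipals_pls1(X - self.x_mean_, y - self.y_mean_, self.n_factors)
        a_eff = W.shape[1]
        if a_eff < self.n_factors:
            warnings.warn(
                f"rank exhausted after {a_eff} of {self.n_factors} requested "
                "latent factors; using the reduced count",
                stacklevel=2,
            )
        self.n_factors_ = max(a_eff, 0)
        B = _coef_path(W, P, q, max(self.n_factors, 1))
        self.coef_ = B[:, max(self.n_factors, 1) - 1]
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = _as_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was fitted with "
                f"{self.n_features_in_}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


def fit_pls(X, y, n_factors: int) -> PLS1:
    """Fit a PLS1 model; thin wrapper over :class:`PLS1`."""
    return PLS1(n_factors=n_factors).fit(X, y)


def predict(model: PLS1, X) -> np.ndarray:
    return model.predict(X)


def make_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle, then contiguous near-equal blocks."""
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"need 2 <= n_folds <= N, got n_folds={n_folds}, N={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def _cv_press(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray], max_a: int) -> np.ndarray:
    """Sum of squared out-of-fold residuals per component count 1..max_a."""
    n = len(y)
    press = np.zeros(max_a)
    mask = np.ones(n, dtype=bool)
    for fold in folds:
        mask[:] = True
        mask[fold] = False
        Xtr, ytr = X[mask], y[mask]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        W, P, q = _nipals_pls1(Xtr - xm, ytr - ym, max_a)
        B = _coef_path(W, P, q, max_a)
        pred = (X[fold] - xm) @ B + ym  # (n_fold, max_a)
        press += ((pred - y[fold][:, None]) ** 2).sum(axis=0)
    return press


def rmsecv_curve(X, y, cv: CVConfig, folds: list[np.ndarray] | None = None) -> np.ndarray:
    """RMSECV for every factor count 1..A, A capped by fold size and P."""
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if folds is None:
        folds = make_folds(n, cv.n_folds, cv.seed)
    min_train = n - max(len(f) for f in folds)
    if min_train < 1:
        raise ValueError("a fold leaves no training samples")
    max_a = min(cv.max_factors, p, min_train - 1)
    max_a = max(max_a, 1)
    press = _cv_press(X, y, folds, max_a)
    return np.sqrt(press / n)


def rmsecv(X, y, n_factors: int, cv: CVConfig, folds: list[np.ndarray] | None = None) -> float:
    """Root-mean-square error of k-fold cross validation at one factor count.

    Out-of-fold predictions for all N samples are pooled:
    ``sqrt(sum_i (y_i - yhat_{\\i})^2 / N)``.  ``n_folds = N`` gives exact
    leave-one-out.
    """
    curve = rmsecv_curve(X, y, cv, folds=folds)
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    idx = min(n_factors, len(curve)) - 1
    return float(curve[idx])


def rmsep(y_true, y_pred) -> float:
    """Root-mean-square error of prediction on an independent set."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot <= 0.0:
        raise ValueError("y_true is constant; R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def select_n_factors(
    X, y, cv: CVConfig, folds: list[np.ndarray] | None = None
) -> tuple[int, float]:
    """Factor count minimising RMSECV; ties broken toward fewer factors.

    Returns ``(n_factors, rmsecv_at_choice)``.
    """
    curve = rmsecv_curve(X, y, cv, folds=folds)
    best = int(np.argmin(curve))  # first occurrence == fewest factors on ties
    return best + 1, float(curve[best])
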