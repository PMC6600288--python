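"""Bootstrapping soft shrinkage (BOSS) wavenumber selection.

BOSS is a model-population-analysis selector.  Each iteration draws K
variable subsets by bootstrap sampling in *variable space* (draws with
replacement, keeping the distinct indices), fits a cross-validated PLS
sub-model on every subset, extracts the best 10 % of sub-models by
RMSECV, and turns their regression coefficients into per-variable
sampling weights

    w_i = sum_k |b|_{i,k}

where |b|_{i,k} is the absolute value of sub-model k's unit-length
(l2-normalised) coefficient vector at variable i, taken as 0 when the
variable is absent from the sub-model.  The next iteration draws with
probability proportional to w (weighted bootstrap sampling), using a
draw count equal to the rounded mean subset size of the extracted
sub-models.  Variables missing from every extracted sub-model get weight
zero and can never re-enter — soft shrinkage: weights fade, nothing is
deleted outright while it retains any weight.  The loop ends when the
draw count reaches one, and the returned subset is the best sub-model's
variable set at the iteration chosen from the RMSECV trajectory (first
local minimum by default; global minimum optionally).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .pls import CVConfig, PLS1, make_folds, select_n_factors

__all__ = [
    "BossConfig",
    "SubModel",
    "BossIterationRecord",
    "BossResult",
    "draw_subsets",
    "fit_submodels",
    "select_top",
    "update_weights",
    "next_n_draws",
    "run_boss",
    "BossPLS",
]


@dataclass(frozen=True)
class BossConfig:
    """Settings for one BOSS run.

    n_subsets        : K, bootstrap subsets per iteration (default 1000).
    top_fraction     : fraction of sub-models extracted each iteration.
    cv               : cross-validation settings for every sub-model.
    subset_choice_rule : "first_local_min" (default) or "global_min" on
                       the per-iteration best-RMSECV trajectory.
    draw_count_over  : population whose mean subset size sets the next
                       draw count — "top" (the extracted sub-models,
                       default) or "all" (all K sub-models).
    seed             : seed for all sampling in the run.
    max_iterations   : safety bound on the shrinkage loop.
    """

    n_subsets: int = 1000
    top_fraction: float = 0.10
    cv: CVConfig = field(default_factory=CVConfig)
    subset_choice_rule: str = "first_local_min"
    draw_count_over: str = "top"
    seed: int = 0
    max_iterations: int = 500

    def __post_init__(self) -> None:
        if self.n_subsets < 10:
            raise ValueError("n_subsets must be >= 10")
        if not 0.0 < self.top_fraction < 1.0:
            raise ValueError("top_fraction must lie in (0, 1)")
        if self.n_subsets * self.top_fraction < 1.0:
            raise ValueError("n_subsets * top_fraction must be >= 1")
        if self.subset_choice_rule not in ("first_local_min", "global_min"):
            raise ValueError(f"unknown subset_choice_rule {self.subset_choice_rule!r}")
        if self.draw_count_over not in ("top", "all"):
            raise ValueError(f"unknown draw_count_over {self.draw_count_over!r}")


@dataclass(frozen=True)
class SubModel:
    """One PLS sub-model on a bootstrap-drawn variable subset."""

    variable_indices: np.ndarray  # sorted, distinct
    rmsecv: float
    b_normalized: np.ndarray      # |b| of the unit-length coefficient vector
    n_factors: int

    @property
    def n_variables(self) -> int:
        return int(self.variable_indices.size)


@dataclass(frozen=True)
class BossIterationRecord:
    """Per-iteration snapshot of the shrinkage loop."""

    iteration: int                 # 1-based
    n_draws: int                   # draw count used this iteration
    mean_top_size: float           # mean distinct-variable count of extracted sub-models
    best_rmsecv: float
    best_variables: np.ndarray
    best_n_factors: int
    weights: np.ndarray            # weight vector after the update
    support_size: int              # nonzero weights after the update


@dataclass(frozen=True)
class BossResult:
    """Outcome of a BOSS run."""

    selected_indices: np.ndarray
    chosen_iteration: int          # 1-based index into trajectory
    rmsecv_at_choice: float
    n_factors_at_choice: int
    trajectory: tuple[BossIterationRecord, ...]
    final_weights: np.ndarray
    selected_wavenumbers: np.ndarray | None = None


def _check_weights(weights: np.ndarray, P: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != P:
        raise ValueError(f"weight vector has length {w.size}, expected {P}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weight vector: nothing can be drawn")
    return w / total


def draw_subsets(
    P: int,
    weights: np.ndarray,
    K: int,
    n_draws: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """K variable subsets by (weighted) bootstrap sampling.

    Each subset is the set of distinct indices among ``n_draws``
    independent draws with replacement, with draw probability
    proportional to ``weights``.  Uniform weights reproduce plain
    bootstrap sampling; zero-weight variables never appear.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    p = _check_weights(weights, P)
    draws = rng.choice(P, size=(K, n_draws), replace=True, p=p)
    return [np.unique(row) for row in draws]


def fit_submodels(
    X: np.ndarray,
    y: np.ndarray,
    subsets: list[np.ndarray],
    cv: CVConfig,
    folds: list[np.ndarray] | None = None,
) -> list[SubModel]:
    """Cross-validated PLS sub-model for every subset.

    The factor count of each sub-model is re-selected by k-fold CV on its
    own columns (capped at min(max_factors, |subset|, fold-train size - 1));
    the coefficient vector is then fitted on the full calibration set
    restricted to the subset, l2-normalised to unit length and made
    absolute.  A shared fold assignment keeps duplicate subsets
    bit-identical.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, P = X.shape
    if folds is None:
        folds = make_folds(n, cv.n_folds, cv.seed)
    out: list[SubModel] = []
    for subset in subsets:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise ValueError("empty variable subset")
        if subset.min() < 0 or subset.max() >= P:
            raise ValueError("subset references out-of-range columns")
        Xs = X[:, subset]
        a, cv_rmse = select_n_factors(Xs, y, cv, folds=folds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rank warnings expected on tiny subsets
            model = PLS1(n_factors=a).fit(Xs, y)
        b = model.coef_
        norm = np.linalg.norm(b)
        b_norm = np.abs(b / norm) if norm > 0 else np.zeros_like(b)
        out.append(
            SubModel(
                variable_indices=subset,
                rmsecv=float(cv_rmse),
                b_normalized=b_norm,
                n_factors=a,
            )
        )
    return out


def select_top(submodels: list[SubModel], top_fraction: float) -> list[SubModel]:
    """The ceil(K * top_fraction) sub-models with smallest RMSECV.

    Ties break toward fewer variables, then stable input order.
    """
    if not submodels:
        raise ValueError("no sub-models to rank")
    k_top = math.ceil(len(submodels) * top_fraction)
    order = sorted(
        range(len(submodels)),
        key=lambda i: (submodels[i].rmsecv, submodels[i].n_variables, i),
    )
    return [submodels[i] for i in order[:k_top]]


def update_weights(top: list[SubModel], P: int) -> np.ndarray:
    """Soft-shrinkage weight update: w_i = sum over extracted sub-models of |b|_i.

    A variable absent from a sub-model contributes 0 to that term;
    variables in no extracted sub-model end with weight 0 and drop out of
    all future draws.
    """
    if not top:
        raise ValueError("no extracted sub-models")
    w = np.zeros(P)
    for sm in top:
        np.add.at(w, sm.variable_indices, sm.b_normalized)
    return w


def next_n_draws(submodels: list[SubModel]) -> int:
    """Rounded (half-up) mean distinct-variable count, floor 1."""
    if not submodels:
        raise ValueError("no sub-models")
    mean = float(np.mean([sm.n_variables for sm in submodels]))
    return max(1, int(math.floor(mean + 0.5)))


def _choose_iteration(rmse: np.ndarray, rule: str) -> int:
    """0-based chosen index on the best-RMSECV trajectory."""
    if rule == "global_min":
        return int(np.argmin(rmse))
    # first local minimum: first t with r[t] < r[t-1] and r[t] <= r[t+1]
    for t in range(1, len(rmse) - 1):
        if rmse[t] < rmse[t - 1] and rmse[t] <= rmse[t + 1]:
            return t
    # no interior local minimum (e.g. monotone trajectory): fall back to
    # the global minimum
    return int(np.argmin(rmse))


def run_boss(
    X: np.ndarray,
    y: np.ndarray,
    config: BossConfig,
    wavenumbers: np.ndarray | None = None,
) -> BossResult:
    """Run the full BOSS shrinkage loop on (preprocessed) calibration data.

    Starts from uniform weights and a draw count equal to P (plain
    bootstrap over the full variable space), iterates
    draw -> fit -> extract -> reweight -> shrink until the draw count
    reaches one, and picks the iteration by ``config.subset_choice_rule``.
    Fully reproducible from ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, P = X.shape
    if P < 2:
        raise ValueError("need at least 2 variables")
    if n < config.cv.n_folds:
        raise ValueError("fewer samples than CV folds")
    if np.all(X.std(axis=0) == 0.0):
        raise ValueError("degenerate X: all columns constant")

    rng = np.random.default_rng(config.seed)
    folds = make_folds(n, config.cv.n_folds, int(rng.integers(2**31 - 1)))

    weights = np.ones(P)
    n_draws = P
    trajectory: list[BossIterationRecord] = []
    for it in range(1, config.max_iterations + 1):
        subsets = draw_subsets(P, weights, config.n_subsets, n_draws, rng)
        submodels = fit_submodels(X, y, subsets, config.cv, folds=folds)
        top = select_top(submodels, config.top_fraction)
        weights = update_weights(top, P)
        best = top[0]
        support = int(np.count_nonzero(weights))
        trajectory.append(
            BossIterationRecord(
                iteration=it,
                n_draws=n_draws,
                mean_top_size=float(np.mean([sm.n_variables for sm in top])),
                best_rmsecv=best.rmsecv,
                best_variables=best.variable_indices,
                best_n_factors=best.n_factors,
                weights=weights,
                support_size=support,
            )
        )
        if n_draws == 1:
            break
        pool = top if config.draw_count_over == "top" else submodels
        nd = next_n_draws(pool)
        # strict shrinkage: the rounded mean can equal the current draw
        # count once subsets are small, which would stall the loop — force
        # the variable space to contract every iteration
        n_draws = max(1, min(nd, n_draws - 1))
        if support <= 1:
            n_draws = 1
    else:
        warnings.warn(
            f"BOSS did not shrink to a single variable within "
            f"{config.max_iterations} iterations; stopping",
            stacklevel=2,
        )

    rmse = np.array([rec.best_rmsecv for rec in trajectory])
    chosen = _choose_iteration(rmse, config.subset_choice_rule)
    rec = trajectory[chosen]
    return BossResult(
        selected_indices=rec.best_variables,
        chosen_iteration=rec.iteration,
        rmsecv_at_choice=rec.best_rmsecv,
        n_factors_at_choice=rec.best_n_factors,
        trajectory=tuple(trajectory),
        final_weights=trajectory[-1].weights,
        selected_wavenumbers=(
            np.asarray(wavenumbers, dtype=float)[rec.best_variables]
            if wavenumbers is not None
            else None
        ),
    )


class BossPLS(RegressorMixin, BaseEstimator):
    """PLS calibration on BOSS-selected variables.

    ``fit`` runs the BOSS shrinkage loop on the training data, then
    refits a PLS1 model on the selected columns with a factor count
    re-selected by k-fold cross validation (capped at ``max_factors``).

    Parameters mirror :class:`BossConfig`; ``random_state`` seeds all
    sampling.

    Attributes
    ----------
    selected_indices_ : ndarray
        Column indices of the selected wavenumbers.
    result_ : BossResult
        Full trajectory and weights of the selection run.
    n_factors_ : int
        Factor count of the final reduced model.
    model_ : PLS1
        The final fitted calibration model.
    rmsecv_ : float
        RMSECV of the final reduced model on the training set.
    """

    def __init__(
        self,
        n_subsets: int = 1000,
        top_fraction: float = 0.10,
        cv_folds: int = 5,
        max_factors: int = 15,
        subset_choice_rule: str = "first_local_min",
        draw_count_over: str = "top",
        random_state: int = 0,
    ):
        self.n_subsets = n_subsets
        self.top_fraction = top_fraction
        self.cv_folds = cv_folds
        self.max_factors = max_factors
        self.subset_choice_rule = subset_choice_rule
        self.draw_count_over = draw_count_over
        self.random_state = random_state

    def _config(self) -> BossConfig:
        return BossConfig(
            n_subsets=self.n_subsets,
            top_fraction=self.top_fraction,
            cv=CVConfig(
                n_folds=self.cv_folds,
                seed=self.random_state,
                max_factors=self.max_factors,
            ),
            subset_choice_rule=self.subset_choice_rule,
            draw_count_over=self.draw_count_over,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        config = self._config()
        self.result_ = run_boss(X, y, config)
        self.selected_indices_ = self.result_.selected_indices
        Xs = X[:, self.selected_indices_]
        self.n_factors_, self.rmsecv_ = select_n_factors(Xs, y, config.cv)
        self.model_ = PLS1(n_factors=self.n_factors_).fit(Xs, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was fitted with "
                f"{self.n_features_in_}"
            )
        return self.model_.predict(X[:, self.selected_indices_])

    def transform(self, X):
        """Restrict X to the selected wavenumber columns."""
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_indices_]
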