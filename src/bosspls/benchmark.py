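"""Planted-channel recovery benchmark.

Ground truth is only available for synthetic data: spectra with a known
set of informative channels let us measure how much of the true signal
support the selector recovers, and whether the reduced calibration
outperforms the full-spectrum one on held-out samples — the qualitative
claim the selection method stands on.
"""

from __future__ import annotations

import numpy as np

from .boss import BossConfig, run_boss
from .pls import CVConfig, PLS1, rmsep, select_n_factors
from .preprocessing import snv
from .synthetic import make_planted_dataset, split_calibration_validation

__all__ = ["planted_recovery_trial", "planted_recovery_study"]


def planted_recovery_trial(
    seed: int,
    n_subsets: int = 200,
    n_channels: int = 200,
    n_informative: int = 10,
) -> dict:
    """One benchmark run: simulate, split, select, evaluate.

    Returns recall of the planted channels in the selected set plus
    RMSECV/RMSEP of the full-spectrum and the reduced model on the
    identical 60/40 split.
    """
    ds, planted = make_planted_dataset(
        seed=seed, n_channels=n_channels, n_informative=n_informative
    )
    cal, val = split_calibration_validation(ds, 3, seed=seed + 1000)
    X_cal, X_val = snv(cal.X), snv(val.X)

    cv = CVConfig(n_folds=5, seed=seed + 5, max_factors=15)
    a_full, rmsecv_full = select_n_factors(X_cal, cal.y, cv)
    full = PLS1(n_factors=a_full).fit(X_cal, cal.y)
    rmsep_full = rmsep(val.y, full.predict(X_val))

    config = BossConfig(n_subsets=n_subsets, cv=cv, seed=seed + 5)
    result = run_boss(X_cal, cal.y, config)
    sel = result.selected_indices
    a_boss, rmsecv_boss = select_n_factors(X_cal[:, sel], cal.y, cv)
    boss = PLS1(n_factors=a_boss).fit(X_cal[:, sel], cal.y)
    rmsep_boss = rmsep(val.y, boss.predict(X_val[:, sel]))

    return {
        "seed": seed,
        "recall": float(np.isin(planted, sel).mean()),
        "n_selected": int(sel.size),
        "chosen_iteration": result.chosen_iteration,
        "rmsecv_full": rmsecv_full,
        "rmsep_full": rmsep_full,
        "rmsecv_boss": rmsecv_boss,
        "rmsep_boss": rmsep_boss,
    }


def planted_recovery_study(
    seeds=range(20), n_subsets: int = 200
) -> dict:
    """Benchmark medians over independent seeds."""
    trials = [planted_recovery_trial(int(s), n_subsets=n_subsets) for s in seeds]
    med = lambda key: float(np.median([t[key] for t in trials]))
    return {
        "trials": trials,
        "median_recall": med("recall"),
        "median_rmsep_full": med("rmsep_full"),
        "median_rmsep_boss": med("rmsep_boss"),
        "median_rmsecv_full": med("rmsecv_full"),
        "median_rmsecv_boss": med("rmsecv_boss"),
        "median_n_selected": med("n_selected"),
    }
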