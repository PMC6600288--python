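"""Standard normal variate (SNV) row-wise spectral normalisation.

SNV centres and scales each spectrum independently, removing the
per-sample multiplicative gain (surface scattering, optical-path change)
and additive baseline offset that transmission NIR measurements pick up.
Because it is row-local it involves no training-set statistics and cannot
leak information across a calibration/validation split.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["snv", "SNV"]


def snv(X) -> np.ndarray:
    """Transform each row to zero mean and unit sample standard deviation.

    The denominator is the sample (n-1) standard deviation, the dominant
    chemometrics convention.  SNV is invariant to per-row affine maps
    ``a*x + b`` with ``a > 0``, which is exactly the artifact family it
    is meant to cancel.

    Raises
    ------
    ValueError
        If a row is constant (zero variance): a flat NIR spectrum
        indicates a corrupted sample, not a normalisable one.
    """
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("snv needs rows of at least 2 points")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0.0)
    if bad.size:
        raise ValueError(
            f"constant spectrum (zero variance) at row index {bad[0]}; "
            "SNV is undefined for flat spectra"
        )
    out = (X - mean) / sd
    return out[0] if one_d else out


class SNV(TransformerMixin, BaseEstimator):
    """Stateless SNV transformer for pipeline composition.

    ``fit`` learns nothing (SNV is per-row); it only records the input
    width for dimension checks.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return snv(X)
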