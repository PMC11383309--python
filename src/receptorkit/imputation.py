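"""Low-abundance (missing-not-at-random) Gaussian imputation.

Non-detections in LFQ proteomics concentrate at low abundance, so missing
cells are replaced with draws from a per-sample normal distribution shifted
into the low-intensity tail of the observed values:

    mu    = median(observed) - shift_sd * sd(observed)
    sigma = scale_sd * sd(observed)

with defaults shift_sd = 1.8 and scale_sd = 0.3, and the sample (n-1)
standard deviation.  Observed cells are never touched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .quant_io import Log2Matrix

DEFAULT_SHIFT_SD = 1.8
DEFAULT_SCALE_SD = 0.3


def imputation_params(
    sample_values: np.ndarray,
    shift_sd: float = DEFAULT_SHIFT_SD,
    scale_sd: float = DEFAULT_SCALE_SD,
) -> tuple[float, float]:
    """(mu, sigma) of the imputation normal for one sample's observed values."""
    v = np.asarray(sample_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError(
            f"need at least 2 observed values to parameterize imputation, got {v.size}"
        )
    sd = float(np.std(v, ddof=1))
    mu = float(np.median(v)) - shift_sd * sd
    sigma = scale_sd * sd
    return mu, sigma


class GaussianTailImputer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer drawing missing cells from a down-shifted normal.

    ``fit`` learns per-column (per-sample) ``mu_`` and ``sigma_`` from the
    observed values of a proteins x samples matrix; ``transform`` fills NaN
    cells with independent Normal(mu_s, sigma_s) draws.  The RNG is a single
    ``numpy.random.default_rng(random_state)`` stream (PCG64) consuming one
    deviate per matrix cell in row-major (protein, sample) order, so a fixed
    ``random_state`` reproduces the output bit for bit.
    """

    def __init__(self, shift_sd: float = DEFAULT_SHIFT_SD,
                 scale_sd: float = DEFAULT_SCALE_SD,
                 random_state: int | None = 0):
        self.shift_sd = shift_sd
        self.scale_sd = scale_sd
        self.random_state = random_state

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, Log2Matrix):
            return X.values
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def fit(self, X, y=None):
        frame = self._as_frame(X)
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)
        mu, sigma = {}, {}
        for col in frame.columns:
            obs = frame[col].to_numpy(dtype=float)
            if np.all(np.isnan(obs)):
                raise ValueError(f"sample {col!r} is entirely missing; cannot impute")
            mu[col], sigma[col] = imputation_params(obs, self.shift_sd, self.scale_sd)
        self.mu_ = pd.Series(mu, name="mu")
        self.sigma_ = pd.Series(sigma, name="sigma")
        return self

    def transform(self, X):
        frame = self._as_frame(X)
        if list(frame.columns) != list(self.feature_names_in_):
            raise ValueError("samples differ from those seen in fit")
        arr = frame.to_numpy(dtype=float)
        missing = np.isnan(arr)
        rng = np.random.default_rng(self.random_state)
        # One standard-normal deviate per cell, row-major, so that which cells
        # are missing does not change the draws used for the remaining ones
        # within a row ordering; scale/shift per column afterwards.
        z = rng.standard_normal(arr.shape)
        draws = self.mu_[frame.columns].to_numpy() + z * self.sigma_[frame.columns].to_numpy()
        out = np.where(missing, draws, arr)
        out_frame = pd.DataFrame(out, index=frame.index, columns=frame.columns)
        self.imputed_mask_ = pd.DataFrame(missing, index=frame.index, columns=frame.columns)
        if isinstance(X, Log2Matrix):
            return X.with_values(out_frame, "imputed")
        if isinstance(X, pd.DataFrame):
            return out_frame
        return out


def impute(
    matrix: Log2Matrix,
    shift_sd: float = DEFAULT_SHIFT_SD,
    scale_sd: float = DEFAULT_SCALE_SD,
    seed: int | None = 0,
    allow_raw: bool = False,
) -> tuple[Log2Matrix, pd.DataFrame]:
    """Impute a normalized log2 matrix; returns (imputed matrix, boolean mask).

    The mask marks exactly the cells that were replaced.  By default the input
    must carry 'normalized' provenance (imputation happens strictly after
    normalization); pass ``allow_raw=True`` when normalization is disabled.
    """
    if matrix.provenance == "imputed":
        raise ValueError("matrix is already imputed")
    if matrix.provenance == "raw" and not allow_raw:
        raise ValueError("matrix is not normalized (pass allow_raw=True to override)")
    imputer = GaussianTailImputer(shift_sd=shift_sd, scale_sd=scale_sd, random_state=seed)
    out = imputer.fit_transform(matrix)
    return out, imputer.imputed_mask_
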