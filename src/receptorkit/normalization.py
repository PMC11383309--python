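"""Mode-based between-sample normalization of log2 LFQ matrices.

In an affinity-purification experiment most proteins are background that is
common to every pull-down, so the distribution of log2 ratios between any two
samples has a dominant peak (mode) at the systematic abundance offset between
them, even when a minority of proteins is genuinely differential.  The
normalizer estimates that mode for every sample pair and reconciles the
pairwise offsets into one zero-sum log2 factor per sample by least squares.
Unlike a median or mean, the mode ignores a heavily spiked minority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .quant_io import Log2Matrix

DEFAULT_MIN_SHARED = 30
DEFAULT_GRID_SIZE = 512
_KDE_MIN_N = 100  # below this, fall back to a Freedman-Diaconis histogram


@dataclass
class PairwiseModeMatrix:
    """Mode of the log2-ratio distribution for every ordered sample pair.

    ``modes`` is antisymmetric by construction (m_ji = -m_ij, zero diagonal);
    ``n_shared`` counts proteins observed in both samples of a pair.
    """

    modes: pd.DataFrame
    n_shared: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.modes.to_numpy(dtype=float)
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("mode matrix diagonal must be zero")
        if not np.allclose(m, -m.T, atol=1e-9):
            raise ValueError("mode matrix must be antisymmetric")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.modes.columns)


@dataclass
class NormalizationFactors:
    """Per-sample log2 normalization factors in the zero-sum gauge."""

    factors: pd.Series
    residual_rms: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.residual_rms):
            raise ValueError("residual_rms must be finite")
        if abs(float(self.factors.sum())) > 1e-8 * max(1, len(self.factors)):
            raise ValueError("factors must sum to zero")


def _argmax_toward_zero(heights: np.ndarray, centers: np.ndarray) -> float:
    """Argmax position; ties broken toward the center closest to 0."""
    top = heights == heights.max()
    candidates = centers[top]
    return float(candidates[np.argmin(np.abs(candidates))])


def ratio_mode(
    values_i: np.ndarray,
    values_j: np.ndarray,
    min_shared: int = DEFAULT_MIN_SHARED,
    grid_size: int = DEFAULT_GRID_SIZE,
    pair: tuple[str, str] | None = None,
) -> float:
    """Mode of the pairwise log2-ratio distribution values_i - values_j.

    Only positions observed in both vectors contribute.  The mode is a
    Gaussian-KDE (Silverman bandwidth) grid argmax; for fewer than 100 shared
    observations a Freedman-Diaconis histogram argmax is used instead.
    """
    vi = np.asarray(values_i, dtype=float)
    vj = np.asarray(values_j, dtype=float)
    if vi.shape != vj.shape:
        raise ValueError("vectors must have the same length")
    shared = ~np.isnan(vi) & ~np.isnan(vj)
    n = int(shared.sum())
    if n < min_shared:
        name = f" for pair {pair[0]!r} vs {pair[1]!r}" if pair else ""
        raise ValueError(
            f"only {n} shared observations{name}; need at least {min_shared}"
        )
    d = vi[shared] - vj[shared]
    if np.ptp(d) == 0:
        return float(d[0])
    if n < _KDE_MIN_N:
        edges = np.histogram_bin_edges(d, bins="fd")
        counts, edges = np.histogram(d, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return _argmax_toward_zero(counts, centers)
    kde = stats.gaussian_kde(d, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(d.min() - bw, d.max() + bw, grid_size)
    return _argmax_toward_zero(kde(grid), grid)


def pairwise_modes(
    matrix: Log2Matrix | pd.DataFrame,
    min_shared: int = DEFAULT_MIN_SHARED,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> PairwiseModeMatrix:
    """Ratio-distribution modes for all sample pairs of a log2 matrix."""
    values = matrix.values if isinstance(matrix, Log2Matrix) else matrix
    samples = list(values.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    arr = values.to_numpy(dtype=float)
    observed = ~np.isnan(arr)
    k = len(samples)
    modes = np.zeros((k, k))
    n_shared = np.zeros((k, k), dtype=int)
    for i in range(k):
        n_shared[i, i] = int(observed[:, i].sum())
        for j in range(i + 1, k):
            m = ratio_mode(
                arr[:, i], arr[:, j],
                min_shared=min_shared, grid_size=grid_size,
                pair=(samples[i], samples[j]),
            )
            modes[i, j] = m
            modes[j, i] = -m
            n_shared[i, j] = n_shared[j, i] = int((observed[:, i] & observed[:, j]).sum())
    return PairwiseModeMatrix(
        modes=pd.DataFrame(modes, index=samples, columns=samples),
        n_shared=pd.DataFrame(n_shared, index=samples, columns=samples),
    )


def estimate_factors(modes: PairwiseModeMatrix) -> NormalizationFactors:
    """Zero-sum least-squares reconciliation of pairwise modes into factors.

    Minimizes sum over pairs i<j of (f_i - f_j - m_ij)^2 subject to
    sum(f) = 0.  For an antisymmetric mode matrix the normal equations give
    the row-mean closed form f_i = mean_j m_ij exactly, whether or not the
    matrix is consistent; ``residual_rms`` reports the leftover inconsistency.
    """
    m = modes.modes.to_numpy(dtype=float)
    k = m.shape[0]
    f = m.mean(axis=1)
    diffs = f[:, None] - f[None, :] - m
    iu = np.triu_indices(k, 1)
    residual_rms = float(np.sqrt(np.mean(diffs[iu] ** 2))) if iu[0].size else 0.0
    return NormalizationFactors(
        factors=pd.Series(f, index=modes.sample_ids, name="factor"),
        residual_rms=residual_rms,
    )


def apply_factors(matrix: Log2Matrix, factors: NormalizationFactors) -> Log2Matrix:
    """Subtract per-sample factors; missingness unchanged; provenance 'normalized'."""
    if matrix.provenance != "raw":
        raise ValueError(f"expected a raw matrix, got provenance {matrix.provenance!r}")
    unknown = set(matrix.sample_ids) - set(factors.factors.index)
    if unknown:
        raise ValueError(f"no factor for sample(s) {sorted(unknown)}")
    values = matrix.values.sub(factors.factors[matrix.sample_ids], axis="columns")
    return matrix.with_values(values, "normalized")


class ModeNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer aligning samples by pairwise ratio-distribution modes.

    ``fit`` expects a proteins x samples matrix (DataFrame or ndarray, NaN for
    missing; columns are MS samples) and learns one zero-sum log2 factor per
    column; ``transform`` subtracts the factors.

    Attributes (after fit)
    ----------------------
    factors_ : pandas.Series, per-sample log2 factors (zero-sum)
    pairwise_modes_ : PairwiseModeMatrix
    residual_rms_ : float, RMS inconsistency of the pairwise modes
    """

    def __init__(self, min_shared: int = DEFAULT_MIN_SHARED,
                 grid_size: int = DEFAULT_GRID_SIZE):
        self.min_shared = min_shared
        self.grid_size = grid_size

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, Log2Matrix):
            return X.values
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def fit(self, X, y=None):
        frame = self._as_frame(X)
        self.n_features_in_ = frame.shape[1]
        self.feature_names_in_ = np.asarray(frame.columns)
        self.pairwise_modes_ = pairwise_modes(
            frame, min_shared=self.min_shared, grid_size=self.grid_size
        )
        fit = estimate_factors(self.pairwise_modes_)
        self.factors_ = fit.factors
        self.residual_rms_ = fit.residual_rms
        return self

    def transform(self, X):
        frame = self._as_frame(X)
        if list(frame.columns) != list(self.feature_names_in_):
            raise ValueError("samples differ from those seen in fit")
        out = frame.sub(self.factors_[frame.columns], axis="columns")
        if isinstance(X, Log2Matrix):
            return X.with_values(out, "normalized")
        if isinstance(X, pd.DataFrame):
            return out
        return out.to_numpy()

    def inverse_transform(self, X):
        frame = self._as_frame(X)
        out = frame.add(self.factors_[frame.columns], axis="columns")
        return out if isinstance(X, pd.DataFrame) else out.to_numpy()
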