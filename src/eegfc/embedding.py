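"""Time-delay embedding and embedding-parameter selection.

A scalar series ``{x_t}`` is lifted to m-dimensional state-space vectors
``(x_j, x_{j+tau}, ..., x_{j+(m-1)tau})``.  The embedding dimension is
chosen with the false-nearest-neighbors criterion; the delay, for series
that are not already decorrelated, from the sample autocorrelation.  Band
coefficients from the dyadic wavelet decomposition are subsampled by
construction, so the pipeline default is tau = 1 and a global m = 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Embedding", "embed", "fnn_dimension", "acf_lag"]


@dataclass(frozen=True)
class Embedding:
    m: int
    tau: int
    vectors: np.ndarray  # (T - (m-1)*tau, m)
    T: int


def embed(series, m: int, tau: int = 1) -> Embedding:
    """Time-delay embed a scalar series into m dimensions with delay tau."""
    x = np.asarray(series, dtype=float).ravel()
    if m < 1 or tau < 1:
        raise ValueError("embedding requires m >= 1 and tau >= 1")
    T = x.size
    n = T - (m - 1) * tau
    if n < 1:
        raise ValueError(
            f"series of length {T} too short: need at least {(m - 1) * tau + 1} "
            f"samples for m={m}, tau={tau}")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return Embedding(m=m, tau=tau, vectors=x[idx], T=T)


def _false_neighbor_fraction(x: np.ndarray, m: int, tau: int,
                             rtol: float, atol: float) -> float:
    """Kennel false-neighbor fraction going from dimension m to m+1."""
    n = x.size - m * tau  # points embeddable in both m and m+1
    if n < 2:
        return np.nan
    v = embed(x, m, tau).vectors[:n]
    nxt = x[np.arange(n) + m * tau]  # the (m+1)-th coordinate
    from scipy.spatial.distance import cdist
    dist = cdist(v, v)
    np.fill_diagonal(dist, np.inf)
    nn = np.argmin(dist, axis=1)
    rd = dist[np.arange(n), nn]
    extra = np.abs(nxt - nxt[nn])
    sigma = max(x.std(), 1e-300)
    aug = np.sqrt(rd**2 + extra**2)
    # division-free ratio test with a tiny absolute floor so that repeated
    # or nearly-repeated states (periodic signals, rd at rounding level)
    # are not flagged by numerical noise
    false = (extra > rtol * rd + 1e-9 * sigma) | (aug > atol * sigma)
    return float(false.mean())


def fnn_dimension(series, m_max: int = 10, tolerance: float = 0.01,
                  tau: int = 1, rtol: float = 15.0, atol: float = 2.0) -> int:
    """Smallest embedding dimension with a false-neighbor fraction below
    ``tolerance``, by the Kennel distance-ratio test.

    A neighbor is declared false when the added (m+1)-th coordinate inflates
    its distance by more than ``rtol``, or when the augmented distance
    exceeds ``atol`` standard deviations of the series (the loneliness
    test).  If no dimension up to ``m_max`` converges — as for white noise,
    whose neighbors are spurious at every dimension — ``m_max`` is returned
    with a warning.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 10 * m_max:
        raise ValueError(
            f"series of length {x.size} too short for FNN up to m={m_max}; "
            f"need at least {10 * m_max}")
    for m in range(1, m_max + 1):
        frac = _false_neighbor_fraction(x, m, tau, rtol, atol)
        if np.isnan(frac):
            break
        if frac < tolerance:
            return m
    warnings.warn(
        f"false-neighbor fraction never fell below {tolerance:g} up to "
        f"m={m_max}; returning m_max", stacklevel=2)
    return m_max


def sample_acf(series, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag."""
    x = np.asarray(series, dtype=float).ravel()
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("constant series has undefined autocorrelation")
    return np.array([1.0] + [float(x[:-k] @ x[k:]) / denom
                             for k in range(1, max_lag + 1)])


def acf_lag(series, criterion: str = "first_zero") -> int:
    """Delay selection from the sample autocorrelation function.

    criterion:
      - ``first_zero``: smallest lag at which the ACF has reached zero,
        read against the white-noise sampling floor: acf <= 1.96/sqrt(T)
        (sequential samples uncorrelated on average beyond it);
      - ``first_min``: smallest lag that is a local minimum of the ACF;
      - ``inv_e``: smallest lag at which the ACF has decayed to <= 1/e.

    If the criterion is never met, the last computed lag is returned with a
    warning.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 20:
        raise ValueError("need at least 20 samples to estimate the ACF")
    max_lag = x.size - 1
    acf = sample_acf(x, max_lag)
    lags = np.arange(1, max_lag + 1)
    if criterion == "first_zero":
        hits = lags[acf[1:] <= 1.96 / np.sqrt(x.size)]
    elif criterion == "inv_e":
        hits = lags[acf[1:] <= 1.0 / np.e]
    elif criterion == "first_min":
        interior = lags[:-1]
        is_min = (acf[interior] < acf[interior - 1]) & (acf[interior] < acf[interior + 1])
        hits = interior[is_min]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if hits.size:
        return int(hits[0])
    warnings.warn(f"ACF criterion {criterion!r} never met; returning "
                  f"series length - 1", stacklevel=2)
    return max_lag
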