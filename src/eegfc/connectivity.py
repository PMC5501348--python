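"""Generalized measure of association (GMA) and its embedded variant TGMA.

GMA is a rank-based, nonparametric dependence statistic for paired samples
``{(x_i, y_i)}`` living in arbitrary metric spaces.  For each realization
``i`` the nearest neighbor ``j*`` of ``x_i`` is located in X-space, and the
rank ``r_i`` of ``y_{j*}`` among the Y-space distances to ``y_i`` is
recorded.  If X and Y are associated, close pairs in X tend to be close in
Y, the empirical rank distribution ``P(R=r)`` skews toward 1, and the
normalized statistic

    GMA = 1/(n-1) * sum_r (n-r) P(R=r)

approaches 1; under independence ranks are uniform and GMA is 0.5.  The
sum telescopes to ``(n - mean(r_i)) / (n - 1)``, which is how it is
evaluated here (midranks are substituted for ranks within groups of tied
Y-distances, so the mean need not be an integer).

TGMA applies GMA to time-delay embeddings of two time series, turning a
dependence measure on random vectors into a functional-connectivity
measure on signals.  Because the statistic is directional (X-neighbors
ranked in Y), the undirected connectivity used downstream symmetrizes the
two directed values (mean by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .embedding import embed

try:  # numba accelerates the all-pairs kernel; the numpy path is equivalent
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

__all__ = [
    "gma", "gma_directed", "tgma", "tgma_matrix", "trial_average",
    "DependenceMatrix",
]


def _as_points(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError("samples must be a 1-D sequence or an (n, d) array")
    return a


def _neighbor_ranks(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Per-realization rank of the X-nearest neighbor's Y-distance.

    ``dx``/``dy`` are full (n, n) distance matrices.  Self-distances are
    excluded from both the neighbor search and the ranking; argmin breaks
    distance ties deterministically by smallest index.
    """
    n = dx.shape[0]
    dx = dx.copy()
    np.fill_diagonal(dx, np.inf)
    nn = np.argmin(dx, axis=1)
    dy = dy.copy()
    np.fill_diagonal(dy, np.inf)
    # midranks per row; the +inf diagonal always ranks last so ranks of the
    # true entries equal their rank among the n-1 non-self distances
    ranks = rankdata(dy, axis=1, method="average")
    return ranks[np.arange(n), nn]


def gma_directed(x, y, metric: str = "euclidean") -> float:
    """Directed GMA of y on the neighborhood structure of x.

    The statistic depends on distances only through their within-row
    ranks, so it is invariant under any strictly monotone rescaling of the
    metric; Euclidean distances are therefore compared as squares, which
    keeps exact ties exact in floating point.
    """
    xp, yp = _as_points(x), _as_points(y)
    if len(xp) != len(yp):
        raise ValueError(f"sample counts differ: {len(xp)} vs {len(yp)}")
    n = len(xp)
    if n < 5:
        raise ValueError(f"GMA requires at least 5 samples, got {n}")
    if metric in ("euclidean", "sqeuclidean"):
        dx, dy = _sq_dist(xp), _sq_dist(yp)
    else:
        dx, dy = cdist(xp, xp, metric=metric), cdist(yp, yp, metric=metric)
    r = _neighbor_ranks(dx, dy)
    return float((n - r.mean()) / (n - 1))


def gma(x, y, metric: str = "euclidean", reduction: str = "mean") -> float:
    """Symmetrized GMA between two samples of points.

    ``reduction`` combines the two directed values: ``mean`` (default),
    ``min``, or ``max``.
    """
    a = gma_directed(x, y, metric=metric)
    b = gma_directed(y, x, metric=metric)
    return _reduce(a, b, reduction)


def _reduce(a: float, b: float, reduction: str) -> float:
    if reduction == "mean":
        return 0.5 * (a + b)
    if reduction == "min":
        return min(a, b)
    if reduction == "max":
        return max(a, b)
    raise ValueError(f"unknown reduction {reduction!r}")


def tgma(sx, sy, m: int = 4, tau: int = 1, metric: str = "euclidean",
         reduction: str = "mean") -> float:
    """GMA between the time-delay embeddings of two series (TGMA)."""
    ex = embed(sx, m=m, tau=tau).vectors
    ey = embed(sy, m=m, tau=tau).vectors
    return gma(ex, ey, metric=metric, reduction=reduction)


def _sq_dist(v: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows of an (n, m) array.

    Computed from coordinate differences (not the Gram expansion) so the
    values — and hence exact ties — match ``cdist(..., "sqeuclidean")``
    bit for bit.
    """
    diff = v[:, None, :] - v[None, :, :]
    return (diff * diff).sum(axis=-1)


if _numba is not None:

    @_numba.njit(cache=True)
    def _directed_tgma_kernel(emb):  # pragma: no cover - exercised via wrapper
        """Directed all-pairs GMA on embedded channels (C, n, m).

        Identical tie semantics to the numpy path: strict-< argmin (earlier
        index wins nearest-neighbor ties) and midranks over groups of
        exactly tied squared distances.
        """
        C, n, m = emb.shape
        ranks = np.empty((C, n, n))
        nn = np.empty((C, n), np.int64)
        d = np.empty(n)
        for c in range(C):
            for i in range(n):
                best = -1
                best_d = np.inf
                for j in range(n):
                    s = 0.0
                    for k in range(m):
                        t = emb[c, i, k] - emb[c, j, k]
                        s += t * t
                    d[j] = s
                    if j != i and s < best_d:
                        best_d = s
                        best = j
                nn[c, i] = best
                d[i] = np.inf
                order = np.argsort(d)
                pos = 0
                while pos < n:
                    q = pos
                    while q + 1 < n and d[order[q + 1]] == d[order[pos]]:
                        q += 1
                    mid = 0.5 * (pos + q) + 1.0  # midrank of the tied group
                    for t_ in range(pos, q + 1):
                        ranks[c, i, order[t_]] = mid
                    pos = q + 1
        directed = np.empty((C, C))
        for a in range(C):
            for b in range(C):
                acc = 0.0
                for i in range(n):
                    acc += ranks[b, i, nn[a, i]]
                directed[a, b] = acc / n
        return directed


def tgma_matrix(trial: np.ndarray, m: int = 4, tau: int = 1,
                reduction: str = "mean", engine: str = "auto") -> np.ndarray:
    """All-pairs TGMA for one trial, channels x samples -> channels x channels.

    Exploits the telescoped form of the statistic: each channel's embedding
    contributes one nearest-neighbor index vector and one per-row midrank
    matrix, after which every directed pair value is a gather and a mean.
    This is algebraically identical to calling :func:`tgma` per pair but
    O(C * n^2) instead of O(C^2 * n^2) in distance work.
    """
    trial = np.asarray(trial, dtype=float)
    n_ch, n_samp = trial.shape
    nvec = n_samp - (m - 1) * tau
    if nvec < 5:
        raise ValueError(
            f"trial too short to embed: {n_samp} samples give {nvec} vectors")
    idx = np.arange(nvec)[:, None] + tau * np.arange(m)[None, :]
    if engine == "auto":
        engine = "numpy" if _numba is None else "numba"
    if engine == "numba":
        if _numba is None:
            raise ValueError("numba engine requested but numba is not installed")
        directed = _directed_tgma_kernel(np.ascontiguousarray(trial[:, idx]))
    elif engine == "numpy":
        ranks = np.empty((n_ch, nvec, nvec))
        nn = np.empty((n_ch, nvec), dtype=np.intp)
        rows_ = np.arange(nvec)[:, None]
        cols_ = np.arange(1.0, nvec + 1.0)[None, :]
        for c in range(n_ch):
            d = _sq_dist(trial[c][idx])  # squared distances rank identically
            np.fill_diagonal(d, np.inf)
            nn[c] = np.argmin(d, axis=1)
            order = np.argsort(d, axis=1)
            srt = np.take_along_axis(d, order, axis=1)
            if np.any(np.diff(srt[:, :-1], axis=1) == 0.0):
                # exact distance ties: use midranks (tied groups share a rank)
                ranks[c] = rankdata(d, axis=1, method="average")
            else:
                ranks[c][rows_, order] = cols_
        rows = np.arange(nvec)
        directed = np.empty((n_ch, n_ch))
        for a in range(n_ch):
            # mean over i of rank, in every channel b, of b's distance to
            # the point indexed by a's nearest neighbor of i
            directed[a] = ranks[:, rows, nn[a]].mean(axis=1)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    directed = (nvec - directed) / (nvec - 1)
    if reduction == "mean":
        out = 0.5 * (directed + directed.T)
    elif reduction == "min":
        out = np.minimum(directed, directed.T)
    elif reduction == "max":
        out = np.maximum(directed, directed.T)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class DependenceMatrix:
    """Trial-averaged TGMA adjacency for one subject, session, and band."""

    subject_id: str
    session: str  # "pre" or "post"
    band: str
    values: np.ndarray  # (n_channels, n_channels), symmetric, zero diagonal
    labels: tuple[str, ...]
    n_trials_averaged: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dependence matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("dependence matrix must be symmetric")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("off-diagonal dependence values must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def offdiag_upper(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries as a flat vector."""
        n = self.values.shape[0]
        iu = np.triu_indices(n, k=1)
        return self.values[iu]


def trial_average(per_trial, subject_id: str = "", session: str = "pre",
                  band: str = "", labels=None) -> DependenceMatrix:
    """Entrywise mean of per-trial TGMA matrices."""
    mats = [np.asarray(m, dtype=float) for m in per_trial]
    if not mats:
        raise ValueError("need at least one trial to average")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("per-trial matrices have mismatched shapes")
    mean = np.mean(mats, axis=0)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(shape[0]))
    return DependenceMatrix(subject_id=subject_id, session=session, band=band,
                            values=mean, labels=tuple(labels),
                            n_trials_averaged=len(mats))
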