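"""Binarization of dependence matrices and graph-theoretic biomarkers.

A trial-averaged dependence matrix is reduced to an unweighted graph
either by a per-subject statistical threshold (one standard deviation
above the median of the pooled pre/post entries) or by a sparsity
threshold that keeps a fixed fraction of the strongest links.  The
efficiency-cost-optimization (ECO) criterion provides an a-priori sparsity
of 3/(N-1), about 0.053 for 58 nodes — close to the 0.05 operating point
used throughout.

From the binary graph the package computes global efficiency (mean inverse
shortest-path length), local efficiency (mean efficiency of each node's
neighbor-induced subgraph, also exposed per node), the interdensity
between the two hemisphere electrode sets, and the intradensity within
each set.  All are dimensionless fractions in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import DependenceMatrix
from .montage import HemisphereMap, default_hemisphere_map

__all__ = [
    "BinaryGraph", "GraphMetricsRecord", "eco_threshold", "binarize_sparsity",
    "binarize_statistical", "global_efficiency", "local_efficiency",
    "interdensity", "intradensity", "flip_hemispheres", "compute_metrics",
]


@dataclass
class BinaryGraph:
    """Unweighted graph plus the threshold provenance that produced it."""

    adjacency: np.ndarray  # (N, N) in {0, 1}, symmetric, zero diagonal
    labels: tuple[str, ...]
    threshold_kind: str    # "sparsity", "statistical", or "eco"
    threshold_value: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def eco_threshold(n_nodes: int) -> float:
    """Efficiency-cost-optimization sparsity: mean degree 3, i.e. 3/(N-1)."""
    if n_nodes < 2:
        raise ValueError("ECO threshold needs at least 2 nodes")
    return 3.0 / (n_nodes - 1)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def binarize_sparsity(m: DependenceMatrix, t: float) -> BinaryGraph:
    """Keep the fraction ``t`` strongest links of the dependence matrix.

    Exactly round(t * N(N-1)/2) upper-triangle entries are kept (half-up
    rounding); ties at the cut are resolved in (row, column) index order so
    the result is deterministic.
    """
    if not 0.0 < t <= 0.5:
        raise ValueError(f"sparsity threshold must lie in (0, 0.5], got {t}")
    n = m.values.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    vals = m.values[rows, cols]
    k = _round_half_up(t * vals.size)
    order = np.lexsort((cols, rows, -vals))[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[rows[order], cols[order]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, labels=m.labels,
                       threshold_kind="sparsity", threshold_value=t)


def binarize_statistical(m_pre: DependenceMatrix,
                         m_post: DependenceMatrix) -> tuple[BinaryGraph, BinaryGraph]:
    """Per-subject statistical threshold: median + 1 SD across conditions.

    The threshold pools the off-diagonal entries of both sessions of one
    subject and band; an edge is kept where its dependence value strictly
    exceeds the threshold.  A degenerate pooled distribution (zero spread)
    yields empty graphs with a warning.
    """
    if m_pre.subject_id != m_post.subject_id or m_pre.band != m_post.band:
        raise ValueError("statistical threshold pools the two sessions of one "
                         "subject and band")
    pooled = np.concatenate([m_pre.offdiag_upper(), m_post.offdiag_upper()])
    sd = pooled.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(pooled).max(initial=0.0))):
        warnings.warn("pooled dependence values are constant; statistical "
                      "threshold yields empty graphs", stacklevel=2)
        thr = np.inf
    else:
        thr = float(np.median(pooled) + sd)
    out = []
    for m in (m_pre, m_post):
        adj = (m.values > thr).astype(np.int8)
        np.fill_diagonal(adj, 0)
        out.append(BinaryGraph(adjacency=adj, labels=m.labels,
                               threshold_kind="statistical",
                               threshold_value=thr))
    return out[0], out[1]


def _efficiency_from_adjacency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(adj.astype(float), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Disconnected pairs contribute zero, so the measure is well defined on
    sparse graphs; for an unweighted graph it already lies in [0, 1] (the
    complete graph attains 1), so no further normalization is applied.
    """
    return _efficiency_from_adjacency(g.adjacency)


def local_efficiency(g: BinaryGraph) -> tuple[float, np.ndarray]:
    """Network local efficiency and the per-node subgraph efficiencies.

    Node i's value is the global efficiency of the subgraph induced by its
    neighbors (i itself removed), quantifying fault tolerance; nodes with
    fewer than two neighbors contribute 0.  The network value is the mean
    over all nodes.
    """
    adj = g.adjacency
    n = adj.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        if nbrs.size >= 2:
            per_node[i] = _efficiency_from_adjacency(adj[np.ix_(nbrs, nbrs)])
    return float(per_node.mean()), per_node


def _set_indices(labels: tuple[str, ...], electrode_set) -> np.ndarray:
    idx = []
    for lab in electrode_set:
        if lab not in labels:
            raise KeyError(f"electrode {lab!r} not in graph labels")
        idx.append(labels.index(lab))
    return np.asarray(idx)


def interdensity(g: BinaryGraph, hmap: HemisphereMap) -> float:
    """Fraction of realized edges between the two hemisphere sets.

    Normalized by N^2, the number of possible crossing edges between two
    disjoint sets of equal cardinality N.
    """
    sa = _set_indices(g.labels, hmap.affected_set)
    sb = _set_indices(g.labels, hmap.unaffected_set)
    if sa.size != sb.size:
        raise ValueError("interdensity requires equal-cardinality sets")
    cross = g.adjacency[np.ix_(sa, sb)].sum()
    return float(cross / sa.size**2)


def intradensity(g: BinaryGraph, electrode_set) -> float:
    """Fraction of realized edges within one electrode set."""
    idx = _set_indices(g.labels, tuple(electrode_set))
    ns = idx.size
    if ns < 2:
        raise ValueError("intradensity needs a set of at least 2 electrodes")
    within = g.adjacency[np.ix_(idx, idx)].sum() / 2  # unordered pairs
    return float(2.0 * within / (ns**2 - ns))


def flip_hemispheres(m: DependenceMatrix, affected_side: str,
                     hmap: HemisphereMap | None = None) -> DependenceMatrix:
    """Midsagittal flip so the ipsilesional hemisphere is consistent.

    Subjects with a right-hemisphere lesion (left arm affected) have their
    homologous left/right channels swapped; midline channels and
    left-lesion subjects are untouched.  Applying the flip twice is the
    identity.
    """
    if affected_side not in ("left", "right"):
        raise ValueError(f"affected_side must be 'left' or 'right', got {affected_side!r}")
    if affected_side == "right":
        return m
    hmap = hmap or default_hemisphere_map()
    fmap = hmap.flip_map
    perm = []
    for lab in m.labels:
        target = fmap.get(lab)
        if target is None:
            raise KeyError(f"channel {lab!r} has no midsagittal flip mapping")
        perm.append(m.labels.index(target))
    perm = np.asarray(perm)
    return DependenceMatrix(subject_id=m.subject_id, session=m.session,
                            band=m.band, values=m.values[np.ix_(perm, perm)],
                            labels=m.labels,
                            n_trials_averaged=m.n_trials_averaged)


@dataclass
class GraphMetricsRecord:
    """The biomarker panel for one binary graph."""

    E_glo: float
    E_loc: float
    E_loc_node: np.ndarray
    K_inter: float
    K_intra_affected: float
    K_intra_unaffected: float

    def as_dict(self) -> dict[str, float]:
        return {
            "global_efficiency": self.E_glo,
            "local_efficiency": self.E_loc,
            "interdensity": self.K_inter,
            "intradensity_affected": self.K_intra_affected,
            "intradensity_unaffected": self.K_intra_unaffected,
        }


def compute_metrics(g: BinaryGraph,
                    hmap: HemisphereMap | None = None) -> GraphMetricsRecord:
    """Compute the full biomarker panel for one graph."""
    hmap = hmap or default_hemisphere_map()
    e_loc, per_node = local_efficiency(g)
    return GraphMetricsRecord(
        E_glo=global_efficiency(g),
        E_loc=e_loc,
        E_loc_node=per_node,
        K_inter=interdensity(g, hmap),
        K_intra_affected=intradensity(g, hmap.affected_set),
        K_intra_unaffected=intradensity(g, hmap.unaffected_set),
    )
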