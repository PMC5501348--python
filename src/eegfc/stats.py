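"""Rank statistics and permutation inference for biomarker validation.

Biomarkers are associated with functional recovery (dFMUE) by Spearman
correlation (change vs. change) and rank regression (initial value vs.
change).  Significance comes from a permutation null obtained by shuffling
the dFMUE values across subjects — 10,000 times by default — with a
two-sided, observed-included p-value (1 + #{|T_b| >= |T_obs|}) / (B + 1).
Node-level (per-electrode) maps are corrected for multiple comparisons
with the max-statistic distribution over the shared permutation stream,
which gives strong family-wise control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "spearman", "rank_regression", "permutation_test", "maxstat_correction",
    "threshold_sweep", "biomarker_analysis", "StatResult",
    "GLOBAL_METRICS",
]

#: The five global/hemispheric biomarkers, in reporting order.
GLOBAL_METRICS = (
    "global_efficiency", "local_efficiency", "interdensity",
    "intradensity_unaffected", "intradensity_affected",
)


def _check_pair(x, y, min_n: int = 4) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank statistics are undefined for constant input")
    return x, y


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x, y = _check_pair(x, y)
    return _pearson(rankdata(x), rankdata(y))


def rank_regression(x, y) -> float:
    """Coefficient of determination of the rank-on-rank least-squares fit.

    For a single predictor this equals the squared Spearman correlation.
    """
    x, y = _check_pair(x, y)
    rx, ry = rankdata(x), rankdata(y)
    slope, intercept = np.polyfit(rx, ry, 1)
    resid = ry - (slope * rx + intercept)
    ss_tot = ((ry - ry.mean()) ** 2).sum()
    return float(1.0 - (resid @ resid) / ss_tot)


def _permuted_spearman(x: np.ndarray, y: np.ndarray, B: int,
                       rng: np.random.Generator) -> tuple[float, np.ndarray]:
    """Observed Spearman and its B values under permutation of y."""
    rx = rankdata(x)
    ry = rankdata(y)
    obs = _pearson(rx, ry)
    perms = rng.permuted(np.tile(ry, (B, 1)), axis=1)
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    null = (pc @ rxc) / np.sqrt((rxc @ rxc) * ((ry - ry.mean()) @ (ry - ry.mean())))
    return obs, null


def permutation_test(x, y, statistic="spearman", B: int = 10000,
                     seed: int | None = None) -> tuple[float, float]:
    """Two-sided permutation p-value for a dependence statistic.

    Only ``y`` (the outcome, dFMUE in the pipeline) is permuted.  Returns
    ``(observed statistic, p)`` with the observed-included correction
    p = (1 + #{|T_b| >= |T_obs|}) / (B + 1), so p is never 0 and is exact
    under the null.  ``statistic`` is ``"spearman"`` (vectorized fast
    path), ``"rank_r2"``, or any callable ``f(x, y) -> float``.
    """
    if B < 100:
        raise ValueError("need at least 100 permutations")
    x, y = _check_pair(x, y)
    rng = np.random.default_rng(seed)
    if statistic in ("spearman", "rank_r2"):
        obs, null = _permuted_spearman(x, y, B, rng)
        if statistic == "rank_r2":
            obs, null = obs**2, null**2
    else:
        obs = float(statistic(x, y))
        null = np.array([float(statistic(x, rng.permutation(y)))
                         for _ in range(B)])
    p = (1.0 + np.count_nonzero(np.abs(null) >= np.abs(obs) - 1e-12)) / (B + 1.0)
    return float(obs), float(p)


def maxstat_correction(node_statistics, permuted_node_statistics) -> np.ndarray:
    """Family-wise corrected p-values via the max-statistic distribution.

    ``permuted_node_statistics`` has shape (B, n_nodes) and must come from
    one shared permutation stream.  Electrode e's corrected p is the
    proportion of permutations whose maximum |statistic| over all
    electrodes reaches |observed_e| (observed-included, as above).  With a
    single electrode this reduces to the uncorrected p-value.
    """
    obs = np.abs(np.asarray(node_statistics, dtype=float))
    perm = np.abs(np.asarray(permuted_node_statistics, dtype=float))
    if perm.ndim != 2 or perm.shape[1] != obs.size:
        raise ValueError("permuted statistics must be (B, n_nodes)")
    maxima = perm.max(axis=1)
    count = (maxima[:, None] >= obs[None, :] - 1e-12).sum(axis=0)
    return (1.0 + count) / (perm.shape[0] + 1.0)


@dataclass
class StatResult:
    """One association cell: metric x band x subject group x mode."""

    metric: str
    band: str
    group: str          # "all" or "cortex"
    mode: str           # "change_vs_change" or "initial_vs_change"
    statistic_kind: str  # "spearman_r" or "rank_R2"
    value: float
    p_perm: float
    n_subjects: int
    n_permutations: int
    seed: int
    p_corrected: float | None = None
    status: str = "ok"


def _metric_wide(metrics: pd.DataFrame) -> pd.DataFrame:
    need = {"subject", "session", "band", "metric", "value"}
    if not need.issubset(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(need)}")
    return metrics.pivot_table(index=["subject", "band", "metric"],
                               columns="session", values="value",
                               aggfunc="first")


def biomarker_analysis(metrics: pd.DataFrame, cohort: pd.DataFrame,
                       mode: str = "change_vs_change",
                       groups=("all", "cortex"), B: int = 10000,
                       seed: int = 0,
                       metric_names=GLOBAL_METRICS) -> pd.DataFrame:
    """The full association grid: metrics x bands x subject groups.

    ``metrics`` is a long table (subject, session, band, metric, value);
    ``cohort`` must carry Patient, Location, and dFMUE columns with Patient
    matching the metrics' subject ids.  For ``change_vs_change`` the
    statistic is the Spearman correlation of the pre-to-post metric change
    with dFMUE; for ``initial_vs_change`` the rank-regression R^2 of dFMUE
    on the pre-intervention value.  Each cell gets a permutation p-value
    from its own seeded stream; rerunning with the same seed reproduces
    the table exactly.  Degenerate cells (constant values, too few
    subjects) are reported with a status message instead of a number.
    """
    if mode not in ("change_vs_change", "initial_vs_change"):
        raise ValueError(f"unknown mode {mode!r}")
    wide = _metric_wide(metrics)
    missing = [c for c in ("pre", "post") if c not in wide.columns]
    if missing and (mode == "change_vs_change" or "pre" in missing):
        raise ValueError(f"metrics table lacks session(s) {missing}")
    cohort = cohort.set_index(cohort["Patient"].astype(str))
    bands = sorted(metrics["band"].unique())
    stat_kind = "spearman_r" if mode == "change_vs_change" else "rank_R2"
    rows, cell = [], 0
    for group in groups:
        if group == "all":
            members = cohort
        elif group == "cortex":
            members = cohort[cohort["Location"].str.contains("cortex", case=False)]
        else:
            raise ValueError(f"unknown group {group!r}")
        for band in bands:
            for metric in metric_names:
                cell += 1
                cell_seed = int(np.random.SeedSequence([seed, cell]).generate_state(1)[0] % (2**31))
                res = StatResult(metric=metric, band=band, group=group,
                                 mode=mode, statistic_kind=stat_kind,
                                 value=np.nan, p_perm=np.nan,
                                 n_subjects=0, n_permutations=B, seed=cell_seed)
                try:
                    sub = wide.xs((band, metric), level=("band", "metric"))
                    sub = sub.loc[sub.index.intersection(members.index)]
                    if mode == "change_vs_change":
                        sub = sub.dropna(subset=["pre", "post"])
                        biom = (sub["post"] - sub["pre"]).to_numpy()
                    else:
                        sub = sub.dropna(subset=["pre"])
                        biom = sub["pre"].to_numpy()
                    outcome = members.loc[sub.index, "dFMUE"].to_numpy(dtype=float)
                    res.n_subjects = biom.size
                    stat = "spearman" if stat_kind == "spearman_r" else "rank_r2"
                    res.value, res.p_perm = permutation_test(
                        biom, outcome, statistic=stat, B=B, seed=cell_seed)
                except (ValueError, KeyError) as err:
                    res.status = f"degenerate: {err}"
                rows.append(res)
    out = pd.DataFrame([vars(r) for r in rows])
    out["significant"] = out["p_perm"] < 0.05
    return out


def threshold_sweep(matrices: dict, cohort: pd.DataFrame, t_grid,
                    hemisphere_map=None, metric_names=GLOBAL_METRICS):
    """Sparsity sweep: Spearman(change in metric, dFMUE) per (t, metric, band).

    ``matrices`` maps (subject_id, session, band) to a DependenceMatrix
    (already flipped to a consistent ipsilesional side).  Returns the full
    table and the threshold maximizing the mean |r_s| over the
    metric x band grid, so the circularity of the selection is auditable.
    """
    from .graphs import binarize_sparsity, compute_metrics
    from .montage import default_hemisphere_map

    t_grid = list(t_grid)
    if not t_grid:
        raise ValueError("empty threshold grid")
    hmap = hemisphere_map or default_hemisphere_map()
    cohort = cohort.set_index(cohort["Patient"].astype(str))
    subjects = sorted({k[0] for k in matrices})
    if len(subjects) < 2:
        raise ValueError("threshold sweep needs at least 2 subjects")
    bands = sorted({k[2] for k in matrices})
    rows = []
    for t in t_grid:
        for band in bands:
            deltas = {name: [] for name in metric_names}
            outcome = []
            for s in subjects:
                try:
                    pre = matrices[(s, "pre", band)]
                    post = matrices[(s, "post", band)]
                except KeyError:
                    continue
                rec_pre = compute_metrics(binarize_sparsity(pre, t), hmap).as_dict()
                rec_post = compute_metrics(binarize_sparsity(post, t), hmap).as_dict()
                for name in metric_names:
                    deltas[name].append(rec_post[name] - rec_pre[name])
                outcome.append(float(cohort.loc[s, "dFMUE"]))
            for name in metric_names:
                try:
                    r = spearman(deltas[name], outcome)
                except ValueError:
                    r = np.nan
                rows.append({"t": t, "band": band, "metric": name, "r_s": r})
    table = pd.DataFrame(rows)
    score = table.groupby("t")["r_s"].apply(lambda v: np.nanmean(np.abs(v)))
    t_selected = float(score.idxmax())
    return table, t_selected
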