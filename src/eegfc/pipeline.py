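"""End-to-end pipeline: simulate/read -> preprocess -> connectivity ->
graphs -> statistics, with a manifest for exact reproducibility.

One master seed deterministically derives every stage seed through
``numpy.random.SeedSequence``, so rerunning with the same configuration
and seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import COHORT_COLUMNS, derive_delta
from .connectivity import DependenceMatrix, tgma_matrix, trial_average
from .graphs import binarize_sparsity, compute_metrics, flip_hemispheres
from .io import write_dependence_tsv, write_trialset
from .montage import default_hemisphere_map
from .preprocess import BAND_LABELS, highpass, reject_artifacts, wavelet_bands
from .simulate import EffectSpec, SubjectSpec, make_cohort, simulate_session
from .stats import biomarker_analysis

__all__ = ["PipelineConfig", "run_all", "subject_band_matrices",
           "metrics_table", "cohort_frame"]


@dataclass
class PipelineConfig:
    """Serializable configuration covering every pipeline stage."""

    fs: float = 200.0
    wavelet: str = "coif1"
    highpass_cutoff: float = 0.3
    artifact_limit: float = 150.0
    m: int = 4
    tau: int = 1
    threshold_kind: str = "sparsity"   # or "statistical"
    t: float = 0.05
    n_permutations: int = 10000
    seed: int = 0
    symmetric_hemispheres: bool = False
    groups: tuple[str, ...] = ("all", "cortex")

    @property
    def bands(self) -> tuple[str, ...]:
        return BAND_LABELS

    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["pipeline"] = {k: (",".join(v) if isinstance(v, tuple) else str(v))
                          for k, v in asdict(self).items()}
        with open(path, "w") as f:
            cp.write(f)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise ValueError(f"cannot read config file {path}")
        sec = cp["pipeline"]
        kw: dict = {}
        for name, f in cls.__dataclass_fields__.items():
            if name not in sec:
                continue
            raw = sec[name]
            if f.type in ("float",):
                kw[name] = float(raw)
            elif f.type in ("int",):
                kw[name] = int(raw)
            elif f.type == "bool":
                kw[name] = raw.lower() in ("1", "true", "yes")
            elif f.type == "tuple[str, ...]":
                kw[name] = tuple(s for s in raw.split(",") if s)
            else:
                kw[name] = raw
        return cls(**kw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def cohort_frame(cohort: list[SubjectSpec]) -> pd.DataFrame:
    """Cohort table (reference column layout) for a synthetic cohort."""
    rows = []
    for s in cohort:
        rows.append({
            "Patient": s.subject_id,
            "Months post insult": 0,
            "Type": "Synthetic",
            "Location": {"cortex": "Cortex", "subcortical": "Subcortical",
                         "other": "Other"}[s.lesion_class],
            "Affected arm": "L" if s.affected_side == "left" else "R",
            "FMUE_Pre": s.fmue_pre,
            "FMUE_Post": s.fmue_post,
        })
    return derive_delta(pd.DataFrame(rows, columns=COHORT_COLUMNS))


def subject_band_matrices(trials, config: PipelineConfig,
                          affected_side: str = "right",
                          hmap=None, apply_flip: bool = True) -> dict[str, DependenceMatrix]:
    """Preprocess one session's trials and compute per-band TGMA matrices."""
    hmap = hmap or default_hemisphere_map(config.symmetric_hemispheres)
    ts = highpass(trials, cutoff=config.highpass_cutoff)
    ts = reject_artifacts(ts, peak_to_peak_limit=config.artifact_limit)
    bands = wavelet_bands(ts, wavelet=config.wavelet)
    out = {}
    for band, bts in bands.items():
        per_trial = [tgma_matrix(tr, m=config.m, tau=config.tau)
                     for tr in bts.trials]
        dm = trial_average(per_trial, subject_id=ts.subject_id,
                           session=ts.session, band=band, labels=ts.labels)
        if apply_flip:
            dm = flip_hemispheres(dm, affected_side, hmap)
        out[band] = dm
    return out


def metrics_table(matrices: dict, config: PipelineConfig, hmap=None) -> pd.DataFrame:
    """Long-format biomarker table from (subject, session, band) matrices."""
    hmap = hmap or default_hemisphere_map(config.symmetric_hemispheres)
    rows = []
    for (subject, session, band), dm in sorted(matrices.items()):
        if config.threshold_kind != "sparsity":
            raise ValueError("metrics_table computes sparsity-thresholded "
                             "metrics; use graphs.binarize_statistical directly "
                             "for the statistical threshold")
        g = binarize_sparsity(dm, config.t)
        rec = compute_metrics(g, hmap)
        for name, value in rec.as_dict().items():
            rows.append({"subject": subject, "session": session, "band": band,
                         "metric": name, "value": value})
        for lab, value in zip(dm.labels, rec.E_loc_node):
            rows.append({"subject": subject, "session": session, "band": band,
                         "metric": f"local_efficiency:{lab}", "value": value})
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig, outdir, effect: EffectSpec | None = None,
            write_trials: bool = False) -> Path:
    """Execute the full pipeline and write every intermediate artifact.

    With an :class:`EffectSpec`, a synthetic cohort is generated (the
    simulator emits movement-windowed trials, so the kinematic segmentation
    stage applies to continuous recordings only).  Artifacts: cohort CSV,
    per subject/session/band dependence TSVs, long-format metrics TSV,
    statistics tables for both analysis modes, and a manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if effect is None:
        raise ValueError("run_all currently requires an EffectSpec "
                         "(simulation input); file-based inputs go through "
                         "io.read_eeg and the stage functions")
    effect.fs = config.fs
    hmap = default_hemisphere_map(config.symmetric_hemispheres)
    seeds = np.random.SeedSequence(config.seed)
    s_cohort, s_stats = (int(s.generate_state(1)[0] % 2**31)
                         for s in seeds.spawn(2))

    cohort = make_cohort(effect, seed=s_cohort, hemisphere_map=hmap)
    table = cohort_frame(cohort)
    table[COHORT_COLUMNS].to_csv(outdir / "cohort.csv", index=False)

    matdir = outdir / "matrices"
    matdir.mkdir(exist_ok=True)
    matrices = {}
    for subj in cohort:
        for session in ("pre", "post"):
            ts = simulate_session(subj, session, effect)
            if write_trials:
                tdir = outdir / "trials"
                tdir.mkdir(exist_ok=True)
                write_trialset(ts, tdir / f"{subj.subject_id}_{session}.h5")
            per_band = subject_band_matrices(ts, config, subj.affected_side,
                                             hmap=hmap)
            for band, dm in per_band.items():
                matrices[(subj.subject_id, session, band)] = dm
                write_dependence_tsv(
                    dm, matdir / f"{subj.subject_id}_{session}_{band}.tsv")

    mtable = metrics_table(matrices, config, hmap=hmap)
    mtable.to_csv(outdir / "metrics.tsv", sep="\t", index=False,
                  float_format="%.17g")

    global_metrics = mtable[~mtable["metric"].str.contains(":")]
    results = []
    for mode in ("change_vs_change", "initial_vs_change"):
        res = biomarker_analysis(global_metrics, table, mode=mode,
                                 groups=config.groups,
                                 B=config.n_permutations, seed=s_stats)
        results.append(res)
    stats = pd.concat(results, ignore_index=True)
    stats.to_csv(outdir / "stat_results.tsv", sep="\t", index=False,
                 float_format="%.17g")
    stats.to_json(outdir / "stat_results.json", orient="records", indent=1)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "effect_spec": asdict(effect),
        "stage_seeds": {"cohort": s_cohort, "stats": s_stats},
        "n_subjects": len(cohort),
        "artifacts": sorted(str(p.relative_to(outdir))
                            for p in outdir.rglob("*") if p.is_file()
                            and p.name != "manifest.json"),
        "n_dependence_matrices": len(matrices),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
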