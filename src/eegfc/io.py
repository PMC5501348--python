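"""File formats: HDF5 trial sets, TSV dependence matrices, EDF input.

Trial sets use a documented HDF5 layout::

    /trials/0, /trials/1, ...   (n_channels, n_samples) float64
    attrs: fs, labels, subject_id, session  [band, level for band sets]

Dependence matrices are TSV (header of channel labels, one row per
channel) with a JSON sidecar carrying subject/session/band/trial-count
provenance.  EDF recordings are read through MNE; a channel subset map may
be supplied when the file does not carry exactly the 58 montage channels.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import DependenceMatrix
from .preprocess import BandTrialSet, TrialSet

__all__ = [
    "write_trialset", "read_trialset", "write_band_trialset",
    "read_band_trialset", "write_dependence_tsv", "read_dependence_tsv",
    "read_eeg",
]


def write_trialset(ts: TrialSet, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trials")
        for k, tr in enumerate(ts.trials):
            g.create_dataset(str(k), data=np.asarray(tr, dtype=np.float64))
        f.attrs["fs"] = ts.fs
        f.attrs["labels"] = list(ts.labels)
        f.attrs["subject_id"] = ts.subject_id
        f.attrs["session"] = ts.session


def read_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        if "trials" not in f:
            raise ValueError(f"{path}: not a trial-set file (no /trials group)")
        g = f["trials"]
        trials = [g[str(k)][()] for k in sorted(g, key=int)]
        return TrialSet(subject_id=str(f.attrs["subject_id"]),
                        session=str(f.attrs["session"]),
                        labels=tuple(str(x) for x in f.attrs["labels"]),
                        fs=float(f.attrs["fs"]), trials=trials)


def write_band_trialset(bts: BandTrialSet, path, subject_id: str = "",
                        session: str = "") -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("trials")
        for k, tr in enumerate(bts.trials):
            g.create_dataset(str(k), data=np.asarray(tr, dtype=np.float64))
        f.attrs["band"] = bts.band
        f.attrs["level"] = bts.level
        f.attrs["fs"] = bts.coeff_rate  # coefficient rate of this band
        f.attrs["labels"] = list(bts.labels)
        f.attrs["subject_id"] = subject_id
        f.attrs["session"] = session


def read_band_trialset(path) -> BandTrialSet:
    with h5py.File(path, "r") as f:
        if "trials" not in f or "band" not in f.attrs:
            raise ValueError(f"{path}: not a band trial-set file")
        g = f["trials"]
        trials = [g[str(k)][()] for k in sorted(g, key=int)]
        return BandTrialSet(band=str(f.attrs["band"]),
                            level=int(f.attrs["level"]),
                            coeff_rate=float(f.attrs["fs"]),
                            trials=trials,
                            labels=tuple(str(x) for x in f.attrs["labels"]))


def write_dependence_tsv(m: DependenceMatrix, path) -> None:
    """TSV adjacency (labels as header and row order) plus JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame(m.values, columns=list(m.labels))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {"subject_id": m.subject_id, "session": m.session,
               "band": m.band, "n_trials_averaged": m.n_trials_averaged,
               "labels": list(m.labels)}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_dependence_tsv(path) -> DependenceMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    side_path = path.with_suffix(path.suffix + ".json")
    if not side_path.exists():
        raise ValueError(f"{path}: missing JSON sidecar {side_path.name}")
    meta = json.loads(side_path.read_text())
    values = frame.to_numpy(dtype=float)
    return DependenceMatrix(subject_id=meta["subject_id"],
                            session=meta["session"], band=meta["band"],
                            values=0.5 * (values + values.T),
                            labels=tuple(frame.columns),
                            n_trials_averaged=int(meta["n_trials_averaged"]))


def read_eeg(path, expected_labels=None, channel_subset=None,
             subject_id: str = "", session: str = "pre") -> TrialSet:
    """Read EEG into a TrialSet: HDF5 trial sets or continuous EDF.

    An EDF recording yields a single-trial TrialSet holding the full
    continuous record (segment it with :func:`eegfc.preprocess.segment`).
    If ``expected_labels`` is given and the file's channels differ, a
    ``channel_subset`` sequence must select/reorder them, otherwise a
    channel-count error is raised.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return read_trialset(path)
    if path.suffix.lower() != ".edf":
        raise ValueError(f"{path}: unrecognized EEG format "
                         "(expected .edf or .h5/.hdf5)")
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    data = raw.get_data()
    if channel_subset is not None:
        idx = [labels.index(ch) for ch in channel_subset]
        data, labels = data[idx], tuple(channel_subset)
    if expected_labels is not None and labels != tuple(expected_labels):
        raise ValueError(
            f"{path}: has {len(labels)} channels, expected "
            f"{len(tuple(expected_labels))}; supply channel_subset to map them")
    return TrialSet(subject_id=subject_id, session=session, labels=labels,
                    fs=float(raw.info["sfreq"]), trials=[data])
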