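"""Filtering, movement segmentation, artifact screening, and the wavelet
filter bank.

Continuous task EEG is high-pass filtered at 0.3 Hz, cut into one window
per reaching movement using the synchronized kinematic trace, screened for
gross artifacts by a peak-to-peak amplitude criterion, and decomposed with
a Coiflet-1 dyadic wavelet filter bank into three non-overlapping analysis
bands: 6.25-12.5 Hz (mu/alpha), 12.5-25 Hz (beta), and 25-50 Hz (low
gamma).  Detail level k of the dyadic decomposition spans fs/2^(k+1) to
fs/2^k, so the band-to-level mapping is computed from the sampling rate
rather than hard-coded; rates of the form 200*2^k Hz place the three bands
exactly on detail levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

__all__ = [
    "TrialSet", "BandTrialSet", "BAND_LABELS", "highpass", "segment",
    "reject_artifacts", "wavelet_bands", "band_levels",
]

#: The three analysis bands, low to high, as "<lo>-<hi>" Hz tokens.
BAND_LABELS: tuple[str, ...] = ("6.25-12.5", "12.5-25", "25-50")

DURATION_RANGE = (1.24, 3.98)  # movement-window bounds, seconds


@dataclass
class TrialSet:
    """Segmented multichannel EEG trials for one subject and session."""

    subject_id: str
    session: str  # "pre" or "post"
    labels: tuple[str, ...]
    fs: float
    trials: list  # of (n_channels, n_samples) arrays
    intervals: list = field(default_factory=list)  # (onset, end) sample indices

    def __post_init__(self) -> None:
        if self.fs <= 100.0:
            raise ValueError(
                f"fs={self.fs} Hz cannot resolve the 25-50 Hz band "
                "(need fs > 100 Hz)")
        n_ch = len(self.labels)
        for k, tr in enumerate(self.trials):
            tr = np.asarray(tr, dtype=float)
            if tr.ndim != 2 or tr.shape[0] != n_ch:
                raise ValueError(
                    f"trial {k} has shape {tr.shape}; expected ({n_ch}, n_samples)")
            self.trials[k] = tr
        out = [d for d in self.durations
               if not (DURATION_RANGE[0] <= d <= DURATION_RANGE[1])]
        if out:
            warnings.warn(
                f"{len(out)} trial(s) outside the {DURATION_RANGE[0]}-"
                f"{DURATION_RANGE[1]} s movement-window range", stacklevel=2)

    @property
    def durations(self) -> list[float]:
        return [tr.shape[1] / self.fs for tr in self.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class BandTrialSet:
    """Detail coefficients of one analysis band for every trial."""

    band: str
    level: int
    coeff_rate: float  # fs / 2**level
    trials: list  # of (n_channels, n_coeffs) arrays
    labels: tuple[str, ...] = ()


def highpass(trials: TrialSet, cutoff: float = 0.3, order: int = 4) -> TrialSet:
    """Zero-phase Butterworth high-pass; removes DC and slow drift.

    Applied forward-backward so movement-onset timing is not shifted.
    """
    if cutoff >= trials.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist ({trials.fs / 2} Hz)")
    sos = butter(order, cutoff, btype="highpass", fs=trials.fs, output="sos")
    filtered = [sosfiltfilt(sos, tr, axis=1) for tr in trials.trials]
    return TrialSet(subject_id=trials.subject_id, session=trials.session,
                    labels=trials.labels, fs=trials.fs, trials=filtered,
                    intervals=list(trials.intervals))


def _movement_windows(speed: np.ndarray, frac: float, floor: float) -> list[tuple[int, int]]:
    """Detect movements as excursions of the speed trace.

    A movement is seeded at each local speed maximum above ``floor`` times
    the global peak; its onset/end are where the speed last/first crosses
    ``frac`` of that movement's own peak.  Overlapping windows are merged.
    """
    n = speed.size
    peak = speed.max(initial=0.0)
    if peak <= 0.0:
        return []
    seeds = [i for i in range(1, n - 1)
             if speed[i] >= speed[i - 1] and speed[i] > speed[i + 1]
             and speed[i] >= floor * peak]
    windows: list[tuple[int, int]] = []
    for s in seeds:
        thr = frac * speed[s]
        a = s
        while a > 0 and speed[a - 1] > thr:
            a -= 1
        b = s
        while b < n - 1 and speed[b + 1] > thr:
            b += 1
        if windows and a <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], b))
        else:
            windows.append((a, b))
    return windows


def segment(continuous: np.ndarray, kinematics: np.ndarray, fs: float,
            labels: tuple[str, ...], onset_frac: float = 0.05,
            subject_id: str = "", session: str = "pre",
            smooth_sec: float = 0.05) -> TrialSet:
    """Cut continuous EEG into one window per reaching movement.

    ``kinematics`` is the goniometer angle trace sampled on the EEG clock;
    movement onset and end are where the angular speed crosses
    ``onset_frac`` of that movement's peak speed.  Adding a constant to the
    angle trace does not change the segmentation (only the derivative is
    used).
    """
    continuous = np.asarray(continuous, dtype=float)
    angle = np.asarray(kinematics, dtype=float).ravel()
    if continuous.shape[1] != angle.size:
        raise ValueError("kinematic trace must be sampled on the EEG clock "
                         f"({continuous.shape[1]} EEG vs {angle.size} kinematic samples)")
    speed = np.abs(np.gradient(angle)) * fs
    w = max(1, int(round(smooth_sec * fs)))
    if w > 1:
        speed = np.convolve(speed, np.ones(w) / w, mode="same")
    windows = _movement_windows(speed, onset_frac, floor=0.5)
    if not windows:
        warnings.warn("no movement detected in kinematic trace; "
                      "returning an empty TrialSet", stacklevel=2)
    trials = [continuous[:, a:b + 1] for a, b in windows]
    return TrialSet(subject_id=subject_id, session=session, labels=labels,
                    fs=fs, trials=trials, intervals=windows)


def reject_artifacts(trials: TrialSet, peak_to_peak_limit: float = 150.0) -> TrialSet:
    """Drop trials whose peak-to-peak amplitude exceeds the limit on any
    channel (automated stand-in for visual artifact screening; limit in the
    amplitude units of the data, conventionally microvolts)."""
    keep, intervals = [], []
    for k, tr in enumerate(trials.trials):
        if np.ptp(tr, axis=1).max(initial=0.0) <= peak_to_peak_limit:
            keep.append(tr)
            if trials.intervals:
                intervals.append(trials.intervals[k])
    n_drop = trials.n_trials - len(keep)
    logger.info("artifact screening: retained %d, dropped %d trials",
                len(keep), n_drop)
    if trials.n_trials and not keep:
        raise ValueError(
            f"all {trials.n_trials} trials exceeded the {peak_to_peak_limit} "
            "peak-to-peak limit; review the limit or the data scaling")
    return TrialSet(subject_id=trials.subject_id, session=trials.session,
                    labels=trials.labels, fs=trials.fs, trials=keep,
                    intervals=intervals)


def band_levels(fs: float) -> dict[str, int]:
    """Map each analysis band to its dyadic detail level at rate ``fs``.

    Detail level k spans fs/2^(k+1) .. fs/2^k, so the 25-50 Hz band requires
    fs = 50 * 2^k; together with the Nyquist constraint the admissible rates
    are 200*2^j Hz (200, 400, 800, ...).
    """
    ratio = fs / 50.0
    k = np.log2(ratio)
    if ratio < 4 or abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"fs={fs} Hz does not place the analysis bands on dyadic detail "
            "levels; admissible rates are 200*2^k Hz (200, 400, 800, ...)")
    top = int(round(k))  # detail level of the 25-50 Hz band
    return {"25-50": top, "12.5-25": top + 1, "6.25-12.5": top + 2}


def wavelet_bands(trials: TrialSet, wavelet: str = "coif1",
                  mode: str = "periodization") -> dict[str, BandTrialSet]:
    """Coiflet-1 dyadic wavelet decomposition into the three analysis bands.

    Returns one :class:`BandTrialSet` per band, keyed by band label.  Each
    trial is trimmed to a multiple of 2^max_level samples (at most 75 ms at
    200 Hz) so that the periodized transform is exactly orthonormal: the
    coefficient energies then add up to the analyzed window's energy and
    level k holds exactly n_samples/2^k coefficients.
    """
    levels = band_levels(trials.fs)
    max_level = max(levels.values())
    out = {band: BandTrialSet(band=band, level=lev,
                              coeff_rate=trials.fs / 2 ** lev, trials=[],
                              labels=trials.labels)
           for band, lev in levels.items()}
    block = 2 ** max_level
    for tr in trials.trials:
        if mode == "periodization":
            n_use = tr.shape[1] - tr.shape[1] % block
            if n_use:
                tr = tr[:, :n_use]
        if pywt.dwt_max_level(tr.shape[1], wavelet) < max_level:
            raise ValueError(
                f"trial of {tr.shape[1]} samples too short for a level-"
                f"{max_level} decomposition with {wavelet}")
        coeffs = pywt.wavedec(tr, wavelet, level=max_level, mode=mode, axis=1)
        # wavedec order: [cA_L, cD_L, cD_{L-1}, ..., cD_1]
        for band, lev in levels.items():
            out[band].trials.append(coeffs[max_level - lev + 1])
    return out
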