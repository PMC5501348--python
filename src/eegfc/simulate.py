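"""Synthetic cohorts with a planted biomarker-recovery relationship.

The generator emulates the structure of the study this package targets: 58
scalp channels of task EEG recorded pre and post a 12-week intervention,
five sets of ten reaching trials per session, and an upper-extremity
Fugl-Meyer score (FMUE) per session.  Each subject carries a known
pairwise source-coupling structure; the planted effect is a decrease in
coupling density within the unaffected hemisphere whose magnitude grows
with the subject's FMUE improvement, so the full pipeline should recover a
negative Spearman correlation between the change in unaffected-hemisphere
intradensity and dFMUE.

Signal model per trial and frequency band: every channel owns a private
resonant AR(2) source with pole frequency centered in the band, and
coupling is carried by shared AR(2) sources loaded by groups of channels,
each contributing a controlled fraction of its members' variance — the
generic statistical dependence GMA responds to.  Volume conduction is
emulated by an instantaneous distance-decaying mixing kernel over the 2-D
montage layout, and white sensor noise is added.

The coupled network is broadband: each source group (a coupled channel
pair or triangle) shares one independent source per frequency band, so a
coupled pair is dependent in every band.  This matters because the
Coiflet-1 filter bank has soft band edges — a channel's band coefficients
carry substantial energy leaked from the neighboring bands — and
broadband coupling makes the leaked energy shared as well, keeping the
in-band dependence at full strength instead of being diluted by
independent leakage.

The planted effect lives on a ring of pairwise source groups over the 15
unaffected-hemisphere electrodes (every set electrode on two coupled
pairs).  Pre-intervention the ring is complete; post-intervention the
planted fraction of ring edges loses its *target-band* shared source only
(with one fractional-strength edge so the planted continuous density
change is realized exactly), while the other bands keep the full ring.
The band-specific decoupling mirrors a beta-band reorganization on top of
a persistent broadband network, and it keeps the contrast bands nearly
stable: their own shared-source structure is unchanged between sessions,
so they see only an attenuated echo of the change through filter
leakage.

The remaining 43 channels carry a session-stable background network of
broadband triangle groups (three channels sharing one source).  The
triangles emulate the ongoing functional network of the rest of the
scalp, and they matter for the measurement: a sparsity threshold always
keeps a fixed number of links, so the thresholded graph must be anchored
by stable links; otherwise the spare budget churns among borderline
noise links from session to session and drowns the planted intradensity
change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .montage import CHANNELS_58, HemisphereMap, channel_positions, default_hemisphere_map
from .preprocess import BAND_LABELS, TrialSet

__all__ = ["EffectSpec", "SubjectSpec", "make_cohort", "simulate_session",
           "planted_delta_density", "planted_pair_set"]

#: Geometric band centers, Hz, for the resonant sources.
BAND_CENTERS = {"6.25-12.5": 8.84, "12.5-25": 17.68, "25-50": 35.36}

N_SET = 15            # electrodes per hemisphere set
N_SET_PAIRS = N_SET * (N_SET - 1) // 2  # 105 unordered within-set pairs


@dataclass
class EffectSpec:
    """Study conditions for a synthetic cohort.

    ``target_rho`` is the magnitude of the planted Spearman correlation
    between the change in unaffected-hemisphere coupling density and
    dFMUE (the realized correlation is -target_rho); at the default 1.0
    the planted density change is a strictly decreasing function of dFMUE.
    """

    n_subjects: int = 30
    target_rho: float = 1.0
    band: str = "12.5-25"
    noise_sd: float = 0.3          # white sensor noise, relative amplitude
    mixing_spread: float = 0.05    # volume-conduction kernel width (head radii)
    fs: float = 200.0
    n_trials: int = 50             # five sets of ten reaches
    duration_range: tuple[float, float] = (1.24, 3.98)
    rejection_fraction: float = 0.0  # simulated artifact-rejection rate
    shared_variance: float = 0.45  # per-group shared fraction at full strength
    delta_range: tuple[float, float] = (0.02, 0.12)  # |density change| span
    #: relative strengths of the two background triangle rounds; the weaker
    #: round oversubscribes the sparsity budget so borderline competition
    #: happens among stable out-of-set links, not random noise links
    background_strengths: tuple[float, float] = (1.0, 0.8)
    amplitude: float = 10.0        # channel scale, microvolts
    source_radius: float = 0.95    # AR(2) pole radius (bandwidth control)

    def validate(self) -> None:
        if not 0.0 <= self.target_rho <= 1.0:
            raise ValueError(f"target_rho must be in [0, 1], got {self.target_rho}")
        if self.n_subjects < 5:
            raise ValueError(f"need at least 5 subjects, got {self.n_subjects}")
        if self.band not in BAND_LABELS:
            raise ValueError(f"band must be one of {BAND_LABELS}, got {self.band!r}")
        if not 0.0 <= self.rejection_fraction < 1.0:
            raise ValueError("rejection_fraction must be in [0, 1)")
        if not 0.0 < self.shared_variance <= 1.0:
            raise ValueError("shared_variance must be in (0, 1]")
        lo, hi = self.delta_range
        if not 0.0 < lo < hi or hi * N_SET_PAIRS > N_SET:
            raise ValueError(
                f"delta_range must satisfy 0 < lo < hi <= "
                f"{N_SET / N_SET_PAIRS:.4f} (the planted ring holds "
                f"{N_SET} pairs)")


@dataclass
class SubjectSpec:
    """One synthetic subject: scores plus pre/post source-coupling structure."""

    subject_id: str
    affected_side: str            # "left" or "right" (arm)
    lesion_class: str             # "cortex", "subcortical", "other"
    fmue_pre: int
    fmue_post: int
    coupling_pre: np.ndarray      # (58, 58) symmetric, zero diagonal, [0, 1]
    coupling_post: np.ndarray
    seed: int
    #: generative detail behind the coupling matrices: per session, a dict
    #: mapping band label -> list of (channel-index tuple, shared-variance
    #: fraction) source groups.  The coupling matrices record the target
    #: band's pairwise structure.  When absent, every nonzero coupling
    #: entry becomes its own two-channel group in the target band with
    #: fraction shared_variance * entry.
    sources_pre: dict | None = None
    sources_post: dict | None = None

    def __post_init__(self) -> None:
        for name in ("fmue_pre", "fmue_post"):
            v = getattr(self, name)
            if not 0 <= v <= 66:
                raise ValueError(f"{name}={v} outside the 0-66 FMUE range")
        for name in ("coupling_pre", "coupling_post"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (len(CHANNELS_58),) * 2:
                raise ValueError(f"{name} must be 58x58")
            if not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
                raise ValueError(f"{name} must be symmetric with zero diagonal")
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"{name} entries must lie in [0, 1]")
            setattr(self, name, m)

    @property
    def delta_fmue(self) -> int:
        return self.fmue_post - self.fmue_pre


def planted_pair_set(affected_side: str,
                     hemisphere_map: HemisphereMap | None = None) -> list[int]:
    """Channel indices of the subject's anatomically unaffected hemisphere.

    The downstream analysis flips right-lesion subjects (left arm affected)
    across the midsagittal plane before measuring the unaffected-hemisphere
    set, so for those subjects the planted set is the flip image of the
    map's unaffected set; for left-lesion subjects it is the set itself.
    """
    hmap = hemisphere_map or default_hemisphere_map()
    labels = list(hmap.unaffected_set)
    if affected_side == "left":
        flip = hmap.flip_map
        labels = [flip[lab] for lab in labels]
    elif affected_side != "right":
        raise ValueError(f"affected_side must be 'left' or 'right', got {affected_side!r}")
    return [CHANNELS_58.index(lab) for lab in labels]


def _ring_weights(order: list[int], total_weight: float) -> list[tuple[int, int, float]]:
    """Distribute ``total_weight`` over the ring edges of ``order``.

    Ring edges join consecutive elements of the permuted electrode order
    (every electrode on exactly two pairs).  Full edges get weight 1 in
    order; one marginal edge carries the fractional remainder, so the
    summed weight equals ``total_weight`` exactly and densities vary
    continuously.
    """
    edges = [(order[k], order[(k + 1) % len(order)]) for k in range(len(order))]
    full = int(np.floor(total_weight + 1e-12))
    rem = total_weight - full
    out = [(i, j, 1.0) for i, j in edges[:full]]
    if rem > 1e-12 and full < len(edges):
        i, j = edges[full]
        out.append((i, j, rem))
    return out


def _coupling_matrix(pairs: list[tuple[int, int, float]]) -> np.ndarray:
    m = np.zeros((len(CHANNELS_58),) * 2)
    for i, j, w in pairs:  # accumulate coincident pairs, cap at full strength
        m[i, j] = m[j, i] = min(1.0, m[i, j] + w)
    return m


def _triangle_groups(order: list[int]) -> list[tuple[int, ...]]:
    """Partition a permuted channel list into triples (plus one larger or
    smaller final group when the count is not divisible by three)."""
    n3 = len(order) // 3
    groups = [tuple(order[3 * k:3 * k + 3]) for k in range(n3)]
    rem = len(order) - 3 * n3
    if rem == 1 and groups:
        groups[-1] = groups[-1] + (order[-1],)
    elif rem:
        groups.append(tuple(order[3 * n3:]))
    return groups


def planted_delta_density(subject: SubjectSpec,
                          hemisphere_map: HemisphereMap | None = None) -> float:
    """Planted pre-to-post change in unaffected-hemisphere coupling density.

    Density is the summed within-set coupling weight over the number of
    possible within-set pairs, i.e. the mean coupling strength.
    """
    idx = planted_pair_set(subject.affected_side, hemisphere_map)
    sub_pre = subject.coupling_pre[np.ix_(idx, idx)]
    sub_post = subject.coupling_post[np.ix_(idx, idx)]
    return float((sub_post.sum() - sub_pre.sum()) / 2.0 / N_SET_PAIRS)


def make_cohort(spec: EffectSpec, seed: int,
                hemisphere_map: HemisphereMap | None = None) -> list[SubjectSpec]:
    """Generate a cohort with the planted density-recovery relationship.

    dFMUE values are an evenly spread permutation of the 0-22 clinical
    range (so they always span >= 20 points); the planted density change is
    tied to dFMUE through a Gaussian copula calibrated so the sample
    Spearman correlation is -target_rho on average (Pearson latent
    correlation 2*sin(pi*rho/6)).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    hmap = hemisphere_map or default_hemisphere_map()

    latent = rng.standard_normal(n)
    order = rankdata(latent, method="ordinal") - 1  # 0..n-1, no ties
    dfmue = np.round(22.0 * order / (n - 1)).astype(int)
    fmue_pre = np.array([rng.integers(8, min(49, 66 - d) + 1) for d in dfmue])

    z = ndtri(rankdata(dfmue, method="average") / (n + 1))
    z = (z - z.mean()) / max(z.std(), 1e-12)
    # exact at the endpoint so rho=1 adds no tie-breaking noise at all
    rho_lat = 1.0 if spec.target_rho == 1.0 else \
        2.0 * np.sin(np.pi * spec.target_rho / 6.0)
    g = rho_lat * z + np.sqrt(max(0.0, 1.0 - rho_lat**2)) * rng.standard_normal(n)
    lo, hi = spec.delta_range
    delta_density = -(lo + (hi - lo) * ndtr(g))

    sides = rng.choice(["right", "left"], size=n, p=[22 / 30, 8 / 30])
    lesions = rng.choice(["cortex", "subcortical", "other"],
                         size=n, p=[17 / 30, 11 / 30, 2 / 30])

    cohort = []
    for k in range(n):
        idx = planted_pair_set(sides[k], hmap)
        order = list(rng.permutation(idx))
        w_pre = float(N_SET)  # full ring over the set
        w_post = w_pre + delta_density[k] * N_SET_PAIRS
        rest = [i for i in range(len(CHANNELS_58)) if i not in idx]
        bg_groups, bg_pairs = [], []
        for strength in spec.background_strengths:
            c_bg = spec.shared_variance * strength
            for members in _triangle_groups(list(rng.permutation(rest))):
                bg_groups.append((members, c_bg))
                bg_pairs.extend((a, b, strength) for ai, a in enumerate(members)
                                for b in members[ai + 1:])
        full_ring = [((i, j), spec.shared_variance * wt)
                     for i, j, wt in _ring_weights(order, w_pre)]
        sources = {}
        for session, w in (("pre", w_pre), ("post", w_post)):
            # band-specific decoupling: only the target band loses edges
            target_ring = [((i, j), spec.shared_variance * wt)
                           for i, j, wt in _ring_weights(order, w)]
            sources[session] = {
                band: (target_ring if band == spec.band else full_ring)
                + bg_groups
                for band in BAND_LABELS
            }
        cohort.append(SubjectSpec(
            subject_id=f"S{k + 1:02d}",
            affected_side=str(sides[k]),
            lesion_class=str(lesions[k]),
            fmue_pre=int(fmue_pre[k]),
            fmue_post=int(fmue_pre[k] + dfmue[k]),
            coupling_pre=_coupling_matrix(_ring_weights(order, w_pre) + bg_pairs),
            coupling_post=_coupling_matrix(_ring_weights(order, w_post) + bg_pairs),
            seed=int(rng.integers(0, 2**31 - 1)),
            sources_pre=sources["pre"],
            sources_post=sources["post"],
        ))
    return cohort


def _ar2_sources(rng: np.random.Generator, n_sources: int, n_samples: int,
                 f0: float, fs: float, radius: float) -> np.ndarray:
    """Unit-variance resonant AR(2) processes with poles at f0."""
    theta = 2.0 * np.pi * f0 / fs
    a = np.array([1.0, -2.0 * radius * np.cos(theta), radius**2])
    burn = 200
    w = rng.standard_normal((n_sources, n_samples + burn))
    y = lfilter([1.0], a, w, axis=1)[:, burn:]
    sd = y.std(axis=1, keepdims=True)
    return y / np.where(sd > 0, sd, 1.0)


def mixing_matrix(spread: float) -> np.ndarray:
    """Distance-decaying instantaneous volume-conduction kernel.

    Rows are normalized to unit L2 norm so channel variances are preserved;
    spread = 0 disables mixing (identity).
    """
    if spread <= 0:
        return np.eye(len(CHANNELS_58))
    pos = channel_positions()
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    k = np.exp(-d2 / (2.0 * spread**2))
    return k / np.linalg.norm(k, axis=1, keepdims=True)


def simulate_session(subject: SubjectSpec, session: str, spec: EffectSpec,
                     seed: int | None = None) -> TrialSet:
    """Simulate one recording session (all trials) for a subject.

    Deterministic given the subject's seed (or an explicit ``seed``) and
    the session label.
    """
    if session not in ("pre", "post"):
        raise ValueError(f"session must be 'pre' or 'post', got {session!r}")
    spec.validate()
    base = subject.seed if seed is None else seed
    rng = np.random.default_rng([base, 0 if session == "pre" else 1])
    if session == "pre":
        coupling, band_groups = subject.coupling_pre, subject.sources_pre
    else:
        coupling, band_groups = subject.coupling_post, subject.sources_post
    if band_groups is None:
        # fallback for hand-built subjects: one two-channel source per
        # nonzero coupling entry, in the target band only
        iu = np.triu_indices(len(CHANNELS_58), k=1)
        pw = coupling[iu]
        active = np.nonzero(pw > 0)[0]
        band_groups = {spec.band: [((int(iu[0][a]), int(iu[1][a])),
                                    spec.shared_variance * pw[a])
                                   for a in active]}
    # per-channel, per-band total shared variance; the private source
    # carries the remainder
    shared_tot = {}
    for band in BAND_LABELS:
        tot = np.zeros(len(CHANNELS_58))
        for members, c in band_groups.get(band, []):
            for i in members:
                tot[i] += c
        if tot.max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("coupling structure commits more than 100% of a "
                             "channel's variance; reduce shared_variance")
        shared_tot[band] = tot

    mix = mixing_matrix(spec.mixing_spread)
    keep = rng.random(spec.n_trials) >= spec.rejection_fraction
    trials = []
    for t in range(spec.n_trials):
        dur = rng.uniform(*spec.duration_range)
        n = int(round(dur * spec.fs))
        z = np.zeros((len(CHANNELS_58), n))
        for band in BAND_LABELS:
            f0 = BAND_CENTERS[band]
            groups = band_groups.get(band, [])
            priv = _ar2_sources(rng, len(CHANNELS_58), n, f0, spec.fs,
                                spec.source_radius)
            zb = np.sqrt(np.clip(1.0 - shared_tot[band], 0.0, 1.0))[:, None] * priv
            if groups:
                shared = _ar2_sources(rng, len(groups), n, f0, spec.fs,
                                      spec.source_radius)
                for p, (members, c) in enumerate(groups):
                    for i in members:
                        zb[i] += np.sqrt(c) * shared[p]
            z += zb
        z /= np.sqrt(len(BAND_LABELS))
        z = mix @ z
        z += spec.noise_sd * rng.standard_normal(z.shape)
        if keep[t]:
            trials.append(spec.amplitude * z)
    return TrialSet(subject_id=subject.subject_id, session=session,
                    labels=CHANNELS_58, fs=spec.fs, trials=trials)
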