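# Methods

## Overview

`eegfc` implements a functional-connectivity biomarker pipeline for
task-state EEG recorded before and after an upper-limb rehabilitation
intervention, together with a synthetic-cohort generator that makes the
entire chain testable without clinical recordings.  The stages are:

1. **Preprocessing** — 0.3 Hz zero-phase high-pass, kinematic movement
   segmentation, peak-to-peak artifact screening, and a Coiflet-1 dyadic
   wavelet filter bank splitting each trial into 6.25–12.5, 12.5–25 and
   25–50 Hz bands.
2. **Connectivity** — the generalized measure of association (GMA)
   applied in a time-delay embedding space (TGMA) for every channel pair,
   averaged across trials into one dependence matrix per subject, session
   and band.
3. **Graphs** — binarization by sparsity (default 5% of links, near the
   efficiency-cost-optimization value 3/(N−1) ≈ 0.053 for N = 58) or by a
   per-subject statistical threshold (median + 1 SD across sessions);
   global/local efficiency, hemispheric interdensity and intradensity.
4. **Statistics** — Spearman correlation (biomarker change vs. FMUE
   change) and rank regression (initial biomarker vs. FMUE change), with
   permutation p-values from shuffling the outcome across subjects, and a
   max-statistic permutation correction for per-electrode maps.

## The dependence measure

For paired samples `{(x_i, y_i)}` in arbitrary metric spaces, GMA finds
for each `i` the nearest X-neighbor `j* = argmin_{j≠i} δ(x_i, x_j)` and
the rank `r_i` of `δ(y_{j*}, y_i)` among all Y-distances to `y_i`
(midranks over exactly tied distances).  The statistic

    GMA = 1/(n−1) · Σ_r (n−r) P(R=r) = (n − mean r_i)/(n−1)

is 0.5 under independence and approaches 1 as dependence concentrates
ranks at 1.  The telescoped right-hand form is the implementation; the
test suite checks exact agreement against a literal enumeration of the
procedure.  Distances are Euclidean, compared as squares (a strictly
monotone rescaling, so ranks and ties are unchanged) to keep exact ties
exact in floating point.  TGMA embeds each band coefficient series with
dimension m = 4 (false-nearest-neighbors default; Kennel ratio test,
ratio 15, 1% floor) and delay τ = 1 — the dyadic subsampling of the
wavelet bands decorrelates successive coefficients, so no ACF-based delay
selection is needed for band inputs (an `acf_lag` utility with
first-zero / first-minimum / 1-e-decay criteria is provided for raw
series; its first-zero criterion is read against the 1.96/√T white-noise
sampling floor).  GMA is directional; the undirected edge weight is the
mean of the two directions (configurable min/mean/max).

All-pairs computation uses the identity above: per channel, one
nearest-neighbor vector and one per-row midrank matrix are precomputed,
after which every directed pair value is a vectorized gather — O(C·n²)
distance work instead of O(C²·n²).

## Sampling rate and the filter bank

The dyadic detail level k spans fs/2^(k+1)–fs/2^k, so the three analysis
bands sit exactly on detail levels only for fs = 200·2^j Hz; the package
default is 200 Hz (levels 2, 3, 4) and other rates are rejected with the
admissible list.  Boundary handling is periodized with each trial trimmed
to a multiple of 2^4 samples (at most 75 ms at 200 Hz): the transform is
then exactly orthonormal, so band energies add up to the analyzed-window
energy and level k holds exactly n/2^k coefficients.  (Symmetric
extension remains available via the `mode` argument but inflates energy
by the redundant boundary coefficients.)

## Graph metrics and thresholds

Efficiency uses BFS shortest paths with 1/d = 0 for disconnected pairs;
for unweighted graphs the global value already lies in [0, 1], so no
further normalization is applied.  Local efficiency of a node is the
global efficiency of its neighbor-induced subgraph (0 for degree < 2),
reported per node and as the network mean.  Interdensity between the two
15-electrode hemisphere sets is the crossing-edge count over 15²;
intradensity is realized over possible unordered within-set pairs.
Sparsity binarization keeps round(t·1653) strongest upper-triangle
entries with half-up rounding and (row, column) tie-breaking, so the
result is deterministic; the statistical threshold pools both sessions of
one subject within a band (sample SD) and keeps strictly-greater entries.
The right-hemisphere electrode list is used exactly as published
(including C5P where mirror symmetry would suggest C4P); a
`symmetric=True` map substitutes C4P.  Matrices of subjects with
right-hemisphere lesions are flipped across the midsagittal plane before
any hemispheric measurement, so "affected" is always the left list.

## Statistics

Permutation p-values are two-sided and observed-included,
p = (1 + #{|T_b| ≥ |T_obs|})/(B + 1), with B = 10,000 by default and only
the outcome (ΔFMUE) permuted.  Rank regression on a single predictor
satisfies R² = r_s² exactly; this identity is asserted in the tests.  The
per-electrode correction uses the maximum |statistic| over electrodes
within one shared permutation stream, giving strong family-wise control.
The cortex subgroup is a case-insensitive substring match on the lesion
location, which includes mixed cortical/subcortical lesions.  The
sparsity-threshold sweep reports the full r_s table over the t-grid along
with the selected t (maximum mean |r_s| over the metric × band grid), so
the circularity of threshold selection is auditable rather than hidden.

## The synthetic cohort

The generator emulates the reference study's structure: 30 subjects
(22 right / 8 left affected arm, 17/11/2 cortex/subcortical/other lesions
in expectation), FMUE integer scores with pre ∈ [8, 49] and improvements
spread over the full 0–22 clinical range, two sessions of 50 reaching
trials of 1.24–3.98 s at 200 Hz (both defaults following the study
conditions; tests use reduced trial counts/durations, stated below).

**Signals.**  Per band, every channel owns a private resonant AR(2)
source (pole radius 0.95, pole frequency at the band's geometric center);
coupling is carried by shared AR(2) sources loaded by groups of channels,
each contributing a set fraction (default 0.45) of its members' variance.
Volume conduction is a distance-decaying instantaneous mixing kernel over
the approximate 2-D montage layout (Gaussian width 0.05 head radii by
default; rows unit-normalized; width 0 disables mixing), plus white
sensor noise (0.3 relative).  Channels are scaled to
10 µV so the default 150 µV artifact limit passes clean data.

**Planted effect.**  The coupled network is broadband — each source group
has one independent source per band — because the Coiflet-1 bank has soft
band edges: roughly a quarter of a band's coefficient energy is leakage
from neighboring bands, and broadband coupling makes that leakage shared
rather than diluting.  The planted structure is a ring over the 15
unaffected-hemisphere electrodes; post-intervention a planted fraction of
ring edges loses its 12.5–25 Hz shared source only (other bands keep the
full ring), with one fractional-strength edge realizing the planted
continuous density change exactly.  The remaining 43 channels carry a
session-stable background of broadband triangle groups in two rounds
(relative strengths 1.0 and 0.8).  The second round intentionally
oversubscribes the 83-edge sparsity budget: borderline competition then
happens among stable out-of-set links instead of random noise links,
which would otherwise churn between sessions and drown the planted
intradensity change.  The planted density change is tied to ΔFMUE by a
Gaussian copula with latent correlation 2·sin(π·ρ/6), giving a sample
Spearman of −ρ on average; at the default ρ = 1 the change is a strictly
decreasing function of ΔFMUE.

Band specificity of the planted effect is approximate, as it would be in
real data analyzed with this filter bank: because part of the beta-band
change leaks into the adjacent bands' coefficients, the contrast bands
show attenuated echoes of the planted association rather than exact
nulls.

**What the generator does not model.**  No biophysical head geometry, no
lesion anatomy, no 1/f spectral slope, no ocular/muscle artifacts beyond
white noise, no nonstationarity within a trial.  Passing tests therefore
demonstrate that the pipeline recovers statistical dependence structure
planted under these idealized conditions — not that it would behave
identically on clinical EEG, where volume conduction is stronger and the
dependence floor between neighboring channels is higher.

## Problem sizes used in tests

The end-to-end recovery check runs 10 cohort seeds × 30 subjects × 2
sessions × 20 trials of ~2 s (the level-3 band then gives 47 embedding
points per trial), with B = 1000 permutations; at this scale the measured
Spearman between the unaffected-hemisphere intradensity change and ΔFMUE
averages ≈ −0.69 for a planted ρ = 0.7.  Shorter trials weaken TGMA
(fewer embedding points) faster than extra trials compensate, which is
why ~2 s windows are used rather than the 1.24 s minimum.  Statistical
calibration uses 2,000 null data sets at n = 30, B = 1000.  Oracle
equivalence suites use 1,000 random GMA instances (n ≤ 12) and 500 random
graphs (N ≤ 12).

## Numerical conventions

- Nearest-neighbor ties break to the smallest index; rank ties take
  midranks; both are identical across the pairwise, all-pairs numpy, and
  all-pairs numba code paths (verified bitwise in tests).
- Sparsity edge counts round half-up; value ties at the cut break in
  (row, column) order.
- Degenerate statistics (constant inputs, zero pooled SD) are reported as
  errors or empty graphs with warnings, never silently as numbers.
- One master seed derives all stage seeds via `numpy.random.SeedSequence`;
  rerunning a pipeline with the same configuration and seed reproduces
  every artifact byte for byte.

## Known limitations

- The 58-channel montage beyond the 30 published hemisphere electrodes is
  a reconstruction (symmetric 10/10 layout in the same naming
  convention); coordinates are approximate and only drive the synthetic
  mixing kernel.
- EDF files are read (via MNE) but trial sets are written only in the
  documented HDF5 layout; no EDF export.
- The statistical-threshold route is implemented and tested but the
  planted-effect recovery is validated on the sparsity route, mirroring
  where the reference analysis found its effects.
- GMA's null value exceeds 0.5 slightly for short autocorrelated series
  (embedding bias); trial averaging and the rank statistics downstream
  are unaffected because the bias is common to all pairs.
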