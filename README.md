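# eegfc — EEG functional-connectivity biomarkers of motor recovery

`eegfc` builds and validates graph-theoretic biomarkers of post-stroke
motor recovery from task-state EEG.  It targets the setting of an
upper-limb rehabilitation study: 58-channel EEG recorded during robotic
reaching, before and after a 12-week intervention, scored with the
upper-extremity Fugl-Meyer assessment (FMUE, 0–66).  The question the
package answers is whether network-level reorganization visible in EEG
tracks, or predicts, functional improvement (ΔFMUE).

It is written for researchers in rehabilitation neurophysiology and
EEG network analysis who want a tested, reproducible implementation of
this analysis chain — including a synthetic-cohort simulator with a
*planted, known* biomarker–recovery relationship, so every stage can be
verified end to end without access to clinical recordings.

## The method

1. **Preprocess** — 0.3 Hz zero-phase high-pass; one window per reaching
   movement cut from the goniometer trace (onset/end at 5% of each
   movement's peak angular speed); peak-to-peak artifact screening; a
   Coiflet-1 dyadic wavelet filter bank splitting trials into the
   6.25–12.5 Hz (mu/alpha), 12.5–25 Hz (beta) and 25–50 Hz (low gamma)
   bands.

2. **Connectivity** — the generalized measure of association applied in
   a time-delay embedding space (TGMA).  For samples {(xᵢ, yᵢ)} GMA finds
   each point's nearest X-neighbor j\* and ranks δ(y_{j\*}, yᵢ) among the
   Y-distances; with the empirical rank distribution P(R=r),

   GMA = 1/(n−1) · Σᵣ (n−r) P(R=r),

   which is 0.5 under independence and → 1 under dependence.  Band
   coefficient series are embedded with m = 4, τ = 1 (the dyadic
   subsampling decorrelates successive coefficients), and the two
   directed values are averaged into one undirected edge weight.  Trials
   are averaged into one 58×58 dependence matrix per subject, session
   and band.

3. **Graphs** — binarize by sparsity (default t = 0.05, corroborated by
   the efficiency-cost-optimization threshold 3/(58−1) ≈ 0.053) or by a
   per-subject statistical threshold (median + 1 SD across sessions);
   compute global efficiency E_glo, local efficiency E_loc (network and
   per-electrode), hemispheric interdensity K_inter and the intradensity
   K_intra of the affected and unaffected hemisphere electrode sets,
   after flipping right-lesion subjects across the midsagittal plane.

4. **Validate** — Spearman r_s between biomarker change and ΔFMUE, and
   rank-regression R² of ΔFMUE on initial biomarker values, over the full
   cohort and the cortical-lesion subgroup; p-values from shuffling ΔFMUE
   across subjects (10,000 permutations by default); max-statistic
   permutation correction for the 58-electrode local-efficiency maps.

## Worked example

Simulate a small cohort with a perfectly planted effect (the change in
unaffected-hemisphere coupling density strictly decreasing in ΔFMUE) and
run every stage:

```python
from eegfc import EffectSpec, PipelineConfig, run_all

run_all(PipelineConfig(seed=7, n_permutations=1000), "results/demo",
        effect=EffectSpec(n_subjects=12, target_rho=1.0, n_trials=12,
                          duration_range=(1.9, 2.1)))
```

then inspect the association between the unaffected-hemisphere
intradensity change and functional improvement in each band:

```python
import pandas as pd
res = pd.read_csv("results/demo/stat_results.tsv", sep="\t")
rows = res[(res["mode"] == "change_vs_change") & (res.group == "all")
           & (res.metric == "intradensity_unaffected")]
for _, c in rows.iterrows():
    print(f"{c.band}: r_s = {c.value:.2f}, p = {c.p_perm:.4f} (n = {c.n_subjects})")
```

```
6.25-12.5: r_s = -0.47, p = 0.1059 (n = 12)
12.5-25: r_s = -0.90, p = 0.0010 (n = 12)
25-50: r_s = -0.60, p = 0.0350 (n = 12)
```

The planted beta-band decoupling of the unaffected hemisphere is
recovered as a strong negative Spearman correlation with ΔFMUE in the
12.5–25 Hz cell — the biomarker moves opposite to recovery.  The
neighboring bands show attenuated echoes of the effect: the Coiflet-1
filter bank has soft band edges, so part of the beta-band change leaks
into the adjacent bands' coefficients.  `results/demo/` now holds the cohort
CSV, every per-subject dependence matrix (TSV + JSON sidecar), the
long-format biomarker table, the full statistics grid and a manifest
that reproduces the run byte for byte.

The same stages are available as a CLI (`eegfc simulate / preprocess /
connect / graph / stats / run-all`), all reading one plain-text config
file (`[pipeline]` section, `key = value` entries matching
`PipelineConfig` fields) with flag overrides.

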