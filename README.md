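# vfcsf

Contrast sensitivity across (eccentricity) and around (polar angle) the
visual field: a reusable pipeline for simulating adaptive
orientation-discrimination experiments, fitting contrast sensitivity
functions (CSFs) to trial-wise binary responses, comparing models by BIC,
M-scaling stimulus sizes via cortical magnification, and quantifying
visual-field asymmetries.

## What it does

* **Cortical M-scaling** (`vfcsf.magnification`) — meridian-specific linear
  cortical magnification `M(E) = M0 / (1 + aE + bE³)` and computation of
  peripheral stimulus sizes that equate cortical extent with a parafoveal
  reference (horizontal meridian = mean of nasal- and temporal-scaled
  sizes).
* **Logistic contrast-response function** (`vfcsf.crf`) — fixed slope
  (κ = 11.8 per log10-contrast unit) and asymptotes (pl = 0.5, pu = 0.99),
  with a threshold transformation guaranteeing exactly 75% correct at the
  nominal threshold, plus Bernoulli response sampling.
* **Nine CSF forms** (`vfcsf.csf`) — LP, aLP, dEXP, DoG, MS, HmH, HmG,
  EmG, YQM — and attribute extraction (peak-CS, peak-SF, cutoff-SF,
  AULCSF, octave bandwidth) on a 0.25–24 cpd window.
  *Note:* the aLP, MS and YQM rows of the source table are garbled in
  extraction; canonical published forms are implemented instead and pinned
  by unit tests.
* **Visual-field tying models and trial-wise MLE** (`vfcsf.fitting`) — six
  tying models sharing CSF parameters across the six location cells
  (2°/6° × HM/LVM/UVM), joint Bernoulli maximum likelihood with seeded
  multistart bounded optimization, and BIC ranking
  (`BIC = k·ln n − 2·ln L`).
* **Adaptive titration** (`vfcsf.titration`) — best PEST (ML placement on
  a 61-level log10-contrast grid) and a weighted 3-down-1-up staircase
  (up/down step ratio `0.75³/(1−0.75³)`), both targeting 75% correct.
* **Synthetic observers** (`vfcsf.observer`) — ground-truth CSF layouts
  with configurable eccentricity effect, horizontal-vertical anisotropy
  (HVA) and vertical-meridian asymmetry (VMA) knobs, constructed by exact
  inversion of the symmetric percent-change formula, plus full-experiment
  simulation matching the source design (8 SFs, independent titration per
  SF × location, seeded interleaving).
* **Asymmetry statistics** (`vfcsf.asymmetry`) — percent-change extents
  and reference-denominator magnitudes, repeated-measures ANOVA
  (Greenhouse–Geisser, generalized η²), Bonferroni paired t-tests with
  Cohen's d, percentile bootstrap CIs over observers, and Spearman
  brain–behavior correlations.
* **Pipeline + CLI** (`vfcsf.pipeline`, `vfcsf.cli`) — two-stage model
  selection (stage 1: CSF form under the most permissive tying model;
  stage 2: tying model under the stage-1 winner, fixed-size conditions
  only), per-observer attribute extraction, asymmetry summaries, and a
  provenance manifest with per-stage hashes.

## CLI

```bash
vfcsf mscale                              # printed M-scaled sizes (7.08/7.68/7.70)
vfcsf simulate --trials-per-sf 40 --seed 1 --out trials.csv
vfcsf fit --trials trials.csv --csf-model LP --out fit.json
vfcsf fit --trials trials.csv --tying +Ecc-HVA-VMA --out fit2.json
vfcsf compare --trials trials.csv --csf-model LP
vfcsf attributes --trials trials.csv --csf-model LP --out attrs.csv
vfcsf asymmetry --attributes attrs.csv --out asym.csv
vfcsf report --quick --out-dir out/       # full pipeline + manifest
```

Trial tables are plain CSV; the column dictionary is documented in
`vfcsf.io`.

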