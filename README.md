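# thermofmri

A task- and resting-state fMRI analysis pipeline for thermal-stimulation
studies in the rat, exercised end to end on synthetic 4D BOLD phantoms.

## The problem

Noxious heat applied to a rat's hind paw evokes BOLD responses whose
amplitude and spatial extent grow steeply once the stimulus crosses the
nociceptive threshold (~48 °C). Desensitizing TRPV1-expressing afferents
(e.g. with resiniferatoxin, "RTX") abolishes that rise. Quantifying this
requires a long chain of analyses — voxel-wise GLMs per stimulation
temperature, atlas-based region metrics, functional-connectivity graphs and
permutation statistics — whose correctness is hard to audit on animal data
alone. This package re-implements that chain as a tested library and
validates every stage on phantoms with known ground truth: a **baseline**
effect model whose peak %BOLD amplitude rises linearly from 0 at 48 °C to
1.5 % at 54 °C, and a flat **rtx** model with an optional small 54 °C term.

## The analysis chain

* **Stimulation protocol** — eight temperatures (40–54 °C in 2 °C steps),
  20 s stimuli (5 s ramp + 15 s plateau), 220 s rest, pseudo-randomized per
  set with no temperature repeated across set transitions.
* **GLM** — regressors are event boxcars convolved with a rodent two-gamma
  HRF, `h(t) ∝ γ(t; k₁, θ₁) − c·γ(t; k₂, θ₂)`, parameterized so the response
  peak falls at 16 s and the undershoot peak at 40 s; one predictor per
  temperature; Benjamini–Hochberg FDR masks at q = 0.05 within the brain
  mask.
* **ROI metrics** — per-structure activated volume, event-related mean
  time courses (10 points pre, 5 during, 10 post at TR_eff = 4 s), response
  amplitudes in %BOLD, and voxel-wise maximum-amplitude maps.
* **Networks** — global-mean regression of structure traces, Pearson →
  Fisher-z adjacency per animal and temperature, k-standardization to the
  N·k/2 strongest positive connections (k = 10: 1010 edges for 202
  symmetric nodes, 2020 directed), small-world indices γ = C/⟨C_rand⟩,
  λ = L/⟨L_rand⟩, σ = γ/λ, and Louvain (Blondel) communities.
* **Resting state** — 1.173 mm spherical seeds at each structure's center
  of mass; per-seed correlation volumes averaged (on the Fisher-z scale)
  within target structures into an asymmetric region × region matrix.
* **Group statistics** — network-based statistic (edge-wise t at α = 0.05,
  largest-component extent, permutation FWE), max-|t| permutation control
  for voxel-wise and paired matrix tests, one-way ANOVA with Tukey HSD, and
  t-test tables corrected by BH-FDR.

## Worked example

`analysis/` contains numbered drivers over the library. The network
contrast (one seeded 18-vs-9 cohort replication at desk scale):

```bash
$ python analysis/03_stimulus_networks.py
 temperature_C  max_component_edges  p_value  significant ...
            40                   37    0.500        False
            ...
            48                   40    0.365        False
            50                  740    0.000         True
            52                  780    0.000         True
            54                  780    0.000         True
significant network differences at: [50, 52, 54] degC
```

The network-based statistic flags a baseline-vs-rtx connectivity difference
only at the noxious analogs (≥ 50 °C) where the phantom plants a response
difference; at ≤ 48 °C both groups are statistically identical and the
permutation p-values stay uniform. The full study driver
(`analysis/05_group_study.py`) additionally reports the amplitude–temperature
correlation of the responsive structures (baseline r ≈ 0.80, rtx r ≈ 0.45),
the activated-volume correlation (≈ 0.89), a significant temperature effect
in the baseline ANOVA (p ≈ 3 × 10⁻⁸) and none in rtx, and null paired
pre/post resting-state comparisons.

A CLI mirrors the stages (`thermofmri simulate|preprocess|glm|roi|network|rsnet|stats|run-all`).

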