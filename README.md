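# tonopipe

Analysis pipeline for asking whether a population of auditory-cortex
neurons is **tonotopically organized**, built for two-photon (2P) calcium
imaging at single-neuron resolution combined with wide-field functional
mapping. It reproduces the full measurement chain used to compare
thalamocortical-recipient (TR) input neurons with corticothalamic (CT)
output neurons in mouse primary auditory cortex — populations that differ
sharply: TR neurons form a clear caudal-to-rostral low-to-high best-frequency
gradient while CT neurons, recorded the same way, do not.

The package is aimed at systems-neuroscience labs doing tone-mapping
experiments: it takes raw movies (TIFF) or per-ROI fluorescence traces (CSV)
plus a tone-protocol table, and returns per-neuron tuning metrics and
population-level topography statistics. A first-class synthetic-data
generator renders ground-truth populations, traces and movies, so every
stage is verifiable without any recording.

## What it computes

**Wide-field branch** — 10× block downsampling (750×1200 → 75×120 px),
trial averaging, 5×5 spatial box filter, 3-frame temporal average,
ΔF/F = (F − F₀)/F₀ with F₀ the 800 ms pre-stimulus mean; the 4 kHz ("LF")
and 32 kHz ("HF") response areas define the tonotopic axis (LF→HF unit
vector).

**2P branch** — rigid integer-pixel motion correction by SSD minimization
against a mean-image template; ROI mean traces; ΔF/F with F₀ = 25th
percentile of the whole recording; calcium-transient detection by threshold
criteria (3× the 1 s-window baseline SD, plus a rising-rate criterion on
the 200 ms exponentially filtered trace) and iterative **peeling** of
overlapping transients (detect → fit template → subtract → re-detect).

**Tuning** — each neuron's frequency-response area (FRA) is the 11×6 matrix
of trial-averaged evoked amplitudes (200 ms around the post-stimulus peak
minus 100 ms pre-stimulus baseline) over 11 tones (2–40 kHz, geometric) × 6
levels (30–80 dB SPL) × 5 repeats. Neurons are **tuned** (a contiguous
significant FRA region responding in ≥3/5 repeats), **irregular** (active
but not stimulus-locked) or **silent**. Tuned neurons get a best frequency
(BF, argmax of the level-averaged response), FRA shape (V/I/O), half-peak
bandwidth, Q = BF / half-peak width, maximum bandwidth BW_max (octaves),
and a monotonicity index MI = response at 80 dB / maximum response (MI <
0.5 marks intensity-tuned neurons).

**Topography** — OLS gradient of log₂(BF) versus axis position (octaves/mm
with Pearson R), field IQR_BF (≥5 tuned neurons within 100 µm), local
IQR_BF (25 µm radius), nearest-neighbor Δfrequency, LF/HF area assignment,
and rank-based group comparisons in the median\Q1–Q3 style.

## Worked example

```python
import numpy as np
from tonopipe.pipeline import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(preset="TR", n_neurons=90, seed=1), "out_tr")
g = res["gradient"]
print(f"tuned fraction: {np.mean(res['neurons']['cls'] == 'tuned'):.2f}")
print(f"gradient: {g.slope_oct_per_mm:.2f} oct/mm, R={g.pearson_r:.2f}, p={g.p_value:.1e}")
```

prints

```
tuned fraction: 0.47
gradient: 2.09 oct/mm, R=0.64, p=5.2e-06
```

i.e. of 90 simulated TR-preset neurons, 47 % pass the tuned criteria after
full trace rendering and transient peeling, and their best frequencies rise
by ~2 octaves per mm along the tonotopic axis with a significant
correlation — a tonotopic population. The same run with `preset="CT"`
yields a non-significant, near-zero slope: heterogeneous local tuning
despite a smooth wide-field map (the `tonopipe.widefield` pipeline on the
same CT scene still shows |R| > 0.9, because the neuropil carries the
global gradient).

The same steps are available from the shell:

```bash
tonopipe run --preset TR --n 90 --seed 1 --out out_tr
tonopipe simulate --preset CT --what movie2p --n 20 --seed 3 --out sim_ct
tonopipe preprocess --movie sim_ct/movie2p.tif --rois sim_ct/rois.tif --out pre_ct
```

## Layout

- `tonopipe.synthetic` — protocols, TR/CT presets (with calibrated BF
  scatter), populations, traces, 2P and wide-field movie rendering
- `tonopipe.widefield` / `tonopipe.twophoton` — movie processing branches
- `tonopipe.transients` — detection, peeling, evoked amplitudes, BBN
  reliability
- `tonopipe.tuning` — FRA construction and per-neuron metrics
- `tonopipe.topography` / `tonopipe.group_stats` — spatial statistics and
  group comparisons
- `tonopipe.pipeline` / `tonopipe.cli` / `tonopipe.io` — end-to-end driver,
  CLI, file formats

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
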