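# Methods

This note documents the models and numerical choices behind `tonopipe`: the
measurement chain itself, the synthetic populations used to validate it,
and the places where the package had to make a concrete choice among
defensible alternatives.

## Stimulus model

The standard session presents 11 pure tones geometrically spaced from 2 to
40 kHz (f_k = 2·20^(k/10) kHz, adjacent tones log₂(20)/10 ≈ 0.432 octaves
apart) at 6 levels (30–80 dB SPL in 10 dB steps), 5 repeats per
combination, in a seeded random order: 330 presentations over 66 unique
frequency×level combinations. Octave values throughout are relative to
2 kHz. The default inter-trial interval is 6 s (a 330-tone session then
lasts ≈ 33 min, comfortably longer than a GCaMP6s transient), and the first
tone is presented at t = 2 s so every trial has a full pre-stimulus
baseline.

## 2P trace processing

ΔF/F uses F₀ = the 25th percentile of the entire raw trace, with the
linear-interpolation percentile convention everywhere in the package (so
an R or Python re-implementation agrees exactly). Motion correction is
integer-pixel rigid translation minimizing the SSD against a template (mean
of the first 100 frames, one refinement pass against the corrected mean);
sub-pixel registration is deliberately omitted, and translation-exposed
edges are filled with the template border median. ROI traces are plain
pixel means — no neuropil subtraction.

### Transient detection

The noise level is 3× the baseline SD. The baseline SD is estimated as the
25th percentile of per-window SDs over non-overlapping 1 s windows — robust
against windows that contain transients (at default activity levels well
under half the windows are contaminated). Candidate events are contiguous
excursions of the exponentially IIR-filtered trace (200 ms window) above 3×
the *filtered* trace's baseline SD; a candidate becomes a transient only
if

1. its peak amplitude — the 200 ms raw-trace mean centered on the peak — is
   ≥ 3× the raw baseline SD (and ≥ `min_amplitude` = 0.01 ΔF/F, a floor
   that keeps noiseless traces from dividing by zero), and
2. its rising rate (peak amplitude minus the pre-onset 100 ms mean, divided
   by the onset→peak time) is ≥ threshold / 1.0 s.

The rise-denominator default of 1.0 s is deliberate: the filtered GCaMP6s
template (τ_rise 0.18 s, τ_decay 1.5 s) peaks ≈ 0.7 s after onset, so any
denominator much below that makes the rate criterion strictly harsher than
the amplitude criterion and silently rejects threshold-level transients.
Onsets are found by backtracking from the peak to the last up-crossing of
20 % of the local rise (local baseline = 25th percentile of the preceding
second — robust to noise dips and to the decaying tail of a preceding
transient), then subtracting the template's known 20 %-rise lag; on
isolated 5σ events this lands within 1–2 frames of the true onset.

### Peeling

Overlapping events are decomposed by iterative subtraction: each detection
pass fits every event with a fixed-kinetics difference-of-exponentials
template (amplitude by least squares on a 2 s post-onset window, clipped at
0), subtracts the full template, and re-detects on the residual; passes
repeat until nothing new appears (events re-detected within 250 ms of an
already-peeled onset are ignored) or `max_iterations` = 8, in which case
the result is flagged unconverged. Components + residual always equal the
input exactly, by construction. Fitting amplitude on a 2 s window slightly
overestimates the first of two transients closer than ~1 s; the second is
still recovered on the residual, which is the property the pipeline needs
(per-trial amplitudes come from the evoked-amplitude windows, not from the
template fits).

## FRA and tuning metrics

Evoked amplitude per trial = mean ΔF/F over 200 ms centered on the
post-onset peak (searched on the filtered trace within 1 s after onset)
minus the 100 ms pre-onset mean. A combination is significant when its
5-repeat mean amplitude exceeds 3× the baseline SD *and* a detected
transient follows the stimulus within 1 s in ≥ 3 of 5 repeats; the paper
trail behind this reconstruction is thin (no explicit test is published for
"tuned"), so both knobs are config-exposed. The FRA region is the largest
4-connected significant component (ties: larger summed response, then lower
frequency). Classes partition the population: silent (no transient
anywhere), tuned (nonempty region), irregular (the rest).

Width conventions: a region row spanning n frequencies has width
(n−1)×0.432 oct, so a single-frequency region has width 0 — consistent
with published Δfrequency/IQR values being multiples of 0.43 including 0.
BW_max is the widest region row at any level. The half-peak bandwidth is
the contiguous run of frequencies around BF whose level-averaged response
exceeds half its maximum; Q = BF / the kHz width between the outer
effective-frequency edges (missing when that width is 0). MI is computed on
the BF column (response at 80 dB / maximum response, clamped to [0, 1]; a
global-max-column variant is a config switch), with MI < 0.5 flagging
intensity-tuned neurons.

## Wide-field branch

Block-mean 10× downsampling, per-stimulus trial averaging over a window of
800 ms before to 1.2 s after onset, 5×5 box filter with reflect padding,
3-frame moving average; ΔF/F against the 800 ms pre-onset mean; the
response map is the mean ΔF/F over 1 s post-onset (the response window is
not published; 0–1 s covers the GCaMP6s rise). LF/HF areas are the largest
8-connected components above 50 % of each map's maximum (both the
connectivity and the fraction are unpublished; 0.5 is the conventional
half-max criterion), centroids are response-weighted, and the LF→HF unit
vector with origin at the LF centroid is the tonotopic axis onto which 2P
fields of view are projected. A map-level gradient can be computed by
assigning each responsive pixel the frequency of its largest response and
regressing log₂(pixel BF) on axis position.

## Synthetic populations

The generator emulates two population archetypes:

| parameter | TR | CT |
|---|---|---|
| class fractions (tuned/irregular/silent) | 0.46 / 0.41 / 0.13 | 0.18 / 0.57 / 0.25 |
| neuron-level gradient (slope, R) | 1.76 oct/mm, 0.52 | 0.37 oct/mm, 0.079 |
| plane-level gradient (slope, R) | 2.13 oct/mm, 0.77 | 0.21 oct/mm, 0.20 |
| BW_max step table median (IQR) | 3 (2–5) steps ≈ 1.30 oct | 7 (5–9) steps ≈ 3.02 oct |
| shape fractions (V/I/O) | 0.395 / 0.362 / 0.243 | 0.507 / 0.228 / 0.265 |
| within-plane BF scatter σ_w | 0.96 oct | 1.44 oct |

Axis positions are uniform over 1.2 mm; within a field of view, (x, y) are
uniform over 200 µm.

### Gradient calibration

Best frequencies live on a bounded grid, so the textbook variance
decomposition σ = |slope|·SD(x)·√(R⁻²−1) of an unbounded linear model is
only a starting point: clamping a normal scatter to the 4.32-octave grid
range attenuates the recoverable slope and caps the attainable variance
(a CT-like R of 0.079 is unreachable under pure truncation). The presets
therefore solve numerically for the *inner* slope and scatter SD of the
clamped-normal model y = clamp(a + b·x + ε, 0, 4.32) such that the
*expected OLS slope and Pearson R of the observed values* — including
grid-snapping quantization — equal the targets (closed-form clamped-normal
moments, integrated over the uniform position distribution, solved by
least squares). Snapping to the nearest grid frequency happens after the
clamp and therefore never moves a value by more than half a grid step.

Focal planes are hierarchical: plane centers are uniform on the axis, each
plane has a latent BF from the plane-level calibrated model, and its
neurons scatter around it with σ_w (set from the published field-IQR
medians: σ_w = IQR/1.349). Plane medians are robust to grid clamping, so
the plane-level slope is recovered without bias; the median of ~12–21
neurons does add sampling noise that the calibration removes from the
between-plane SD when possible (for CT the required between-plane SD falls
below that noise floor and is clamped at 0, which lowers the effective
plane-level R below its target — in the direction of even less detectable
CT tonotopy).

### Responses, kinetics and noise

Tuned neurons respond to every presentation inside their FRA support with
a difference-of-exponentials transient (τ_rise 0.18 s, τ_decay 1.5 s,
GCaMP6s-like; 30 Hz sampling; 50 ms stimulus-to-onset latency). The FRA
support is built from the drawn maximum width (s steps → s+1 frequencies at
the widest level, shifted to fit the grid so the measured BW_max equals the
drawn value exactly), with V regions growing from 1 frequency at threshold,
I regions constant, and O regions confined to an interior 3-level band.
Response amplitude = gain × frequency taper (−2 %/step from BF) × level
ramp (0.85 at threshold → 1 at the peak level), with the 80 dB row of V/I
neurons scaled to the drawn MI. Per-neuron gain is U(0.2, 0.4) ΔF/F, trial
amplitudes get multiplicative lognormal jitter (σ = 0.15), and additive
Gaussian noise has SD = gain/5, i.e. maximum responses are 5σ events. The
taper and ramp floors are pinned by self-consistency: with 5σ peak
responses and a 3σ detection criterion, within-FRA amplitudes must stay
≥ ~3.8σ for the detector to reach ≥ 90 % event recall, which a floor of
0.85 provides and lower floors provably cannot. Irregular neurons emit
Poisson-timed transients at 0.04 Hz — low enough that chance stimulus
coincidences pass the 3-of-5 consistency rule in ≲ 1 % of irregular
neurons. Silent neurons emit nothing. Traces are rendered as raw
fluorescence F = F₀(1 + ΔF/F) with F₀ = 200, so the percentile baseline is
well defined. Poisson shot noise is available as an option but off by
default.

### Movies

2P movies paint somata as 2-D Gaussians (σ = 3 µm) on a 2 µm/px grid with
optional integer-pixel frame jitter (ground truth recorded) and a smooth
neuropil background. Wide-field scenes are rendered at 150×240 px
(20 µm/px; same aspect as 750×1200 and the same 10× downsampling factor —
full-size rendering is just a `frame_shape` argument) with a neuropil field
whose preferred frequency rises linearly 2→40 kHz over 1.2 mm along x
(Gaussian tuning σ = 0.5 oct, Gaussian band envelope in y), plus compact
somatic bumps with their own heterogeneous tuning; each trial renders 800 ms
of baseline and 1.2 s of response at 10 Hz.

### What the generator does not emulate

No optical PSF, shot-noise statistics by default, blood-vessel artifacts,
hemodynamic signals, behavioral state, slow drift, or spike-level
biophysics; FRAs are deterministic cell-wise supports rather than draws
from a spiking encoding model; irregular activity is homogeneous Poisson.
Passing tests on this data demonstrate that the *analysis chain* is
correct and internally consistent at realistic SNR — not that it is robust
to every artifact of real recordings.

## Statistics

Group summaries report median\Q1–Q3 with box-plot whiskers at Q1−1.5·IQR
and Q3+1.5·IQR. Comparisons use the two-sided Wilcoxon rank-sum
(Mann–Whitney; exact null when both groups have n ≤ 10 without ties,
normal approximation with tie correction otherwise) and the Wilcoxon
signed-rank test for paired data, with stars at 0.05/0.01/0.001. No
multiple-testing correction is applied. Pearson correlation is the default
"R" for gradient fits (Spearman available).

## Known limitations

* Amplitude fits during peeling assume shared kinetics across events; cells
  with strongly variable indicator dynamics would need per-event τ fitting.
* The plane-level CT preset cannot simultaneously honor the published
  plane-level correlation and the published within-plane heterogeneity —
  the hierarchical model floors the between-plane scatter at zero and
  accepts a lower effective R (see gradient calibration above).
* A two-sided test on a true correlation of ~0.2 at n = 40 is significant
  in roughly a fifth of resamples; "the CT plane-level fit is not
  significant" is therefore a statement about one dataset, not a
  reproducible property of the generating model.
* Only the LF/HF-centroid axis is implemented for wide-field parcellation;
  drawing A1/AAF/A2 boundaries is out of scope.
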