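"""Frequency-response areas and per-neuron tuning metrics.

The FRA is the 11 x 6 matrix of trial-averaged evoked amplitudes over the
frequency x level grid.  A combination is significant when its trial-mean
amplitude exceeds ``noise_k`` x the baseline noise SD *and* a detected
transient follows the stimulus in at least 3 of 5 repeats; if several
contiguous significant areas remain, the largest (4-connected) one is the
FRA region.  Derived metrics: neuron class (tuned / irregular / silent),
best frequency (highest response averaged across all sound levels), FRA
shape (V / I / O), half-peak bandwidth and Q, maximum bandwidth at any
level, and the monotonicity index (response at 80 dB / maximum response,
cutoff 0.5 for intensity tuning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .synthetic.protocol import ToneProtocol, OCTAVE_REF_KHZ
from .transients import DetectionParams, PeelResult, evoked_amplitudes, noise_sd
from .twophoton import DffTrace

__all__ = [
    "FRA",
    "NeuronTuning",
    "build_fra",
    "classify_neuron",
    "best_frequency",
    "classify_shape",
    "bandwidths",
    "monotonicity",
    "characterize_neuron",
]


@dataclass
class FRA:
    """Mean and per-trial evoked amplitudes on the stimulus grid, the
    significance mask, and the largest contiguous significant region."""

    mean_resp: np.ndarray  # (n_freq, n_level), levels ascending 30 -> 80 dB
    trial_resp: np.ndarray = field(repr=False)  # (n_freq, n_level, n_repeats)
    sig_mask: np.ndarray = field(repr=False)
    region_mask: np.ndarray = field(repr=False)
    protocol: ToneProtocol = field(repr=False, default=None)


@dataclass
class NeuronTuning:
    """Per-neuron derived tuning metrics; tuning fields are None unless the
    neuron is tuned (and Q/MI may be None when degenerate)."""

    cls: str
    bf_khz: "float | None" = None
    bf_oct: "float | None" = None
    shape: "str | None" = None
    halfpeak_bw_oct: "float | None" = None
    q_value: "float | None" = None
    bwmax_oct: "float | None" = None
    mi: "float | None" = None
    monotonic: "bool | None" = None


def _largest_component(sig: np.ndarray, mean_resp: np.ndarray) -> np.ndarray:
    """Largest 4-connected significant component; ties broken by larger
    summed response, then by lower frequency."""
    region = np.zeros_like(sig)
    if not sig.any():
        return region
    lab = measure.label(sig, connectivity=1)
    best_key, best_id = None, None
    for i in range(1, lab.max() + 1):
        comp = lab == i
        key = (comp.sum(), mean_resp[comp].sum(), -int(np.nonzero(comp.any(axis=1))[0][0]))
        if best_key is None or key > best_key:
            best_key, best_id = key, i
    region[lab == best_id] = True
    return region


def build_fra(
    dff: DffTrace,
    protocol: ToneProtocol,
    events: "PeelResult | list | None" = None,
    params: DetectionParams = DetectionParams(),
    consistency_min: int = 3,
    evoked_window_s: float = 1.0,
) -> FRA:
    """Construct the FRA from a delta f/f trace and the tone protocol.

    ``events`` (from :func:`tonopipe.transients.peel` or
    :func:`detect_transients`) drive the response-consistency rule; pass
    None to skip that rule (amplitude criterion only).
    """
    nf, nl, nr = protocol.n_freq, protocol.n_level, protocol.n_repeats
    onsets = protocol.onsets_s
    if onsets[-1] + 1.5 > len(dff.values) / dff.fs_hz:
        raise ValueError("trace does not cover the protocol")
    amps = evoked_amplitudes(dff, onsets, response_search_s=evoked_window_s)

    fi = protocol.trials["freq_idx"].to_numpy()
    li = protocol.trials["level_idx"].to_numpy()
    ri = protocol.trials["repeat"].to_numpy()
    trial_resp = np.zeros((nf, nl, nr))
    trial_resp[fi, li, ri] = amps
    mean_resp = trial_resp.mean(axis=2)

    sigma = noise_sd(np.asarray(dff.values, float), dff.fs_hz, params.noise_window_s)
    thresh = max(params.noise_k * sigma, params.min_amplitude)
    sig = mean_resp > thresh

    if events is not None:
        ev_onsets = (
            events.onsets_s
            if isinstance(events, PeelResult)
            else np.array([e.onset_s for e in events])
        )
        evoked = np.zeros(len(onsets), dtype=bool)
        if ev_onsets.size:
            ev_sorted = np.sort(ev_onsets)
            lo = np.searchsorted(ev_sorted, onsets)
            hi = np.searchsorted(ev_sorted, onsets + evoked_window_s)
            evoked = hi > lo
        counts = np.zeros((nf, nl), dtype=int)
        np.add.at(counts, (fi, li), evoked.astype(int))
        sig &= counts >= consistency_min

    region = _largest_component(sig, mean_resp)
    return FRA(mean_resp, trial_resp, sig, region, protocol)


def classify_neuron(fra: FRA, events: "PeelResult | list") -> str:
    """Silent if no transient was detected anywhere; tuned if the FRA has a
    significant region; irregular otherwise."""
    n_events = len(events.events) if isinstance(events, PeelResult) else len(events)
    if n_events == 0:
        return "silent"
    return "tuned" if fra.region_mask.any() else "irregular"


def best_frequency(fra: FRA) -> float:
    """BF (kHz): frequency with the highest response averaged across all
    sound levels; ties go to the lower frequency."""
    if not fra.region_mask.any():
        raise ValueError("best_frequency requires a tuned neuron (nonempty region)")
    curve = fra.mean_resp.mean(axis=1)
    return float(fra.protocol.frequencies_khz[int(np.argmax(curve))])


def _region_widths(region: np.ndarray):
    """Per-level region width in grid steps (span max-min) over the levels
    the region occupies; returns (level indices, widths)."""
    lvls = np.nonzero(region.any(axis=0))[0]
    widths = []
    for l in lvls:
        cols = np.nonzero(region[:, l])[0]
        widths.append(int(cols[-1] - cols[0]))
    return lvls, np.array(widths, dtype=int)


def classify_shape(fra: FRA) -> str:
    """V / I / O / unclassified from the FRA region geometry.

    O: peak mean response away from the top level and region excluding the
    top level.  V: region reaches the top level with widths non-decreasing
    and growing by >= 2 steps.  I: width varies by <= 1 step.
    """
    region = fra.region_mask
    if not region.any():
        raise ValueError("classify_shape requires a nonempty FRA region")
    top = fra.mean_resp.shape[1] - 1
    lvls, widths = _region_widths(region)
    masked = np.where(region, fra.mean_resp, -np.inf)
    peak_lvl = int(np.unravel_index(np.argmax(masked), masked.shape)[1])
    if peak_lvl != top and top not in lvls:
        return "O"
    if lvls[-1] == top and np.all(np.diff(widths) >= 0) and widths[-1] - widths[0] >= 2:
        return "V"
    if widths.max() - widths.min() <= 1:
        return "I"
    return "unclassified"


def bandwidths(fra: FRA, bf_khz: float):
    """Half-peak bandwidth (oct), Q, and BW_max (oct).

    Effective frequencies respond above half the maximum of the
    level-averaged tuning curve; the half-peak bandwidth is the contiguous
    effective run containing the BF, counted as (n - 1) grid steps.  Q =
    BF / width between the outer effective-frequency edges in kHz (None
    when the width is zero).  BW_max = the widest FRA-region row at any
    level, in octaves.
    """
    step = fra.protocol.octave_step
    curve = fra.mean_resp.mean(axis=1)
    bf_idx = int(np.argmin(np.abs(fra.protocol.frequencies_khz - bf_khz)))
    eff = curve > 0.5 * curve.max()
    lo = bf_idx
    while lo > 0 and eff[lo - 1]:
        lo -= 1
    hi = bf_idx
    while hi < len(eff) - 1 and eff[hi + 1]:
        hi += 1
    halfpeak_bw_oct = (hi - lo) * step
    if hi > lo:
        width_khz = fra.protocol.frequencies_khz[hi] - fra.protocol.frequencies_khz[lo]
        q = float(bf_khz / width_khz)
    else:
        q = None
    _, widths = _region_widths(fra.region_mask)
    bwmax_oct = float(widths.max() * step) if widths.size else 0.0
    return float(halfpeak_bw_oct), q, bwmax_oct


def monotonicity(fra: FRA, bf_khz: float, column: str = "bf"):
    """Monotonicity index: response at the maximum intensity (80 dB) divided
    by the maximum response across intensities, on the BF column (or the
    global-max column with ``column='max'``); responses clamp at 0, so
    MI is always in [0, 1].  Returns ``(mi, monotonic)``; (None, None) when
    the maximum response is 0."""
    resp = np.clip(fra.mean_resp, 0.0, None)
    if column == "bf":
        ci = int(np.argmin(np.abs(fra.protocol.frequencies_khz - bf_khz)))
        col = resp[ci]
    elif column == "max":
        col = resp[int(np.unravel_index(np.argmax(resp), resp.shape)[0])]
    else:
        raise ValueError("column must be 'bf' or 'max'")
    if col.max() <= 0:
        return None, None
    mi = float(np.clip(col[-1] / col.max(), 0.0, 1.0))
    return mi, mi >= 0.5


def characterize_neuron(fra: FRA, events: "PeelResult | list") -> NeuronTuning:
    """Full per-neuron readout: class plus tuning metrics when tuned."""
    cls = classify_neuron(fra, events)
    if cls != "tuned":
        return NeuronTuning(cls=cls)
    bf = best_frequency(fra)
    shape = classify_shape(fra)
    hp, q, bwmax = bandwidths(fra, bf)
    mi, mono = monotonicity(fra, bf)
    return NeuronTuning(
        cls=cls,
        bf_khz=bf,
        bf_oct=float(np.log2(bf / OCTAVE_REF_KHZ)),
        shape=shape,
        halfpeak_bw_oct=hp,
        q_value=q,
        bwmax_oct=bwmax,
        mi=mi,
        monotonic=mono,
    )
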