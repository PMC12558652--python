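"""Raw fluorescence traces from ground-truth neurons.

Tuned neurons emit a GCaMP6s-like double-exponential transient after every
presentation of a stimulus inside their FRA support, with amplitude from
their generating amplitude surface and per-trial multiplicative jitter.
Irregular neurons emit Poisson-timed transients uncorrelated with stimuli;
silent neurons emit none.  Traces are raw fluorescence
F(t) = F0 * (1 + dff(t)) + F0 * noise, so the downstream percentile baseline
and delta f/f are well defined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .population import GroundTruthNeuron
from .protocol import ToneProtocol

__all__ = ["transient_template", "render_trace", "render_traces"]

#: Stimulus-to-transient onset latency (s).
RESPONSE_LATENCY_S = 0.05


def transient_template(
    fs_hz: float, tau_rise_s: float = 0.18, tau_decay_s: float = 1.5, duration_s: float = 7.0
) -> np.ndarray:
    """Difference-of-exponentials calcium transient, normalized to peak 1."""
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    h = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate kinetics: tau_rise must be < tau_decay")
    return h / peak


def _add_events(dff: np.ndarray, template: np.ndarray, onsets_idx, amplitudes) -> None:
    n = len(dff)
    for i0, a in zip(onsets_idx, amplitudes):
        i1 = min(i0 + len(template), n)
        if i0 < n:
            dff[i0:i1] += a * template[: i1 - i0]


def render_trace(
    neuron: GroundTruthNeuron,
    protocol: ToneProtocol,
    fs_hz: float = 30.0,
    duration_s: "float | None" = None,
    seed: int = 0,
    trial_jitter_sd: float = 0.15,
    f0: float = 200.0,
):
    """Raw fluorescence trace and ground-truth event list for one neuron.

    Returns ``(raw, events)`` where ``raw`` is the fluorescence time series
    and ``events`` a DataFrame with columns ``onset_s`` and ``amplitude``
    (delta f/f units).
    """
    duration_s = duration_s or protocol.duration_s
    last_onset = float(protocol.trials["onset_s"].iloc[-1])
    if duration_s < last_onset + 2.0:
        raise ValueError("duration_s must cover the last stimulus onset + 2 s")
    n = int(round(duration_s * fs_hz))
    rng = np.random.default_rng(seed)
    template = transient_template(fs_hz, neuron.tau_rise_s, neuron.tau_decay_s)

    onsets_s: list = []
    amps: list = []
    if neuron.cls == "tuned":
        fi = protocol.trials["freq_idx"].to_numpy()
        li = protocol.trials["level_idx"].to_numpy()
        on = protocol.trials["onset_s"].to_numpy()
        cell_amp = neuron.amp_surface[fi, li]
        hit = cell_amp > 0
        jitter = np.exp(rng.normal(0.0, trial_jitter_sd, size=int(hit.sum())))
        onsets_s = list(on[hit] + RESPONSE_LATENCY_S)
        amps = list(cell_amp[hit] * jitter)
    elif neuron.cls == "irregular" and neuron.spont_rate_hz > 0:
        n_ev = rng.poisson(neuron.spont_rate_hz * duration_s)
        onsets_s = list(np.sort(rng.uniform(0, duration_s, size=n_ev)))
        amps = list(neuron.gain * rng.uniform(0.7, 1.2, size=n_ev))

    dff = np.zeros(n)
    idx = np.round(np.asarray(onsets_s) * fs_hz).astype(int) if onsets_s else np.array([], int)
    _add_events(dff, template, idx, amps)
    if neuron.noise_sd > 0:
        dff = dff + rng.normal(0.0, neuron.noise_sd, size=n)
    raw = f0 * (1.0 + dff)
    events = pd.DataFrame({"onset_s": onsets_s, "amplitude": amps}).sort_values(
        "onset_s", ignore_index=True
    )
    return raw, events


def render_traces(
    neurons: "list[GroundTruthNeuron]",
    protocol: ToneProtocol,
    fs_hz: float = 30.0,
    duration_s: "float | None" = None,
    seed: int = 0,
    trial_jitter_sd: float = 0.15,
):
    """Render all neurons; returns ``(traces, events)``.

    ``traces`` is an (n_neurons, n_frames) float32 array of raw fluorescence;
    ``events`` a concatenated ground-truth event table with a ``neuron_id``
    column.  Each neuron gets an independent child seed, so rendering a
    subset reproduces the same traces.
    """
    duration_s = duration_s or protocol.duration_s
    n = int(round(duration_s * fs_hz))
    out = np.empty((len(neurons), n), dtype=np.float32)
    ev_frames = []
    for row, neuron in enumerate(neurons):
        child = int(np.random.SeedSequence((seed, neuron.id)).generate_state(1)[0])
        raw, ev = render_trace(
            neuron, protocol, fs_hz, duration_s, seed=child, trial_jitter_sd=trial_jitter_sd
        )
        out[row] = raw
        ev.insert(0, "neuron_id", neuron.id)
        ev_frames.append(ev)
    events = pd.concat(ev_frames, ignore_index=True) if ev_frames else pd.DataFrame(
        columns=["neuron_id", "onset_s", "amplitude"]
    )
    return out, events
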