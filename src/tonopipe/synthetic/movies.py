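"""Synthetic movie rendering: two-photon FOV stacks and wide-field scenes.

The 2P renderer paints each neuron as a 2-D Gaussian soma whose brightness
follows its fluorescence trace, optionally jitters whole frames by integer
pixels (recorded as ground truth for motion-correction tests), and adds a
smooth neuropil background.

The wide-field renderer draws a spatially smooth neuropil/dendrite field
whose local frequency preference follows a linear tonotopic map along the
image x-axis, plus compact somatic signals; each trial contributes 800 ms of
pre-stimulus frames followed by a tone-evoked response.  By default frames
are 150 x 240 px (same aspect as 750 x 1200, 5x smaller linearly) so the
standard 10x block downsampling still applies; full-size rendering is just a
``frame_shape`` argument away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .population import GroundTruthNeuron
from .protocol import OCTAVE_REF_KHZ

__all__ = ["render_movie_2p", "render_widefield", "WidefieldScene"]


def _gaussian_kernel(h, w, cy, cx, sigma_px):
    rr, cc = np.indices((h, w))
    return np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * sigma_px**2))


def _shift_int(frame, dy, dx, fill):
    out = np.full_like(frame, fill)
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    out[ys, xs] = frame[slice(max(-dy, 0), min(h - dy, h)), slice(max(-dx, 0), min(w - dx, w))]
    return out


def render_movie_2p(
    neurons: "list[GroundTruthNeuron]",
    traces: np.ndarray,
    fov_size_um: float = 200.0,
    um_per_px: float = 2.0,
    soma_sigma_um: float = 3.0,
    motion_sd_px: float = 0.0,
    neuropil_gain: float = 0.0,
    background: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Render a (T, H, W) 2P movie from per-neuron traces.

    Returns ``(movie, roi_labels, shifts)``: the float movie, a labeled ROI
    mask image (label = neuron id + 1), and the per-frame integer (dy, dx)
    jitter that was applied (all zeros when ``motion_sd_px`` is 0).
    """
    n_px = int(round(fov_size_um / um_per_px))
    if n_px < 32:
        raise ValueError("pixel grid must be at least 32 x 32")
    if motion_sd_px < 0:
        raise ValueError("motion_sd_px must be >= 0")
    rng = np.random.default_rng(seed)
    t_frames = traces.shape[1]

    kernels = []
    labels = np.zeros((n_px, n_px), dtype=np.uint16)
    sig_px = soma_sigma_um / um_per_px
    for nrn in neurons:
        cy, cx = nrn.y_um / um_per_px, nrn.x_um / um_per_px
        if not (0 <= cy < n_px and 0 <= cx < n_px):
            raise ValueError(f"ROI for neuron {nrn.id} falls outside the frame")
        k = _gaussian_kernel(n_px, n_px, cy, cx, sig_px)
        kernels.append(k)
        labels[k > np.exp(-2.0)] = nrn.id + 1  # ~2-sigma disk

    neuropil = 0.0
    if neuropil_gain > 0:
        neuropil = neuropil_gain * ndimage.gaussian_filter(
            rng.random((n_px, n_px)), sigma=n_px / 8
        )

    if motion_sd_px > 0:
        shifts = np.round(rng.normal(0, motion_sd_px, size=(t_frames, 2))).astype(int)
    else:
        shifts = np.zeros((t_frames, 2), dtype=int)

    kstack = np.stack(kernels) if kernels else np.zeros((0, n_px, n_px))
    movie = np.empty((t_frames, n_px, n_px), dtype=np.float32)
    for t in range(t_frames):
        frame = background + neuropil + np.tensordot(traces[:, t], kstack, axes=(0, 0))
        if shifts[t].any():
            frame = _shift_int(frame, shifts[t, 0], shifts[t, 1], background)
        if noise_sd > 0:
            frame = frame + rng.normal(0, noise_sd, frame.shape)
        movie[t] = frame
    return movie, labels, shifts


@dataclass
class WidefieldScene:
    """A rendered wide-field session plus its generating ground truth."""

    movie: np.ndarray = field(repr=False)
    trial_table: pd.DataFrame
    fs_hz: float
    um_per_px: float
    bf_map_oct: np.ndarray = field(repr=False)
    amp_maps: dict = field(repr=False)

    def generating_centroid_px(self, freq_khz: float) -> np.ndarray:
        """Response-weighted centroid of the generating field for a tone."""
        w = self.amp_maps[freq_khz]
        rr, cc = np.indices(w.shape)
        return np.array([(rr * w).sum() / w.sum(), (cc * w).sum() / w.sum()])


def render_widefield(
    neurons: "list[GroundTruthNeuron] | None" = None,
    freqs_khz=(4.0, 32.0),
    n_trials: int = 20,
    frame_shape: "tuple[int, int]" = (150, 240),
    um_per_px: float = 20.0,
    fs_hz: float = 10.0,
    axis_extent_mm: float = 1.2,
    tuning_sigma_oct: float = 0.5,
    neuropil_gain: float = 0.08,
    soma_gain: float = 0.04,
    baseline: float = 1000.0,
    noise_sd: float = 1.0,
    pre_s: float = 0.8,
    post_s: float = 1.2,
    seed: int = 0,
) -> WidefieldScene:
    """Render a wide-field session for a set of pure tones.

    The neuropil field's preferred frequency rises linearly from 2 to 40 kHz
    over ``axis_extent_mm`` along the image x-axis (centered in the frame),
    with a Gaussian band envelope in y — a smooth global tonotopic map even
    when the somatic BFs scattered on top of it are heterogeneous.  Each
    trial is ``pre_s`` of baseline frames followed by the tone response.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    h, w = frame_shape
    rng = np.random.default_rng(seed)
    span_oct = float(np.log2(40.0 / 2.0))

    x_mm = (np.arange(w) * um_per_px) / 1000.0
    x0 = (x_mm[-1] - axis_extent_mm) / 2.0
    bf_line = np.clip((x_mm - x0) / axis_extent_mm, 0, 1) * span_oct
    bf_map = np.broadcast_to(bf_line, (h, w)).copy()
    band = np.exp(-((np.arange(h) - h / 2) ** 2) / (2 * (h / 6.0) ** 2))
    # trim the field outside the mapped strip so blobs stay compact
    strip = np.exp(-np.clip(np.abs(x_mm - (x0 + axis_extent_mm / 2)) - axis_extent_mm / 2, 0, None) ** 2 / (2 * 0.15**2))
    envelope = band[:, None] * strip[None, :]

    amp_maps = {}
    for f in freqs_khz:
        oct_f = np.log2(f / OCTAVE_REF_KHZ)
        amp = neuropil_gain * envelope * np.exp(-((oct_f - bf_map) ** 2) / (2 * tuning_sigma_oct**2))
        if neurons:
            for nrn in neurons:
                cx = (x0 + nrn.axis_mm) * 1000.0 / um_per_px
                cy = h / 2 + (nrn.y_um - 100.0) / um_per_px
                if not (0 <= cy < h and 0 <= cx < w):
                    continue
                if nrn.cls == "tuned":
                    resp = np.exp(-((oct_f - nrn.bf_oct) ** 2) / (2 * tuning_sigma_oct**2))
                elif nrn.cls == "irregular":
                    resp = 0.3
                else:
                    continue
                amp += soma_gain * resp * _gaussian_kernel(h, w, cy, cx, 1.0)
        amp_maps[float(f)] = amp

    n_pre = int(round(pre_s * fs_hz))
    n_post = int(round(post_s * fs_hz))
    t_post = np.arange(n_post) / fs_hz
    profile = (1 - np.exp(-t_post / 0.15)) * np.exp(-t_post / 0.8)
    profile /= profile.max()

    order = np.tile(np.asarray(freqs_khz, float), n_trials)
    rng.shuffle(order)
    frames_per_trial = n_pre + n_post
    movie = np.empty((len(order) * frames_per_trial, h, w), dtype=np.float32)
    rows = []
    for i, f in enumerate(order):
        start = i * frames_per_trial
        dff = np.zeros((frames_per_trial, h, w))
        dff[n_pre:] = profile[:, None, None] * amp_maps[float(f)][None]
        block = baseline * (1.0 + dff)
        if noise_sd > 0:
            block = block + rng.normal(0, noise_sd, block.shape)
        movie[start : start + frames_per_trial] = block
        rows.append({"stimulus": float(f), "onset_frame": start + n_pre})
    trial_table = pd.DataFrame(rows)
    return WidefieldScene(movie, trial_table, fs_hz, um_per_px, bf_map, amp_maps)
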