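"""Ground-truth neuron populations.

Each tuned neuron carries a generating best frequency on the protocol grid,
an FRA support (which frequency/level cells respond), a response-amplitude
surface over that support, a shape label (V/I/O), and a monotonicity index.
Irregular neurons fire spontaneously at a Poisson rate; silent neurons never
fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .presets import SynthPreset, calibrate_gradient, GRID_STEP_OCT
from .protocol import ToneProtocol, standard_protocol, OCTAVE_REF_KHZ

__all__ = ["GroundTruthNeuron", "sample_population", "sample_tuned", "sample_planes"]

CLASSES = ("tuned", "irregular", "silent")
SHAPES = ("V", "I", "O")

#: Frequency taper of response amplitude: fractional drop per grid step from BF.
FREQ_TAPER_PER_STEP = 0.02
#: Response amplitude at the FRA threshold level relative to the peak level.
LEVEL_RAMP_FLOOR = 0.85


@dataclass
class GroundTruthNeuron:
    """One generating neuron: identity, geometry, class, and FRA parameters.

    ``amp_surface`` is an (n_freq, n_level) array of generating evoked peak
    amplitudes (delta f/f); zero outside the FRA support.  ``support`` is the
    boolean FRA support mask.  Both are None for non-tuned classes.
    """

    id: int
    x_um: float
    y_um: float
    axis_mm: float
    cls: str
    gain: float
    noise_sd: float
    tau_rise_s: float = 0.18
    tau_decay_s: float = 1.5
    bf_khz: "float | None" = None
    bf_idx: "int | None" = None
    shape: "str | None" = None
    bwmax_steps: "int | None" = None
    mi: "float | None" = None
    threshold_level_idx: "int | None" = None
    support: "np.ndarray | None" = field(default=None, repr=False)
    amp_surface: "np.ndarray | None" = field(default=None, repr=False)
    spont_rate_hz: float = 0.0
    plane: int = 0

    @property
    def bf_oct(self) -> "float | None":
        if self.bf_khz is None:
            return None
        return float(np.log2(self.bf_khz / OCTAVE_REF_KHZ))


def _row_interval(bf_idx: int, width: int, n_freq: int) -> "tuple[int, int]":
    """Place an interval of ``width`` frequencies containing the BF column,
    centered when possible and shifted minimally to stay on the grid."""
    start = bf_idx - (width - 1) // 2
    start = max(0, min(start, n_freq - width))
    start = min(max(start, bf_idx - width + 1), bf_idx)
    return start, start + width


def _build_fra_surface(
    rng: np.random.Generator,
    preset: SynthPreset,
    bf_idx: int,
    shape: str,
    steps: int,
    gain: float,
    mi: float,
    n_freq: int,
    n_level: int,
):
    """FRA support and amplitude surface for one tuned neuron.

    The widest row spans ``steps + 1`` frequencies (so the measured BW_max
    equals ``steps`` grid steps).  Amplitude = gain x frequency taper x level
    ramp; the level ramp rises from LEVEL_RAMP_FLOOR at threshold to 1 at the
    peak level, and for V/I neurons the top (80 dB) row is scaled so the
    measured monotonicity index equals ``mi``.
    """
    support = np.zeros((n_freq, n_level), dtype=bool)
    level_gain = np.zeros(n_level)
    w_max = steps + 1
    top = n_level - 1

    if shape == "V":
        thr = int(rng.integers(0, 3))
        n_lvl = top - thr
        widths = 1 + np.round(steps * (np.arange(n_lvl + 1)) / n_lvl).astype(int)
        lvl_range = range(thr, top + 1)
    elif shape == "I":
        thr = int(rng.integers(0, 3))
        widths = np.full(top - thr + 1, w_max, dtype=int)
        lvl_range = range(thr, top + 1)
    else:  # O: interior band excluding the top level
        thr = int(rng.integers(1, 3))
        hi = min(top - 1, thr + 2)
        n_lvl = hi - thr + 1
        widths = np.full(n_lvl, max(1, (w_max + 1) // 2), dtype=int)
        widths[n_lvl // 2] = w_max
        lvl_range = range(thr, hi + 1)

    lvls = list(lvl_range)
    for lvl, w in zip(lvls, widths):
        lo, hi_ = _row_interval(bf_idx, int(w), n_freq)
        support[lo:hi_, lvl] = True

    # level ramp toward the peak level
    if shape == "O":
        peak_lvl = lvls[len(lvls) // 2]
    else:
        peak_lvl = top if mi >= 1.0 else top - 1
        peak_lvl = max(peak_lvl, lvls[0])
    for lvl in lvls:
        if lvl <= peak_lvl:
            span = max(peak_lvl - lvls[0], 1)
            level_gain[lvl] = LEVEL_RAMP_FLOOR + (1 - LEVEL_RAMP_FLOOR) * (lvl - lvls[0]) / span
        else:
            level_gain[lvl] = 1.0
    if shape != "O" and peak_lvl < top:
        level_gain[top] = mi  # measured MI = resp(80 dB)/max resp at BF

    d = np.abs(np.arange(n_freq) - bf_idx)
    taper = 1.0 - FREQ_TAPER_PER_STEP * d
    amp = gain * taper[:, None] * level_gain[None, :]
    amp[~support] = 0.0
    return support, amp, int(lvls[0]), int(peak_lvl)


def _draw_mi(rng: np.random.Generator, preset: SynthPreset, shape: str) -> float:
    if shape == "O":
        return 0.0  # no response at 80 dB by construction
    if rng.random() < preset.p_nonmono_vi:
        return float(rng.uniform(0.15, 0.45))
    return 1.0 if rng.random() < 0.6 else float(rng.uniform(0.5, 1.0))


def _make_tuned(rng, preset, protocol, nid, x, y, axis_mm, bf_oct_latent, plane=0):
    bf_idx = int(protocol.snap_to_grid(np.array([bf_oct_latent]))[0])
    gain = float(rng.uniform(*preset.gain_range))
    steps = int(rng.choice(np.arange(1, len(preset.bwmax_step_pmf) + 1), p=preset.bwmax_step_pmf))
    shape = str(rng.choice(SHAPES, p=preset.shape_fractions))
    if shape == "V" and steps < 2:
        shape = "I"  # a V needs >= 2 steps of width growth
    mi = _draw_mi(rng, preset, shape)
    support, amp, thr, _peak = _build_fra_surface(
        rng, preset, bf_idx, shape, steps, gain, mi, protocol.n_freq, protocol.n_level
    )
    return GroundTruthNeuron(
        id=nid, x_um=x, y_um=y, axis_mm=axis_mm, cls="tuned",
        gain=gain, noise_sd=gain * preset.noise_over_gain,
        tau_rise_s=preset.tau_rise_s, tau_decay_s=preset.tau_decay_s,
        bf_khz=float(protocol.frequencies_khz[bf_idx]), bf_idx=bf_idx,
        shape=shape, bwmax_steps=steps, mi=mi, threshold_level_idx=thr,
        support=support, amp_surface=amp, plane=plane,
    )


def _make_untuned(rng, preset, nid, x, y, axis_mm, cls, plane=0):
    gain = float(rng.uniform(*preset.gain_range))
    return GroundTruthNeuron(
        id=nid, x_um=x, y_um=y, axis_mm=axis_mm, cls=cls,
        gain=gain, noise_sd=gain * preset.noise_over_gain,
        tau_rise_s=preset.tau_rise_s, tau_decay_s=preset.tau_decay_s,
        spont_rate_hz=preset.spont_rate_hz if cls == "irregular" else 0.0,
        plane=plane,
    )


def sample_population(
    preset: SynthPreset,
    n: int,
    seed: int,
    protocol: "ToneProtocol | None" = None,
    fov_size_um: float = 200.0,
    tuned_only: bool = False,
) -> "list[GroundTruthNeuron]":
    """Draw ``n`` neurons: classes from the preset fractions, positions
    uniform in the FOV and along the tonotopic axis, and tuned BFs from the
    calibrated clamped-normal gradient model snapped to the protocol grid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    protocol = protocol or standard_protocol()
    rng = np.random.default_rng(seed)
    g = preset.neuron_gradient
    b_in, sigma_in, intercept = calibrate_gradient(
        g.slope_oct_per_mm, g.r_target, preset.axis_extent_mm
    )
    neurons = []
    for i in range(n):
        x, y = rng.uniform(0, fov_size_um, size=2)
        axis_mm = float(rng.uniform(0, preset.axis_extent_mm))
        cls = "tuned" if tuned_only else str(rng.choice(CLASSES, p=preset.class_fractions))
        if cls == "tuned":
            bf_oct = intercept + b_in * axis_mm + rng.normal(0.0, sigma_in)
            neurons.append(_make_tuned(rng, preset, protocol, i, x, y, axis_mm, bf_oct))
        else:
            neurons.append(_make_untuned(rng, preset, i, x, y, axis_mm, cls))
    return neurons


def sample_tuned(preset: SynthPreset, n: int, seed: int, **kw) -> "list[GroundTruthNeuron]":
    """``sample_population`` restricted to the tuned class (all ``n`` tuned)."""
    return sample_population(preset, n, seed, tuned_only=True, **kw)


def sample_planes(
    preset: SynthPreset,
    n_planes: int,
    neurons_per_plane: int,
    seed: int,
    protocol: "ToneProtocol | None" = None,
    fov_size_um: float = 200.0,
) -> "list[list[GroundTruthNeuron]]":
    """Draw focal planes along the tonotopic axis.

    Plane centers are uniform on the axis; each plane has a latent BF center
    from the plane-level calibrated gradient model, and its tuned neurons
    scatter around that center with the preset's within-plane SD (set from
    the printed field-IQR medians).  The per-plane *median* BF is robust to
    grid clamping, so the plane-level OLS slope is recovered unbiased.
    """
    if n_planes < 1 or neurons_per_plane < 1:
        raise ValueError("n_planes and neurons_per_plane must be >= 1")
    protocol = protocol or standard_protocol()
    rng = np.random.default_rng(seed)
    g = preset.plane_gradient
    b_in, sigma_b, intercept = calibrate_gradient(
        g.slope_oct_per_mm, g.r_target, preset.axis_extent_mm, quant_var=0.0
    )
    # remove the median-sampling noise contribution when possible
    n_tuned_exp = max(preset.tuned_fraction * neurons_per_plane, 1.0)
    med_se = 1.2533 * preset.sigma_within_oct / np.sqrt(n_tuned_exp)
    sigma_between = float(np.sqrt(max(sigma_b**2 - med_se**2, 0.0)))

    planes = []
    nid = 0
    for p in range(n_planes):
        axis_mm = float(rng.uniform(0, preset.axis_extent_mm))
        latent = intercept + b_in * axis_mm + rng.normal(0.0, sigma_between)
        latent = float(np.clip(latent, 0.0, protocol.frequencies_oct[-1]))
        plane = []
        for _ in range(neurons_per_plane):
            x, y = rng.uniform(0, fov_size_um, size=2)
            cls = str(rng.choice(CLASSES, p=preset.class_fractions))
            if cls == "tuned":
                bf_oct = latent + rng.normal(0.0, preset.sigma_within_oct)
                plane.append(_make_tuned(rng, preset, protocol, nid, x, y, axis_mm, bf_oct, plane=p))
            else:
                plane.append(_make_untuned(rng, preset, nid, x, y, axis_mm, cls, plane=p))
            nid += 1
        planes.append(plane)
    return planes
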