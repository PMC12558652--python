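"""Named synthetic-population presets and gradient calibration.

Two presets describe the populations being emulated:

* ``TR`` — thalamocortical-recipient-like: tonotopic (neuron-level gradient
  1.76 oct/mm, R 0.52; focal-plane gradient 2.13 oct/mm, R 0.77), narrowly
  tuned (median BW_max 3 grid steps = 1.30 oct), 46 % tuned / 41 % irregular
  / 13 % silent.
* ``CT`` — corticothalamic-like: non-tonotopic (0.37 oct/mm, R 0.079 at the
  neuron level; 0.21 oct/mm, R 0.20 at the plane level), broadly tuned
  (median BW_max 7 steps = 3.02 oct), 18 % / 57 % / 25 %.

Best frequencies live on a bounded grid (2-40 kHz), so the naive variance
decomposition sigma = |slope| * SD(x) * sqrt(R^-2 - 1) of an unbounded linear
model understates the scatter and overstates the recovered slope once values
are clamped to the grid range.  :func:`calibrate_gradient` therefore solves
numerically for the *inner* slope and scatter SD of a clamped-normal model

    y = clamp(a + b_in * x + eps, 0, span),  eps ~ N(0, sigma_in^2)

such that the expected OLS slope and Pearson R of (x, y) equal the requested
targets.  The closed form above seeds the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

__all__ = ["SynthPreset", "GradientSpec", "get_preset", "calibrate_gradient", "PRESET_NAMES"]

#: Octave span of the standard 2-40 kHz grid.
GRID_SPAN_OCT = float(np.log2(40.0 / 2.0))
#: Octave step of the standard 11-frequency grid.
GRID_STEP_OCT = GRID_SPAN_OCT / 10.0


@dataclass(frozen=True)
class GradientSpec:
    """Target tonotopic gradient: OLS slope (oct/mm) and Pearson R."""

    slope_oct_per_mm: float
    r_target: float


@dataclass(frozen=True)
class SynthPreset:
    """Generating parameters for one neuron population.

    Class and shape fractions must each sum to 1.  ``bwmax_step_pmf`` is a
    probability table over maximum FRA widths expressed in grid *steps*
    (a region s steps wide spans s + 1 grid frequencies, width s * 0.432 oct).
    """

    name: str
    class_fractions: tuple = (0.46, 0.41, 0.13)  # tuned, irregular, silent
    neuron_gradient: GradientSpec = field(default_factory=lambda: GradientSpec(1.76, 0.52))
    plane_gradient: GradientSpec = field(default_factory=lambda: GradientSpec(2.13, 0.77))
    axis_extent_mm: float = 1.2
    sigma_within_oct: float = 0.956
    shape_fractions: tuple = (0.395, 0.362, 0.243)  # V, I, O
    bwmax_step_pmf: tuple = (0.10, 0.17, 0.31, 0.12, 0.10, 0.08, 0.05, 0.04, 0.03)
    #: Probability that a V- or I-shaped neuron is intensity tuned (MI < 0.5).
    p_nonmono_vi: float = 0.05
    #: Spontaneous transient rate of irregular neurons (Hz).
    spont_rate_hz: float = 0.04
    #: Per-neuron peak-response gain range (delta f/f).
    gain_range: tuple = (0.2, 0.4)
    #: Trace noise SD as a fraction of the neuron's gain (1/5 -> 5-sigma peaks).
    noise_over_gain: float = 0.2
    #: Per-trial multiplicative amplitude jitter (lognormal sigma).
    trial_jitter_sd: float = 0.15
    #: Transient kinetics (GCaMP6s-like) and sampling.
    tau_rise_s: float = 0.18
    tau_decay_s: float = 1.5
    fs_hz: float = 30.0

    def __post_init__(self):
        for name, fr in (("class_fractions", self.class_fractions),
                         ("shape_fractions", self.shape_fractions)):
            fr = np.asarray(fr, float)
            if abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any() or (fr > 1).any():
                raise ValueError(f"{name} must be probabilities summing to 1")
        pmf = np.asarray(self.bwmax_step_pmf, float)
        if abs(pmf.sum() - 1.0) > 1e-9 or (pmf < 0).any():
            raise ValueError("bwmax_step_pmf must be a probability table")

    @property
    def tuned_fraction(self) -> float:
        return self.class_fractions[0]

    def with_overrides(self, **kwargs) -> "SynthPreset":
        return replace(self, **kwargs)


_TR = SynthPreset(name="TR")
_CT = SynthPreset(
    name="CT",
    class_fractions=(0.18, 0.57, 0.25),
    neuron_gradient=GradientSpec(0.37, 0.079),
    plane_gradient=GradientSpec(0.21, 0.20),
    sigma_within_oct=1.438,
    shape_fractions=(0.507, 0.228, 0.265),
    # median 7 steps (3.02 oct), quartiles ~5 and ~8-9 steps
    bwmax_step_pmf=(0.02, 0.03, 0.05, 0.08, 0.12, 0.14, 0.17, 0.13, 0.26),
)

_PRESETS = {"TR": _TR, "CT": _CT}
PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> SynthPreset:
    try:
        return _PRESETS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None


# ---------------------------------------------------------------------------
# Clamped-normal gradient calibration
# ---------------------------------------------------------------------------

def _clamped_normal_moments(mu, sigma, lo, hi):
    """Mean and variance of clamp(X, lo, hi) with X ~ N(mu, sigma^2)."""
    mu = np.asarray(mu, float)
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    inside = Fb - Fa
    m = lo * Fa + hi * (1.0 - Fb) + mu * inside - sigma * (fb - fa)
    e2_mid = (mu**2) * inside + 2 * mu * sigma * (fa - fb) + sigma**2 * (inside + a * fa - b * fb)
    e2 = lo**2 * Fa + hi**2 * (1.0 - Fb) + e2_mid
    return m, e2 - m**2


def _predicted(b_in, sigma_in, extent_mm, span_oct, quant_var):
    """Expected OLS slope and Pearson R of the clamped-normal model."""
    xs = (np.arange(400) + 0.5) / 400 * extent_mm
    a = (span_oct - b_in * extent_mm) / 2.0
    m, v = _clamped_normal_moments(a + b_in * xs, sigma_in, 0.0, span_oct)
    var_x = extent_mm**2 / 12.0
    cov = np.mean((xs - xs.mean()) * (m - m.mean()))
    slope_out = cov / np.mean((xs - xs.mean()) ** 2)
    var_y = np.mean(v) + np.var(m) + quant_var
    r_out = slope_out * np.sqrt(var_x) / np.sqrt(var_y)
    return slope_out, r_out


@lru_cache(maxsize=64)
def calibrate_gradient(
    slope_target: float,
    r_target: float,
    extent_mm: float = 1.2,
    span_oct: float = GRID_SPAN_OCT,
    quant_var: float = GRID_STEP_OCT**2 / 12.0,
) -> "tuple[float, float, float]":
    """Inner (slope, scatter SD, intercept) whose clamped-normal model yields
    the target OLS slope and Pearson R.

    ``quant_var`` accounts for grid-snapping quantization; pass 0 when the
    values are not snapped (focal-plane latent means).
    """
    sd_x = extent_mm / np.sqrt(12.0)
    sigma0 = abs(slope_target) * sd_x * np.sqrt(max(r_target, 1e-6) ** -2 - 1.0)

    def resid(p):
        b_in, log_sig = p
        s_out, r_out = _predicted(b_in, np.exp(log_sig), extent_mm, span_oct, quant_var)
        return [s_out - slope_target, r_out - r_target]

    sol = optimize.least_squares(
        resid, x0=[slope_target, np.log(max(sigma0, 1e-3))],
        bounds=([0.0, np.log(1e-4)], [20.0, np.log(50.0)]),
        xtol=1e-12, ftol=1e-12,
    )
    b_in, sigma_in = sol.x[0], float(np.exp(sol.x[1]))
    achieved = np.asarray(resid(sol.x))
    if np.abs(achieved[0]) > 0.02 * max(abs(slope_target), 0.1) or np.abs(achieved[1]) > 0.02:
        raise RuntimeError(
            f"gradient calibration did not converge for slope={slope_target}, R={r_target}"
        )
    intercept = (span_oct - b_in * extent_mm) / 2.0
    return float(b_in), sigma_in, float(intercept)
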