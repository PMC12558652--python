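"""Spatial statistics of best-frequency maps.

Covers the tonotopic-gradient fit (OLS of log2 BF on position along the
caudal-to-rostral axis), the field and local interquartile ranges of BF
(IQR_BF, a heterogeneity measure), nearest-neighbor BF differences, and the
bookkeeping that places two-photon fields of view on the wide-field axis.
All octave values are relative to 2 kHz; percentiles use the
linear-interpolation convention throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic.protocol import OCTAVE_REF_KHZ

__all__ = [
    "FieldOfView",
    "GradientFit",
    "project_to_axis",
    "fit_gradient",
    "field_iqr",
    "local_iqr",
    "nn_delta_frequency",
    "assign_area",
]


@dataclass
class FieldOfView:
    """One ~200 um two-photon plane: spatial context plus its neurons.

    ``neurons`` is a DataFrame with at least columns ``x_um``, ``y_um``,
    ``cls``, and ``bf_oct`` (NaN for non-tuned neurons).
    """

    mouse: str
    plane: int
    center_x_um: float
    center_y_um: float
    axis_mm: float
    neurons: pd.DataFrame = field(repr=False)
    depth_um: float = 0.0
    size_um: float = 200.0
    area: str = "other"

    def tuned(self) -> pd.DataFrame:
        return self.neurons[self.neurons["cls"] == "tuned"]


@dataclass
class GradientFit:
    """OLS fit of log2(BF) versus axis position."""

    slope_oct_per_mm: float
    intercept_oct: float
    pearson_r: float
    p_value: float
    n: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < 0.05


def project_to_axis(points_um: np.ndarray, origin_um: np.ndarray, unit_vec: np.ndarray):
    """Scalar projection (mm) of map-frame points onto the tonotopic axis.

    The axis is the unit vector from the LF-area centroid (origin) toward
    the HF-area centroid, both in the wide-field frame (um).
    """
    pts = np.atleast_2d(np.asarray(points_um, float))
    u = np.asarray(unit_vec, float)
    norm = np.linalg.norm(u)
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("axis unit vector is degenerate")
    u = u / norm
    return (pts - np.asarray(origin_um, float)) @ u / 1000.0


def fit_gradient(axis_mm: np.ndarray, bf_khz: np.ndarray) -> GradientFit:
    """Least-squares tonotopic gradient: log2(BF / 2 kHz) on axis position."""
    x = np.asarray(axis_mm, float)
    bf = np.asarray(bf_khz, float)
    if x.size != bf.size or x.size < 3:
        raise ValueError("need >= 3 matched (position, BF) points")
    y = np.log2(bf / OCTAVE_REF_KHZ)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in axis positions")
    if np.ptp(y) == 0:
        return GradientFit(0.0, float(y[0]), 0.0, 1.0, x.size, degenerate=True)
    res = stats.linregress(x, y)
    return GradientFit(
        slope_oct_per_mm=float(res.slope),
        intercept_oct=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def field_iqr(fov: FieldOfView, radius_um: float = 100.0, min_neighbors: int = 5):
    """Plane-level IQR of tuned-neuron BFs (octaves), or None.

    No IQR is computed unless at least ``min_neighbors`` tuned neurons
    (center included) lie within ``radius_um`` of the field center.
    """
    tuned = fov.tuned()
    if tuned.empty:
        return None
    cx = fov.size_um / 2.0
    cy = fov.size_um / 2.0
    d = np.hypot(tuned["x_um"].to_numpy() - cx, tuned["y_um"].to_numpy() - cy)
    if int((d <= radius_um).sum()) < min_neighbors:
        return None
    bf = tuned["bf_oct"].to_numpy()
    return float(np.percentile(bf, 75) - np.percentile(bf, 25))


def local_iqr(
    neurons: pd.DataFrame,
    radius_um: float = 25.0,
    n_centers: "int | None" = None,
    min_neighbors: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """IQR_BF within ``radius_um`` of randomly chosen tuned center neurons.

    Centers are sampled without replacement (at most ``n_centers``, default
    all tuned capped at 40); a sample is retained when >= ``min_neighbors``
    tuned neurons (center included) fall inside the radius.  Returns a
    DataFrame with center coordinates and ``iqr_oct``.
    """
    tuned = neurons[neurons["cls"] == "tuned"]
    if tuned.empty:
        return pd.DataFrame(columns=["center_x_um", "center_y_um", "iqr_oct"])
    rng = np.random.default_rng(seed)
    n_centers = min(n_centers or min(len(tuned), 40), len(tuned))
    pick = rng.choice(len(tuned), size=n_centers, replace=False)
    xy = tuned[["x_um", "y_um"]].to_numpy()
    bf = tuned["bf_oct"].to_numpy()
    rows = []
    for i in pick:
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        sel = d <= radius_um
        if int(sel.sum()) < min_neighbors:
            continue
        rows.append(
            {
                "center_x_um": xy[i, 0],
                "center_y_um": xy[i, 1],
                "iqr_oct": float(np.percentile(bf[sel], 75) - np.percentile(bf[sel], 25)),
            }
        )
    return pd.DataFrame(rows, columns=["center_x_um", "center_y_um", "iqr_oct"])


def nn_delta_frequency(neurons: pd.DataFrame) -> np.ndarray:
    """|log2 BF difference| (octaves) between each tuned neuron and its
    Euclidean-nearest tuned neighbor in the plane; distance ties go to the
    lower neuron index.  Empty when fewer than 2 tuned neurons."""
    tuned = neurons[neurons["cls"] == "tuned"]
    if len(tuned) < 2:
        return np.array([])
    xy = tuned[["x_um", "y_um"]].to_numpy(dtype=float)
    bf = tuned["bf_oct"].to_numpy(dtype=float)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argmin(d2, axis=1)  # argmin returns the lowest index on ties
    return np.abs(bf - bf[nn])


def assign_area(center_px: "tuple[float, float]", lf_mask: np.ndarray, hf_mask: np.ndarray) -> str:
    """LF / HF / other by mask membership of a map-frame point (row, col);
    boundary pixels are inclusive."""
    if lf_mask.shape != hf_mask.shape:
        raise ValueError("LF and HF masks must share the map frame")
    r, c = int(round(center_px[0])), int(round(center_px[1]))
    if not (0 <= r < lf_mask.shape[0] and 0 <= c < lf_mask.shape[1]):
        return "other"
    if lf_mask[r, c]:
        return "LF"
    if hf_mask[r, c]:
        return "HF"
    return "other"
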