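"""Wide-field functional mapping.

The wide-field branch downsamples the raw movie 10x by block averaging,
averages frames across the trials of each stimulus, smooths with a 5 x 5
spatial box kernel and a 3-frame moving average, converts to delta f/f
against the mean of the 800 ms preceding sound onset, and localizes the
low-frequency (4 kHz) and high-frequency (32 kHz) response areas.  The unit
vector from the LF centroid to the HF centroid defines the caudal-to-rostral
tonotopic axis used to place two-photon fields of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .topography import GradientFit, fit_gradient, project_to_axis

__all__ = [
    "WidefieldMap",
    "block_downsample",
    "preprocess_widefield",
    "dff_widefield",
    "locate_areas",
    "widefield_gradient",
]


@dataclass
class WidefieldMap:
    """LF/HF area masks, centroids, and the tonotopic axis they define.

    Centroids and the axis origin are (row, col) in downsampled-pixel
    coordinates; ``um_per_px`` converts to physical units.
    """

    lf_mask: np.ndarray = field(repr=False)
    hf_mask: np.ndarray = field(repr=False)
    lf_centroid_px: np.ndarray
    hf_centroid_px: np.ndarray
    axis_unit: np.ndarray
    um_per_px: float = 1.0
    degenerate: bool = False

    @property
    def origin_um(self) -> np.ndarray:
        return self.lf_centroid_px * self.um_per_px

    def project_um(self, points_um: np.ndarray) -> np.ndarray:
        """Axis position (mm) of map-frame points given in um (row, col)."""
        return project_to_axis(points_um, self.origin_um, self.axis_unit)


def block_downsample(frames: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean spatial downsampling of a (T, H, W) stack or (H, W) frame."""
    arr = np.asarray(frames, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    t, h, w = arr.shape
    if h % factor:
        raise ValueError(f"frame height {h} not divisible by downsample factor {factor}")
    if w % factor:
        raise ValueError(f"frame width {w} not divisible by downsample factor {factor}")
    out = arr.reshape(t, h // factor, factor, w // factor, factor).mean(axis=(2, 4))
    return out[0] if squeeze else out


def preprocess_widefield(
    movie: np.ndarray,
    trial_table: pd.DataFrame,
    downsample_factor: int = 10,
    spatial_kernel: int = 5,
    temporal_window: int = 3,
    pre_frames: int = 8,
    post_frames: int = 12,
) -> dict:
    """Downsample, trial-average, and smooth a wide-field movie.

    ``trial_table`` has one row per trial with columns ``stimulus`` and
    ``onset_frame``.  Returns ``{stimulus: movie}`` where each movie is the
    trial average over a window of ``pre_frames`` before to ``post_frames``
    after onset (onset at index ``pre_frames``), box-filtered spatially
    (reflect padding) and with a ``temporal_window``-frame moving average.
    """
    small = block_downsample(movie, downsample_factor)
    out = {}
    for stim, grp in trial_table.groupby("stimulus", sort=True):
        wins = []
        for onset in grp["onset_frame"].astype(int):
            if onset - pre_frames < 0 or onset + post_frames > small.shape[0]:
                raise ValueError(f"trial at frame {onset} does not fit the window")
            wins.append(small[onset - pre_frames : onset + post_frames])
        avg = np.mean(wins, axis=0)
        avg = ndimage.uniform_filter(avg, size=(1, spatial_kernel, spatial_kernel), mode="reflect")
        avg = ndimage.uniform_filter1d(avg, size=temporal_window, axis=0, mode="reflect")
        out[stim] = avg
    return out


def dff_widefield(
    movie: np.ndarray,
    onset_frame: int,
    fs_hz: float = 10.0,
    baseline_s: float = 0.8,
    response_s: float = 1.0,
):
    """Pixelwise delta f/f and the post-onset response map.

    f0 is the per-pixel mean over the ``baseline_s`` preceding onset; the
    response map is the mean delta f/f over (onset, onset + response_s].
    """
    movie = np.asarray(movie, dtype=float)
    n_base = int(np.ceil(baseline_s * fs_hz))
    if onset_frame < n_base:
        raise ValueError(f"need >= {n_base} baseline frames before onset")
    f0 = movie[onset_frame - n_base : onset_frame].mean(axis=0)
    bad = int((f0 <= 0).sum())
    if bad:
        raise ValueError(f"baseline fluorescence <= 0 at {bad} pixels")
    dff = (movie - f0) / f0
    n_resp = max(int(round(response_s * fs_hz)), 1)
    stop = min(onset_frame + n_resp, movie.shape[0])
    resp_map = dff[onset_frame:stop].mean(axis=0)
    return dff, resp_map


def _dominant_blob(resp_map: np.ndarray, threshold_frac: float):
    mask = resp_map >= threshold_frac * resp_map.max()
    if not mask.any():
        raise ValueError("empty mask after thresholding; lower threshold_frac")
    lab = measure.label(mask, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = lab == int(np.argmax(sizes))
    w = np.where(keep, np.clip(resp_map, 0, None), 0.0)
    total = w.sum()
    rr, cc = np.indices(resp_map.shape)
    centroid = np.array([(rr * w).sum() / total, (cc * w).sum() / total])
    return keep, centroid


def locate_areas(
    map_lf: np.ndarray,
    map_hf: np.ndarray,
    threshold_frac: float = 0.5,
    um_per_px: float = 1.0,
) -> WidefieldMap:
    """LF/HF area masks, centroids, and the tonotopic axis.

    Each area is the largest 8-connected component of pixels at or above
    ``threshold_frac`` of its map's maximum; centroids are response-weighted.
    The axis runs from the LF centroid toward the HF centroid; coincident
    centroids flag the result as degenerate.
    """
    if map_lf.shape != map_hf.shape:
        raise ValueError("LF and HF maps must share a shape")
    lf_mask, lf_c = _dominant_blob(map_lf, threshold_frac)
    hf_mask, hf_c = _dominant_blob(map_hf, threshold_frac)
    delta = hf_c - lf_c
    norm = float(np.linalg.norm(delta))
    degenerate = norm < 1e-9
    unit = delta / norm if not degenerate else np.array([np.nan, np.nan])
    return WidefieldMap(lf_mask, hf_mask, lf_c, hf_c, unit, um_per_px, degenerate)


def widefield_gradient(
    freq_maps: "dict[float, np.ndarray]",
    wf_map: WidefieldMap,
    resp_frac: float = 0.3,
) -> GradientFit:
    """Map-level tonotopic gradient from per-frequency response maps.

    Each pixel responding above ``resp_frac`` of the global maximum gets the
    frequency of its largest response as a pixel-level BF; the gradient is
    the OLS fit of log2(pixel BF) against the pixel's position along the
    LF-to-HF axis.
    """
    freqs = np.array(sorted(freq_maps))
    stack = np.stack([freq_maps[f] for f in freqs])
    peak = stack.max(axis=0)
    sel = peak >= resp_frac * stack.max()
    if sel.sum() < 3:
        raise ValueError("too few responsive pixels for a gradient fit")
    bf = freqs[np.argmax(stack, axis=0)][sel]
    rr, cc = np.indices(peak.shape)
    pts_um = np.column_stack([rr[sel], cc[sel]]) * wf_map.um_per_px
    axis_mm = wf_map.project_um(pts_um)
    return fit_gradient(axis_mm, bf)
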