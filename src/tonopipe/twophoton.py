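"""Two-photon movie preprocessing: rigid motion correction, ROI trace
extraction, and delta f/f.

Motion correction is integer-pixel rigid translation chosen to minimize the
sum of squared intensity differences (SSD) against a template (the mean of
the first 100 frames, refined once with the corrected mean).  The baseline
for delta f/f is the 25th percentile of the entire recording
(linear-interpolation percentile convention, shared across the package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DffTrace", "RoiSet", "motion_correct", "extract_traces", "compute_dff"]


@dataclass
class DffTrace:
    """Relative fluorescence change per frame for one ROI."""

    values: np.ndarray
    fs_hz: float
    f0: float
    baseline_rule: str = "percentile25"

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs_hz


@dataclass
class RoiSet:
    """Labeled ROI masks (0 = background) with physical scale."""

    labels: np.ndarray
    um_per_px: float = 1.0

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def centroids_um(self) -> dict:
        out = {}
        for i in self.ids:
            rr, cc = np.nonzero(self.labels == i)
            out[int(i)] = (float(cc.mean() * self.um_per_px), float(rr.mean() * self.um_per_px))
        return out


def _shift_frame(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(frame, fill)
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def _best_shift(frame: np.ndarray, template: np.ndarray, max_shift: int, fill: float):
    best = (0, 0)
    best_ssd = np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ssd = float(np.sum((_shift_frame(frame, dy, dx, fill) - template) ** 2))
            if ssd < best_ssd - 1e-12 or (
                abs(ssd - best_ssd) <= 1e-12 and (abs(dy) + abs(dx) < abs(best[0]) + abs(best[1]))
            ):
                best_ssd = ssd
                best = (dy, dx)
    return best


def motion_correct(movie: np.ndarray, max_shift_px: int = 5, template_frames: int = 100):
    """Integer-pixel rigid registration by SSD minimization.

    Returns ``(shifts, corrected)`` where ``shifts[t] = (dy, dx)`` is the
    translation *applied* to frame ``t``.  Template = mean of the first
    ``template_frames`` frames, then one refinement pass against the
    corrected mean.  Edges exposed by the translation are filled with the
    template border median.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be a (frames, H, W) stack with >= 2 frames")
    if max_shift_px < 0 or max_shift_px > min(movie.shape[1:]) // 2:
        raise ValueError("max_shift_px must be in [0, min(H, W) / 2]")

    def one_pass(template):
        border = np.concatenate(
            [template[0], template[-1], template[:, 0], template[:, -1]]
        )
        fill = float(np.median(border))
        shifts = np.zeros((movie.shape[0], 2), dtype=int)
        corrected = np.empty_like(movie)
        for t in range(movie.shape[0]):
            dy, dx = _best_shift(movie[t], template, max_shift_px, fill)
            shifts[t] = (dy, dx)
            corrected[t] = _shift_frame(movie[t], dy, dx, fill)
        return shifts, corrected

    template = movie[: min(template_frames, movie.shape[0])].mean(axis=0)
    shifts, corrected = one_pass(template)
    shifts, corrected = one_pass(corrected.mean(axis=0))
    return shifts, corrected


def extract_traces(movie: np.ndarray, rois: RoiSet) -> dict:
    """Per-frame mean over each ROI's pixels (no neuropil subtraction)."""
    movie = np.asarray(movie)
    if movie.shape[1:] != rois.labels.shape:
        raise ValueError("ROI mask shape does not match movie frames")
    traces = {}
    flat = movie.reshape(movie.shape[0], -1)
    lab = rois.labels.ravel()
    for i in rois.ids:
        sel = lab == i
        if not sel.any():
            raise ValueError(f"ROI {int(i)} is empty")
        traces[int(i)] = flat[:, sel].mean(axis=1)
    return traces


def compute_dff(raw_trace: np.ndarray, fs_hz: float = 30.0) -> DffTrace:
    """Delta f/f with f0 = 25th percentile of the whole recording."""
    raw = np.asarray(raw_trace, dtype=float)
    if raw.size == 0:
        raise ValueError("empty trace")
    f0 = float(np.percentile(raw, 25))
    if f0 <= 0:
        raise ValueError(
            "25th-percentile baseline is <= 0; offset-correct the raw fluorescence first"
        )
    return DffTrace(values=(raw - f0) / f0, fs_hz=fs_hz, f0=f0)
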