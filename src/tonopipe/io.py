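"""Readers and writers for the pipeline's on-disk formats.

Movies and mask images travel as multi-page 16-bit TIFF; tabular data
(protocols, traces, events, neurons, FOVs) as CSV with unit-bearing
headers; axes/gradients/manifests as JSON; presets and configuration as
YAML.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic.presets import SynthPreset, GradientSpec, get_preset
from .synthetic.protocol import ToneProtocol
from .topography import GradientFit

__all__ = [
    "write_movie",
    "read_movie",
    "write_labels",
    "read_labels",
    "write_protocol",
    "read_protocol",
    "write_traces",
    "read_traces",
    "write_preset",
    "read_preset",
    "write_gradient",
    "read_gradient",
    "write_manifest",
]


def write_movie(path, movie: np.ndarray) -> None:
    """Grayscale multi-page 16-bit TIFF (values clipped to uint16 range)."""
    arr = np.round(np.clip(np.asarray(movie), 0, 65535)).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_movie(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels).astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_protocol(path, protocol: ToneProtocol) -> None:
    df = protocol.trials.copy()
    df["frequency_khz"] = protocol.frequencies_khz[df["freq_idx"]]
    df["level_db"] = protocol.levels_db[df["level_idx"]]
    df.attrs = {}
    header = {
        "frequencies_khz": list(map(float, protocol.frequencies_khz)),
        "levels_db": list(map(float, protocol.levels_db)),
        "n_repeats": protocol.n_repeats,
        "tone_duration_s": protocol.tone_duration_s,
        "iti_s": protocol.iti_s,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        df.to_csv(fh, index=False)


def read_protocol(path) -> ToneProtocol:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# "))
        df = pd.read_csv(fh)
    return ToneProtocol(
        frequencies_khz=np.asarray(header["frequencies_khz"]),
        levels_db=np.asarray(header["levels_db"]),
        n_repeats=int(header["n_repeats"]),
        trials=df[["freq_idx", "level_idx", "repeat", "onset_s"]],
        tone_duration_s=float(header["tone_duration_s"]),
        iti_s=float(header["iti_s"]),
    )


def write_traces(path, traces: np.ndarray, ids=None, fs_hz: float = 30.0) -> None:
    """Frames x ROIs CSV; column names are ROI ids, first column is time (s)."""
    ids = ids if ids is not None else range(traces.shape[0])
    df = pd.DataFrame(np.asarray(traces).T, columns=[f"roi_{i}" for i in ids])
    df.insert(0, "time_s", np.arange(traces.shape[1]) / fs_hz)
    df.to_csv(path, index=False)


def read_traces(path):
    df = pd.read_csv(path)
    t = df.pop("time_s").to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 30.0
    return df.to_numpy().T, [int(c.removeprefix("roi_")) for c in df.columns], float(fs)


def write_preset(path, preset: SynthPreset) -> None:
    d = dataclasses.asdict(preset)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_preset(path) -> SynthPreset:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("neuron_gradient", "plane_gradient"):
        d[key] = GradientSpec(**d[key])
    for key in ("class_fractions", "shape_fractions", "bwmax_step_pmf", "gain_range"):
        d[key] = tuple(d[key])
    return SynthPreset(**d)


def write_gradient(path, fit: GradientFit) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(fit), fh, indent=2)


def read_gradient(path) -> GradientFit:
    with open(path) as fh:
        return GradientFit(**json.load(fh))


def write_manifest(path, config: dict, seed: int) -> None:
    """Record the run's seed and a hash of its configuration."""
    import tonopipe

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "tonopipe_version": tonopipe.__version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
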