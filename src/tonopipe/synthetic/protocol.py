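"""Pure-tone stimulation protocols.

The standard protocol delivers 11 tone frequencies geometrically spaced from
2 to 40 kHz at 6 sound levels (30-80 dB SPL), 5 repeats each, in a seeded
random order: 330 presentations over 55 unique frequency/level combinations.
Adjacent frequencies are log2(40/2)/10 = 0.432 octaves apart; octave values
throughout the package are expressed relative to 2 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ToneProtocol",
    "make_protocol",
    "standard_protocol",
    "OCTAVE_REF_KHZ",
]

#: Reference frequency for octave values (bottom of the standard grid).
OCTAVE_REF_KHZ = 2.0


@dataclass(frozen=True)
class ToneProtocol:
    """A frequency x level x repeat tone grid with presentation times.

    ``trials`` is a DataFrame with one row per presentation and columns
    ``freq_idx``, ``level_idx``, ``repeat``, ``onset_s``; rows are ordered by
    onset time.
    """

    frequencies_khz: np.ndarray
    levels_db: np.ndarray
    n_repeats: int
    trials: pd.DataFrame = field(repr=False)
    tone_duration_s: float = 0.1
    iti_s: float = 6.0

    @property
    def n_freq(self) -> int:
        return len(self.frequencies_khz)

    @property
    def n_level(self) -> int:
        return len(self.levels_db)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_combinations(self) -> int:
        return self.n_freq * self.n_level

    @property
    def octave_step(self) -> float:
        """Log2 spacing between adjacent grid frequencies."""
        return float(np.log2(self.frequencies_khz[1] / self.frequencies_khz[0]))

    @property
    def frequencies_oct(self) -> np.ndarray:
        """Grid frequencies in octaves relative to 2 kHz."""
        return np.log2(self.frequencies_khz / OCTAVE_REF_KHZ)

    @property
    def onsets_s(self) -> np.ndarray:
        return self.trials["onset_s"].to_numpy()

    @property
    def duration_s(self) -> float:
        """Recording length needed to cover the session (last onset + 8 s)."""
        return float(self.trials["onset_s"].iloc[-1] + 8.0)

    def snap_to_grid(self, oct_values: np.ndarray) -> np.ndarray:
        """Indices of the grid frequencies nearest to octave values.

        Values outside the grid range clamp to the edge index; values inside
        move by at most half a grid step.
        """
        grid = self.frequencies_oct
        idx = np.searchsorted(grid, np.atleast_1d(oct_values))
        idx = np.clip(idx, 1, len(grid) - 1)
        lo = grid[idx - 1]
        hi = grid[idx]
        take_lo = np.abs(np.atleast_1d(oct_values) - lo) <= np.abs(hi - np.atleast_1d(oct_values))
        return np.where(take_lo, idx - 1, idx)


def make_protocol(
    f_min_khz: float = 2.0,
    f_max_khz: float = 40.0,
    n_freq: int = 11,
    levels_db: "list[float] | np.ndarray" = (30, 40, 50, 60, 70, 80),
    n_repeats: int = 5,
    iti_s: float = 6.0,
    seed: int = 0,
    tone_duration_s: float = 0.1,
    t0_s: float = 2.0,
) -> ToneProtocol:
    """Build a tone protocol with a seeded random presentation order.

    Frequencies are geometric from ``f_min_khz`` to ``f_max_khz``; every
    frequency/level combination appears exactly ``n_repeats`` times.  Onsets
    start at ``t0_s`` and advance by ``iti_s`` per presentation.
    """
    if f_min_khz <= 0 or f_max_khz <= 0:
        raise ValueError("frequencies must be positive")
    if f_min_khz >= f_max_khz:
        raise ValueError("f_min_khz must be < f_max_khz")
    if n_freq < 2:
        raise ValueError("n_freq must be >= 2")
    levels = np.asarray(levels_db, dtype=float)
    if levels.size == 0:
        raise ValueError("levels_db must be nonempty")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if iti_s < tone_duration_s:
        raise ValueError("iti_s must be >= tone_duration_s")

    freqs = f_min_khz * (f_max_khz / f_min_khz) ** (np.arange(n_freq) / (n_freq - 1))

    fi, li, ri = np.meshgrid(
        np.arange(n_freq), np.arange(levels.size), np.arange(n_repeats), indexing="ij"
    )
    combos = np.column_stack([fi.ravel(), li.ravel(), ri.ravel()])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    combos = combos[order]
    onsets = t0_s + iti_s * np.arange(len(combos))

    trials = pd.DataFrame(
        {
            "freq_idx": combos[:, 0],
            "level_idx": combos[:, 1],
            "repeat": combos[:, 2],
            "onset_s": onsets,
        }
    )
    return ToneProtocol(
        frequencies_khz=freqs,
        levels_db=levels,
        n_repeats=n_repeats,
        trials=trials,
        tone_duration_s=tone_duration_s,
        iti_s=iti_s,
    )


def standard_protocol(seed: int = 0, iti_s: float = 6.0) -> ToneProtocol:
    """The 330-tone session: 11 freqs (2-40 kHz) x 6 levels x 5 repeats."""
    return make_protocol(seed=seed, iti_s=iti_s)
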