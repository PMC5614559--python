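"""Tone stimulus protocols: frequency-level grids and randomized trial schedules.

The imaging protocol presents pure tones drawn from a lattice of log-spaced
frequencies crossed with linearly spaced sound levels.  Each frequency-level
combination (a *condition*) is repeated a fixed number of times; the trial
order is a seeded random permutation and trials are delivered at a constant
inter-onset interval, partitioned into consecutive blocks.

Frequencies live in Hz externally; the analysis works on the octave axis
``log2(f / 1 kHz)`` (see :func:`boutonmap.tuning.hz_to_octaves`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusGrid", "StimulusSchedule", "make_stimulus_grid", "make_schedule"]


@dataclass(frozen=True)
class StimulusGrid:
    """A frequency x level stimulus lattice.

    Condition ids are flattened row-major with level as the row axis:
    ``condition = level_index * n_frequencies + frequency_index``, matching
    the layout of the frequency response area (levels in rows, frequencies
    in columns).
    """

    frequencies_hz: np.ndarray  # ascending, log-spaced
    levels_db: np.ndarray  # ascending, arithmetic

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies_hz", np.asarray(self.frequencies_hz, float))
        object.__setattr__(self, "levels_db", np.asarray(self.levels_db, float))
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.frequencies_hz <= 0):
            raise ValueError("frequencies must be positive")

    @property
    def n_frequencies(self) -> int:
        return self.frequencies_hz.size

    @property
    def n_levels(self) -> int:
        return self.levels_db.size

    @property
    def n_conditions(self) -> int:
        return self.n_frequencies * self.n_levels

    def condition_id(self, level_index: int, frequency_index: int) -> int:
        return int(level_index) * self.n_frequencies + int(frequency_index)

    def condition_freq_level(self, condition: int) -> tuple[float, float]:
        """(frequency Hz, level dB) of a flattened condition id."""
        li, fi = divmod(int(condition), self.n_frequencies)
        return float(self.frequencies_hz[fi]), float(self.levels_db[li])

    def condition_frequencies(self) -> np.ndarray:
        """Frequency (Hz) of every condition id, shape (n_conditions,)."""
        return np.tile(self.frequencies_hz, self.n_levels)

    def condition_levels(self) -> np.ndarray:
        """Level (dB SPL) of every condition id, shape (n_conditions,)."""
        return np.repeat(self.levels_db, self.n_frequencies)

    def to_json(self) -> str:
        return json.dumps(
            {"frequencies_hz": self.frequencies_hz.tolist(), "levels_db": self.levels_db.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusGrid":
        d = json.loads(text)
        return cls(np.asarray(d["frequencies_hz"]), np.asarray(d["levels_db"]))


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered trials: per-trial condition id and onset frame.

    Onsets are strictly increasing with constant spacing ``interval`` and the
    condition sequence is a seeded uniform permutation of the multiset in
    which each condition appears exactly ``repeats`` times.
    """

    condition_ids: np.ndarray  # int, length n_trials
    onsets: np.ndarray  # int frames, strictly increasing
    interval: int
    repeats: int
    n_blocks: int = 1
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition_ids", np.asarray(self.condition_ids, int))
        object.__setattr__(self, "onsets", np.asarray(self.onsets, int))
        if self.condition_ids.shape != self.onsets.shape:
            raise ValueError("condition_ids and onsets must have equal length")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.condition_ids.size

    @property
    def span_frames(self) -> int:
        """Frames from 0 through the end of the last inter-onset interval."""
        return int(self.onsets[-1]) + self.interval

    def block_slices(self) -> list[slice]:
        per = self.n_trials // self.n_blocks
        return [slice(i * per, (i + 1) * per) for i in range(self.n_blocks)]

    def block_of_trial(self, trial: int) -> int:
        return int(trial) // (self.n_trials // self.n_blocks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "condition_ids": self.condition_ids.tolist(),
                "onsets": self.onsets.tolist(),
                "interval": self.interval,
                "repeats": self.repeats,
                "n_blocks": self.n_blocks,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusSchedule":
        d = json.loads(text)
        return cls(
            np.asarray(d["condition_ids"]),
            np.asarray(d["onsets"]),
            interval=d["interval"],
            repeats=d["repeats"],
            n_blocks=d["n_blocks"],
            seed=d.get("seed"),
        )


def make_stimulus_grid(
    f_min_hz: float,
    f_max_hz: float,
    step_octaves: float,
    level_min_db: float,
    level_max_db: float,
    level_step_db: float,
) -> StimulusGrid:
    """Build a log-spaced frequency x arithmetic level grid.

    Frequencies are ``f_min * 2**(k * step)`` for ``k = 0 .. floor(log2(f_max
    / f_min) / step)``; levels run arithmetically from ``level_min`` to
    ``level_max``.  The canonical protocol (1.25-80 kHz in 1/4-octave steps,
    20-80 dB SPL in 20 dB steps) yields 25 frequencies x 4 levels = 100
    conditions.
    """
    if f_min_hz <= 0 or step_octaves <= 0:
        raise ValueError("f_min and step_octaves must be positive")
    if f_min_hz > f_max_hz:
        raise ValueError("f_min must not exceed f_max")
    if level_step_db <= 0:
        raise ValueError("level_step must be positive")
    n_freq = int(np.floor(np.log2(f_max_hz / f_min_hz) / step_octaves + 1e-9)) + 1
    freqs = f_min_hz * 2.0 ** (step_octaves * np.arange(n_freq))
    n_lev = int(np.floor((level_max_db - level_min_db) / level_step_db + 1e-9)) + 1
    levels = level_min_db + level_step_db * np.arange(n_lev)
    return StimulusGrid(freqs, levels)


def make_schedule(
    grid: StimulusGrid,
    repeats: int,
    interval: int,
    n_blocks: int = 1,
    seed: int = 0,
    first_onset: int | None = None,
) -> StimulusSchedule:
    """Randomized interleaved schedule: every condition `repeats` times.

    Trial order is a seeded uniform permutation of the condition multiset;
    onsets are ``first_onset + k * interval`` (default first onset one
    interval in, leaving a pre-stimulus baseline).
    """
    if repeats < 1 or interval < 1:
        raise ValueError("repeats and interval must be >= 1")
    n_trials = grid.n_conditions * repeats
    if n_trials % n_blocks != 0:
        raise ValueError(
            f"{n_trials} trials cannot be split into {n_blocks} equal blocks"
        )
    rng = np.random.default_rng(seed)
    ids = np.repeat(np.arange(grid.n_conditions), repeats)
    ids = rng.permutation(ids)
    if first_onset is None:
        first_onset = interval
    onsets = first_onset + interval * np.arange(n_trials)
    return StimulusSchedule(ids, onsets, interval=interval, repeats=repeats,
                            n_blocks=n_blocks, seed=seed)
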