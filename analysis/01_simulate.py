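#!/usr/bin/env python
"""Generate the standard synthetic session and summarize what it contains.

Writes the stimulus protocol (grid + schedule), the ground-truth bouton
table and the session movie's summary statistics under results/analysis/.
The tone protocol is the canonical one: 25 frequencies (1.25-80 kHz in
1/4-octave steps) x 4 levels (20-80 dB SPL in 20 dB steps), one tone every
45 frames at ~30 Hz; the scene is the package's standard scaled-down field.
"""

from pathlib import Path

import numpy as np

from boutonmap.io import write_grid, write_schedule
from boutonmap.pipeline import stage_seed, validate_config
from boutonmap.stimuli import make_schedule, make_stimulus_grid
from boutonmap.synth import linear_level_gain, make_scene, render_movie

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

cfg = validate_config({"seed": 1}).data
g, s, sc = cfg["grid"], cfg["schedule"], cfg["scene"]
grid = make_stimulus_grid(g["f_min_hz"], g["f_max_hz"], g["step_octaves"],
                          g["level_min_db"], g["level_max_db"], g["level_step_db"])
schedule = make_schedule(grid, s["repeats"], s["interval"], s["n_blocks"],
                         seed=stage_seed(cfg["seed"], "simulate"))
scene = make_scene(shape=tuple(sc["shape"]), n_boutons=sc["n_boutons"],
                   baseline=sc["baseline"], noise_floor=sc["noise_floor"],
                   noise_gain=sc["noise_gain"],
                   response_jitter_sd=sc["response_jitter_sd"],
                   drift_amplitude_px=sc["drift_amplitude_px"],
                   n_frames=schedule.span_frames + 15, on_grid=grid,
                   level_gain=linear_level_gain(g["level_min_db"], g["level_max_db"]),
                   seed=stage_seed(cfg["seed"], "simulate"))
movie, _ = render_movie(scene, grid, schedule, seed=stage_seed(cfg["seed"], "simulate"))

write_grid(OUT / "grid.json", grid)
write_schedule(OUT / "schedule.json", schedule)
scene.to_frame().to_csv(OUT / "ground_truth.csv", index=False)

print(f"protocol: {grid.n_frequencies} frequencies x {grid.n_levels} levels "
      f"= {grid.n_conditions} conditions")
print(f"schedule: {schedule.n_trials} trials in {schedule.n_blocks} blocks of "
      f"{schedule.n_trials // schedule.n_blocks}")
print(f"scene: {scene.n_boutons} boutons on a {scene.shape[0]}x{scene.shape[1]} px "
      f"field, drift up to {np.abs(scene.drift_px).max():.1f} px")
print(f"movie: {movie.n_frames} frames at {movie.frame_rate:.0f} Hz, "
      f"mean intensity {movie.frames.mean():.1f}")
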