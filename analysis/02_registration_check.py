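#!/usr/bin/env python
"""Validate motion correction against an injected drift trajectory.

A noiseless synthetic movie is rendered with a smooth +/-3 px x-y drift;
phase-correlation registration must recover the trajectory with sub-0.1 px
RMS error, and a drift-free movie must pass through unchanged.
"""

import json
from pathlib import Path

from boutonmap.benchmarks import registration_benchmark

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

out = registration_benchmark(seed=1)
(OUT / "registration_check.json").write_text(json.dumps(out, indent=2) + "\n")

print(f"injected +/-3 px drift over {out['n_frames']} frames")
print(f"recovered shift series RMS error: {out['rms_error_px']:.3f} px")
print(f"drift-free movie max change through registration: "
      f"{out['static_max_change']:.2e}")
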