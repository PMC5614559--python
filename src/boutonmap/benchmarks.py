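"""Ground-truth benchmark runs used by the validation suite.

Each function builds a synthetic dataset with known generative parameters,
runs the corresponding pipeline stage(s) on it, and returns the recovery
metrics.  They are deliberately deterministic given their seed so the same
numbers can be recomputed by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .pipeline import run_pipeline, validate_config
from .popstats import co_tuning, compare_paired, tonotopic_axis
from .registration import register_stack
from .roi import detect_rois, make_training_patches, match_rois, train_bouton_classifier
from .roi import RoiConfig
from .stimuli import make_schedule, make_stimulus_grid
from .synth import make_scene, render_mean_image, render_movie, sample_bouton_population
from .tuning import responsiveness_test_batch

__all__ = [
    "registration_benchmark",
    "detection_benchmark",
    "null_gate_benchmark",
    "bf_recovery_benchmark",
    "score_bf_recovery",
    "noiseless_bf_benchmark",
    "score_noiseless_bf",
    "axis_sweep_benchmark",
    "layer_comparison_benchmark",
]


def registration_benchmark(seed: int = 0, drift_px: float = 3.0) -> dict:
    """Inject a smooth +/- ``drift_px`` drift into a noiseless movie and
    measure the RMS error of the recovered shift series; also check that a
    static movie passes through registration untouched."""
    grid = make_stimulus_grid(4000, 32000, 0.5, 60, 80, 20)
    schedule = make_schedule(grid, repeats=2, interval=30, seed=seed)
    n_frames = schedule.span_frames + 15
    scene = make_scene(shape=(64, 64), n_boutons=10, min_separation_px=8,
                       seed=seed, noise_floor=0, noise_gain=0,
                       response_jitter_sd=0, drift_amplitude_px=drift_px,
                       n_frames=n_frames)
    movie, _ = render_movie(scene, grid, schedule, seed=seed)
    _, shifts = register_stack(movie, n_template_frames=50)
    drift = scene.drift_px[:movie.n_frames]
    offset = drift[:50].mean(axis=0)  # absorbed into the 50-frame template
    rms = float(np.sqrt(np.mean((shifts - (drift - offset)) ** 2)))

    static_scene = make_scene(shape=(64, 64), n_boutons=10, min_separation_px=8,
                              seed=seed, noise_floor=0, noise_gain=0,
                              response_jitter_sd=0, amplitude_range=(0.0, 0.0))
    static, _ = render_movie(static_scene, grid, schedule, seed=seed)
    registered, _ = register_stack(static, n_template_frames=50)
    static_max_dev = float(np.abs(registered.frames.astype(float)
                                  - static.frames.astype(float)).max())
    return {"rms_error_px": rms, "static_max_change": static_max_dev,
            "n_frames": movie.n_frames}


def detection_benchmark(seed: int = 0, n_boutons: int = 50, snr: float = 5.0) -> dict:
    """Precision/recall of the ROI chain on a noisy 50-bouton mean image."""
    scene = make_scene(shape=(256, 256), n_boutons=n_boutons, min_separation_px=12,
                       seed=3 + seed, noise_floor=0, noise_gain=0)
    noise_sd = scene.brightness.min() / snr
    image = render_mean_image(scene, noise_sd=noise_sd, seed=4 + seed)
    cfg = RoiConfig()
    patches, labels = make_training_patches(300, cfg.patch_size, seed=seed)
    clf = train_bouton_classifier(patches, labels, seed=seed, config=cfg)
    rois = detect_rois(image, clf, cfg)
    _, precision, recall = match_rois(rois, scene.centers_px, tolerance_px=2.0)
    return {"precision": precision, "recall": recall,
            "n_detected": rois.n_rois, "n_true": n_boutons}


def null_gate_benchmark(seed: int = 0, n_boutons: int = 10_000) -> dict:
    """Inclusion rate of the p < 0.001 ANOVA gate on i.i.d. Gaussian nulls
    under the full 900-trial protocol."""
    grid = make_stimulus_grid(1250, 80000, 0.25, 20, 80, 20)
    schedule = make_schedule(grid, repeats=9, interval=45, n_blocks=3, seed=seed)
    rng = np.random.default_rng(seed + 123)
    responses = rng.standard_normal((n_boutons, schedule.n_trials))
    _, flags = responsiveness_test_batch(responses, schedule.condition_ids)
    return {"inclusion_rate": float(flags.mean()), "n_boutons": n_boutons,
            "binomial_se": float(np.sqrt(0.001 * 0.999 / n_boutons))}


def score_bf_recovery(res: dict) -> dict:
    """Score an end-to-end session result against its generative scene."""
    scene = res["scene"]
    assignment, precision, recall = match_rois(res["rois"], scene.centers_px, 2.0)
    bt = res["bouton_table"]
    errors = []
    for i, truth in enumerate(assignment):
        row = bt.iloc[i]
        if truth >= 0 and row["responsive"] and np.isfinite(row["bf_oct"]):
            errors.append(abs(row["bf_oct"] - scene.bf_oct[truth]))
    errors = np.array(errors)
    return {
        "fraction_within_quarter_octave": float(np.mean(errors <= 0.25)),
        "median_abs_error_oct": float(np.median(errors)),
        "n_scored": int(errors.size),
        "detection_precision": precision,
        "detection_recall": recall,
        "n_responsive": int(bt["responsive"].sum()),
    }


def bf_recovery_benchmark(seed: int = 7, out_dir=None) -> dict:
    """Full end-to-end session at the standard configuration: fraction of
    detected responsive boutons whose BF lands within one grid step (0.25
    octaves) of the generative BF."""
    import tempfile

    if out_dir is None:
        with tempfile.TemporaryDirectory() as td:
            res = run_pipeline(validate_config({"seed": seed}), out_dir=td)
    else:
        res = run_pipeline(validate_config({"seed": seed}), out_dir=out_dir)
    return score_bf_recovery(res)


def score_noiseless_bf(res: dict) -> dict:
    scene = res["scene"]
    assignment, _, _ = match_rois(res["rois"], scene.centers_px, 2.0)
    bt = res["bouton_table"]
    exact = total = 0
    for i, truth in enumerate(assignment):
        row = bt.iloc[i]
        if truth >= 0 and row["responsive"] and np.isfinite(row["bf_oct"]):
            total += 1
            exact += np.isclose(row["bf_oct"], scene.bf_oct[truth], atol=1e-9)
    return {"n_scored": total, "n_exact": int(exact)}


def noiseless_bf_benchmark(seed: int = 2, out_dir=None) -> dict:
    """Noiseless, drift-free, on-grid session: every matched responsive
    bouton's BF must reproduce the generative BF exactly."""
    import tempfile

    cfg = validate_config({
        "seed": seed,
        "schedule": {"repeats": 2, "n_blocks": 1},
        "scene": {"shape": [80, 80], "n_boutons": 10, "noise_floor": 0.0,
                  "noise_gain": 0.0, "response_jitter_sd": 0.0,
                  "drift_amplitude_px": 0.0},
        "registration": {"enabled": False},
    })
    if out_dir is None:
        with tempfile.TemporaryDirectory() as td:
            res = run_pipeline(cfg, out_dir=td)
    else:
        res = run_pipeline(cfg, out_dir=out_dir)
    return score_noiseless_bf(res)


def axis_sweep_benchmark(seed: int = 0, n_replicates: int = 100) -> dict:
    """Angle recovery of the 360-degree sweep: a 0.02 oct/um gradient at
    125 degrees with 0.5 octave scatter, 300 boutons over 500 um."""
    hits = 0
    errors = []
    for rep in range(n_replicates):
        pop = sample_bouton_population(300, 500.0, 125.0, 0.02, 0.5,
                                       bf_range_oct=(-50, 50), seed=seed * 1000 + rep)
        est = tonotopic_axis(pop, step_deg=1.0)
        err = abs((est.angle_deg - 125.0 + 180) % 360 - 180)
        errors.append(err)
        hits += err <= 10.0
    return {"fraction_within_10deg": hits / n_replicates,
            "median_error_deg": float(np.median(errors)),
            "n_replicates": n_replicates}


def layer_comparison_benchmark(seed: int = 0, n_replicates: int = 50,
                               n_regions: int = 36, boutons_per_region: int = 90
                               ) -> dict:
    """Paired-layer co-tuning contrast: per region, superficial-layer BFs are
    drawn with generative scatter 1.15 octaves and middle-layer BFs with
    0.93 octaves; counts the replicates in which the pipeline reproduces the
    ordering (superficial less homogeneous) with a significant paired test."""
    rng = np.random.default_rng(seed + 77)
    successes = 0
    p_values = []
    for _ in range(n_replicates):
        l1 = np.array([co_tuning(rng.normal(0.0, 1.15, boutons_per_region))
                       for _ in range(n_regions)])
        l34 = np.array([co_tuning(rng.normal(0.0, 0.93, boutons_per_region))
                        for _ in range(n_regions)])
        out = compare_paired(l1, l34)
        p_values.append(out.p_value)
        if np.median(l1) > np.median(l34) and out.p_value < 0.05:
            successes += 1
    return {"fraction_replicated": successes / n_replicates,
            "median_p": float(np.median(p_values)),
            "n_replicates": n_replicates}
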