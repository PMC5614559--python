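"""Seed-reproducible orchestration of the full analysis chain.

``validate_config`` turns a (possibly partial) mapping - typically parsed
from YAML - into a checked :class:`PipelineConfig` with documented defaults,
rejecting unknown keys and cross-field inconsistencies (response window vs
stimulus interval, high-pass cutoff vs Nyquist).  ``run_pipeline`` executes
generate -> register -> detect -> extract -> tune -> summarize, writes every
stage output under ``out_dir`` and finishes with a manifest of content
hashes; rerunning an identical config reproduces identical tables.

The single global seed fans out to per-stage seeds through a fixed
``numpy.random.SeedSequence`` derivation, so each stage is independently
reproducible.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .registration import register_stack, shifts_to_frame
from .roi import RoiConfig, detect_rois, make_training_patches, train_bouton_classifier
from .signals import compute_dff, extract_traces, highpass, trial_responses
from .stimuli import make_schedule, make_stimulus_grid
from .synth import linear_level_gain, make_scene, render_movie
from .tuning import analyze_rois, records_to_frame
from .popstats import co_tuning, summarize_region, tonotopic_axis

log = logging.getLogger("boutonmap")

__all__ = ["PipelineConfig", "ConfigError", "StageError", "validate_config",
           "run_pipeline", "stage_seed", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the offending key."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name as a machine-readable
    code (``stage``) plus the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


# Defaults are the package's standard synthetic study conditions: the
# canonical tone protocol (25 freqs x 4 levels, 45-frame interval at ~30 Hz)
# over a scaled-down field sized for desk-scale runs.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "frame_rate": 30.0,
    "layer_label": "L1",
    "grid": {
        "f_min_hz": 1250.0,
        "f_max_hz": 80000.0,
        "step_octaves": 0.25,
        "level_min_db": 20.0,
        "level_max_db": 80.0,
        "level_step_db": 20.0,
    },
    "schedule": {"repeats": 3, "interval": 45, "n_blocks": 3},
    "scene": {
        "shape": [120, 120],
        "n_boutons": 25,
        "noise_floor": 4.0,
        "noise_gain": 0.05,
        "response_jitter_sd": 0.2,
        "drift_amplitude_px": 2.0,
        "baseline": 20.0,
    },
    "registration": {
        "enabled": True,
        "n_template_frames": 50,
        "upsample": 20,
        "per_block_template": False,
    },
    "roi": {
        "patch_size": 8,
        "stride": 4,
        "grow_threshold": 0.5,
        "erosion_size": 2,
        "merge_iou": 0.5,
        "n_training_patches": 300,
    },
    "signal": {
        "f0_percentile": 20.0,
        "highpass_hz": 0.03,
        "window_frames": 15,
        "per_block_f0": True,
    },
    "gate": {"alpha": 0.001},
    "output": {"write_movie": False},
}

_STAGES = ("simulate", "register", "detect", "extract", "tune", "stats")


@dataclass
class PipelineConfig:
    """Validated configuration; attribute access mirrors the YAML layout."""

    data: dict = dc_field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return self.data["seed"]


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def validate_config(raw: dict | None) -> PipelineConfig:
    """Fill defaults, reject unknown keys, enforce cross-field constraints."""
    cfg = _merge(DEFAULT_CONFIG, raw or {})
    g = cfg["grid"]
    if g["f_min_hz"] <= 0 or g["step_octaves"] <= 0:
        raise ConfigError("grid.f_min_hz and grid.step_octaves must be positive")
    if g["f_min_hz"] > g["f_max_hz"]:
        raise ConfigError("grid.f_min_hz exceeds grid.f_max_hz")
    s = cfg["schedule"]
    if s["repeats"] < 1 or s["interval"] < 1:
        raise ConfigError("schedule.repeats and schedule.interval must be >= 1")
    if cfg["signal"]["window_frames"] > s["interval"]:
        raise ConfigError(
            "signal.window_frames must not exceed schedule.interval "
            f"({cfg['signal']['window_frames']} > {s['interval']})"
        )
    if cfg["signal"]["highpass_hz"] >= cfg["frame_rate"] / 2:
        raise ConfigError("signal.highpass_hz must be below the Nyquist frequency")
    if not 0 < cfg["gate"]["alpha"] <= 1:
        raise ConfigError("gate.alpha must be in (0, 1]")
    return PipelineConfig(cfg)


from contextlib import contextmanager


@contextmanager
def _stage(name: str):
    """Re-raise any stage failure tagged with the stage name."""
    try:
        yield
    except (StageError, ConfigError):
        raise
    except Exception as exc:  # noqa: BLE001 - deliberate broad tag-and-rethrow
        raise StageError(name, exc) from exc


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed per-stage seed derivation from the single global seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig | dict | None = None,
                 out_dir: str | Path = "results/session",
                 skip_registration: bool = False) -> dict:
    """End-to-end synthetic session; returns the in-memory stage products.

    Writes grid/schedule JSON, ground-truth and result CSVs, the ROI label
    image (TIFF) and a manifest with a sha256 per output file.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    cfg = config.data
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.9g")
        written.append(p)

    with _stage("simulate"):
        log.info("stage simulate")
        g = cfg["grid"]
        grid = make_stimulus_grid(g["f_min_hz"], g["f_max_hz"], g["step_octaves"],
                                  g["level_min_db"], g["level_max_db"],
                                  g["level_step_db"])
        s = cfg["schedule"]
        schedule = make_schedule(grid, s["repeats"], s["interval"], s["n_blocks"],
                                 seed=stage_seed(cfg["seed"], "simulate"))
        sc = cfg["scene"]
        n_frames = schedule.span_frames + 15
        scene = make_scene(
            shape=tuple(sc["shape"]),
            n_boutons=sc["n_boutons"],
            baseline=sc["baseline"],
            noise_floor=sc["noise_floor"],
            noise_gain=sc["noise_gain"],
            response_jitter_sd=sc["response_jitter_sd"],
            drift_amplitude_px=sc["drift_amplitude_px"],
            n_frames=n_frames,
            on_grid=grid,
            level_gain=linear_level_gain(g["level_min_db"], g["level_max_db"]),
            seed=stage_seed(cfg["seed"], "simulate"),
        )
        movie, _ = render_movie(scene, grid, schedule,
                                seed=stage_seed(cfg["seed"], "simulate"),
                                frame_rate=cfg["frame_rate"])
        for name, writer in [("grid.json", lambda p: bio.write_grid(p, grid)),
                             ("schedule.json", lambda p: bio.write_schedule(p, schedule))]:
            writer(out / name)
            written.append(out / name)
        save_csv("ground_truth.csv", scene.to_frame())
        if cfg["output"]["write_movie"]:
            bio.write_movie(out / "movie.tif", movie)
            written.append(out / "movie.tif")
        log.info("simulated %d frames, %d boutons", movie.n_frames, scene.n_boutons)

    with _stage("register"):
        shifts = np.zeros((movie.n_frames, 2))
        if cfg["registration"]["enabled"] and not skip_registration:
            log.info("stage register")
            r = cfg["registration"]
            blocks = None
            if r["per_block_template"]:
                per = movie.n_frames // s["n_blocks"]
                blocks = [slice(i * per, (i + 1) * per if i < s["n_blocks"] - 1
                                else movie.n_frames)
                          for i in range(s["n_blocks"])]
            movie, shifts = register_stack(movie, r["n_template_frames"],
                                           r["upsample"], block_slices=blocks)
        save_csv("shifts.csv", shifts_to_frame(shifts))

    with _stage("detect"):
        log.info("stage detect")
        roi_cfg = RoiConfig(
            patch_size=cfg["roi"]["patch_size"], stride=cfg["roi"]["stride"],
            grow_threshold=cfg["roi"]["grow_threshold"],
            erosion_size=cfg["roi"]["erosion_size"], merge_iou=cfg["roi"]["merge_iou"],
        )
        patches, labels = make_training_patches(cfg["roi"]["n_training_patches"],
                                                roi_cfg.patch_size,
                                                seed=stage_seed(cfg["seed"], "detect"),
                                                smooth_sigma=roi_cfg.smooth_sigma)
        clf = train_bouton_classifier(patches, labels,
                                      seed=stage_seed(cfg["seed"], "detect"),
                                      config=roi_cfg)
        rois = detect_rois(movie.mean_image(), clf, roi_cfg,
                           pixel_size_um=scene.pixel_size_um)
        bio.write_label_image(out / "roi_labels.tif", rois.label_image())
        written.append(out / "roi_labels.tif")
        save_csv("roi_centroids.csv", rois.centroid_frame())
        log.info("detected %d ROIs", rois.n_rois)

    records = []
    table = None
    if rois.n_rois:
        with _stage("extract"):
            log.info("stage extract")
            sig = cfg["signal"]
            raw = extract_traces(movie, rois)
            block_frames = None
            if sig["per_block_f0"] and s["n_blocks"] > 1:
                per = movie.n_frames // s["n_blocks"]
                block_frames = [slice(i * per, (i + 1) * per if i < s["n_blocks"] - 1
                                      else movie.n_frames)
                                for i in range(s["n_blocks"])]
            dff = np.vstack([
                highpass(compute_dff(tr, sig["f0_percentile"], block_frames),
                         cfg["frame_rate"], sig["highpass_hz"])
                for tr in raw
            ])
            table = trial_responses(dff, schedule, sig["window_frames"])
            save_csv("responses.csv", table.to_frame())

        with _stage("tune"):
            log.info("stage tune")
            cents = rois.centroids_px() * scene.pixel_size_um
            records = analyze_rois(table, grid, centroids_um=cents,
                                   alpha=cfg["gate"]["alpha"])
    bouton_df = records_to_frame(records)
    bouton_df["layer"] = cfg["layer_label"]
    save_csv("boutons.csv", bouton_df)
    n_resp = int(bouton_df["responsive"].sum()) if len(bouton_df) else 0
    log.info("%d / %d ROIs responsive", n_resp, len(bouton_df))

    with _stage("stats"):
        log.info("stage stats")
        stats_report: dict = {"n_rois": int(rois.n_rois), "n_responsive": n_resp}
        resp = bouton_df[bouton_df["responsive"] & bouton_df["bf_oct"].notna()] \
            if len(bouton_df) else bouton_df
        if len(resp) >= 2:
            stats_report["co_tuning_oct"] = co_tuning(resp["bf_oct"].to_numpy())
            summary = summarize_region(0, cfg["layer_label"],
                                       resp["bf_oct"].to_numpy())
            stats_report["mean_bf_oct"] = summary.mean_bf_oct
            stats_report["median_bf_oct"] = summary.median_bf_oct
        if len(resp) >= 3 and np.ptp(resp["bf_oct"].to_numpy()) > 0:
            from .synth import BoutonPopulation

            pop = BoutonPopulation(resp["x_um"].to_numpy(), resp["y_um"].to_numpy(),
                                   resp["bf_oct"].to_numpy())
            axis = tonotopic_axis(pop)
            stats_report["tonotopic_axis_deg"] = axis.angle_deg
            stats_report["tonotopic_axis_r"] = axis.correlation
        bio.write_json(out / "region_stats.json", stats_report)
        written.append(out / "region_stats.json")

    manifest = {
        "seed": cfg["seed"],
        "parameters": cfg,
        "outputs": {p.name: bio.sha256_file(p) for p in written},
    }
    bio.write_json(out / "manifest.json", manifest)

    return {
        "grid": grid,
        "schedule": schedule,
        "scene": scene,
        "movie": movie,
        "shifts": shifts,
        "rois": rois,
        "responses": table,
        "records": records,
        "bouton_table": bouton_df,
        "stats": stats_report,
        "manifest": manifest,
    }
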