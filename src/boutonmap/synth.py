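"""Synthetic two-photon session generator with known ground truth.

Forward model of a tone-mapping imaging session: punctate boutons (Gaussian
intensity blobs) scattered over the field, each with Gaussian log-frequency
tuning; tone presentations drive calcium transients (difference-of-
exponentials kernel) that modulate each bouton's brightness; frames carry
signal-dependent Gaussian noise and an optional slow x-y drift.

Every downstream stage of the pipeline (registration, ROI detection, dF/F
extraction, tuning, population statistics) can therefore be scored against
the generative parameters rather than against manual annotation.

Units: positions in pixels internally (row = y, col = x); best frequencies on
the octave axis log2(f / 1 kHz); time in frames at ``frame_rate`` Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .stimuli import StimulusGrid, StimulusSchedule

__all__ = [
    "MovieStack",
    "GroundTruthScene",
    "BoutonPopulation",
    "tuning_response",
    "calcium_kernel",
    "linear_level_gain",
    "make_drift",
    "make_scene",
    "render_movie",
    "render_mean_image",
    "sample_bouton_population",
    "DEFAULT_PIXEL_SIZE_UM",
]

# 512 px spanning a ~90 um field
DEFAULT_PIXEL_SIZE_UM = 90.0 / 512.0


@dataclass
class MovieStack:
    """A T x H x W fluorescence movie with its frame rate (Hz)."""

    frames: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def mean_image(self) -> np.ndarray:
        return self.frames.mean(axis=0)


def tuning_response(
    true_bf_oct: float,
    sigma_oct: float,
    amplitude: float,
    freq_hz: float | np.ndarray,
    level_db: float | np.ndarray = None,
    level_gain: Callable[[np.ndarray], np.ndarray] | None = None,
):
    """Expected transient amplitude for a tone: Gaussian tuning on log2 frequency.

    ``amplitude * exp(-(log2(f/1kHz) - bf)^2 / (2 sigma^2)) * level_gain(level)``
    with ``level_gain`` monotone non-decreasing in [0, 1] (1 when omitted).
    """
    if sigma_oct <= 0:
        raise ValueError("sigma must be positive")
    x = np.log2(np.asarray(freq_hz, float) / 1000.0)
    resp = amplitude * np.exp(-((x - true_bf_oct) ** 2) / (2.0 * sigma_oct**2))
    if level_gain is not None and level_db is not None:
        resp = resp * level_gain(np.asarray(level_db, float))
    return resp


def linear_level_gain(level_min_db: float, level_max_db: float,
                      gain_min: float = 0.5) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone level gain: linear ramp from ``gain_min`` at the lowest level to 1."""
    span = max(level_max_db - level_min_db, 1e-12)

    def gain(level_db):
        frac = np.clip((np.asarray(level_db, float) - level_min_db) / span, 0.0, 1.0)
        return gain_min + (1.0 - gain_min) * frac

    return gain


def calcium_kernel(
    tau_rise_s: float = 0.07,
    tau_decay_s: float = 0.4,
    frame_rate: float = 30.0,
    duration_s: float = 2.0,
) -> np.ndarray:
    """Discrete calcium transient kernel, difference of exponentials, unit peak.

    ``k(t) = exp(-t/tau_d) - exp(-t/tau_r)`` sampled at the frame rate and
    normalized so the peak is 1; k(0) = 0 and k >= 0.  Defaults emulate a
    GCaMP6m-like transient that has essentially decayed by the next tone
    onset (45 frames = 1.5 s at 30 Hz).
    """
    if not (0 < tau_rise_s < tau_decay_s):
        raise ValueError("need 0 < tau_rise < tau_decay")
    t = np.arange(0.0, duration_s, 1.0 / frame_rate)
    k = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


@dataclass
class GroundTruthScene:
    """Generative bouton field: geometry, tuning, imaging noise and drift.

    ``centers_px`` rows are (row, col).  ``brightness`` is each bouton's
    static peak intensity above the baseline; tuning ``amplitude`` is the
    peak fractional modulation of that brightness (a dF/F-like quantity).
    Noise is Gaussian with variance ``noise_floor + noise_gain * signal``
    (Poisson-like mean-variance scaling).  ``drift_px`` (T x 2, row/col
    offset per frame) shifts every bouton center.
    """

    shape: tuple[int, int]
    centers_px: np.ndarray  # (n, 2) row, col
    radii_px: np.ndarray
    bf_oct: np.ndarray
    sigma_oct: np.ndarray
    amplitude: np.ndarray
    brightness: np.ndarray
    baseline: float = 20.0
    noise_floor: float = 0.0
    noise_gain: float = 0.0
    response_jitter_sd: float = 0.0  # multiplicative trial-to-trial variability
    drift_px: np.ndarray | None = None
    level_gain: Callable[[np.ndarray], np.ndarray] | None = None
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.centers_px = np.atleast_2d(np.asarray(self.centers_px, float))
        for name in ("radii_px", "bf_oct", "sigma_oct", "amplitude", "brightness"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        h, w = self.shape
        if np.any(self.centers_px[:, 0] < 0) or np.any(self.centers_px[:, 0] >= h) \
                or np.any(self.centers_px[:, 1] < 0) or np.any(self.centers_px[:, 1] >= w):
            raise ValueError("bouton centers must lie inside the field")
        if np.any(self.radii_px <= 0) or np.any(self.sigma_oct <= 0):
            raise ValueError("radii and tuning widths must be positive")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_boutons(self) -> int:
        return self.centers_px.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """One row per bouton, positions in px and um."""
        return pd.DataFrame(
            {
                "x_px": self.centers_px[:, 1],
                "y_px": self.centers_px[:, 0],
                "x_um": self.centers_px[:, 1] * self.pixel_size_um,
                "y_um": self.centers_px[:, 0] * self.pixel_size_um,
                "radius_px": self.radii_px,
                "bf_oct": self.bf_oct,
                "sigma_oct": self.sigma_oct,
                "amplitude": self.amplitude,
            }
        )


def make_drift(n_frames: int, amplitude_px: float = 3.0, smooth_frames: int = 300,
               seed: int = 0) -> np.ndarray:
    """Smoothed random-walk x-y drift, clipped to +/- ``amplitude_px``.

    A cumulative Gaussian walk per axis, boxcar-smoothed and rescaled so the
    maximum absolute excursion equals ``amplitude_px``; zero at frame 0.
    """
    if amplitude_px == 0:
        return np.zeros((n_frames, 2))
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.standard_normal((n_frames, 2)), axis=0)
    kernel = np.ones(smooth_frames) / smooth_frames
    for ax in range(2):
        walk[:, ax] = np.convolve(walk[:, ax], kernel, mode="same")
    walk -= walk[0]
    peak = np.abs(walk).max()
    if peak > 0:
        walk *= amplitude_px / peak
    return walk


def make_scene(
    shape: tuple[int, int] = (120, 120),
    n_boutons: int = 25,
    min_separation_px: float = 8.0,
    radius_range_px: tuple[float, float] = (1.5, 3.0),
    bf_range_oct: tuple[float, float] = (1.0, 5.5),
    sigma_range_oct: tuple[float, float] = (0.5, 1.2),
    amplitude_range: tuple[float, float] = (1.0, 2.5),
    brightness_range: tuple[float, float] = (30.0, 60.0),
    baseline: float = 20.0,
    noise_floor: float = 4.0,
    noise_gain: float = 0.05,
    response_jitter_sd: float = 0.2,
    drift_amplitude_px: float = 0.0,
    n_frames: int | None = None,
    on_grid: StimulusGrid | None = None,
    level_gain: Callable | None = None,
    seed: int = 0,
) -> GroundTruthScene:
    """Sample a random bouton scene with minimum center separation.

    ``on_grid`` snaps every true BF to the nearest interior grid frequency
    (used for exact-recovery checks).  ``n_frames`` must be given when a
    nonzero drift amplitude is requested.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 6.0
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_boutons and attempts < 20000:
        c = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(c - p)) >= min_separation_px for p in centers):
            centers.append(c)
        attempts += 1
    if len(centers) < n_boutons:
        raise ValueError("could not place boutons with requested separation")
    centers_arr = np.array(centers)
    bf = rng.uniform(*bf_range_oct, size=n_boutons)
    if on_grid is not None:
        grid_oct = np.log2(on_grid.frequencies_hz / 1000.0)
        interior = grid_oct[1:-1]  # keep peaks away from the grid edges
        bf = interior[np.argmin(np.abs(bf[:, None] - interior[None, :]), axis=1)]
    drift = None
    if drift_amplitude_px > 0:
        if n_frames is None:
            raise ValueError("n_frames required when drift is enabled")
        drift = make_drift(n_frames, drift_amplitude_px, seed=int(rng.integers(2**31)))
    return GroundTruthScene(
        shape=shape,
        centers_px=centers_arr,
        radii_px=rng.uniform(*radius_range_px, size=n_boutons),
        bf_oct=bf,
        sigma_oct=rng.uniform(*sigma_range_oct, size=n_boutons),
        amplitude=rng.uniform(*amplitude_range, size=n_boutons),
        brightness=rng.uniform(*brightness_range, size=n_boutons),
        baseline=baseline,
        noise_floor=noise_floor,
        noise_gain=noise_gain,
        response_jitter_sd=response_jitter_sd,
        drift_px=drift,
        level_gain=level_gain,
    )


def _blob_patch(center: np.ndarray, radius_px: float, shape: tuple[int, int]):
    """Isotropic Gaussian blob (sigma = radius/2, truncated at 3 sigma).

    Returns (row slice, col slice, patch) for adding into a frame; separable
    evaluation keeps rendering cheap.
    """
    sigma = radius_px / 2.0
    half = max(int(np.ceil(3.0 * sigma)), 1)
    r0 = int(np.floor(center[0])) - half
    c0 = int(np.floor(center[1])) - half
    r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, shape[0]), min(c1, shape[1])
    if rr0 >= rr1 or cc0 >= cc1:
        return None
    rows = np.arange(rr0, rr1) - center[0]
    cols = np.arange(cc0, cc1) - center[1]
    gr = np.exp(-(rows**2) / (2 * sigma**2))
    gc = np.exp(-(cols**2) / (2 * sigma**2))
    patch = np.outer(gr, gc)
    patch[patch < np.exp(-4.5)] = 0.0  # truncate at 3 sigma
    return slice(rr0, rr1), slice(cc0, cc1), patch


def bouton_traces(
    scene: GroundTruthScene,
    grid: StimulusGrid,
    schedule: StimulusSchedule,
    n_frames: int,
    kernel: np.ndarray | None = None,
    frame_rate: float = 30.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noise-free fractional modulation traces, shape (n_boutons, T).

    Per bouton: trial amplitudes from the Gaussian tuning model (optionally
    jittered trial-to-trial), laid down at schedule onsets and convolved with
    the calcium kernel.
    """
    if kernel is None:
        kernel = calcium_kernel(frame_rate=frame_rate)
    if rng is None:
        rng = np.random.default_rng(0)
    cond_freq = grid.condition_frequencies()
    cond_level = grid.condition_levels()
    traces = np.zeros((scene.n_boutons, n_frames))
    for b in range(scene.n_boutons):
        amps = tuning_response(
            scene.bf_oct[b], scene.sigma_oct[b], scene.amplitude[b],
            cond_freq[schedule.condition_ids], cond_level[schedule.condition_ids],
            scene.level_gain,
        )
        if scene.response_jitter_sd > 0:
            amps = amps * np.clip(
                1.0 + scene.response_jitter_sd * rng.standard_normal(amps.size), 0.0, None
            )
        impulses = np.zeros(n_frames)
        valid = schedule.onsets < n_frames
        np.add.at(impulses, schedule.onsets[valid], amps[valid])
        traces[b] = np.convolve(impulses, kernel)[:n_frames]
    return traces


def render_movie(
    scene: GroundTruthScene,
    grid: StimulusGrid,
    schedule: StimulusSchedule,
    seed: int = 0,
    frame_rate: float = 30.0,
    pad_frames: int = 15,
    kernel: np.ndarray | None = None,
    dtype=np.float32,
) -> tuple[MovieStack, np.ndarray]:
    """Render the full session movie; returns (movie, per-bouton traces).

    Frame t = baseline + sum_b brightness_b * blob_b(center + drift_t) *
    (1 + trace_b(t)), plus Gaussian noise with variance ``noise_floor +
    noise_gain * signal``.  Identical (scene, schedule, seed) yield
    bit-identical movies.
    """
    n_frames = schedule.span_frames + pad_frames
    if scene.drift_px is not None and len(scene.drift_px) < n_frames:
        raise ValueError("drift trajectory shorter than the movie")
    rng = np.random.default_rng(seed)
    traces = bouton_traces(scene, grid, schedule, n_frames, kernel=kernel,
                           frame_rate=frame_rate, rng=rng)
    h, w = scene.shape
    frames = np.empty((n_frames, h, w), dtype=dtype)
    drift = scene.drift_px
    static_drift = drift is None or np.allclose(drift, drift[0] if drift is not None else 0)
    if drift is not None and np.abs(drift).max() > min(h, w):
        warnings.warn("drift exceeds the field size; boutons may leave the frame")

    # With no drift the blob geometry is frame-independent: precompute patches.
    if static_drift:
        blobs = [_blob_patch(scene.centers_px[b], scene.radii_px[b], (h, w))
                 for b in range(scene.n_boutons)]
        for t in range(n_frames):
            frame = np.full((h, w), scene.baseline)
            for b, blob in enumerate(blobs):
                if blob is None:
                    continue
                rs, cs, patch = blob
                frame[rs, cs] += scene.brightness[b] * (1.0 + traces[b, t]) * patch
            frames[t] = frame
    else:
        for t in range(n_frames):
            frame = np.full((h, w), scene.baseline)
            off = drift[t]
            for b in range(scene.n_boutons):
                blob = _blob_patch(scene.centers_px[b] + off, scene.radii_px[b], (h, w))
                if blob is None:
                    continue
                rs, cs, patch = blob
                frame[rs, cs] += scene.brightness[b] * (1.0 + traces[b, t]) * patch
            frames[t] = frame

    if scene.noise_floor > 0 or scene.noise_gain > 0:
        # chunked so the noise temporaries stay small for long sessions
        for t0 in range(0, n_frames, 512):
            chunk = frames[t0:t0 + 512]
            sd = np.sqrt(scene.noise_floor + scene.noise_gain * np.clip(chunk, 0, None))
            chunk += (sd * rng.standard_normal(chunk.shape)).astype(dtype)
        np.clip(frames, 0, None, out=frames)
    return MovieStack(frames, frame_rate=frame_rate), traces


def render_mean_image(scene: GroundTruthScene, noise_sd: float = 0.0,
                      seed: int = 0) -> np.ndarray:
    """Static field image (no stimulus modulation) with optional Gaussian noise.

    Peak-brightness / noise_sd is the SNR used when scoring ROI detection.
    """
    h, w = scene.shape
    img = np.full((h, w), scene.baseline)
    for b in range(scene.n_boutons):
        blob = _blob_patch(scene.centers_px[b], scene.radii_px[b], (h, w))
        if blob is None:
            continue
        rs, cs, patch = blob
        img[rs, cs] += scene.brightness[b] * patch
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + noise_sd * rng.standard_normal(img.shape)
    return img


@dataclass
class BoutonPopulation:
    """Positions (um) and BFs (octaves) of a bouton sample, the unit of the
    population statistics.  ``region_id``/``layer``/``depth_um`` group boutons
    into imaged regions for region-level summaries."""

    x_um: np.ndarray
    y_um: np.ndarray
    bf_oct: np.ndarray
    depth_um: np.ndarray | None = None
    region_id: np.ndarray | None = None
    layer: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, float)
        self.y_um = np.asarray(self.y_um, float)
        self.bf_oct = np.asarray(self.bf_oct, float)

    @property
    def n(self) -> int:
        return self.x_um.size

    def to_frame(self) -> pd.DataFrame:
        d = {"x_um": self.x_um, "y_um": self.y_um, "bf_oct": self.bf_oct}
        if self.depth_um is not None:
            d["depth_um"] = self.depth_um
        if self.region_id is not None:
            d["region_id"] = self.region_id
        if self.layer is not None:
            d["layer"] = self.layer
        return pd.DataFrame(d)


def sample_bouton_population(
    n: int,
    extent_um: float,
    gradient_angle_deg: float,
    gradient_slope_oct_per_um: float,
    scatter_sd_oct: float,
    bf_range_oct: tuple[float, float] = (0.0, 6.5),
    base_bf_oct: float | None = None,
    seed: int = 0,
) -> BoutonPopulation:
    """Boutons uniform in a square field with a linear tonotopic gradient.

    BF = base + slope * (projection of position on the unit vector at
    ``gradient_angle_deg``) + N(0, scatter_sd), clipped to ``bf_range``.
    The projection is centered on the field midpoint so ``base`` is the
    field-center BF (default: midpoint of ``bf_range``).
    """
    if n < 1 or scatter_sd_oct < 0:
        raise ValueError("need n >= 1 and scatter_sd >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, extent_um, n)
    y = rng.uniform(0, extent_um, n)
    theta = np.deg2rad(gradient_angle_deg)
    proj = (x - extent_um / 2) * np.cos(theta) + (y - extent_um / 2) * np.sin(theta)
    if base_bf_oct is None:
        base_bf_oct = 0.5 * (bf_range_oct[0] + bf_range_oct[1])
    bf = base_bf_oct + gradient_slope_oct_per_um * proj
    if scatter_sd_oct > 0:
        bf = bf + scatter_sd_oct * rng.standard_normal(n)
    bf = np.clip(bf, *bf_range_oct)
    return BoutonPopulation(x_um=x, y_um=y, bf_oct=bf)
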