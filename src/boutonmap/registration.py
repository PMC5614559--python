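"""Rigid x-y motion correction by subpixel phase correlation.

Every frame is aligned to a template (the mean of the first 50 frames by
default) with Fourier-upsampled phase cross-correlation, then translated by
the negated estimated shift.  Only whole-frame rigid translation is
corrected; rotation, non-rigid warping and z-motion are out of scope.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .synth import MovieStack

__all__ = ["build_template", "estimate_shift", "register_stack", "shifts_to_frame"]

DEFAULT_TEMPLATE_FRAMES = 50
DEFAULT_UPSAMPLE = 20


def build_template(movie: MovieStack, n_frames: int = DEFAULT_TEMPLATE_FRAMES) -> np.ndarray:
    """Pixelwise mean of the first ``n_frames`` frames."""
    if movie.n_frames == 0:
        raise ValueError("empty movie")
    n = min(n_frames, movie.n_frames)
    if n < 1:
        raise ValueError("n_frames must be >= 1")
    return movie.frames[:n].astype(float).mean(axis=0)


def estimate_shift(image: np.ndarray, template: np.ndarray,
                   upsample: int = DEFAULT_UPSAMPLE) -> tuple[float, float]:
    """(dy, dx) displacement of ``image`` relative to ``template``.

    An image that is the template translated by (dy, dx) yields (dy, dx), so
    an injected drift trajectory is recovered with its own sign; applying the
    *negated* estimate re-aligns the image.  Subpixel resolution 1/upsample
    px via Fourier-upsampled phase correlation.  All-zero inputs are
    degenerate and return (0, 0) with a warning.
    """
    if image.shape != template.shape:
        raise ValueError("image and template shapes differ")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if not image.any() or not template.any():
        warnings.warn("degenerate (all-zero) image in shift estimation")
        return (0.0, 0.0)
    shift, _, _ = phase_cross_correlation(
        template, image, upsample_factor=upsample, normalization=None
    )
    # skimage returns the shift to apply to `image`; negate to report the
    # displacement itself
    return (-float(shift[0]), -float(shift[1]))


def register_stack(
    movie: MovieStack,
    n_template_frames: int = DEFAULT_TEMPLATE_FRAMES,
    upsample: int = DEFAULT_UPSAMPLE,
    block_slices: list[slice] | None = None,
    interpolation_order: int = 1,
) -> tuple[MovieStack, np.ndarray]:
    """Register every frame to the template; returns (registered, shifts T x 2).

    ``block_slices`` (frame ranges) optionally rebuilds the template at the
    start of each block, emulating between-block drift correction.  Frames
    are translated by spline interpolation with edge replication; frames with
    an exactly zero estimated shift are passed through untouched.
    """
    if movie.n_frames < 1:
        raise ValueError("empty movie")
    frames = movie.frames
    out = np.empty_like(frames)
    shifts = np.zeros((movie.n_frames, 2))
    ranges = block_slices or [slice(0, movie.n_frames)]
    for blk in ranges:
        tpl_src = MovieStack(frames[blk], frame_rate=movie.frame_rate)
        template = build_template(tpl_src, n_template_frames)
        for t in range(*blk.indices(movie.n_frames)):
            dy, dx = estimate_shift(frames[t].astype(float), template, upsample)
            shifts[t] = (dy, dx)
            if dy == 0.0 and dx == 0.0:
                out[t] = frames[t]
            else:
                out[t] = ndimage.shift(
                    frames[t].astype(float), (-dy, -dx),
                    order=interpolation_order, mode="nearest",
                ).astype(frames.dtype)
    return MovieStack(out, frame_rate=movie.frame_rate), shifts


def shifts_to_frame(shifts: np.ndarray) -> pd.DataFrame:
    """Shift series as a tidy table (frame, dy_px, dx_px) for CSV export."""
    return pd.DataFrame(
        {"frame": np.arange(len(shifts)), "dy_px": shifts[:, 0], "dx_px": shifts[:, 1]}
    )
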