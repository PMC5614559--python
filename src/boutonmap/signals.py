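"""dF/F extraction: ROI-averaged traces, baseline normalization, high-pass
filtering, and windowed single-trial responses.

The fluorescence of each ROI is the unweighted mean of its pixels per frame.
dF/F uses a low-percentile baseline (20th percentile per recording block by
default), is high-pass filtered at 0.03 Hz (zero-phase, 2nd-order
Butterworth) to remove slow drift, and single-trial responses are the mean
dF/F over the half-open response window [onset, onset + window) - 15 frames
(~500 ms at 30 Hz) for imaging, or the short post-onset window appropriate
to other modalities via the ``window`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .roi import ROISet
from .stimuli import StimulusSchedule
from .synth import MovieStack

__all__ = [
    "extract_trace",
    "extract_traces",
    "compute_dff",
    "highpass",
    "trial_responses",
    "TrialResponseTable",
    "DEFAULT_F0_PERCENTILE",
    "DEFAULT_HIGHPASS_HZ",
    "DEFAULT_RESPONSE_WINDOW",
]

DEFAULT_F0_PERCENTILE = 20.0
DEFAULT_HIGHPASS_HZ = 0.03
DEFAULT_RESPONSE_WINDOW = 15  # frames (~500 ms at 30 Hz)


def extract_trace(movie: MovieStack, mask: np.ndarray) -> np.ndarray:
    """Per-frame unweighted mean over the masked pixels."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    if mask.shape != movie.shape:
        raise ValueError("mask shape does not match the movie")
    return movie.frames[:, mask].mean(axis=1).astype(float)


def extract_traces(movie: MovieStack, rois: ROISet) -> np.ndarray:
    """All ROI traces, shape (n_rois, T)."""
    return np.array([extract_trace(movie, m) for m in rois.masks])


def compute_dff(
    raw: np.ndarray,
    baseline_percentile: float = DEFAULT_F0_PERCENTILE,
    block_slices: list[slice] | None = None,
) -> np.ndarray:
    """(F - F0) / F0 with F0 a low percentile of the raw trace.

    With ``block_slices`` the baseline is computed independently per
    recording block (the default pipeline behaviour), otherwise over the
    whole trace.  A non-positive F0 indicates a miscalibrated input and
    raises.
    """
    raw = np.asarray(raw, float)
    out = np.empty_like(raw)
    for blk in (block_slices or [slice(None)]):
        seg = raw[blk]
        f0 = np.percentile(seg, baseline_percentile)
        if f0 <= 0:
            raise ValueError(f"non-positive baseline F0={f0:g}")
        out[blk] = (seg - f0) / f0
    return out


def highpass(dff: np.ndarray, frame_rate: float,
             cutoff_hz: float = DEFAULT_HIGHPASS_HZ, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth high-pass; removes DC and slow fluctuations.

    Applied forward-backward (sosfiltfilt) so transient timing is preserved;
    gain ~1 well above the cutoff.
    """
    if cutoff_hz >= frame_rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=frame_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(dff, float), axis=-1)


class TrialResponseTable:
    """ROI x trial matrix of windowed mean dF/F plus the trial->condition map."""

    def __init__(self, responses: np.ndarray, condition_ids: np.ndarray, window: int):
        self.responses = np.atleast_2d(np.asarray(responses, float))
        self.condition_ids = np.asarray(condition_ids, int)
        self.window = int(window)
        if self.responses.shape[1] != self.condition_ids.size:
            raise ValueError("responses and condition ids disagree on trial count")

    @property
    def n_rois(self) -> int:
        return self.responses.shape[0]

    @property
    def n_trials(self) -> int:
        return self.responses.shape[1]

    def roi_responses(self, roi: int) -> np.ndarray:
        return self.responses[roi]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses,
                          columns=[f"trial_{t}" for t in range(self.n_trials)])
        df.insert(0, "roi", np.arange(self.n_rois))
        return df


def trial_responses(
    dff: np.ndarray,
    schedule: StimulusSchedule,
    window: int = DEFAULT_RESPONSE_WINDOW,
) -> TrialResponseTable:
    """Mean dF/F in [onset, onset + window) per ROI and trial.

    The onset frame is included; a trial whose window runs past the end of
    the trace raises with the offending trial ids.
    """
    dff = np.atleast_2d(np.asarray(dff, float))
    n_frames = dff.shape[1]
    bad = np.nonzero(schedule.onsets + window > n_frames)[0]
    if bad.size:
        raise ValueError(f"trials {bad.tolist()} exceed the trace (T={n_frames})")
    idx = schedule.onsets[:, None] + np.arange(window)[None, :]
    resp = dff[:, idx].mean(axis=2)
    return TrialResponseTable(resp, schedule.condition_ids, window)
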