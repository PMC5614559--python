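"""Per-bouton tuning: responsiveness gate, frequency response area (FRA),
best frequency (BF) and Gaussian tuning-curve fits.

A bouton enters the analysis only if its single-trial responses differ
significantly across the frequency-level conditions (one-way ANOVA,
p < 0.001; no correction across ROIs - the gate is per ROI).  The FRA is the
condition-mean response arranged levels x frequencies, smoothed across
frequency with a 3-point running average; BF is the frequency whose
level-averaged smoothed response is maximal.  Tuning quality is summarized
by a Gaussian fit (with offset) to the level-averaged curve on the
log2-frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stimuli import StimulusGrid

__all__ = [
    "hz_to_octaves",
    "octaves_to_hz",
    "FRA",
    "TuningFit",
    "BoutonRecord",
    "responsiveness_test",
    "build_fra",
    "smooth_fra",
    "best_frequency",
    "fit_gaussian_tuning",
    "analyze_rois",
    "records_to_frame",
    "RESPONSIVE_ALPHA",
]

RESPONSIVE_ALPHA = 0.001


def hz_to_octaves(freq_hz) -> np.ndarray | float:
    """Octaves re 1 kHz: log2(f / 1000)."""
    return np.log2(np.asarray(freq_hz, float) / 1000.0)


def octaves_to_hz(oct_re_1k) -> np.ndarray | float:
    return 1000.0 * 2.0 ** np.asarray(oct_re_1k, float)


@dataclass
class FRA:
    """Levels x frequencies matrix of condition-mean responses."""

    matrix: np.ndarray  # (n_levels, n_frequencies)
    grid: StimulusGrid
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (self.grid.n_levels, self.grid.n_frequencies):
            raise ValueError("FRA shape does not match the stimulus grid")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("FRA must be finite")

    def level_averaged(self) -> np.ndarray:
        """Mean over levels -> tuning curve across frequency."""
        return self.matrix.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.grid.levels_db,
                            columns=self.grid.frequencies_hz)


@dataclass
class TuningFit:
    """Gaussian fit offset + amp * exp(-(x - center)^2 / (2 sigma^2))."""

    center_oct: float
    sigma_oct: float
    amplitude: float
    offset: float
    r_squared: float
    converged: bool = True


@dataclass
class BoutonRecord:
    """Per-bouton result row: position, gate outcome, BF, tuning fit."""

    roi: int
    x_um: float
    y_um: float
    p_value: float
    responsive: bool
    bf_oct: float | None = None
    fit: TuningFit | None = None
    depth_um: float | None = None
    layer: str | None = None
    region_id: int | None = None


def responsiveness_test(
    responses: np.ndarray,
    condition_ids: np.ndarray,
    alpha: float = RESPONSIVE_ALPHA,
) -> tuple[float, bool]:
    """One-way fixed-effects ANOVA across condition groups.

    Returns (p, p < alpha).  Degenerate inputs (zero variance everywhere,
    equal means) give p = 1; zero within-group variance with unequal means
    gives p = 0 (infinite F).
    """
    responses = np.asarray(responses, float)
    condition_ids = np.asarray(condition_ids, int)
    groups = [responses[condition_ids == c] for c in np.unique(condition_ids)]
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    means = np.array([g.mean() for g in groups])
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within == 0:
        p = 1.0 if np.allclose(means, means[0]) else 0.0
        return p, p < alpha
    with np.errstate(invalid="ignore"):
        _, p = stats.f_oneway(*groups)
    if np.isnan(p):
        p = 1.0
    return float(p), bool(p < alpha)


def responsiveness_test_batch(
    responses: np.ndarray, condition_ids: np.ndarray, alpha: float = RESPONSIVE_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gate over many ROIs at once (rows of ``responses``).

    Groups must be balanced (equal repeats per condition), which holds for
    the interleaved schedule.  Used for Monte-Carlo calibration at scale.
    """
    responses = np.atleast_2d(np.asarray(responses, float))
    condition_ids = np.asarray(condition_ids, int)
    conds = np.unique(condition_ids)
    counts = np.array([(condition_ids == c).sum() for c in conds])
    if not np.all(counts == counts[0]):
        raise ValueError("batch gate requires balanced conditions")
    # stack per-condition groups: (n_rois, n_conditions, repeats)
    grouped = np.stack([responses[:, condition_ids == c] for c in conds], axis=1)
    _, p = stats.f_oneway(*np.moveaxis(grouped, 1, 0), axis=-1)
    p = np.nan_to_num(p, nan=1.0)
    return p, p < alpha


def build_fra(responses: np.ndarray, condition_ids: np.ndarray,
              grid: StimulusGrid) -> FRA:
    """Condition-mean responses arranged (levels rows) x (frequencies cols)."""
    responses = np.asarray(responses, float)
    condition_ids = np.asarray(condition_ids, int)
    mat = np.full((grid.n_levels, grid.n_frequencies), np.nan)
    for cond in range(grid.n_conditions):
        sel = condition_ids == cond
        if not sel.any():
            raise ValueError(f"condition {cond} has no trials")
        li, fi = divmod(cond, grid.n_frequencies)
        mat[li, fi] = responses[sel].mean()
    return FRA(mat, grid, smoothed=False)


def smooth_fra(fra: FRA) -> FRA:
    """3-point running average across frequency within each level row.

    Edge columns average the two available points; levels are never mixed.
    """
    m = fra.matrix
    out = np.empty_like(m)
    kernel = np.ones(3)
    counts = np.convolve(np.ones(m.shape[1]), kernel, mode="same")
    for i in range(m.shape[0]):
        out[i] = np.convolve(m[i], kernel, mode="same") / counts
    return FRA(out, fra.grid, smoothed=True)


def best_frequency(fra: FRA, grid: StimulusGrid | None = None) -> float | None:
    """BF in octaves re 1 kHz: argmax of the level-averaged (smoothed) curve.

    Ties break to the lowest frequency; a perfectly flat curve has no
    defined BF and returns None.
    """
    grid = grid or fra.grid
    curve = fra.level_averaged()
    if np.allclose(curve, curve[0]):
        return None
    idx = int(np.argmax(curve))  # np.argmax returns the first (lowest-frequency) max
    return float(hz_to_octaves(grid.frequencies_hz[idx]))


def fit_gaussian_tuning(curve: np.ndarray, grid: StimulusGrid) -> TuningFit:
    """Least-squares Gaussian (with offset) on response vs log2 frequency.

    Center constrained to the grid span +/- 1 octave, sigma to [0.1, 6]
    octaves.  A flat curve or non-convergence returns a flagged fit with
    R^2 = nan.
    """
    curve = np.asarray(curve, float)
    x = hz_to_octaves(grid.frequencies_hz)
    if curve.size < 4:
        raise ValueError("need at least 4 frequency points")
    span = (x.min() - 1.0, x.max() + 1.0)
    rng_amp = curve.max() - curve.min()
    if rng_amp <= 0 or not np.isfinite(rng_amp):
        return TuningFit(float(x[int(np.argmax(curve))]), 1.0, 0.0,
                         float(curve.mean()), np.nan, converged=False)

    def model(xx, center, sigma, amp, offset):
        return offset + amp * np.exp(-((xx - center) ** 2) / (2 * sigma**2))

    p0 = (float(x[int(np.argmax(curve))]), 1.0, float(rng_amp), float(curve.min()))
    bounds = ([span[0], 0.1, 0.0, -np.inf], [span[1], 6.0, np.inf, np.inf])
    try:
        popt, _ = optimize.curve_fit(model, x, curve, p0=p0, bounds=bounds,
                                     maxfev=10000)
    except (RuntimeError, ValueError):
        return TuningFit(p0[0], 1.0, 0.0, float(curve.mean()), np.nan, converged=False)
    resid = curve - model(x, *popt)
    ss_res = float((resid**2).sum())
    ss_tot = float(((curve - curve.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return TuningFit(float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]),
                     r2, converged=True)


def analyze_rois(
    table,
    grid: StimulusGrid,
    centroids_um: np.ndarray | None = None,
    alpha: float = RESPONSIVE_ALPHA,
    fit: bool = True,
) -> list[BoutonRecord]:
    """Gate + FRA + BF (+ Gaussian fit) for every ROI of a response table."""
    records: list[BoutonRecord] = []
    for roi in range(table.n_rois):
        resp = table.roi_responses(roi)
        p, responsive = responsiveness_test(resp, table.condition_ids, alpha)
        x_um = y_um = np.nan
        if centroids_um is not None:
            y_um, x_um = centroids_um[roi]
        rec = BoutonRecord(roi=roi, x_um=float(x_um), y_um=float(y_um),
                           p_value=p, responsive=responsive)
        if responsive:
            fra = smooth_fra(build_fra(resp, table.condition_ids, grid))
            rec.bf_oct = best_frequency(fra)
            if fit and rec.bf_oct is not None:
                rec.fit = fit_gaussian_tuning(fra.level_averaged(), grid)
        records.append(rec)
    return records


def records_to_frame(records: list[BoutonRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "roi": r.roi,
                "x_um": r.x_um,
                "y_um": r.y_um,
                "p_value": r.p_value,
                "responsive": r.responsive,
                "bf_oct": np.nan if r.bf_oct is None else r.bf_oct,
                "fit_center_oct": np.nan if r.fit is None else r.fit.center_oct,
                "fit_sigma_oct": np.nan if r.fit is None else r.fit.sigma_oct,
                "fit_r2": np.nan if r.fit is None else r.fit.r_squared,
                "depth_um": np.nan if r.depth_um is None else r.depth_um,
                "layer": "" if r.layer is None else r.layer,
                "region_id": -1 if r.region_id is None else r.region_id,
            }
        )
    return pd.DataFrame(rows)
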