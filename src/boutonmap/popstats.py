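"""Population-level tonotopy statistics.

Operations over collections of (position, BF) records: co-tuning (SD of a
region's BF distribution), pairwise distance vs |dBF| rank correlation,
median-normalized BF distributions averaged across regions, the 360-degree
axis sweep locating the tonotopic gradient, paired layer comparisons with
effect sizes, mean-BF matching of regions across layers, and the depth vs
co-tuning relation.

All BFs are in octaves re 1 kHz and positions in um; distances are in-plane
(x, y) Euclidean separations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .synth import BoutonPopulation

__all__ = [
    "RegionSummary",
    "AxisEstimate",
    "PairedComparison",
    "co_tuning",
    "delta_bf",
    "distance_tuning_relation",
    "normalized_bf_distribution",
    "tonotopic_axis",
    "compare_paired",
    "effect_size_r",
    "region_bf_matching",
    "depth_cotuning_relation",
    "summarize_region",
]


@dataclass
class RegionSummary:
    """One imaged region's BF statistics."""

    region_id: int
    layer: str
    n: int
    co_tuning_oct: float | None
    mean_bf_oct: float
    median_bf_oct: float
    depth_um: float = np.nan


@dataclass
class AxisEstimate:
    """Tonotopic-axis sweep result: best angle plus the full profile."""

    angle_deg: float
    correlation: float
    angles_deg: np.ndarray = field(repr=False)
    profile: np.ndarray = field(repr=False)


@dataclass
class PairedComparison:
    """Paired two-sample result with Rosenthal effect size r = z / sqrt(N)."""

    test: str
    p_value: float
    z: float
    effect_size_r: float
    n_pairs: int
    shapiro_p: float
    statistic: float


def co_tuning(bfs_oct: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of a BF distribution."""
    bfs = np.asarray(bfs_oct, float)
    if bfs.size < 2:
        raise ValueError("co-tuning needs at least two boutons")
    return float(np.std(bfs, ddof=1))


def delta_bf(bf1_oct: float, bf2_oct: float) -> float:
    """|BF1 - BF2| in octaves."""
    return float(abs(bf1_oct - bf2_oct))


def distance_tuning_relation(
    pop: BoutonPopulation,
    exclude_equal_bf: bool = False,
    bin_width_um: float = 10.0,
) -> dict:
    """Pairwise topographic distance vs |dBF| over all unordered pairs.

    Returns the pair table, the Spearman rank correlation with its p-value,
    and distance-binned mean |dBF| for plotting.  ``exclude_equal_bf``
    removes exactly the pairs with dBF = 0 (e.g. same-axon duplicates).
    """
    if pop.n < 2:
        raise ValueError("need at least two boutons")
    xy = np.column_stack([pop.x_um, pop.y_um])
    dist = pdist(xy)
    dbf = pdist(pop.bf_oct[:, None], metric="cityblock")
    if exclude_equal_bf:
        keep = dbf > 0
        dist, dbf = dist[keep], dbf[keep]
    if dist.size < 2:
        raise ValueError("fewer than two usable pairs")
    rho, p = stats.spearmanr(dist, dbf)
    bins = np.arange(0, dist.max() + bin_width_um, bin_width_um)
    which = np.digitize(dist, bins) - 1
    binned = pd.DataFrame({
        "bin_left_um": bins[:-1],
        "mean_dbf_oct": [dbf[which == i].mean() if (which == i).any() else np.nan
                         for i in range(len(bins) - 1)],
        "n_pairs": [(which == i).sum() for i in range(len(bins) - 1)],
    })
    pairs = pd.DataFrame({"distance_um": dist, "dbf_oct": dbf})
    return {"pairs": pairs, "R": float(rho), "p": float(p),
            "n_pairs": int(dist.size), "binned": binned}


def normalized_bf_distribution(
    regions: list[np.ndarray],
    bin_width_oct: float = 0.25,
    span_oct: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average of per-region median-centered BF histograms.

    Each region's BFs are shifted so its median is zero, histogrammed as a
    fraction of the region's boutons on a common grid, and the histograms
    are averaged with equal region weight.  Returns (bin edges, averaged
    fractions).
    """
    edges = np.arange(-span_oct, span_oct + bin_width_oct, bin_width_oct)
    hists = []
    for bfs in regions:
        bfs = np.asarray(bfs, float)
        if bfs.size < 1:
            raise ValueError("empty region")
        centered = bfs - np.median(bfs)
        h, _ = np.histogram(centered, bins=edges)
        hists.append(h / bfs.size)
    return edges, np.mean(hists, axis=0)


def tonotopic_axis(pop: BoutonPopulation, step_deg: float = 1.0) -> AxisEstimate:
    """Sweep axes through 360 degrees; the gradient direction is the axis
    with the strongest *positive* Pearson correlation between BF and the
    scalar projection of position onto the axis.

    The profile is antisymmetric under a 180-degree flip, so the estimate is
    unique; ties break to the smallest angle.
    """
    if pop.n < 3:
        raise ValueError("need at least three boutons")
    bf = pop.bf_oct - pop.bf_oct.mean()
    if np.allclose(bf, 0):
        raise ValueError("zero BF variance")
    x = pop.x_um - pop.x_um.mean()
    y = pop.y_um - pop.y_um.mean()
    angles = np.arange(0.0, 360.0, step_deg)
    theta = np.deg2rad(angles)
    # proj[i, k] = x_k cos t_i + y_k sin t_i, centered by construction
    proj = np.cos(theta)[:, None] * x[None, :] + np.sin(theta)[:, None] * y[None, :]
    num = proj @ bf
    denom = np.sqrt((proj**2).sum(axis=1) * (bf**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    best = int(np.argmax(corr))  # first max = smallest angle on ties
    return AxisEstimate(float(angles[best]), float(corr[best]), angles, corr)


def effect_size_r(z: float, n: int) -> float:
    """Rosenthal's r = z / sqrt(N)."""
    return float(z / np.sqrt(n))


def compare_paired(
    group_a: np.ndarray,
    group_b: np.ndarray,
    method: str = "auto",
    normality_alpha: float = 0.05,
    effect_n: str = "pairs",
) -> PairedComparison:
    """Two-sided paired comparison with a normality-gated test choice.

    ``method='auto'`` runs Shapiro-Wilk on the pairwise differences and uses
    the Wilcoxon signed-rank test when normality is rejected (p < 0.05), a
    paired t-test otherwise; 'wilcoxon' / 'ttest' force the branch.  The
    signed-rank p-value is exact for small samples without ties.  Effect
    size r = z / sqrt(N) with N = number of pairs by default
    (``effect_n='observations'`` uses 2 * pairs); z is the normal
    approximation of the signed-rank statistic, while the t branch uses the
    bounded r = sqrt(t^2 / (t^2 + df)) and defines z = r sqrt(N) for
    consistency.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need equal-length groups with at least 5 pairs")
    diffs = a - b
    n = a.size
    n_eff = n if effect_n == "pairs" else 2 * n
    if np.allclose(diffs, 0):
        return PairedComparison("wilcoxon", 1.0, 0.0, 0.0, n, 1.0, 0.0)
    if np.ptp(diffs) == 0:  # constant nonzero differences: Shapiro undefined
        shapiro_p = 0.0
    else:
        shapiro_p = float(stats.shapiro(diffs).pvalue)
    if method == "auto":
        method = "wilcoxon" if shapiro_p < normality_alpha else "ttest"
    direction = float(np.sign(np.median(diffs)) or np.sign(diffs.mean()))
    if method == "wilcoxon":
        res = stats.wilcoxon(a, b, alternative="two-sided")
        p = float(res.pvalue)
        stat = float(res.statistic)  # min(W+, W-); zeros dropped
        n_nz = int(np.count_nonzero(diffs))
        mu = n_nz * (n_nz + 1) / 4.0
        sigma = np.sqrt(n_nz * (n_nz + 1) * (2 * n_nz + 1) / 24.0)
        z = direction * abs(stat - mu) / sigma if sigma > 0 else 0.0
        r = effect_size_r(z, n_eff)
    elif method == "ttest":
        res = stats.ttest_rel(a, b)
        p = float(res.pvalue)
        stat = float(res.statistic)
        df = n - 1
        # r = sqrt(t^2 / (t^2 + df)) is bounded in [-1, 1]; z is defined so
        # that r = z / sqrt(N) stays self-consistent
        r = float(np.sign(stat) * np.sqrt(stat**2 / (stat**2 + df)))
        z = r * np.sqrt(n_eff)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairedComparison(method, p, float(z), float(r), n, shapiro_p, stat)


def region_bf_matching(mean_bf_a: np.ndarray, mean_bf_b: np.ndarray
                       ) -> tuple[float, float, int]:
    """Pearson correlation of paired region mean BFs (e.g. L1 vs L3b/4)."""
    a = np.asarray(mean_bf_a, float)
    b = np.asarray(mean_bf_b, float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired regions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in region mean BFs")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), int(a.size)


def depth_cotuning_relation(depths_um: np.ndarray, cotunings_oct: np.ndarray
                            ) -> tuple[float, float]:
    """Spearman rank correlation of imaging depth vs region co-tuning."""
    d = np.asarray(depths_um, float)
    c = np.asarray(cotunings_oct, float)
    if d.size != c.size or d.size < 3:
        raise ValueError("need >= 3 regions")
    if np.ptp(c) == 0 or np.ptp(d) == 0:
        raise ValueError("rank correlation undefined for a constant input")
    rho, p = stats.spearmanr(d, c)
    return float(rho), float(p)


def summarize_region(region_id: int, layer: str, bfs_oct: np.ndarray,
                     depth_um: float = np.nan) -> RegionSummary:
    bfs = np.asarray(bfs_oct, float)
    return RegionSummary(
        region_id=region_id,
        layer=layer,
        n=int(bfs.size),
        co_tuning_oct=co_tuning(bfs) if bfs.size >= 2 else None,
        mean_bf_oct=float(bfs.mean()),
        median_bf_oct=float(np.median(bfs)),
        depth_um=depth_um,
    )
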