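"""Automatic bouton ROI extraction from a registered mean image.

The chain mirrors classical patch-based bouton segmentation: the field is
parcellated into overlapping 8x8 px patches; each patch is described by
histogram-of-oriented-gradients (HOG) features and classified bouton /
no-bouton by a linear support vector machine; for positive patches a
circular Hough transform locates the bouton and the brightest pixel inside
the detected circle seeds a region-growing step; grown masks are eroded to
separate touching boutons and recombined across patches into a single ROI
set.

Patches are min-max normalized before HOG and all growing thresholds are
relative to local intensity, so detection is invariant to a global gain.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import canny, hog
from skimage.morphology import erosion, footprint_rectangle
from skimage.transform import hough_circle, hough_circle_peaks
from sklearn.svm import LinearSVC

__all__ = [
    "PatchSet",
    "ROISet",
    "BoutonClassifier",
    "RoiConfig",
    "parcellate",
    "hog_features",
    "train_bouton_classifier",
    "make_training_patches",
    "find_seed",
    "region_grow",
    "erode_mask",
    "detect_rois",
    "match_rois",
]


@dataclass(frozen=True)
class PatchSet:
    """Overlapping square patches cut from one image.

    ``positions`` holds 0-based (row, col) top-left corners, row-major;
    ``patches`` is (n, patch_size, patch_size) and reconstructs exactly from
    the source image at those positions.
    """

    positions: np.ndarray
    patches: np.ndarray
    patch_size: int
    stride: int
    image_shape: tuple[int, int]


@dataclass
class ROISet:
    """Final bouton masks over the full field plus centroids."""

    masks: list[np.ndarray]
    image_shape: tuple[int, int]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        for m in self.masks:
            if not m.any():
                raise ValueError("empty ROI mask")

    @property
    def n_rois(self) -> int:
        return len(self.masks)

    def centroids_px(self) -> np.ndarray:
        """(n, 2) array of (row, col) mask centroids."""
        out = np.zeros((len(self.masks), 2))
        for i, m in enumerate(self.masks):
            rr, cc = np.nonzero(m)
            out[i] = (rr.mean(), cc.mean())
        return out

    def label_image(self) -> np.ndarray:
        """0 = background, k = ROI k (1-based); later ROIs win overlaps."""
        lab = np.zeros(self.image_shape, dtype=np.int32)
        for i, m in enumerate(self.masks, start=1):
            lab[m] = i
        return lab

    def centroid_frame(self) -> pd.DataFrame:
        c = self.centroids_px()
        return pd.DataFrame(
            {
                "roi": np.arange(len(self.masks)),
                "y_px": c[:, 0],
                "x_px": c[:, 1],
                "y_um": c[:, 0] * self.pixel_size_um,
                "x_um": c[:, 1] * self.pixel_size_um,
                "n_pixels": [int(m.sum()) for m in self.masks],
            }
        )


@dataclass
class RoiConfig:
    """Tunables of the detection chain (defaults sized for ~0.18 um/px).

    ``smooth_sigma`` is a light Gaussian pre-smoothing of the mean image
    (applied identically to the training patches);``contrast_sd`` gates both
    patches and final masks on brightness relative to the image's robust
    noise scale (median + k * 1.4826 * MAD), which keeps the chain invariant
    to a global intensity gain while HOG alone is intensity-blind.
    """

    patch_size: int = 8
    stride: int = 4
    hog_orientations: int = 9
    hog_cell_px: int = 4
    hough_radii: tuple[int, int] = (1, 4)
    smooth_sigma: float = 0.8
    contrast_sd: float = 5.0
    grow_threshold: float = 0.5  # fraction of (seed - background)
    grow_margin: int | None = None  # growth window margin; default patch_size // 2
    erosion_size: int = 2
    merge_iou: float = 0.5
    containment: float = 0.8  # overlap/min-area merge rule for clipped fragments
    min_pixels: int = 2
    max_pixels: int = 40  # a grown region larger than any plausible bouton is leakage
    svm_c: float = 1.0


@dataclass
class BoutonClassifier:
    """Linear SVM over per-patch HOG features, with its feature config."""

    svm: LinearSVC
    config: RoiConfig
    seed: int

    def predict(self, patches: np.ndarray) -> np.ndarray:
        feats = np.array([hog_features(p, self.config) for p in patches])
        return self.svm.predict(feats).astype(bool)


def parcellate(image: np.ndarray, patch_size: int = 8, stride: int = 4) -> PatchSet:
    """Cut the image into overlapping patches on a regular stride lattice.

    Top-left corners at {0, stride, 2*stride, ...} along both axes; only
    fully-inside patches are kept, so a HxW image yields
    (floor((H-p)/s)+1) * (floor((W-p)/s)+1) patches.
    """
    h, w = image.shape
    if patch_size > min(h, w):
        raise ValueError("patch larger than image")
    if not (1 <= stride <= patch_size):
        raise ValueError("stride must be in [1, patch_size]")
    rows = np.arange(0, h - patch_size + 1, stride)
    cols = np.arange(0, w - patch_size + 1, stride)
    positions = np.array([(r, c) for r in rows for c in cols], dtype=int).reshape(-1, 2)
    patches = np.stack([image[r:r + patch_size, c:c + patch_size] for r, c in positions])
    return PatchSet(positions, patches, patch_size, stride, (h, w))


def _normalize_patch(patch: np.ndarray) -> np.ndarray:
    p = patch.astype(float)
    lo, hi = p.min(), p.max()
    if hi - lo < 1e-12:
        return np.zeros_like(p)
    return (p - lo) / (hi - lo)


def hog_features(patch: np.ndarray, config: RoiConfig | None = None) -> np.ndarray:
    """HOG descriptor of one (min-max normalized) patch.

    Default layout: 2x2 cells of 4x4 px, 9 unsigned orientation bins, L2
    block normalization -> 36 features for an 8x8 patch.  A constant patch
    has zero gradients and maps to the all-zero vector.
    """
    cfg = config or RoiConfig()
    p = _normalize_patch(np.asarray(patch))
    cells = p.shape[0] // cfg.hog_cell_px
    return hog(
        p,
        orientations=cfg.hog_orientations,
        pixels_per_cell=(cfg.hog_cell_px, cfg.hog_cell_px),
        cells_per_block=(cells, cells),
        block_norm="L2",
        feature_vector=True,
    )


def make_training_patches(
    n_per_class: int = 300,
    patch_size: int = 8,
    seed: int = 0,
    noise_sd: float = 0.15,
    smooth_sigma: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Programmatic training set: bouton-like blob patches vs background.

    Positives: an isotropic Gaussian blob (sigma 0.7-1.6 px) centered within
    the central half of the patch, on a noisy background.  Negatives: noise
    alone, or a faint axon-like line (shaft without a bouton).  Patches are
    pre-smoothed with ``smooth_sigma`` to match the detection chain's
    treatment of the mean image.  Returns (patches, labels); the fixture is
    linearly separable in HOG space at the default noise level.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    patches, labels = [], []
    yy, xx = np.mgrid[0:patch_size, 0:patch_size]
    center_lo, center_hi = patch_size * 0.3, patch_size * 0.7
    for _ in range(n_per_class):
        cy, cx = rng.uniform(center_lo, center_hi, 2)
        sigma = rng.uniform(0.7, 1.6)
        amp = rng.uniform(0.8, 1.5)
        blob = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        patches.append(blob + noise_sd * rng.standard_normal((patch_size, patch_size)))
        labels.append(1)
    for i in range(n_per_class):
        bg = noise_sd * rng.standard_normal((patch_size, patch_size))
        if i % 2:  # axon-like faint line
            theta = rng.uniform(0, np.pi)
            d = np.abs((yy - patch_size / 2) * np.cos(theta)
                       - (xx - patch_size / 2) * np.sin(theta))
            bg = bg + rng.uniform(0.1, 0.3) * np.exp(-(d**2) / (2 * 0.8**2))
        patches.append(bg)
        labels.append(0)
    arr = np.array(patches)
    if smooth_sigma > 0:
        arr = np.array([gaussian_filter(p, smooth_sigma) for p in arr])
    return arr, np.array(labels, dtype=int)


def train_bouton_classifier(
    patches: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    config: RoiConfig | None = None,
) -> BoutonClassifier:
    """Fit the linear SVM on HOG features of labeled patches."""
    cfg = config or RoiConfig()
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    feats = np.array([hog_features(p, cfg) for p in patches])
    svm = LinearSVC(C=cfg.svm_c, loss="hinge", random_state=seed, max_iter=20000)
    svm.fit(feats, labels)
    return BoutonClassifier(svm=svm, config=cfg, seed=seed)


def find_seed(patch: np.ndarray, radii: tuple[int, int] = (1, 4)) -> tuple[int, int]:
    """Seed pixel for region growing: brightest pixel inside the strongest
    Hough circle; falls back to the patch-global argmax when no circle is
    found (degenerate or edge-free patches).
    """
    p = _normalize_patch(np.asarray(patch))
    flat_argmax = np.unravel_index(int(np.argmax(patch)), patch.shape)
    if not p.any():
        return (int(flat_argmax[0]), int(flat_argmax[1]))
    try:
        edges = canny(p, sigma=1.0)
        if edges.any():
            radius_set = np.arange(radii[0], radii[1] + 1)
            h = hough_circle(edges, radius_set)
            _, cx, cy, rad = hough_circle_peaks(h, radius_set, num_peaks=1,
                                                total_num_peaks=1)
            if len(cx):
                yy, xx = np.mgrid[0:patch.shape[0], 0:patch.shape[1]]
                inside = (yy - cy[0]) ** 2 + (xx - cx[0]) ** 2 <= rad[0] ** 2
                if inside.any():
                    masked = np.where(inside, patch, -np.inf)
                    r, c = np.unravel_index(int(np.argmax(masked)), patch.shape)
                    return (int(r), int(c))
    except Exception:  # degenerate geometry: fall through to global argmax
        pass
    return (int(flat_argmax[0]), int(flat_argmax[1]))


def region_grow(
    patch: np.ndarray,
    seed: tuple[int, int],
    inclusion_threshold: float = 0.5,
    background: float | None = None,
) -> np.ndarray:
    """Flood fill from the seed: a pixel joins if it is 8-connected to the
    region and its intensity is at least ``background + threshold * (seed -
    background)``.  Background defaults to the patch median.
    """
    p = np.asarray(patch, float)
    h, w = p.shape
    sr, sc = int(seed[0]), int(seed[1])
    if not (0 <= sr < h and 0 <= sc < w):
        raise ValueError("seed outside patch")
    if background is None:
        background = float(np.median(p))
    cut = background + inclusion_threshold * (p[sr, sc] - background)
    mask = np.zeros((h, w), dtype=bool)
    mask[sr, sc] = True
    queue = deque([(sr, sc)])
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and p[rr, cc] >= cut:
                    mask[rr, cc] = True
                    queue.append((rr, cc))
    return mask


def erode_mask(mask: np.ndarray, selem_size: int = 2) -> np.ndarray:
    """Binary erosion by a square structuring element (may return empty)."""
    if selem_size <= 1:
        return mask.astype(bool)
    return erosion(mask.astype(bool), footprint_rectangle((selem_size, selem_size)))


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    return inter / np.logical_or(a, b).sum()


def _merge_masks(masks: list[np.ndarray], iou_thr: float, containment: float) -> list[np.ndarray]:
    """Union-find merge: masks join when IoU > iou_thr or when the overlap
    covers > ``containment`` of the smaller mask (clipped duplicates)."""
    n = len(masks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sizes = [m.sum() for m in masks]
    for i in range(n):
        for j in range(i + 1, n):
            inter = np.logical_and(masks[i], masks[j]).sum()
            if inter == 0:
                continue
            union = sizes[i] + sizes[j] - inter
            if inter / union > iou_thr or inter / min(sizes[i], sizes[j]) > containment:
                parent[find(i)] = find(j)
    groups: dict[int, np.ndarray] = {}
    for i in range(n):
        root = find(i)
        groups[root] = masks[i] if root not in groups else (groups[root] | masks[i])
    merged = list(groups.values())
    return merged if len(merged) == n else _merge_masks(merged, iou_thr, containment)


def _connected(mask: np.ndarray) -> bool:
    from scipy import ndimage as ndi
    _, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    return n == 1


def _largest_component(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage as ndi
    lab, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask
    sizes = ndi.sum(mask, lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def detect_rois(
    mean_image: np.ndarray,
    classifier: BoutonClassifier,
    config: RoiConfig | None = None,
    pixel_size_um: float = 1.0,
) -> ROISet:
    """Full detection chain on a registered mean image.

    smooth -> parcellate -> HOG/SVM classify (plus a brightness gate at
    ``contrast_sd`` robust SDs over the image median) -> Hough seed ->
    region grow (within a window expanded beyond the patch so masks are not
    clipped at patch borders) -> erode -> recombine with duplicate merging.
    A mask is dropped if erosion leaves it below ``min_pixels``, if it
    exceeds ``max_pixels`` (region leakage) or if it contains no pixel above
    the brightness gate.
    """
    from scipy.ndimage import gaussian_filter

    cfg = config or classifier.config
    h, w = mean_image.shape
    image = gaussian_filter(np.asarray(mean_image, float), cfg.smooth_sigma) \
        if cfg.smooth_sigma > 0 else np.asarray(mean_image, float)
    pset = parcellate(image, cfg.patch_size, cfg.stride)
    positive = classifier.predict(pset.patches)
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med))) * 1.4826
    bright_cut = med + cfg.contrast_sd * mad
    positive &= pset.patches.max(axis=(1, 2)) > bright_cut
    if not positive.any():
        warnings.warn("no patches classified as containing boutons")
        return ROISet([], (h, w), pixel_size_um)
    margin = cfg.grow_margin if cfg.grow_margin is not None else cfg.patch_size // 2
    masks: list[np.ndarray] = []
    for idx in np.nonzero(positive)[0]:
        r0, c0 = pset.positions[idx]
        seed_r, seed_c = find_seed(pset.patches[idx], cfg.hough_radii)
        # re-seed and grow in a window expanded by `margin` around the patch
        wr0, wc0 = max(r0 - margin, 0), max(c0 - margin, 0)
        wr1 = min(r0 + cfg.patch_size + margin, h)
        wc1 = min(c0 + cfg.patch_size + margin, w)
        window = image[wr0:wr1, wc0:wc1]
        local_seed = (r0 - wr0 + seed_r, c0 - wc0 + seed_c)
        grown = region_grow(window, local_seed, cfg.grow_threshold)
        grown = _largest_component(grown)
        eroded = erode_mask(grown, cfg.erosion_size)
        eroded = _largest_component(eroded)
        if not cfg.min_pixels <= eroded.sum() <= cfg.max_pixels:
            continue
        if window[eroded].max() < bright_cut:
            continue
        full = np.zeros((h, w), dtype=bool)
        full[wr0:wr1, wc0:wc1] = eroded
        masks.append(full)
    if not masks:
        warnings.warn("no ROI survived growing/erosion")
        return ROISet([], (h, w), pixel_size_um)
    merged = _merge_masks(masks, cfg.merge_iou, cfg.containment)
    final = []
    for m in merged:
        m = _largest_component(m)
        if m.sum() >= cfg.min_pixels:
            final.append(m)
    return ROISet(final, (h, w), pixel_size_um)


def match_rois(
    roiset: ROISet, true_centers_px: np.ndarray, tolerance_px: float = 2.0
) -> tuple[np.ndarray, float, float]:
    """Greedy one-to-one match of ROI centroids to ground-truth centers.

    Returns (assignment of each ROI to a truth index or -1, precision,
    recall); a match requires centroid-to-center distance <= tolerance.
    """
    true_centers_px = np.atleast_2d(true_centers_px)
    cents = roiset.centroids_px()
    n_roi, n_true = len(cents), len(true_centers_px)
    assignment = np.full(n_roi, -1, dtype=int)
    if n_roi == 0 or n_true == 0:
        return assignment, 0.0, 0.0
    d = np.linalg.norm(cents[:, None, :] - true_centers_px[None, :, :], axis=2)
    pairs = [(d[i, j], i, j) for i in range(n_roi) for j in range(n_true)
             if d[i, j] <= tolerance_px]
    used_roi: set[int] = set()
    used_true: set[int] = set()
    for _, i, j in sorted(pairs):
        if i not in used_roi and j not in used_true:
            assignment[i] = j
            used_roi.add(i)
            used_true.add(j)
    n_match = len(used_true)
    return assignment, n_match / n_roi, n_match / n_true
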