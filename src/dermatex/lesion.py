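"""Lesion-area extraction: marker-controlled watershed over-segmentation,
k-means region merging, morphological cleanup, and the pixel-area
statistic.

Most lesions of the three target diseases are roughly circular, so the
image is first shattered into small watershed basins (markers = gradient
minima deeper than an h-minima threshold, which curbs the classic watershed
over-segmentation), the basins are then grouped into four clusters —
background, normal skin, lesion, and mis-segmented — on their mean color,
intensity and size, and finally the lesion mask is smoothed by a
morphological opening-then-closing before its pixel area is counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import sobel
from skimage.morphology import disk, h_minima, opening, closing
from skimage.segmentation import watershed

ROLES = ("background", "normal_skin", "lesion", "mis_segmented")


@dataclass(frozen=True)
class RegionPartition:
    """Watershed basins: labels 1..W covering every pixel, with per-region
    mean color, mean intensity and size."""

    label_map: np.ndarray  # int array, labels 1..W
    W: int
    mean_color: np.ndarray  # (W, 3)
    mean_intensity: np.ndarray  # (W,)
    size_px: np.ndarray  # (W,)


@dataclass(frozen=True)
class ClusterAssignment:
    cluster_of_region: np.ndarray  # (W,) cluster index 0..k-1
    cluster_roles: dict  # cluster index -> role string


@dataclass(frozen=True)
class LesionSegmentation:
    lesion_mask: np.ndarray
    lesion_area_px: int
    area_fraction: float


@dataclass(frozen=True)
class LesionConfig:
    marker_threshold: float = 0.3  # h-minima depth on the 0..255 gradient
    smoothing_sigma: float = 1.5
    k: int = 4
    color_space: str = "chroma"  # or "rgb"
    se_radius: int = 3
    min_lesion_color_dist: float = 20.0  # 0..255 scale; below it: no lesion
    seed: int = 0


def watershed_partition(img: np.ndarray, marker_threshold: float = 0.3,
                        smoothing_sigma: float = 1.5) -> RegionPartition:
    """Flood the smoothed gradient magnitude from its deep minima.

    Markers are the regional minima that survive h-minima suppression at
    depth ``marker_threshold``; a constant image collapses to one region
    with a warning.
    """
    if img.ndim == 3:
        gray = rgb2gray(img) * 255.0
        color = img.astype(float)
    else:
        gray = img.astype(float)
        color = np.stack([gray] * 3, axis=-1)
    smooth = ndimage.gaussian_filter(gray, smoothing_sigma)
    grad = sobel(smooth)

    if np.ptp(grad) <= 1e-12:
        warnings.warn("constant image: single watershed region", stacklevel=2)
        labels = np.ones(gray.shape, dtype=np.int32)
    else:
        minima = h_minima(grad, marker_threshold)
        markers, n = ndimage.label(minima)
        if n < 2:
            # threshold deeper than every basin: fall back to plain minima
            markers, n = ndimage.label(h_minima(grad, 1e-6))
        if n < 1:
            warnings.warn("no gradient minima found: single region", stacklevel=2)
            labels = np.ones(gray.shape, dtype=np.int32)
        else:
            labels = watershed(grad, markers)

    ids = np.arange(1, labels.max() + 1)
    mean_color = np.stack(
        [ndimage.mean(color[..., c], labels, index=ids) for c in range(3)],
        axis=-1)
    mean_intensity = ndimage.mean(gray, labels, index=ids)
    size_px = ndimage.sum_labels(np.ones_like(gray), labels, index=ids)
    return RegionPartition(label_map=labels, W=int(labels.max()),
                           mean_color=np.asarray(mean_color, dtype=float),
                           mean_intensity=np.asarray(mean_intensity, dtype=float),
                           size_px=np.asarray(size_px, dtype=float))


def _chroma(colors: np.ndarray) -> np.ndarray:
    """Opponent chromaticity (R-G, G-B) of RGB colors, 0..255 units.

    Erythema and scale shift a lesion's chromatic balance away from skin
    while intensity texture leaves it untouched, so these two channels
    isolate the diagnostic color signal from brightness variation.
    """
    colors = np.atleast_2d(colors)
    return np.column_stack([colors[:, 0] - colors[:, 1],
                            colors[:, 1] - colors[:, 2]])


def _region_features(part: RegionPartition, color_space: str) -> np.ndarray:
    """Per-region clustering features: color, intensity, and log size, all
    on commensurate scales."""
    if color_space == "chroma":
        colf = np.column_stack([2.0 * _chroma(part.mean_color) / 255.0,
                                part.mean_color[:, [0]] / 255.0])
    elif color_space == "rgb":
        colf = np.clip(part.mean_color / 255.0, 0.0, 1.0)
    else:
        raise ValueError(f"unknown color_space {color_space!r}")
    inten = part.mean_intensity[:, None] / 255.0
    size = np.log1p(part.size_px[:, None]) / np.log1p(part.label_map.size)
    return np.column_stack([colf, inten, 0.3 * size])


def _kmeans(X: np.ndarray, k: int, seed: int, max_iter: int = 300
            ) -> np.ndarray:
    """Lloyd's algorithm with deterministic farthest-point seeding; iterates
    until the centers stop moving."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    centers = [X[int(rng.integers(n))]]
    for _ in range(1, k):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(-1),
            axis=1)
        centers.append(X[int(np.argmax(d2))])
    centers = np.asarray(centers)
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        assign = np.argmin(d2, axis=1)
        new_centers = centers.copy()
        for c in range(k):
            if np.any(assign == c):
                new_centers[c] = X[assign == c].mean(axis=0)
        if np.allclose(new_centers, centers):
            break
        centers = new_centers
    return assign


def cluster_regions(part: RegionPartition, k: int = 4,
                    color_space: str = "chroma", seed: int = 0,
                    min_lesion_color_dist: float = 20.0) -> ClusterAssignment:
    """Group watershed basins into background / normal skin / lesion /
    mis-segmented clusters.

    Roles: the darkest border-touching cluster is background; among the
    rest, the cluster whose size-weighted median color sits farthest from
    the overall skin color is the lesion — unless that distance falls below
    ``min_lesion_color_dist`` (no lesion present); the cluster nearest the
    skin color is normal skin; anything left is mis-segmented.
    """
    if part.W < k:
        warnings.warn(f"only {part.W} regions; reducing k from {k}",
                      stacklevel=2)
        k = max(1, part.W)
    X = _region_features(part, color_space)
    assign = _kmeans(X, k, seed)

    # which clusters touch the image border (candidate backgrounds)
    border = np.zeros(part.label_map.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = np.unique(part.label_map[border])
    border_clusters = set(assign[border_labels - 1])

    cluster_int = np.array([
        part.mean_intensity[assign == c].mean() if np.any(assign == c) else np.inf
        for c in range(k)])
    bg_candidates = [c for c in range(k) if c in border_clusters] or list(range(k))
    background = min(bg_candidates, key=lambda c: cluster_int[c])

    # skin chromaticity = size-weighted median over non-background regions
    fg_regions = np.flatnonzero(assign != background)
    roles = {background: "background"}
    if fg_regions.size == 0:
        return ClusterAssignment(cluster_of_region=assign, cluster_roles=roles)
    chroma = _chroma(part.mean_color)
    weights = part.size_px[fg_regions]
    skin_chroma = np.array([
        _weighted_median(chroma[fg_regions, c], weights) for c in range(2)])

    fg_clusters = [c for c in range(k) if c != background and np.any(assign == c)]
    dists = {}
    for c in fg_clusters:
        rows = np.flatnonzero(assign == c)
        med = np.array([
            _weighted_median(chroma[rows, ch], part.size_px[rows])
            for ch in range(2)])
        dists[c] = float(np.linalg.norm(med - skin_chroma))
    lesion = max(dists, key=dists.get) if dists else None
    if lesion is not None and dists[lesion] >= min_lesion_color_dist:
        roles[lesion] = "lesion"
    else:
        lesion = None
    normal_candidates = [c for c in fg_clusters if c not in roles]
    if normal_candidates:
        normal = min(normal_candidates, key=lambda c: dists[c])
        roles[normal] = "normal_skin"
    for c in range(k):
        roles.setdefault(c, "mis_segmented")
    return ClusterAssignment(cluster_of_region=assign, cluster_roles=roles)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cw, cw[-1] / 2.0)])


def morphological_cleanup(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Closing then opening with a disk: fills pinholes smaller than the
    element, then removes comparable specks; idempotent.

    Closing runs first — the reverse order erodes around every pinhole
    before it can be filled, eating real lesion area.
    """
    se = disk(radius)
    return opening(closing(np.asarray(mask, bool), se), se)


def pixel_area(mask: np.ndarray) -> tuple[int, float]:
    """Lesion pixel count and its fraction of the whole frame."""
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    return area, area / mask.size


def segment_lesion(img: np.ndarray, cfg: LesionConfig = LesionConfig()
                   ) -> LesionSegmentation:
    """End-to-end lesion quantification: watershed, clustering, role
    assignment (mis-segmented regions rejoin lesion or skin by color),
    morphological cleanup, area statistics."""
    part = watershed_partition(img, cfg.marker_threshold, cfg.smoothing_sigma)
    assign = cluster_regions(part, k=cfg.k, color_space=cfg.color_space,
                             seed=cfg.seed,
                             min_lesion_color_dist=cfg.min_lesion_color_dist)
    role_of = assign.cluster_roles
    lesion_clusters = {c for c, r in role_of.items() if r == "lesion"}
    if not lesion_clusters:
        empty = np.zeros(img.shape[:2], dtype=bool)
        return LesionSegmentation(lesion_mask=empty, lesion_area_px=0,
                                  area_fraction=0.0)

    # mis-segmented regions rejoin lesion or normal skin by chroma distance
    chroma = _chroma(part.mean_color)
    lesion_rows = np.flatnonzero(np.isin(assign.cluster_of_region,
                                         list(lesion_clusters)))
    w_les = part.size_px[lesion_rows]
    lesion_chroma = (chroma[lesion_rows] * w_les[:, None]).sum(0) / w_les.sum()
    normal_clusters = {c for c, r in role_of.items() if r == "normal_skin"}
    normal_rows = np.flatnonzero(np.isin(assign.cluster_of_region,
                                         list(normal_clusters)))
    if normal_rows.size:
        w_nor = part.size_px[normal_rows]
        normal_chroma = (chroma[normal_rows] * w_nor[:, None]).sum(0) / w_nor.sum()
    else:
        normal_chroma = lesion_chroma + 1e6

    region_is_lesion = np.zeros(part.W, dtype=bool)
    for r in range(part.W):
        role = role_of[assign.cluster_of_region[r]]
        if role == "lesion":
            region_is_lesion[r] = True
        elif role == "mis_segmented":
            d_les = np.linalg.norm(chroma[r] - lesion_chroma)
            d_nor = np.linalg.norm(chroma[r] - normal_chroma)
            region_is_lesion[r] = d_les < d_nor

    mask = region_is_lesion[part.label_map - 1]
    # regions fully enclosed by lesion are mistakenly-cut interior zones
    mask = ndimage.binary_fill_holes(mask)
    mask = morphological_cleanup(mask, radius=cfg.se_radius)
    area, frac = pixel_area(mask)
    return LesionSegmentation(lesion_mask=mask, lesion_area_px=area,
                              area_fraction=frac)
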