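"""Image preprocessing: denoise, rotate to horizontal, and cut the
epithelium into ten vertical regions along its medial axis.

The chain is: median filter (salt-and-pepper removal) -> Otsu binarization
-> principal-axis orientation estimate -> rotation to the horizontal ->
Euclidean distance transform -> per-column ridge extraction (the medial
axis) -> partition of the foreground into ten spans of equal axis
arclength, split by perpendiculars to the local axis direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import medfilt
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class RotationParams:
    """Geometry of one rotation: angle, the two centers the coordinate
    relation pivots about, and the enlarged canvas size."""

    theta_deg: float
    center_src: tuple[float, float]  # (row, col) of the source image
    center_dst: tuple[float, float]
    new_size: tuple[int, int]  # (height, width)


@dataclass(frozen=True)
class MedialAxis:
    """Per-column ridge of the distance transform inside the foreground's
    bounding rectangle; ``points`` are (row, col), sorted by column."""

    points: np.ndarray  # (n, 2) int array
    bounding_box: tuple[int, int, int, int]  # (top, left, bottom, right) incl.


@dataclass(frozen=True)
class VerticalSegments:
    """Exactly ten disjoint boolean masks L1..L10 over the rotated image."""

    regions: list  # list of 10 bool arrays

    def __post_init__(self):
        if len(self.regions) != 10:
            raise ValueError(f"expected 10 regions, got {len(self.regions)}")


def to_gray(img: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) image to single-channel luminance (uint8)."""
    if img.ndim == 2:
        return img
    w = np.array([0.299, 0.587, 0.114])
    return np.clip(img.astype(float) @ w, 0, 255).astype(np.uint8)


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with edge replication at the borders.

    Each output pixel is the middle element of its sorted window
    neighborhood — the standard impulse-noise remover that preserves edges.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if img.ndim == 3:
        return np.stack(
            [ndimage.median_filter(img[..., c], size=window, mode="nearest")
             for c in range(img.shape[2])], axis=-1)
    return ndimage.median_filter(img, size=window, mode="nearest")


def rotated_canvas_size(width: int, height: int, theta_deg: float
                        ) -> tuple[int, int]:
    """Tight bounding-box dimensions of a w×h rectangle rotated by theta:
    (w|cosθ| + h|sinθ|, h|cosθ| + w|sinθ|), rounded up."""
    th = math.radians(theta_deg)
    c, s = abs(math.cos(th)), abs(math.sin(th))
    w_new = int(math.ceil(width * c + height * s - 1e-9))
    h_new = int(math.ceil(height * c + width * s - 1e-9))
    return w_new, h_new


def rotate_image(img: np.ndarray, theta_deg: float
                 ) -> tuple[np.ndarray, RotationParams]:
    """Rotate by ``theta_deg`` (counterclockwise in pixel coordinates) onto
    an enlarged canvas, nearest-neighbor sampled; uncovered pixels are 0.

    Each destination pixel maps back to the source through the rotation
    about the two image centers, so right-angle rotations are exact
    bijections on pixels.
    """
    h, w = img.shape[:2]
    w_new, h_new = rotated_canvas_size(w, h, theta_deg)
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    cy_src, cx_src = (h - 1) / 2.0, (w - 1) / 2.0
    cy_dst, cx_dst = (h_new - 1) / 2.0, (w_new - 1) / 2.0

    rows, cols = np.mgrid[0:h_new, 0:w_new].astype(float)
    dx = cols - cx_dst
    dy = rows - cy_dst
    # inverse map: rotate destination offsets by -theta back into the source
    x0 = cx_src + dx * c + dy * s
    y0 = cy_src - dx * s + dy * c
    xi = np.rint(x0).astype(int)
    yi = np.rint(y0).astype(int)
    inside = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)

    out_shape = (h_new, w_new) + img.shape[2:]
    out = np.zeros(out_shape, dtype=img.dtype)
    out[inside] = img[yi[inside], xi[inside]]
    params = RotationParams(theta_deg=theta_deg,
                            center_src=(cy_src, cx_src),
                            center_dst=(cy_dst, cx_dst),
                            new_size=(h_new, w_new))
    return out, params


def estimate_orientation(mask: np.ndarray) -> float:
    """Angle (degrees, in (-90, 90]) of the foreground's principal axis from
    second-order central moments; rotating the image by the negated angle
    makes the long axis horizontal."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot estimate orientation of an empty mask")
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    return math.degrees(theta)


def binarize(img: np.ndarray) -> np.ndarray:
    """Global Otsu threshold; bright pixels become foreground.

    A constant image yields an all-background mask with a warning rather
    than an error, since flat frames occur in degenerate inputs.
    """
    gray = to_gray(img)
    if gray.size == 0:
        raise ValueError("cannot binarize an empty image")
    if gray.max() == gray.min():
        warnings.warn("constant image: binarization returns empty foreground",
                      stacklevel=2)
        return np.zeros_like(gray, dtype=bool)
    t = threshold_otsu(gray)
    return gray > t


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component, with its
    interior holes filled.

    Dark lesion texture can dip below the global threshold and punch holes
    in the epithelium mask; the distance-transform ridge needs a solid
    foreground, so enclosed holes are closed here.
    """
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def euclidean_distance_transform(mask: np.ndarray) -> np.ndarray:
    """Per-pixel shortest Euclidean distance from each foreground pixel to
    the background set; exactly 0 on background pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("distance transform undefined: mask has no background")
    return ndimage.distance_transform_edt(mask)


def extract_medial_axis(dist: np.ndarray, mask: np.ndarray) -> MedialAxis:
    """Ridge of the distance transform, one point per occupied column.

    Within the foreground's bounding rectangle, each column contributes the
    row of maximal distance (ties broken toward the top); the row sequence
    is then smoothed with a 1-D median of window 5.  Requires at least 10
    occupied columns so ten vertical segments can be supported.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot extract a medial axis from an empty mask")
    top, bottom = int(ys.min()), int(ys.max())
    left, right = int(xs.min()), int(xs.max())
    cols = [c for c in range(left, right + 1) if mask[:, c].any()]
    if len(cols) < 10:
        raise ValueError(
            f"foreground spans only {len(cols)} columns; at least 10 required")
    rows = []
    for c in cols:
        col_dist = np.where(mask[:, c], dist[:, c], -np.inf)
        rows.append(int(np.argmax(col_dist)))  # argmax keeps the uppermost tie
    smooth = medfilt(np.asarray(rows, dtype=float), kernel_size=5)
    points = np.column_stack([np.rint(smooth).astype(int),
                              np.asarray(cols, dtype=int)])
    return MedialAxis(points=points, bounding_box=(top, left, bottom, right))


def split_ten_segments(axis: MedialAxis, mask: np.ndarray) -> VerticalSegments:
    """Partition the foreground into ten spans of equal axis arclength.

    Each foreground pixel inside the bounding rectangle is projected onto
    the axis (nearest axis point); the arclength position of that projection
    selects the span.  A projection landing exactly on a division point goes
    to the lower-indexed span.
    """
    pts = axis.points.astype(float)
    if pts.shape[0] < 10:
        raise ValueError("axis too short: need at least 10 points")
    seglen = np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1))
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("axis has zero length")

    top, left, bottom, right = axis.bounding_box
    mask = np.asarray(mask, dtype=bool)
    box = np.zeros_like(mask)
    box[top:bottom + 1, left:right + 1] = True
    ys, xs = np.nonzero(mask & box)

    # nearest axis point per pixel, chunked to bound memory
    idx = np.empty(ys.size, dtype=int)
    coords = np.column_stack([ys, xs]).astype(float)
    for start in range(0, coords.shape[0], 8192):
        chunk = coords[start:start + 8192]
        d2 = ((chunk[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        idx[start:start + 8192] = np.argmin(d2, axis=1)

    s = arclen[idx]
    span = np.clip(np.floor(s * 10.0 / total - 1e-9), 0, 9).astype(int)

    regions = []
    for k in range(10):
        r = np.zeros_like(mask)
        sel = span == k
        r[ys[sel], xs[sel]] = True
        regions.append(r)
    return VerticalSegments(regions=regions)


@dataclass(frozen=True)
class PreprocessResult:
    """Everything the downstream feature extractors need from one image."""

    filtered: np.ndarray          # median-filtered input (same shape as input)
    theta_deg: float              # estimated long-axis orientation
    rotated_gray: np.ndarray      # rotated to horizontal
    rotated_color: np.ndarray | None
    mask: np.ndarray              # foreground of the rotated image
    distance: np.ndarray
    axis: MedialAxis
    segments: VerticalSegments


def preprocess_image(img: np.ndarray, window: int = 3) -> PreprocessResult:
    """Run the full preprocessing chain on a color or grayscale image."""
    filtered = median_filter(img, window=window)
    gray = to_gray(filtered)
    raw_mask = largest_component(binarize(gray))
    theta = estimate_orientation(raw_mask)
    rotated_gray, _ = rotate_image(gray, -theta)
    rotated_color = None
    if filtered.ndim == 3:
        rotated_color, _ = rotate_image(filtered, -theta)
    mask = largest_component(binarize(rotated_gray))
    dist = euclidean_distance_transform(mask)
    axis = extract_medial_axis(dist, mask)
    segments = split_ten_segments(axis, mask)
    return PreprocessResult(filtered=filtered, theta_deg=theta,
                            rotated_gray=rotated_gray,
                            rotated_color=rotated_color, mask=mask,
                            distance=dist, axis=axis, segments=segments)
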