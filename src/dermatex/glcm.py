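"""Gray-level co-occurrence matrices and the five texture statistics used
to characterize lesion texture: contrast, correlation, entropy, uniformity
(inverse difference moment) and energy.

The co-occurrence table G(i, j) counts ordered pixel pairs (p, p+offset)
after uniform quantization of [0, 255] into L bins; offsets default to the
four unit displacements at 0/45/90/135 degrees accumulated into a single
symmetric, probability-normalized matrix, which removes orientation
sensitivity in the usual Haralick fashion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 64
    offsets: tuple = DEFAULT_OFFSETS
    symmetric: bool = True
    normalize: bool = True
    log_base: float = 2.0  # entropy log base; 2 or e

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        for off in self.offsets:
            if off[0] == 0 and off[1] == 0:
                raise ValueError("offsets must be nonzero")


@dataclass(frozen=True)
class GLCMatrix:
    table: np.ndarray  # (L, L) non-negative
    config: GLCMConfig
    total_pairs: int


@dataclass(frozen=True)
class TextureFeatures:
    """The five scalar texture statistics."""

    contrast: float
    correlation: float
    entropy: float
    uniformity: float
    energy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.contrast, self.correlation, self.entropy,
                         self.uniformity, self.energy])


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniform binning of [0, 255] into ``levels`` bins."""
    return (img.astype(np.int64) * levels) // 256


def compute_glcm(img: np.ndarray, region: np.ndarray | None = None,
                 cfg: GLCMConfig = GLCMConfig()) -> GLCMatrix:
    """Accumulate the co-occurrence table over all configured offsets.

    ``region`` (optional boolean mask) restricts counting to pairs whose
    both endpoints lie inside the region.
    """
    if img.size == 0:
        raise ValueError("cannot compute a GLCM of an empty image")
    if img.ndim != 2:
        raise ValueError("compute_glcm expects a single-channel image")
    L = cfg.levels
    q = quantize(img, L)
    h, w = q.shape
    table = np.zeros((L, L), dtype=np.float64)
    for dr, dc in cfg.offsets:
        r0 = slice(max(0, -dr), min(h, h - dr))
        c0 = slice(max(0, -dc), min(w, w - dc))
        r1 = slice(max(0, dr), min(h, h + dr))
        c1 = slice(max(0, dc), min(w, w + dc))
        a = q[r0, c0]
        b = q[r1, c1]
        if region is not None:
            valid = region[r0, c0] & region[r1, c1]
            a, b = a[valid], b[valid]
        np.add.at(table, (a.ravel(), b.ravel()), 1.0)
    total = int(table.sum())
    if total == 0:
        raise ValueError("region yields no valid pixel pairs")
    if cfg.symmetric:
        table = table + table.T
    if cfg.normalize:
        table = table / table.sum()
    return GLCMatrix(table=table, config=cfg, total_pairs=total)


def contrast(g: GLCMatrix) -> float:
    """Sum of (i-j)^2 G(i,j): depth of the texture grooves."""
    L = g.table.shape[0]
    i, j = np.ogrid[0:L, 0:L]
    return float(((i - j) ** 2 * g.table).sum())


def correlation(g: GLCMatrix) -> float:
    """Linear dependence of paired gray levels; in [-1, 1] when defined.

    Returns 0 with a warning when a marginal standard deviation vanishes
    (constant texture), which legitimately happens on flat skin.
    """
    t = g.table / g.table.sum()
    L = t.shape[0]
    levels = np.arange(L, dtype=float)
    px = t.sum(axis=1)
    py = t.sum(axis=0)
    mx = float(levels @ px)
    my = float(levels @ py)
    sx = float(np.sqrt(((levels - mx) ** 2) @ px))
    sy = float(np.sqrt(((levels - my) ** 2) @ py))
    if sx <= 1e-12 or sy <= 1e-12:
        warnings.warn("degenerate GLCM marginals: correlation set to 0",
                      stacklevel=2)
        return 0.0
    i, j = np.ogrid[0:L, 0:L]
    cov = float((((i - mx) * (j - my)) * t).sum())
    return cov / (sx * sy)


def entropy(g: GLCMatrix) -> float:
    """-sum G log G with the 0*log0 := 0 convention; zero means no texture."""
    t = g.table
    nz = t[t > 0]
    if g.config.log_base == 2.0:
        return float(-(nz * np.log2(nz)).sum())
    return float(-(nz * np.log(nz)).sum() / np.log(g.config.log_base))


def uniformity(g: GLCMatrix) -> float:
    """Inverse difference moment: sum G(i,j) / ((i-j)^2 + 1)."""
    L = g.table.shape[0]
    i, j = np.ogrid[0:L, 0:L]
    return float((g.table / ((i - j) ** 2 + 1.0)).sum())


def energy(g: GLCMatrix, raw_counts: bool = False) -> float:
    """Sum of squared table entries.

    With ``raw_counts`` the square sum is taken over unnormalized pair
    counts, which yields large magnitudes on smooth textures; the default
    operates on the table as configured (normalized by default).
    """
    t = g.table
    if raw_counts and g.config.normalize:
        t = t * g.total_pairs * (2 if g.config.symmetric else 1)
    return float((t ** 2).sum())


def texture_features(g: GLCMatrix) -> TextureFeatures:
    return TextureFeatures(contrast=contrast(g), correlation=correlation(g),
                           entropy=entropy(g), uniformity=uniformity(g),
                           energy=energy(g))


def features_for_segments(img: np.ndarray, segments, cfg: GLCMConfig = GLCMConfig()
                          ) -> list[TextureFeatures]:
    """One TextureFeatures record per vertical region L1..L10.

    A region too small to form any pixel pair falls back to the whole-image
    features, with a warning.
    """
    out = []
    whole = None
    for k, region in enumerate(segments.regions):
        try:
            g = compute_glcm(img, region=region, cfg=cfg)
            out.append(texture_features(g))
        except ValueError:
            warnings.warn(
                f"region {k + 1} has no valid pixel pairs; "
                "using whole-image features", stacklevel=2)
            if whole is None:
                whole = texture_features(compute_glcm(img, cfg=cfg))
            out.append(whole)
    return out
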