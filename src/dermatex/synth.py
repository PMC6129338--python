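"""Synthetic skin-image generator.

Produces labeled images that emulate the structure the recognition pipeline
expects: an elongated bright "epithelium" on a dark background, with an
optional textured lesion painted inside it, optionally corrupted by
salt-and-pepper noise.  Three disease classes are modeled alongside normal
skin:

* ``herpes`` — mid-sized lesion with high-contrast sparse speckle;
* ``paederus_dermatitis`` — small lesion with dense fine grain (the highest
  pixel-to-pixel contrast of the three);
* ``psoriasis`` — the largest lesion, with coarse low-contrast patches.

Lesion radii are ordered psoriasis > herpes > paederus dermatitis so the
pixel-area statistic separates the classes, and the lesion textures are
chosen so that at least one co-occurrence feature separates them as well.
Every image carries its ground truth (label, lesion mask, lesion pixel
area), which downstream tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

CLASS_LABELS = ("normal", "herpes", "paederus_dermatitis", "psoriasis")
DISEASE_LABELS = ("herpes", "paederus_dermatitis", "psoriasis")


@dataclass(frozen=True)
class TextureParams:
    """Lesion texture controls.

    spot_density   fraction of lesion pixels hit by speckle spots
    spot_amplitude peak intensity excursion of the texture (gray levels)
    base_intensity mean gray level of the lesion interior
    patch_px       side of the square texture cell (1 = per-pixel grain)
    tint           additive (R, G, B) shift applied to the lesion color
    """

    spot_density: float = 0.5
    spot_amplitude: float = 0.0
    base_intensity: float = 160.0
    patch_px: int = 1
    tint: tuple[float, float, float] = (0.0, 0.0, 0.0)


#: Per-class defaults.  Amplitudes/patch sizes give the three diseases
#: pairwise-disjoint contrast ranges (paederus > herpes > psoriasis at unit
#: offset); radii give the area ordering psoriasis > herpes > paederus.
CLASS_DEFAULTS: dict[str, dict] = {
    "normal": {
        "lesion_radius_px": 0.0,
        "texture_params": TextureParams(),
    },
    "herpes": {
        "lesion_radius_px": 30.0,
        "texture_params": TextureParams(
            spot_density=0.3, spot_amplitude=90.0, base_intensity=150.0,
            patch_px=2, tint=(35.0, -45.0, -45.0)),
    },
    "paederus_dermatitis": {
        "lesion_radius_px": 20.0,
        "texture_params": TextureParams(
            spot_density=1.0, spot_amplitude=127.0, base_intensity=128.0,
            patch_px=2, tint=(15.0, -55.0, -60.0)),
    },
    "psoriasis": {
        "lesion_radius_px": 40.0,
        "texture_params": TextureParams(
            spot_density=1.0, spot_amplitude=25.0, base_intensity=180.0,
            patch_px=10, tint=(35.0, -22.0, -48.0)),
    },
}


@dataclass(frozen=True)
class SynthSpec:
    """Full description of one synthetic image; identical specs (including
    ``seed``) generate bit-identical images."""

    class_label: str = "normal"
    image_size: tuple[int, int] = (256, 256)  # (height, width)
    lesion_radius_px: float | None = None  # None -> class default
    texture_params: TextureParams | None = None  # None -> class default
    noise_fraction: float = 0.0
    orientation_deg: float = 0.0
    seed: int = 0

    def resolved(self) -> "SynthSpec":
        """Fill class-dependent defaults and validate."""
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}")
        defaults = CLASS_DEFAULTS[self.class_label]
        radius = self.lesion_radius_px
        if radius is None:
            radius = defaults["lesion_radius_px"]
        texture = self.texture_params
        if texture is None:
            texture = defaults["texture_params"]
        spec = replace(self, lesion_radius_px=radius, texture_params=texture)
        spec.validate()
        return spec

    def validate(self) -> None:
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError(f"image_size must be at least 16x16, got {self.image_size}")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ValueError(
                f"noise_fraction must lie in [0, 1], got {self.noise_fraction}")
        r = self.lesion_radius_px
        if r is not None and r < 0:
            raise ValueError(f"lesion_radius_px must be non-negative, got {r}")
        if r is not None and r >= min(self.image_size) / 2:
            raise ValueError(
                f"lesion_radius_px must be < min(image_size)/2, got {r}")


def _superellipse_mask(shape: tuple[int, int], orientation_deg: float,
                       semi_a: float, semi_b: float, exponent: float = 3.0
                       ) -> np.ndarray:
    """Axis-aligned super-ellipse rotated by ``orientation_deg`` about the
    image center; gives the distance transform a clean horizontal ridge once
    rotated back."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.deg2rad(orientation_deg)
    # coordinates in the ellipse frame (x along the long axis)
    dx = cols - cx
    dy = rows - cy
    x = dx * np.cos(th) + dy * np.sin(th)
    y = -dx * np.sin(th) + dy * np.cos(th)
    v = np.abs(x / semi_a) ** exponent + np.abs(y / semi_b) ** exponent
    return v <= 1.0


def _lesion_texture(rng: np.random.Generator, shape: tuple[int, int],
                    params: TextureParams) -> np.ndarray:
    """Zero-mean gray-level texture field for the lesion interior."""
    h, w = shape
    p = max(1, int(params.patch_px))
    gh, gw = -(-h // p), -(-w // p)  # ceil
    grain = rng.uniform(-params.spot_amplitude, params.spot_amplitude, (gh, gw))
    if params.spot_density < 1.0:
        keep = rng.random((gh, gw)) < params.spot_density
        grain = np.where(keep, np.sign(grain) * params.spot_amplitude, 0.0)
    field_ = np.repeat(np.repeat(grain, p, axis=0), p, axis=1)
    return field_[:h, :w]


def generate_image(spec: SynthSpec) -> tuple[np.ndarray, dict]:
    """Render one synthetic skin image.

    Returns ``(image, ground_truth)`` where ``image`` is an (H, W, 3) uint8
    array and ``ground_truth`` has keys ``label``, ``lesion_mask`` (bool
    H×W), and ``lesion_area_px``.
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    params = spec.texture_params

    fg = _superellipse_mask((h, w), spec.orientation_deg,
                            semi_a=0.44 * w, semi_b=0.23 * h)

    # dark background, smooth skin-toned foreground (gray 120..200 band)
    img = rng.uniform(0.0, 20.0, (h, w, 3))
    base = ndimage.gaussian_filter(rng.normal(0.0, 12.0, (h, w)), sigma=6.0)
    skin_gray = np.clip(162.0 + base, 125.0, 198.0)
    skin = np.stack([skin_gray * 1.04, skin_gray * 0.96, skin_gray * 0.88], axis=-1)
    img[fg] = skin[fg]

    lesion_mask = np.zeros((h, w), dtype=bool)
    if spec.class_label != "normal" and spec.lesion_radius_px > 0:
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        disk = (rows - cy) ** 2 + (cols - cx) ** 2 <= spec.lesion_radius_px ** 2
        lesion_mask = disk & fg
        texture = _lesion_texture(rng, (h, w), params)
        gray = np.clip(params.base_intensity + texture, 0.0, 255.0)
        tint = np.asarray(params.tint)
        lesion_rgb = gray[..., None] + tint[None, None, :]
        img[lesion_mask] = lesion_rgb[lesion_mask]

    img = np.clip(img, 0.0, 255.0)

    if spec.noise_fraction > 0.0:
        corrupt = rng.random((h, w)) < spec.noise_fraction
        pepper_or_salt = rng.random((h, w)) < 0.5
        img[corrupt & pepper_or_salt] = 0.0
        img[corrupt & ~pepper_or_salt] = 255.0

    ground_truth = {
        "label": spec.class_label,
        "lesion_mask": lesion_mask,
        "lesion_area_px": int(lesion_mask.sum()),
    }
    return img.astype(np.uint8), ground_truth


def generate_dataset(n_per_class: int,
                     classes: Sequence[str] = DISEASE_LABELS,
                     spec_template: SynthSpec | None = None,
                     seed: int = 0) -> list[tuple[np.ndarray, dict]]:
    """Balanced synthetic dataset: ``n_per_class`` images for each class.

    Orientation, lesion radius and texture amplitude are jittered per image
    (radius by ±12%, keeping the class area ordering intact); each image gets
    its own child seed from ``seed`` so the dataset is fully reproducible.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    template = spec_template if spec_template is not None else SynthSpec()
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, dict]] = []
    for label in classes:
        defaults = CLASS_DEFAULTS[label]
        for _ in range(n_per_class):
            radius = defaults["lesion_radius_px"]
            radius *= rng.uniform(0.88, 1.12)
            tp: TextureParams = defaults["texture_params"]
            tp = replace(tp, spot_amplitude=tp.spot_amplitude * rng.uniform(0.9, 1.1))
            spec = replace(
                template,
                class_label=label,
                lesion_radius_px=radius,
                texture_params=tp,
                orientation_deg=float(rng.uniform(-45.0, 45.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append(generate_image(spec))
    return out
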