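"""Pipeline orchestration: configuration, per-image feature extraction,
batch runs with manifests, and the self-contained synthetic experiment
(generate -> preprocess -> features -> train -> evaluate).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import glcm, lesion, preprocess, svm, synth

logger = logging.getLogger("dermatex")

PIPELINE_VERSION = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, with documented defaults.

    median_window    median-filter window (odd, px)
    glcm_levels      gray-level quantization bins
    glcm_log_base    entropy log base (2 or e)
    marker_threshold watershed h-minima depth on the 0..255 gradient scale
    se_radius        disk radius for the morphological cleanup (px)
    min_lesion_color_dist  color-distance floor below which no lesion is declared
    C                SVM penalty factor
    sigma            RBF width; None = median pairwise-distance heuristic
    n_per_class      images generated per class in the experiment
    n_train_per_class training images per class (rest are tested)
    image_size       synthetic image size (px, square)
    noise_fraction   salt-and-pepper fraction applied to synthetic images
    seed             one global seed fanned out to stage-specific children
    """

    median_window: int = 3
    glcm_levels: int = 64
    glcm_log_base: float = 2.0
    marker_threshold: float = 0.3
    se_radius: int = 3
    min_lesion_color_dist: float = 20.0
    color_space: str = "chroma"
    C: float = 50.0
    sigma: float | None = None
    n_per_class: int = 30
    n_train_per_class: int = 10
    image_size: int = 256
    noise_fraction: float = 0.02
    seed: int = 42

    def glcm_config(self) -> glcm.GLCMConfig:
        return glcm.GLCMConfig(levels=self.glcm_levels,
                               log_base=self.glcm_log_base)

    def lesion_config(self, seed: int | None = None) -> lesion.LesionConfig:
        return lesion.LesionConfig(
            marker_threshold=self.marker_threshold,
            se_radius=self.se_radius, color_space=self.color_space,
            min_lesion_color_dist=self.min_lesion_color_dist,
            seed=self.seed if seed is None else seed)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if raw == "None":
                kwargs[key] = None
            else:
                typ = {int: int, float: float, str: str}.get(
                    type(getattr(cls, key, None)), None)
                default = getattr(cls(), key)
                if isinstance(default, int) and not isinstance(default, bool):
                    kwargs[key] = int(raw)
                elif isinstance(default, float) or default is None:
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """One record per processed image plus run-level provenance."""

    records: list
    pipeline_version: str
    config_hash: str


def extract_features(img: np.ndarray, cfg: PipelineConfig,
                     label: str | None = None) -> svm.FeatureVector:
    """Per-image feature extraction: preprocessing and per-segment texture
    on the rotated grayscale image; lesion area on the unrotated filtered
    color image (so the area denominator does not vary with the rotation
    canvas)."""
    pre = preprocess.preprocess_image(img, window=cfg.median_window)
    tex = glcm.features_for_segments(pre.rotated_gray, pre.segments,
                                     cfg=cfg.glcm_config())
    color = pre.filtered if pre.filtered.ndim == 3 else img
    seg = lesion.segment_lesion(color, cfg.lesion_config())
    return svm.build_feature_vector(tex, seg, label=label)


def run_pipeline(images, cfg: PipelineConfig,
                 model: svm.SVMModel | None = None) -> RunManifest:
    """Process a batch of images (paths or arrays).

    Failures on individual images become error records and do not abort
    the batch.  With a model, each record carries a predicted class.
    """
    items = list(images)
    if not items:
        raise ValueError("empty image batch")
    records = []
    for k, item in enumerate(items):
        rec: dict = {"index": k}
        t0 = time.perf_counter()
        try:
            if isinstance(item, (str, Path)):
                from PIL import Image

                rec["input"] = str(item)
                img = np.asarray(Image.open(item).convert("RGB"))
            else:
                rec["input"] = f"<array {k}>"
                img = np.asarray(item)
            fv = extract_features(img, cfg)
            rec["feature_vector"] = fv.values.tolist()
            if model is not None:
                rec["predicted_class"] = svm.predict(model, fv)[0]
            rec["status"] = "ok"
        except Exception as exc:  # per-image isolation
            rec["status"] = "error"
            rec["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("image %s failed: %s", rec.get("input", k), exc)
        rec["elapsed_s"] = time.perf_counter() - t0
        records.append(rec)
    return RunManifest(records=records, pipeline_version=PIPELINE_VERSION,
                       config_hash=cfg.config_hash())


def manifest_key(manifest: RunManifest) -> list:
    """Timing-free view of a manifest, for determinism comparisons."""
    return [
        {k: v for k, v in rec.items() if k != "elapsed_s"}
        for rec in manifest.records
    ] + [manifest.pipeline_version, manifest.config_hash]


def end_to_end_experiment(cfg: PipelineConfig = PipelineConfig()) -> dict:
    """The self-contained study: generate a balanced synthetic three-class
    dataset, split it (first ``n_train_per_class`` per class train, the rest
    test), train the texture (SVM1), area (SVM2) and integrated classifiers,
    and evaluate per-class recognition rates.

    Returns a dict with the per-class table (``table``), overall accuracies
    of the three classifiers, and the underlying feature vectors.
    """
    if cfg.n_train_per_class >= cfg.n_per_class:
        raise ValueError("n_train_per_class must be < n_per_class")
    logger.info("generating %d images per class", cfg.n_per_class)
    template = synth.SynthSpec(image_size=(cfg.image_size, cfg.image_size),
                               noise_fraction=cfg.noise_fraction)
    data = synth.generate_dataset(cfg.n_per_class, spec_template=template,
                                  seed=cfg.seed)
    train_set, test_set = [], []
    t0 = time.perf_counter()
    for i, (img, gt) in enumerate(data):
        fv = extract_features(img, cfg, label=gt["label"])
        # dataset is generated class-by-class, n_per_class each
        (train_set if i % cfg.n_per_class < cfg.n_train_per_class
         else test_set).append(fv)
    logger.info("feature extraction: %.1f s for %d images",
                time.perf_counter() - t0, len(data))

    texture_dims = np.arange(svm.TEXTURE_DIM)
    area_dims = np.array([svm.TEXTURE_DIM])
    model_tex = svm.train(train_set, C=cfg.C, sigma=cfg.sigma, dims=texture_dims)
    model_area = svm.train(train_set, C=cfg.C, sigma=cfg.sigma, dims=area_dims)
    model_full = svm.train(train_set, C=cfg.C, sigma=cfg.sigma)

    def overall(model):
        return float(np.mean([svm.predict(model, fv)[0] == fv.label
                              for fv in test_set]))

    table = svm.evaluate(model_full, test_set)
    return {
        "table": table,
        "overall_accuracy": overall(model_full),
        "svm1_texture_accuracy": overall(model_tex),
        "svm2_area_accuracy": overall(model_area),
        "n_images": len(data),
        "n_train": len(train_set),
        "n_test": len(test_set),
        "model": model_full,
        "train_set": train_set,
        "test_set": test_set,
    }
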