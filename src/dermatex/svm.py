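"""Soft-margin RBF support vector machines for three-way skin-disease
classification.

Three classifiers are built from the same training set: SVM1 on the ten
texture statistics (per-segment min/max of contrast, correlation, entropy,
uniformity, energy), SVM2 on the lesion area fraction alone, and the
integrated SVM on the 11-dimensional concatenation, which produces the
final label.  Binary subproblems are trained one-vs-one by a deterministic
SMO solver at penalty C = 50 (the value at which recognition peaks on the
reference data) with kernel width sigma set by the median pairwise-distance
heuristic; multiclass decisions are majority votes with ties broken toward
the lowest class index.

Classes are conventionally ordered herpes (I), paederus dermatitis (II),
psoriasis (III).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .glcm import TextureFeatures
from .lesion import LesionSegmentation

CLASS_ORDER = ("herpes", "paederus_dermatitis", "psoriasis")

TEXTURE_DIM = 10
AREA_DIM = 1


@dataclass(frozen=True)
class FeatureVector:
    """11-dimensional sample: (min, max) over the ten vertical segments for
    each of the five texture statistics, then the lesion area fraction."""

    values: np.ndarray  # shape (11,)
    label: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (TEXTURE_DIM + AREA_DIM,):
            raise ValueError(f"feature vector must have length 11, got {v.shape}")
        object.__setattr__(self, "values", v)


def build_feature_vector(tex: list[TextureFeatures],
                         area: LesionSegmentation,
                         label: str | None = None) -> FeatureVector:
    """Collapse per-segment texture records into min/max pairs and append
    the area fraction, mirroring the minimum/maximum feature-table layout."""
    if len(tex) != 10:
        raise ValueError(f"expected 10 segment records, got {len(tex)}")
    mat = np.stack([t.as_array() for t in tex])  # (10, 5)
    parts = []
    for f in range(5):
        parts.extend([mat[:, f].min(), mat[:, f].max()])
    parts.append(area.area_fraction)
    return FeatureVector(values=np.asarray(parts), label=label)


def rbf_kernel(u: np.ndarray, v: np.ndarray, sigma: float) -> float:
    """exp(-||u - v||^2 / (2 sigma^2)); 1 at u = v, symmetric."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("rbf_kernel requires equal dimensions")
    return float(np.exp(-np.sum((u - v) ** 2) / (2.0 * sigma ** 2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _smo(K: np.ndarray, y: np.ndarray, C: float, tol: float = 1e-3,
         max_passes: int = 10_000) -> tuple[np.ndarray, float]:
    """Sequential minimal optimization on a precomputed kernel.

    Deterministic variant of Platt's simplified SMO: the first multiplier is
    scanned in index order, the second chosen to maximize |E_i - E_j|.
    Returns (alpha, b); updates preserve sum(alpha * y) = 0 exactly.
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    b = 0.0
    passes = 0
    while passes < max_passes:
        changed = 0
        E = K @ (alpha * y) + b - y
        for i in range(n):
            Ei = float(K[i] @ (alpha * y) + b - y[i])
            if not ((y[i] * Ei < -tol and alpha[i] < C) or
                    (y[i] * Ei > tol and alpha[i] > 0)):
                continue
            j = int(np.argmax(np.abs(E - Ei) + np.where(np.arange(n) == i, -np.inf, 0.0)))
            Ej = float(K[j] @ (alpha * y) + b - y[j])
            ai_old, aj_old = alpha[i], alpha[j]
            if y[i] != y[j]:
                Lo, Hi = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
            else:
                Lo, Hi = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
            if Hi - Lo < 1e-12:
                continue
            eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
            if eta >= 0:
                continue
            aj = np.clip(aj_old - y[j] * (Ei - Ej) / eta, Lo, Hi)
            if abs(aj - aj_old) < 1e-7:
                continue
            ai = ai_old + y[i] * y[j] * (aj_old - aj)
            alpha[i], alpha[j] = ai, aj
            b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] \
                - y[j] * (aj - aj_old) * K[i, j]
            b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] \
                - y[j] * (aj - aj_old) * K[j, j]
            if 0 < ai < C:
                b = b1
            elif 0 < aj < C:
                b = b2
            else:
                b = (b1 + b2) / 2.0
            E = K @ (alpha * y) + b - y
            changed += 1
        passes = passes + 1 if changed == 0 else 0
        if changed == 0:
            break
    return alpha, float(b)


@dataclass
class BinarySVM:
    """One trained one-vs-one subproblem: class_pos gets decision +1."""

    class_pos: str
    class_neg: str
    sv_x: np.ndarray  # (m, d) support vectors in scaled space
    sv_y: np.ndarray  # (m,) labels ±1
    alpha: np.ndarray  # (m,) multipliers in (0, C]
    bias: float

    def decision(self, X: np.ndarray, sigma: float) -> np.ndarray:
        K = _kernel_matrix(np.atleast_2d(X), self.sv_x, sigma)
        return K @ (self.alpha * self.sv_y) + self.bias


@dataclass
class SVMModel:
    classes: tuple
    pairs: list  # list of BinarySVM
    sigma: float
    C: float
    scale_min: np.ndarray  # per-kept-dimension training minima
    scale_max: np.ndarray
    kept_dims: np.ndarray  # indices into the raw 11-dim vector

    def _scale(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))[:, self.kept_dims]
        return (X - self.scale_min) / (self.scale_max - self.scale_min)


def median_sigma(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance (scale-free kernel-width
    heuristic); falls back to 1 when all points coincide."""
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    d = np.sqrt(d2[np.triu_indices(len(X), k=1)])
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def train(data: list[FeatureVector], C: float = 50.0,
          sigma: float | None = None,
          dims: np.ndarray | None = None) -> SVMModel:
    """Fit one-vs-one RBF SVMs on [0,1]-rescaled features.

    ``dims`` restricts training to a subset of the 11 feature dimensions
    (used for the texture-only and area-only diagnostic classifiers).
    Degenerate dimensions (no spread in training) are dropped with a
    warning; sigma defaults to the median pairwise-distance heuristic.
    """
    labels = [fv.label for fv in data]
    if any(lbl is None for lbl in labels):
        raise ValueError("all training vectors must be labeled")
    classes = tuple(c for c in CLASS_ORDER if c in labels)
    extra = sorted(set(labels) - set(classes))
    classes = classes + tuple(extra)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"class {c!r} needs at least 2 training samples")

    X = np.stack([fv.values for fv in data])
    if dims is None:
        dims = np.arange(X.shape[1])
    dims = np.asarray(dims, dtype=int)
    X = X[:, dims]
    lo, hi = X.min(axis=0), X.max(axis=0)
    keep = hi - lo > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} degenerate feature "
                      "dimension(s) with no training spread", stacklevel=2)
    if not keep.any():
        raise ValueError("all feature dimensions are degenerate")
    kept_dims = dims[keep]
    lo, hi = lo[keep], hi[keep]
    Xs = (X[:, keep] - lo) / (hi - lo)

    if sigma is None:
        sigma = median_sigma(Xs)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")

    y_arr = np.asarray(labels)
    pairs = []
    for a_i in range(len(classes)):
        for b_i in range(a_i + 1, len(classes)):
            ca, cb = classes[a_i], classes[b_i]
            sel = (y_arr == ca) | (y_arr == cb)
            Xp = Xs[sel]
            yp = np.where(y_arr[sel] == ca, 1.0, -1.0)
            K = _kernel_matrix(Xp, Xp, sigma)
            alpha, b = _smo(K, yp, C)
            sv = alpha > 1e-8
            pairs.append(BinarySVM(class_pos=ca, class_neg=cb,
                                   sv_x=Xp[sv], sv_y=yp[sv],
                                   alpha=alpha[sv], bias=b))
    return SVMModel(classes=classes, pairs=pairs, sigma=sigma, C=C,
                    scale_min=lo, scale_max=hi, kept_dims=kept_dims)


def predict(model: SVMModel, x: FeatureVector | np.ndarray
            ) -> tuple[str, dict]:
    """Majority vote over the one-vs-one decision functions; ties go to the
    lowest class index."""
    v = x.values if isinstance(x, FeatureVector) else np.asarray(x, float)
    if v.shape[-1] != TEXTURE_DIM + AREA_DIM:
        raise ValueError(f"expected an 11-dim feature vector, got {v.shape}")
    Xs = model._scale(v)
    votes = {c: 0 for c in model.classes}
    decisions = {}
    for p in model.pairs:
        d = float(p.decision(Xs, model.sigma)[0])
        decisions[(p.class_pos, p.class_neg)] = d
        winner = p.class_pos if d >= 0 else p.class_neg
        votes[winner] += 1
    best = max(votes.values())
    for c in model.classes:  # class order breaks ties
        if votes[c] == best:
            return c, decisions
    raise AssertionError("unreachable")


def evaluate(model: SVMModel, test: list[FeatureVector]):
    """Per-class recognition rates as a table: class, number tested, number
    recognized, rate in percent."""
    import pandas as pd

    if not test:
        raise ValueError("empty test set")
    rows = []
    for c in model.classes:
        members = [fv for fv in test if fv.label == c]
        if not members:
            continue
        correct = sum(predict(model, fv)[0] == c for fv in members)
        rows.append({"class": c, "n_test": len(members),
                     "n_recognized": correct,
                     "rate_percent": 100.0 * correct / len(members)})
    return pd.DataFrame(rows)


def save_model(model: SVMModel, path) -> None:
    """Serialize to a single JSON archive (versioned)."""
    payload = {
        "format": "dermatex-svm",
        "version": 1,
        "classes": list(model.classes),
        "sigma": model.sigma,
        "C": model.C,
        "scale_min": model.scale_min.tolist(),
        "scale_max": model.scale_max.tolist(),
        "kept_dims": model.kept_dims.tolist(),
        "pairs": [
            {"class_pos": p.class_pos, "class_neg": p.class_neg,
             "sv_x": p.sv_x.tolist(), "sv_y": p.sv_y.tolist(),
             "alpha": p.alpha.tolist(), "bias": p.bias}
            for p in model.pairs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> SVMModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "dermatex-svm":
        raise ValueError(f"{path} is not a dermatex SVM archive")
    pairs = [BinarySVM(class_pos=p["class_pos"], class_neg=p["class_neg"],
                       sv_x=np.asarray(p["sv_x"], float),
                       sv_y=np.asarray(p["sv_y"], float),
                       alpha=np.asarray(p["alpha"], float),
                       bias=float(p["bias"]))
             for p in payload["pairs"]]
    return SVMModel(classes=tuple(payload["classes"]), pairs=pairs,
                    sigma=float(payload["sigma"]), C=float(payload["C"]),
                    scale_min=np.asarray(payload["scale_min"], float),
                    scale_max=np.asarray(payload["scale_max"], float),
                    kept_dims=np.asarray(payload["kept_dims"], int))
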