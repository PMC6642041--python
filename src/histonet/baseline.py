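"""Classical texture-feature baseline for patchwise tissue classification.

Hand-crafted features — RGB channel statistical moments, grey-level
co-occurrence matrix (GLCM) properties, uniform local-binary-pattern (LBP)
histograms and Tamura texture measures (coarseness, contrast,
directionality) — feed a conventional classifier (RBF-SVM or random forest).
Ground truth for this patchwise setup is sampled from the semantic
annotations and balanced across classes.  The baseline also provides a
patch-granularity segmenter (non-overlapping patches, one label each), the
classical counterpart the semantic network is benchmarked against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import sobel, uniform_filter
from skimage.color import rgb2gray
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .decision import stratified_folds

__all__ = [
    "BaselineConfig",
    "TextureFeatureVector",
    "texture_features",
    "balanced_patches",
    "baseline_cv",
    "fit_patch_classifier",
    "segment_patchwise",
]


@dataclass(frozen=True)
class BaselineConfig:
    """Texture-operator parameters, fixed for reproducibility."""

    glcm_levels: int = 32
    glcm_distances: tuple[int, ...] = (1,)
    #: angles 0, 90, 45, 135 degrees == offsets (0,1), (1,0), (1,1), (1,-1)
    glcm_angles: tuple[float, ...] = (0.0, np.pi / 2, np.pi / 4, 3 * np.pi / 4)
    lbp_radius: int = 1
    lbp_points: int = 8
    tamura_max_scale: int = 32
    directionality_bins: int = 16


@dataclass(frozen=True)
class TextureFeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def _tamura(gray: np.ndarray, config: BaselineConfig) -> dict[str, float]:
    """Tamura coarseness, contrast and directionality.

    Coarseness: per pixel the dyadic window size (up to ``tamura_max_scale``)
    maximizing the horizontal/vertical difference of window averages, then
    averaged.  Contrast: sigma / kurtosis^(1/4).  Directionality: energy
    (peakness) of the gradient-orientation histogram weighted by gradient
    magnitude.
    """
    h, w = gray.shape
    max_k = max(1, int(np.log2(min(config.tamura_max_scale, min(h, w) // 2))))
    best = np.zeros((h, w))
    best_size = np.ones((h, w))
    for k in range(1, max_k + 1):
        size = 2**k
        avg = uniform_filter(gray, size=size, mode="reflect")
        half = size // 2
        eh = np.abs(np.roll(avg, -half, axis=1) - np.roll(avg, half, axis=1))
        ev = np.abs(np.roll(avg, -half, axis=0) - np.roll(avg, half, axis=0))
        e = np.maximum(eh, ev)
        upd = e > best
        best[upd] = e[upd]
        best_size[upd] = size
    coarseness = float(best_size.mean())

    mu = gray.mean()
    sigma = gray.std()
    if sigma < 1e-12:
        contrast = 0.0
    else:
        kurt = ((gray - mu) ** 4).mean() / sigma**4
        contrast = float(sigma / kurt**0.25)

    gx = sobel(gray, axis=1, mode="reflect")
    gy = sobel(gray, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    theta = np.mod(np.arctan2(gy, gx), np.pi)
    if mag.sum() < 1e-12:
        directionality = 0.0
    else:
        hist, _ = np.histogram(
            theta, bins=config.directionality_bins, range=(0, np.pi), weights=mag
        )
        hist = hist / hist.sum()
        directionality = float((hist**2).sum())
    return {
        "tamura_coarseness": coarseness,
        "tamura_contrast": contrast,
        "tamura_directionality": directionality,
    }


def texture_features(
    patch: np.ndarray, config: BaselineConfig = BaselineConfig()
) -> TextureFeatureVector:
    """Deterministic hand-crafted feature vector of one RGB patch."""
    img = np.asarray(patch, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB patch")
    min_side = min(img.shape[:2])
    if min_side < 2 * config.lbp_radius + 2 or min_side < 4:
        raise ValueError("patch is smaller than the largest operator window")
    names: list[str] = []
    values: list[float] = []
    for c, ch in enumerate("rgb"):
        chan = img[..., c].ravel()
        mu, sd = chan.mean(), chan.std()
        sk = float(((chan - mu) ** 3).mean() / sd**3) if sd > 1e-12 else 0.0
        values += [float(mu), float(sd), sk]
        names += [f"{ch}_mean", f"{ch}_std", f"{ch}_skew"]

    gray = rgb2gray(img)
    q = np.clip((gray * config.glcm_levels).astype(np.int64), 0, config.glcm_levels - 1)
    glcm = graycomatrix(
        q.astype(np.uint8),
        distances=list(config.glcm_distances),
        angles=list(config.glcm_angles),
        levels=config.glcm_levels,
        symmetric=True,
        normed=True,
    )
    for prop in ("contrast", "correlation", "energy", "homogeneity"):
        values.append(float(graycoprops(glcm, prop).mean()))
        names.append(f"glcm_{prop}")

    lbp = local_binary_pattern(
        q.astype(np.uint8), P=config.lbp_points, R=config.lbp_radius, method="uniform"
    )
    n_bins = config.lbp_points + 2
    hist, _ = np.histogram(lbp, bins=n_bins, range=(0, n_bins))
    hist = hist / hist.sum()
    values += hist.tolist()
    names += [f"lbp_{i}" for i in range(n_bins)]

    tam = _tamura(gray, config)
    for k, v in tam.items():
        names.append(k)
        values.append(v)
    return TextureFeatureVector(tuple(names), np.asarray(values))


def balanced_patches(
    images: list[np.ndarray],
    annotations: list[np.ndarray],
    patch_size: int,
    seed: int = 0,
    per_class: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced patch sample from annotated mosaics.

    A candidate patch is any fully contained window; its label is the class
    at the patch center.  Each class contributes the same number of patches,
    capped by the rarest class (and ``per_class``); classes without any
    candidate are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    half = patch_size // 2
    pools: dict[int, list[tuple[int, int, int]]] = {}
    for t, ann in enumerate(annotations):
        h, w = ann.shape
        inner = ann[half : h - (patch_size - half), half : w - (patch_size - half)]
        for cls in np.unique(inner):
            rr, cc = np.nonzero(inner == cls)
            pools.setdefault(int(cls), []).extend(
                (t, int(r) + half, int(c) + half) for r, c in zip(rr, cc)
            )
    if not pools:
        raise ValueError("no patch fits inside the provided annotations")
    counts = {c: len(v) for c, v in pools.items()}
    n_each = min(counts.values())
    if per_class is not None:
        n_each = min(n_each, per_class)
    patches, labels = [], []
    for cls in sorted(pools):
        pool = pools[cls]
        if not pool:
            warnings.warn(f"class {cls} has no candidate patches; excluded")
            continue
        take = rng.choice(len(pool), size=n_each, replace=False)
        for j in take:
            t, r, c = pool[j]
            patches.append(
                images[t][r - half : r - half + patch_size, c - half : c - half + patch_size]
            )
            labels.append(cls)
    return np.stack(patches), np.asarray(labels)


def _feature_matrix(patches: np.ndarray, config: BaselineConfig) -> np.ndarray:
    return np.stack([texture_features(p, config).values for p in patches])


def _make_classifier(kind: str, seed: int):
    # features span very different ranges, so standardize before the SVM
    if kind == "rbf_svm":
        return make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
        )
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError("classifier must be rbf_svm or random_forest")


def baseline_cv(
    images: list[np.ndarray],
    annotations: list[np.ndarray],
    classifier: str = "rbf_svm",
    patch_size: int = 12,
    folds: int = 5,
    seed: int = 0,
    per_class: int | None = 200,
    config: BaselineConfig = BaselineConfig(),
) -> pd.DataFrame:
    """Cross-validated patchwise classification with the classical features.

    Returns one row per fold with weighted precision/recall/F1 and macro F1.
    """
    patches, labels = balanced_patches(
        images, annotations, patch_size, seed=seed, per_class=per_class
    )
    x = _feature_matrix(patches, config)
    assignment = stratified_folds(labels, k=folds, seed=seed)
    rows = []
    for fold in range(assignment.max() + 1):
        test = assignment == fold
        clf = _make_classifier(classifier, seed)
        clf.fit(x[~test], labels[~test])
        pred = clf.predict(x[test])
        p, r, f, _ = precision_recall_fscore_support(
            labels[test], pred, average="weighted", zero_division=0
        )
        _, _, f_macro, _ = precision_recall_fscore_support(
            labels[test], pred, average="macro", zero_division=0
        )
        rows.append(
            {
                "fold": fold,
                "precision": float(p),
                "recall": float(r),
                "f1": float(f),
                "macro_f1": float(f_macro),
            }
        )
    return pd.DataFrame(rows).set_index("fold")


def fit_patch_classifier(
    images: list[np.ndarray],
    annotations: list[np.ndarray],
    classifier: str = "rbf_svm",
    patch_size: int = 12,
    seed: int = 0,
    per_class: int | None = 200,
    config: BaselineConfig = BaselineConfig(),
):
    """Fit the baseline patch classifier on balanced patches; returns the
    fitted estimator (operating on texture feature vectors)."""
    patches, labels = balanced_patches(
        images, annotations, patch_size, seed=seed, per_class=per_class
    )
    x = _feature_matrix(patches, config)
    clf = _make_classifier(classifier, seed)
    clf.fit(x, labels)
    return clf


def segment_patchwise(
    clf,
    image: np.ndarray,
    patch_size: int,
    config: BaselineConfig = BaselineConfig(),
) -> np.ndarray:
    """Patch-granularity segmentation: classify non-overlapping patches and
    broadcast each patch's label to its pixels (edge patches are clamped to
    the border)."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    out = np.zeros((h, w), dtype=np.int64)
    starts_r = list(range(0, h - patch_size + 1, patch_size))
    if starts_r[-1] != h - patch_size:
        starts_r.append(h - patch_size)
    starts_c = list(range(0, w - patch_size + 1, patch_size))
    if starts_c[-1] != w - patch_size:
        starts_c.append(w - patch_size)
    patches, slots = [], []
    for r in starts_r:
        for c in starts_c:
            patches.append(img[r : r + patch_size, c : c + patch_size])
            slots.append((r, c))
    feats = _feature_matrix(np.stack(patches), config)
    preds = clf.predict(feats)
    for (r, c), lab in zip(slots, preds):
        out[r : r + patch_size, c : c + patch_size] = lab
    return out
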