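"""Closed-form tumor-micro-environment meta-features from tissue maps.

For a tissue map P(x, y) with class ids i the features are

* absolute areas            f_i^abs = #{(x, y) : P(x, y) = i}   [px]
* tissue area               A = sum of f_i^abs over the six main classes
                            (artifacts TAR and background BGR are omitted)
* relative areas            f_i^rel = f_i^abs / A               (main classes)
* isotype differences       Δf_i = f_i(sample) − f_i(isotype), applicable to
                            absolute or relative features, to A and to the
                            CD45 fraction
* CD45-positive fraction    positive-stain pixels / counterstain pixels,
                            both obtained by thresholding the two-stain
                            decomposition of the CD45 slide.

Undefined quantities (relative areas when A = 0, deltas with an undefined
operand, CD45 fraction without counterstain pixels) are reported as NaN
rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import stain as stain_mod
from .palette import BGR, CLASS_NAMES, MAIN_CLASSES, N_CLASSES, TAR
from .synthetic_data import SMTCohort

__all__ = [
    "MetaFeatures",
    "absolute_areas",
    "tissue_area",
    "relative_areas",
    "isotype_delta",
    "cd45_fraction",
    "compute_metafeatures",
    "build_feature_table",
    "DEFAULT_FEATURES",
]

#: The feature combination used by the decision stage: absolute tumor area,
#: relative tumor area, relative stroma area, and isotype differences in the
#: relative necrosis, the CD45 fraction and the overall tissue area.
DEFAULT_FEATURES = ("abs_TUM", "rel_TUM", "rel_MST", "d_rel_NEC", "d_cd45", "d_area")


def absolute_areas(labels: np.ndarray) -> np.ndarray:
    """Pixel count per class id, length ``N_CLASSES``."""
    lab = np.asarray(labels)
    if lab.size and (lab.min() < 0 or lab.max() >= N_CLASSES):
        raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
    return np.bincount(lab.ravel(), minlength=N_CLASSES).astype(np.int64)


def tissue_area(f_abs: np.ndarray) -> int:
    """Total tissue area A: sum over the six main classes (TAR/BGR excluded)."""
    f = np.asarray(f_abs)
    return int(f[list(MAIN_CLASSES)].sum())


def relative_areas(f_abs: np.ndarray) -> np.ndarray:
    """Relative areas f_i^rel = f_i^abs / A for the main classes.

    TAR and BGR are excluded from the tissue simplex and reported as NaN;
    with A = 0 every entry is NaN (undefined, not an error).
    """
    f = np.asarray(f_abs, dtype=np.float64)
    a = tissue_area(f_abs)
    out = np.full(N_CLASSES, np.nan)
    if a > 0:
        for c in MAIN_CLASSES:
            out[c] = f[c] / a
    return out


@dataclass(frozen=True)
class MetaFeatures:
    """All meta-features of one slide/sample."""

    f_abs: np.ndarray
    area: int
    f_rel: np.ndarray
    cd45_fraction: float = float("nan")
    deltas: dict = field(default_factory=dict)

    def value(self, which: str, mode: str = "abs") -> float:
        """Look up a feature by class name or by 'area' / 'cd45'."""
        if which == "area":
            return float(self.area)
        if which == "cd45":
            return float(self.cd45_fraction)
        idx = CLASS_NAMES.index(which)
        if mode == "abs":
            return float(self.f_abs[idx])
        if mode == "rel":
            return float(self.f_rel[idx])
        raise ValueError(f"unknown mode {mode!r}")


def compute_metafeatures(
    labels: np.ndarray, cd45_fraction_value: float = float("nan")
) -> MetaFeatures:
    f_abs = absolute_areas(labels)
    return MetaFeatures(
        f_abs=f_abs,
        area=tissue_area(f_abs),
        f_rel=relative_areas(f_abs),
        cd45_fraction=cd45_fraction_value,
    )


def isotype_delta(
    sample: MetaFeatures, isotype: MetaFeatures, which: str, mode: str = "abs"
) -> float:
    """Δf = f(sample) − f(isotype); NaN if either operand is undefined."""
    a = sample.value(which, mode)
    b = isotype.value(which, mode)
    return a - b  # NaN propagates


def cd45_fraction(
    positive_map: np.ndarray,
    counterstain_map: np.ndarray,
    positive_threshold: float | None = None,
    counterstain_threshold: float | None = None,
) -> float:
    """Positive-pixel count normalized by counterstain-pixel count.

    Thresholds default to Otsu per channel; NaN when no counterstain pixel
    passes its threshold.
    """
    pos = np.asarray(positive_map, dtype=np.float64)
    cs = np.asarray(counterstain_map, dtype=np.float64)
    if pos.shape != cs.shape:
        raise ValueError("maps must share shape")

    def _thr(channel: np.ndarray, override: float | None) -> float:
        if override is not None:
            return override
        if np.ptp(channel) < 1e-12:
            return np.inf  # constant channel: nothing is positive
        return float(threshold_otsu(channel))

    n_pos = int((pos > _thr(pos, positive_threshold)).sum())
    n_cs = int((cs > _thr(cs, counterstain_threshold)).sum())
    if n_cs == 0:
        return float("nan")
    return n_pos / n_cs


def _cd45_fraction_from_image(image: np.ndarray) -> float:
    cs, pos = stain_mod.destain_cd45(image)
    return cd45_fraction(pos, cs)


def _feature_value(
    name: str, feats: MetaFeatures, iso: MetaFeatures
) -> float:
    if name.startswith("d_"):
        rest = name[2:]
        if rest in ("area", "cd45"):
            return isotype_delta(feats, iso, rest)
        mode, cls = rest.split("_", 1)
        return isotype_delta(feats, iso, cls, mode)
    if name in ("area", "cd45"):
        return feats.value(name)
    mode, cls = name.split("_", 1)
    return feats.value(cls, mode)


def build_feature_table(
    cohort: SMTCohort,
    features: tuple[str, ...] = DEFAULT_FEATURES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-treated-sample feature matrix plus response labels.

    Isotype samples serve only as the Δ reference; samples with unknown
    response are excluded.  Feature names: ``abs_<CLS>``, ``rel_<CLS>``,
    ``area``, ``cd45`` and their isotype differences ``d_...``.  The CD45
    fraction is computed end-to-end from each sample's CD45 image through the
    two-stain decomposition.
    """
    iso_feats: dict[str, MetaFeatures] = {}
    for s in cohort.samples:
        if s.treatment == "isotype":
            iso_feats[s.model_id] = compute_metafeatures(
                s.tissue_map, _cd45_fraction_from_image(s.cd45.image)
            )
    rows, labels, index = [], [], []
    for s in cohort.treated():
        if s.response == "unknown":
            continue
        if s.model_id not in iso_feats:
            raise ValueError(f"model {s.model_id} has no isotype sample")
        feats = compute_metafeatures(
            s.tissue_map, _cd45_fraction_from_image(s.cd45.image)
        )
        iso = iso_feats[s.model_id]
        rows.append({name: _feature_value(name, feats, iso) for name in features})
        labels.append(s.response)
        index.append(f"{s.model_id}_{s.treatment}")
    table = pd.DataFrame(rows, index=index, columns=list(features))
    return table, pd.Series(labels, index=index, name="response")
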