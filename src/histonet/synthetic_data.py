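"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

No public image cohort accompanies this package, so every downstream stage is
exercised on synthetic material:

* eight-class textured tiles with pixel-accurate annotations (distinct
  per-class base color plus a class-specific sinusoidal texture and seeded
  noise — learnable by a small network in minutes, but not constant color);
* two-stain CD45-like patches (blue counterstain, brown positive blobs) with
  the exact ground-truth positive mask;
* variance-map fixtures carrying the light-green BLC-NEC confusion signature;
* single-mouse-trial (SMT) cohorts — one isotype plus three treated samples
  per tumor model — with a planted responder effect: responders have smaller
  absolute tumor area, larger relative necrosis, smaller overall tissue area
  and a CD45 shift relative to their isotype.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .inference import VarianceImage
from .palette import (
    BGR,
    BLC,
    CLASS_NAMES,
    MAIN_CLASSES,
    MUS,
    N_CLASSES,
    NEC,
    TAR,
    TUM,
    VAC,
    MST,
    ClassPalette,
    make_palette,
)

__all__ = [
    "Rect",
    "Disc",
    "SyntheticLayout",
    "TextureParams",
    "EffectSizes",
    "CD45Patch",
    "CohortSample",
    "SMTCohort",
    "make_palette",
    "synth_tissue_sample",
    "synth_cd45_patch",
    "synth_confusion_fixture",
    "synth_smt_cohort",
    "save_tissue_sample",
    "save_cohort",
]

TREATMENTS = ("isotype", "antiPDL1", "antiCTLA4", "combo")
TREATED = TREATMENTS[1:]


# ------------------------------------------------------------------ layouts
@dataclass(frozen=True)
class Rect:
    row0: int
    col0: int
    height: int
    width: int

    def paint(self, canvas: np.ndarray, value: int) -> None:
        h, w = canvas.shape
        if (
            self.row0 < 0
            or self.col0 < 0
            or self.row0 + self.height > h
            or self.col0 + self.width > w
        ):
            raise ValueError("rectangle lies outside the image bounds")
        canvas[self.row0 : self.row0 + self.height, self.col0 : self.col0 + self.width] = value


@dataclass(frozen=True)
class Disc:
    row: int
    col: int
    radius: int

    def paint(self, canvas: np.ndarray, value: int) -> None:
        h, w = canvas.shape
        if (
            self.row - self.radius < 0
            or self.col - self.radius < 0
            or self.row + self.radius >= h
            or self.col + self.radius >= w
        ):
            raise ValueError("disc lies outside the image bounds")
        yy, xx = np.ogrid[:h, :w]
        canvas[(yy - self.row) ** 2 + (xx - self.col) ** 2 <= self.radius**2] = value


@dataclass(frozen=True)
class SyntheticLayout:
    """Geometry of a synthetic tile: regions painted in order over the canvas.

    The first region must cover the whole frame so that the regions tile the
    image; later regions overwrite earlier ones, which keeps every pixel
    uniquely labeled while allowing exact area oracles for rectangles/discs.
    """

    shape: tuple[int, int]
    regions: tuple[tuple[int, Rect | Disc], ...]

    def label_map(self) -> np.ndarray:
        canvas = np.full(self.shape, -1, dtype=np.int16)
        for cls, region in self.regions:
            if not 0 <= cls < N_CLASSES:
                raise ValueError(f"class id {cls} out of range")
            region.paint(canvas, cls)
        if (canvas < 0).any():
            raise ValueError("regions do not tile the image")
        return canvas.astype(np.uint8)

    @classmethod
    def single(cls, shape: tuple[int, int], class_id: int) -> "SyntheticLayout":
        return cls(shape, ((class_id, Rect(0, 0, shape[0], shape[1])),))


# ----------------------------------------------------------------- textures
@dataclass(frozen=True)
class TextureParams:
    base_color: tuple[float, float, float]
    amplitude: float = 0.08
    period: float = 8.0
    angle: float = 0.0


def _default_textures(palette: ClassPalette) -> dict[int, TextureParams]:
    """Per-class signature: base color pulled toward the display color, a
    class-specific sinusoid period/orientation."""
    out = {}
    for entry in palette.entries:
        base = tuple(0.2 + 0.6 * c for c in entry.color)
        out[entry.id] = TextureParams(
            base_color=base,
            amplitude=0.08,
            period=4.0 + 1.5 * entry.id,
            angle=np.pi * entry.id / N_CLASSES,
        )
    return out


def synth_tissue_sample(
    layout: SyntheticLayout,
    seed: int,
    textures: dict[int, TextureParams] | None = None,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a textured RGB tile plus its pixel-accurate annotation.

    Identical (layout, seed, parameters) give bit-identical output.
    """
    ann = layout.label_map()
    textures = textures or _default_textures(make_palette())
    rng = np.random.default_rng(seed)
    h, w = layout.shape
    yy, xx = np.mgrid[:h, :w]
    img = np.zeros((h, w, 3), dtype=np.float64)
    for cls in np.unique(ann):
        tp = textures[int(cls)]
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = np.sin(
            2.0
            * np.pi
            * (np.cos(tp.angle) * xx + np.sin(tp.angle) * yy)
            / tp.period
            + phase
        )
        mask = ann == cls
        tex = np.asarray(tp.base_color) + tp.amplitude * wave[..., None]
        img[mask] = tex[mask]
    img += rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), ann


# -------------------------------------------------------------------- CD45
@dataclass(frozen=True)
class CD45Patch:
    image: np.ndarray
    positive_mask: np.ndarray
    stained_mask: np.ndarray

    @property
    def positive_fraction(self) -> float:
        return float(self.positive_mask.sum() / max(self.stained_mask.sum(), 1))


_BLUE = np.array([0.30, 0.38, 0.72])
_BROWN = np.array([0.52, 0.32, 0.14])
_WHITE = np.array([0.96, 0.96, 0.96])


def synth_cd45_patch(
    shape: tuple[int, int],
    positive_fraction: float,
    seed: int,
    background_fraction: float = 0.15,
    blob_scale: float = 3.0,
    noise_sd: float = 0.02,
) -> CD45Patch:
    """Two-stain CD45-like patch with exact ground truth.

    A central stained region (blue counterstain) is surrounded by an
    unstained white margin covering ``background_fraction`` of the patch.
    Brown positive blobs cover exactly ``round(positive_fraction * stained
    pixels)`` pixels of the stained area; blob geometry comes from a smoothed
    seeded noise field so the mask is blobby rather than speckled.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    radial = np.hypot((yy - (h - 1) / 2) / h, (xx - (w - 1) / 2) / w)
    radial = radial + 0.02 * gaussian_filter(rng.standard_normal(shape), 4.0)
    n_bg = round(background_fraction * h * w)
    stained = np.ones(shape, dtype=bool)
    if n_bg > 0:
        order = np.argsort(radial.ravel())[::-1]
        stained.ravel()[order[:n_bg]] = False
    field = gaussian_filter(rng.standard_normal(shape), blob_scale)
    positive = np.zeros(shape, dtype=bool)
    n_pos = round(positive_fraction * stained.sum())
    if n_pos > 0:
        vals = np.where(stained, field, -np.inf).ravel()
        order = np.argsort(vals)[::-1]
        positive.ravel()[order[:n_pos]] = True
    img = np.empty((h, w, 3))
    img[~stained] = _WHITE
    img[stained] = _BLUE
    img[positive] = _BROWN
    img += rng.normal(0.0, noise_sd, img.shape)
    return CD45Patch(
        image=np.clip(img, 0.0, 1.0).astype(np.float32),
        positive_mask=positive,
        stained_mask=stained,
    )


# --------------------------------------------------------- confusion fixture
def synth_confusion_fixture(
    shape: tuple[int, int], seed: int
) -> tuple[np.ndarray, VarianceImage, np.ndarray]:
    """Label map with a BLC region whose variance rendering is the light-green
    equal yellow/green mixture (Vr/Vg = 0.5, Vb = 0), plus the ground-truth
    corrected map in which that region is relabeled NEC."""
    rng = np.random.default_rng(seed)
    h, w = shape
    labels = np.full(shape, TUM, dtype=np.uint8)
    nec = Rect(0, 0, max(2, h // 5), w)
    nec.paint(labels, NEC)
    radius = max(3, min(h, w) // 5)
    row = int(rng.integers(h // 2 - h // 8, h // 2 + h // 8 + 1))
    col = int(rng.integers(w // 2 - w // 8, w // 2 + w // 8 + 1))
    disc = Disc(row, col, radius)
    disc.paint(labels, BLC)
    # Equal variance mass on BLC (green) and NEC (yellow) renders (0.5, 1, 0).
    rgb = np.zeros((h, w, 3))
    region = labels == BLC
    rgb[region] = (0.5, 1.0, 0.0)
    expected = labels.copy()
    expected[region] = NEC
    return labels, VarianceImage(rgb=rgb), expected


# ------------------------------------------------------------------- cohort
@dataclass(frozen=True)
class EffectSizes:
    """Planted responder-vs-non-responder mean shifts.

    The values are differences applied to the treated sample's composition
    relative to its isotype: relative tumor fraction decrease, relative
    necrosis increase, multiplicative tissue-area change and CD45-positive
    fraction shift for responders (non-responders move mildly the other way).
    ``scaled`` multiplies all four by one factor.
    """

    tum_rel: float = 0.20
    nec_rel: float = 0.15
    area: float = 0.25
    cd45: float = 0.10

    @classmethod
    def scaled(cls, factor: float) -> "EffectSizes":
        base = cls()
        return cls(
            tum_rel=base.tum_rel * factor,
            nec_rel=base.nec_rel * factor,
            area=base.area * factor,
            cd45=base.cd45 * factor,
        )


@dataclass(frozen=True)
class CohortSample:
    model_id: str
    treatment: str
    response: str
    tissue_map: np.ndarray
    cd45: CD45Patch


@dataclass
class SMTCohort:
    """Per-tumor-model groups of one isotype plus treated samples."""

    samples: list[CohortSample]

    def __post_init__(self) -> None:
        for mid in {s.model_id for s in self.samples}:
            isotypes = [
                s for s in self.samples if s.model_id == mid and s.treatment == "isotype"
            ]
            if len(isotypes) != 1:
                raise ValueError(f"model {mid} must have exactly one isotype sample")
            if isotypes[0].response != "not_applicable":
                raise ValueError("isotype samples must have response=not_applicable")

    def __len__(self) -> int:
        return len(self.samples)

    def treated(self) -> list[CohortSample]:
        return [s for s in self.samples if s.treatment != "isotype"]

    def isotype_of(self, model_id: str) -> CohortSample:
        for s in self.samples:
            if s.model_id == model_id and s.treatment == "isotype":
                return s
        raise KeyError(f"model {model_id} has no isotype sample")


_BASE_REL = {TUM: 0.52, MST: 0.20, NEC: 0.12, BLC: 0.06, VAC: 0.05, MUS: 0.05}


def _composition_map(
    fractions: dict[int, float],
    tissue_fraction: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Label map with *exact* planted pixel counts.

    Background occupies the outermost pixels of a noisy radial field; the
    tissue pixels are partitioned among the main classes along a smoothed
    noise field, giving contiguous blobs whose areas equal the planted counts
    exactly (the recovery oracle for the meta-feature stage)."""
    h, w = shape
    n = h * w
    yy, xx = np.mgrid[:h, :w]
    radial = np.hypot((yy - (h - 1) / 2) / h, (xx - (w - 1) / 2) / w)
    radial = radial + 0.03 * gaussian_filter(rng.standard_normal(shape), 3.0)
    n_tissue = int(round(np.clip(tissue_fraction, 0.05, 1.0) * n))
    order = np.argsort(radial.ravel())
    labels = np.full(n, BGR, dtype=np.uint8)
    tissue_idx = order[:n_tissue]
    field = gaussian_filter(rng.standard_normal(shape), 3.0).ravel()[tissue_idx]
    tissue_order = tissue_idx[np.argsort(field)]
    counts = {c: int(round(f * n_tissue)) for c, f in fractions.items()}
    # fix rounding drift on the largest class
    drift = n_tissue - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    pos = 0
    for c in MAIN_CLASSES:
        k = counts.get(c, 0)
        labels[tissue_order[pos : pos + k]] = c
        pos += k
    return labels.reshape(shape)


def synth_smt_cohort(
    n_models: int,
    effect: EffectSizes | float = EffectSizes(),
    seed: int = 0,
    map_shape: tuple[int, int] = (64, 64),
    cd45_shape: tuple[int, int] = (48, 48),
    responder_prob: float = 0.5,
) -> SMTCohort:
    """Generate an SMT cohort with a planted responder effect.

    Each of ``n_models`` tumor models contributes one isotype plus the three
    treated arms (anti-PD-L1, anti-CTLA4, combination), so 17 models yield 68
    samples.  Treated samples are responders with probability
    ``responder_prob``; responders get the composition shifts of ``effect``
    (plus per-sample noise), non-responders drift mildly in the opposite
    direction.  With a zero effect the two groups are statistically identical
    and downstream classification is at chance.
    """
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    if isinstance(effect, (int, float)):
        effect = EffectSizes.scaled(float(effect))
    rng = np.random.default_rng(seed)
    samples: list[CohortSample] = []
    for m in range(n_models):
        mid = f"M{m + 1:02d}"
        rel0 = {
            c: max(0.01, _BASE_REL[c] + rng.normal(0.0, 0.02)) for c in MAIN_CLASSES
        }
        norm = sum(rel0.values())
        rel0 = {c: v / norm for c, v in rel0.items()}
        tissue0 = rng.uniform(0.55, 0.75)
        cd45_0 = rng.uniform(0.15, 0.30)
        iso_map = _composition_map(rel0, tissue0, map_shape, rng)
        iso_cd45 = synth_cd45_patch(
            cd45_shape, cd45_0, seed=int(rng.integers(2**31))
        )
        samples.append(CohortSample(mid, "isotype", "not_applicable", iso_map, iso_cd45))
        for arm in TREATED:
            responder = rng.random() < responder_prob
            if responder:
                d_tum = -effect.tum_rel + rng.normal(0.0, 0.03)
                d_nec = effect.nec_rel + rng.normal(0.0, 0.03)
                area_mul = (1.0 - effect.area) + rng.normal(0.0, 0.05)
                d_cd45 = effect.cd45 + rng.normal(0.0, 0.03)
            else:
                d_tum = 0.3 * effect.tum_rel + rng.normal(0.0, 0.03)
                d_nec = -0.3 * effect.nec_rel + rng.normal(0.0, 0.03)
                area_mul = (1.0 + 0.5 * effect.area) + rng.normal(0.0, 0.05)
                d_cd45 = -0.5 * effect.cd45 + rng.normal(0.0, 0.03)
            rel = dict(rel0)
            rel[TUM] = max(0.01, rel0[TUM] + d_tum)
            rel[NEC] = max(0.01, rel0[NEC] + d_nec)
            norm = sum(rel.values())
            rel = {c: v / norm for c, v in rel.items()}
            tissue = float(np.clip(tissue0 * max(area_mul, 0.1), 0.05, 0.95))
            cd45_f = float(np.clip(cd45_0 + d_cd45, 0.0, 0.9))
            tmap = _composition_map(rel, tissue, map_shape, rng)
            cpatch = synth_cd45_patch(
                cd45_shape, cd45_f, seed=int(rng.integers(2**31))
            )
            samples.append(
                CohortSample(
                    mid,
                    arm,
                    "responder" if responder else "non_responder",
                    tmap,
                    cpatch,
                )
            )
    return SMTCohort(samples)


# ----------------------------------------------------------------- file I/O
def save_tissue_sample(
    image: np.ndarray, annotation: np.ndarray, prefix: str
) -> tuple[str, str]:
    """Write a paired RGB PNG and single-channel 8-bit label PNG."""
    import imageio.v3 as iio

    img_path, ann_path = f"{prefix}_image.png", f"{prefix}_labels.png"
    iio.imwrite(img_path, (np.clip(image, 0, 1) * 255).astype(np.uint8))
    iio.imwrite(ann_path, annotation.astype(np.uint8))
    return img_path, ann_path


def save_cohort(cohort: SMTCohort, directory: str) -> str:
    """Write cohort maps/patches as PNG plus a metadata CSV; returns CSV path."""
    import imageio.v3 as iio
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.samples:
        stem = f"{s.model_id}_{s.treatment}"
        tissue = d / f"{stem}_tissue.png"
        cd45 = d / f"{stem}_cd45.png"
        iio.imwrite(tissue, s.tissue_map.astype(np.uint8))
        iio.imwrite(cd45, (np.clip(s.cd45.image, 0, 1) * 255).astype(np.uint8))
        rows.append(
            {
                "model_id": s.model_id,
                "treatment": s.treatment,
                "response": s.response,
                "tissue_path": tissue.name,
                "cd45_path": cd45.name,
            }
        )
    csv_path = d / "cohort.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return str(csv_path)
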