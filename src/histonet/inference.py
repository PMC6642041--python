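"""Whole-image prediction: foreground selection, overlapping tiling,
stochastic multi-sample inference, blended merging and color rendering.

Large mosaics are processed tile by tile on a grid whose patches overlap by
25%.  Each tile is predicted several times with Alpha-Dropout active; the
per-pixel mean of the sampled probability maps is the prediction and their
per-class variance quantifies uncertainty.  Tiles are merged with separable
triangular (tent) blending windows, normalized so the weights over every
pixel sum to one.  The variance map is rendered by mixing the class display
colors weighted by per-class variance — e.g. a pixel whose variance splits
equally between the green BLC and yellow NEC classes renders light green
with Vr/Vg = 0.5 and Vb = 0, the signature the systematic BLC-NEC confusion
correction keys on (:mod:`histonet.correction`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .palette import ClassPalette, make_palette

__all__ = [
    "TileBox",
    "MeanVarMaps",
    "VarianceImage",
    "foreground_mask",
    "tile_grid",
    "predict_stochastic",
    "merge_tiles",
    "blend_weights",
    "argmax_labels",
    "render_maps",
    "predict_image",
]


@dataclass(frozen=True)
class TileBox:
    """Half-open pixel box [row0, row0+height) x [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


@dataclass
class MeanVarMaps:
    """Per-pixel class probability mean and variance, channel-first (C, H, W)."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and var must share shape")


@dataclass
class VarianceImage:
    """Class-color rendering of the variance map; channels in [0, 1]."""

    rgb: np.ndarray

    @property
    def vr(self) -> np.ndarray:
        return self.rgb[..., 0]

    @property
    def vg(self) -> np.ndarray:
        return self.rgb[..., 1]

    @property
    def vb(self) -> np.ndarray:
        return self.rgb[..., 2]


def foreground_mask(image: np.ndarray, min_object_px: int = 64) -> np.ndarray:
    """Tissue mask: Otsu threshold on luminance (tissue is darker than the
    bright slide background) followed by removal of small components."""
    img = np.asarray(image, dtype=np.float64)
    gray = rgb2gray(img) if img.ndim == 3 else img
    if np.ptp(gray) < 1e-9:
        return np.zeros(gray.shape, dtype=bool)
    thr = threshold_otsu(gray)
    mask = gray < thr
    try:
        return remove_small_objects(mask, max_size=min_object_px - 1)
    except TypeError:  # older scikit-image spells the size cutoff min_size
        return remove_small_objects(mask, min_size=min_object_px)


def tile_grid(
    height: int,
    width: int,
    patch_size: int,
    overlap_fraction: float = 0.25,
) -> list[TileBox]:
    """Grid of equally sized boxes overlapping by ``overlap_fraction``.

    The stride is ``round(patch_size * (1 - overlap_fraction))``; boxes start
    at stride multiples and the final box per axis is clamped to end exactly
    at the image border, so the union always covers the image.
    """
    if patch_size > min(height, width):
        raise ValueError("patch_size exceeds the image dimensions")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    stride = max(1, round(patch_size * (1.0 - overlap_fraction)))

    def _starts(extent: int) -> list[int]:
        starts = list(range(0, extent - patch_size + 1, stride))
        if starts[-1] != extent - patch_size:
            starts.append(extent - patch_size)
        return starts

    return [
        TileBox(r, c, patch_size, patch_size)
        for r in _starts(height)
        for c in _starts(width)
    ]


def predict_stochastic(
    model, patch: np.ndarray, n_samples: int = 5, seed: int = 0
) -> MeanVarMaps:
    """Mean and per-class variance over dropout-active forward passes.

    Sample k uses seed ``seed + k`` so runs are reproducible.  With a single
    sample or a dropout-free model the variance is identically zero.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    stochastic = model.config.dropout_rate > 0
    samples = []
    for k in range(n_samples):
        probs, _ = model.forward(patch, stochastic=stochastic, rng=seed + k)
        samples.append(probs[0].astype(np.float64))
    stack = np.stack(samples)
    return MeanVarMaps(mean=stack.mean(axis=0), var=stack.var(axis=0, ddof=0))


def _tent(patch: int, at_low_border: bool, at_high_border: bool) -> np.ndarray:
    """Strictly positive triangular window, flattened on image-border sides."""
    i = np.arange(patch, dtype=np.float64)
    t = np.minimum(i + 1.0, patch - i)
    peak = t.max()
    if at_low_border:
        t[: int(np.argmax(t))] = peak
    if at_high_border:
        t[int(np.argmax(t)) :] = peak
    return t / peak


def blend_weights(boxes: list[TileBox], shape: tuple[int, int]) -> np.ndarray:
    """(n_boxes, H, W) blending weights; over each covered pixel they sum to 1.

    Raises if any pixel is uncovered.
    """
    h, w = shape
    fields = np.zeros((len(boxes), h, w))
    for i, b in enumerate(boxes):
        wr = _tent(b.height, b.row0 == 0, b.row0 + b.height == h)
        wc = _tent(b.width, b.col0 == 0, b.col0 + b.width == w)
        fields[i][b.slices] = np.outer(wr, wc)
    total = fields.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("tile boxes do not cover the image")
    return fields / total


def merge_tiles(
    tile_maps: list[MeanVarMaps],
    boxes: list[TileBox],
    shape: tuple[int, int],
) -> MeanVarMaps:
    """Blend per-tile mean/variance maps into full-image maps.

    Weights form a partition of unity, so constant tiles merge to the same
    constant and merged means stay on the probability simplex.
    """
    if len(tile_maps) != len(boxes):
        raise ValueError("one MeanVarMaps per box required")
    weights = blend_weights(boxes, shape)
    c = tile_maps[0].mean.shape[0]
    mean = np.zeros((c,) + tuple(shape))
    var = np.zeros_like(mean)
    for mv, box, wf in zip(tile_maps, boxes, weights):
        wtile = wf[box.slices]
        mean[(slice(None),) + box.slices] += wtile * mv.mean
        var[(slice(None),) + box.slices] += wtile * mv.var
    return MeanVarMaps(mean=mean, var=var)


def argmax_labels(mean: np.ndarray) -> np.ndarray:
    """Per-pixel argmax label; exact ties resolve to the lowest class id."""
    m = np.asarray(mean)
    if m.ndim != 3:
        raise ValueError("expected a (C, H, W) probability map")
    return m.argmax(axis=0).astype(np.uint8)


def render_maps(
    maps: MeanVarMaps, palette: ClassPalette | None = None
) -> tuple[np.ndarray, VarianceImage]:
    """Render the tissue map and the class-colored variance image.

    The tissue image is the palette color of the per-pixel argmax label.  The
    variance image sums each class's display color weighted by its variance
    and normalizes by the image-wide maximum channel value, so channel
    *ratios* (which the BLC-NEC correction thresholds) are independent of the
    overall variance scale.  A variance-free image renders black.
    """
    palette = palette or make_palette()
    labels = argmax_labels(maps.mean)
    tissue_rgb = palette.colors[labels]
    mixed = np.einsum("chw,ck->hwk", maps.var, palette.colors)
    peak = mixed.max()
    rgb = mixed / peak if peak > 0 else np.zeros_like(mixed)
    return tissue_rgb, VarianceImage(rgb=rgb)


def predict_image(
    model,
    image: np.ndarray,
    patch_size: int,
    overlap_fraction: float = 0.25,
    n_samples: int = 5,
    seed: int = 0,
) -> MeanVarMaps:
    """Tile a mosaic, predict each tile stochastically and merge the results."""
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape[:2]
    boxes = tile_grid(h, w, patch_size, overlap_fraction)
    tiles = [
        predict_stochastic(
            model, img[b.slices], n_samples=n_samples, seed=seed + 1009 * i
        )
        for i, b in enumerate(boxes)
    ]
    return merge_tiles(tiles, boxes, (h, w))
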