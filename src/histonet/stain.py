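"""Stain handling: Reinhard color normalization, principal-component stain
augmentation, and two-stain optical-density decomposition for CD45 slides.

Reinhard normalization matches per-channel mean and standard deviation of an
image to a target in the decorrelated log-space color representation
(RGB -> LMS -> log10 -> l-alpha-beta).  The forward and inverse transforms are
implemented explicitly below.

Stain augmentation shifts pixels along the principal components of the RGB
scatter of the training data, so a network sees the same patch under
plausible stain variations.

CD45 immunohistochemistry patches carry two stains: a hematoxylin blue
counterstain and diaminobenzidine (DAB) brown marking CD45-positive cells.
``destain_cd45`` separates them by principal-component analysis of the
optical-density pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StainStats",
    "StainBasis",
    "color_stats",
    "reinhard_normalize",
    "stain_basis",
    "augment_stain",
    "destain_cd45",
    "rgb_to_lab",
    "lab_to_rgb",
]

# Ruderman et al. RGB->LMS mixing matrix used by the Reinhard method.
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_S3, _S6, _S2 = 1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)
_LOGLMS2LAB = np.array(
    [
        [_S3, _S3, _S3],
        [_S6, _S6, -2.0 * _S6],
        [_S2, -_S2, 0.0],
    ]
)
_LAB2LOGLMS = np.linalg.inv(_LOGLMS2LAB)
_LMS_FLOOR = 1e-4  # keeps log finite on black pixels
_STD_EPS = 1e-6

# Reference stain optical-density unit vectors (Ruifrok & Johnston):
# used only to assign/orient the data-driven components deterministically.
_HEM_OD = np.array([0.650, 0.704, 0.286])
_HEM_OD /= np.linalg.norm(_HEM_OD)
_DAB_OD = np.array([0.268, 0.570, 0.776])
_DAB_OD /= np.linalg.norm(_DAB_OD)


@dataclass(frozen=True)
class StainStats:
    """Per-channel mean and standard deviation in l-alpha-beta space."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.std):
            raise ValueError("std components must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"mean": self.mean, "std": self.std}))

    @classmethod
    def from_json(cls, path: str | Path) -> "StainStats":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["mean"]), tuple(d["std"]))


@dataclass(frozen=True)
class StainBasis:
    """Principal color directions of an RGB pixel scatter.

    ``components`` rows are orthonormal and ordered by descending
    ``explained_variance``; ``origin`` is the mean RGB value.
    """

    components: np.ndarray
    origin: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float)
        if c.shape != (3, 3) or not np.allclose(c @ c.T, np.eye(3), atol=1e-6):
            raise ValueError("components must be an orthonormal 3x3 matrix")
        ev = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained_variance must be sorted descending")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "components": np.asarray(self.components).tolist(),
                    "origin": np.asarray(self.origin).tolist(),
                    "explained_variance": np.asarray(self.explained_variance).tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "StainBasis":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["components"]),
            np.asarray(d["origin"]),
            np.asarray(d["explained_variance"]),
        )


# ------------------------------------------------------------- color spaces
def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """RGB in [0,1] -> l-alpha-beta (Ruderman log space)."""
    lms = np.asarray(image, dtype=np.float64) @ _RGB2LMS.T
    loglms = np.log10(np.maximum(lms, _LMS_FLOOR))
    return loglms @ _LOGLMS2LAB.T


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    loglms = np.asarray(lab, dtype=np.float64) @ _LAB2LOGLMS.T
    rgb = np.power(10.0, loglms) @ _LMS2RGB.T
    return np.clip(rgb, 0.0, 1.0)


# ------------------------------------------------------------------ Reinhard
def color_stats(image: np.ndarray, mask: np.ndarray | None = None) -> StainStats:
    """Channel-wise mean/std of the image in l-alpha-beta space.

    ``mask`` restricts the statistics to selected pixels (e.g. the foreground
    mask, so slide background does not dominate).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("image is empty")
    lab = rgb_to_lab(img).reshape(-1, 3)
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if not m.any():
            raise ValueError("mask selects no pixels")
        lab = lab[m]
    mean = lab.mean(axis=0)
    std = lab.std(axis=0)
    return StainStats(tuple(mean.tolist()), tuple(std.tolist()))


def reinhard_normalize(
    image: np.ndarray, source: StainStats, target: StainStats
) -> np.ndarray:
    """Shift/scale each l-alpha-beta channel from source to target statistics.

    Channels whose source std is below 1e-6 are shifted only (scale 1), which
    keeps near-constant tiles stable.  Output is clipped to valid RGB.
    """
    lab = rgb_to_lab(image)
    mu_s = np.asarray(source.mean)
    sd_s = np.asarray(source.std)
    mu_t = np.asarray(target.mean)
    sd_t = np.asarray(target.std)
    scale = np.where(sd_s > _STD_EPS, sd_t / np.maximum(sd_s, _STD_EPS), 1.0)
    out = (lab - mu_s) * scale + mu_t
    return lab_to_rgb(out)


# ------------------------------------------------------- principal components
def stain_basis(pixels: np.ndarray) -> StainBasis:
    """Principal axes of an RGB pixel scatter, descending variance.

    Degenerate scatters (fewer than three non-collinear pixels) are padded
    with an arbitrary orthogonal completion; the corresponding explained
    variances are zero.
    """
    pix = np.asarray(pixels, dtype=np.float64).reshape(-1, 3)
    if pix.shape[0] == 0:
        raise ValueError("need at least one pixel")
    origin = pix.mean(axis=0)
    centered = pix - origin
    cov = centered.T @ centered / pix.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # always an orthonormal 3x3 basis
    order = np.argsort(evals)[::-1]
    ev = np.maximum(evals[order], 0.0)
    return StainBasis(evecs[:, order].T, origin, ev)


def augment_stain(
    image: np.ndarray,
    basis: StainBasis,
    magnitudes: tuple[float, float, float],
    seed: int | None = None,
) -> np.ndarray:
    """Shift the whole patch along the principal color components.

    Each component k receives a draw ``uniform(-m_k, +m_k)`` expressed in
    standard deviations of the fitted basis; the summed RGB shift is applied
    to every pixel and the result clipped to [0, 1].
    """
    mags = np.asarray(magnitudes, dtype=np.float64)
    if np.any(mags < 0):
        raise ValueError("magnitudes must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.maximum(np.asarray(basis.explained_variance), 0.0))
    delta = rng.uniform(-mags, mags) * sigma
    shift = delta @ np.asarray(basis.components)
    return np.clip(np.asarray(image, dtype=np.float64) + shift, 0.0, 1.0)


# ------------------------------------------------------------------- destain
def _optical_density(image: np.ndarray) -> np.ndarray:
    i255 = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0) * 255.0
    return -np.log10((i255 + 1.0) / 256.0)


def destain_cd45(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a two-stain CD45 patch into counterstain and positive maps.

    Pixels are converted to optical density and the two leading principal
    color components (PCA about zero OD — concentrations are non-negative, so
    zero absorbance is the natural origin) are extracted.  Each component is
    assigned to hematoxylin (counterstain) or DAB (positive stain) by cosine
    similarity to fixed reference stain vectors and oriented towards its
    reference, making the channel assignment deterministic.  The returned
    maps are the non-negative projections onto the assigned components.

    Returns
    -------
    counterstain, positive : (H, W) float arrays, >= 0
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    od = _optical_density(img).reshape(-1, 3)
    # Uncentered PCA: eigenvectors of the OD second-moment matrix.
    second = od.T @ od / od.shape[0]
    evals, evecs = np.linalg.eigh(second)
    order = np.argsort(evals)[::-1]
    u1, u2 = evecs[:, order[0]], evecs[:, order[1]]
    # Pair the two components with the two reference stains.
    direct = abs(u1 @ _HEM_OD) + abs(u2 @ _DAB_OD)
    swapped = abs(u1 @ _DAB_OD) + abs(u2 @ _HEM_OD)
    if direct >= swapped:
        u_cs, u_pos = u1, u2
    else:
        u_cs, u_pos = u2, u1
    if u_cs @ _HEM_OD < 0:
        u_cs = -u_cs
    if u_pos @ _DAB_OD < 0:
        u_pos = -u_pos
    h, w = img.shape[:2]
    counterstain = np.maximum(od @ u_cs, 0.0).reshape(h, w)
    positive = np.maximum(od @ u_pos, 0.0).reshape(h, w)
    return counterstain, positive
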