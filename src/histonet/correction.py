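"""Automated relabeling of the systematic BLC-NEC confusion.

When the stochastic predictor is unsure between blood cells/vessels (BLC,
green) and necrosis (NEC, yellow) — as happens over hemorrhagic areas — the
class-colored variance map turns light green: equal variance mass on the two
classes gives channel ratio r = Vr/Vg = 0.5 with Vb = 0, exactly.  The
correction selects pixels with r in (r_min, r_max) and near-zero blue
variance, smooths the selection with a Gaussian blur so the relabeled region
blends into the tissue map, and sets the selected pixels to NEC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .inference import VarianceImage
from .palette import NEC

__all__ = ["CorrectionParams", "correct_blc_nec"]


@dataclass(frozen=True)
class CorrectionParams:
    """Thresholds of the light-green selection rule.

    ``r_min``/``r_max`` bound the red-to-green ratio r = Vr/Vg around the
    ideal 0.5 of an equal yellow/green mixture; ``blue_max`` quantifies
    "Vb close to zero" on the normalized variance rendering; ``sigma`` is the
    blur width in pixels and ``mask_threshold`` the cut on the blurred mask.
    """

    r_min: float = 0.35
    r_max: float = 0.7
    blue_max: float = 0.1
    sigma: float = 5.0
    mask_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min < self.r_max:
            raise ValueError("need 0 <= r_min < r_max")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.mask_threshold < 1.0:
            raise ValueError("mask_threshold must lie in (0, 1)")


def correct_blc_nec(
    labels: np.ndarray,
    variance: VarianceImage | np.ndarray,
    params: CorrectionParams = CorrectionParams(),
) -> np.ndarray:
    """Relabel light-green variance regions of the tissue map to NEC.

    Pixels with Vg = 0 are never selected (the ratio is undefined and
    "light green" requires green).  The returned map differs from ``labels``
    only where the blurred selection reaches ``mask_threshold``, and only by
    transitions to the NEC class.
    """
    rgb = variance.rgb if isinstance(variance, VarianceImage) else np.asarray(variance)
    labels = np.asarray(labels)
    if rgb.shape[:2] != labels.shape:
        raise ValueError("labels and variance image must share spatial shape")
    vr, vg, vb = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    sel = (vg > 0) & (vb <= params.blue_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(vg > 0, vr / np.where(vg > 0, vg, 1.0), np.inf)
    sel &= (r > params.r_min) & (r < params.r_max)
    blurred = gaussian_filter(sel.astype(np.float64), params.sigma)
    out = labels.copy()
    out[blurred >= params.mask_threshold] = NEC
    return out
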