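"""HistoNet: a compact residual-bottleneck semantic segmentation network.

The encoder is a stack of *reduce* blocks (strided 3x3 convolution,
Alpha-Dropout, SELU) each followed by residual *bottleneck* blocks
(1x1 compress -> 3x3 convolve -> 1x1 expand, residual add, SELU).  Two output
heads share the encoder:

* a **semantic head** that compresses every feature level with a 1x1
  convolution, bilinearly upsamples each to input resolution, concatenates
  them and classifies per pixel into the eight tissue classes (softmax map);
* a **distribution head** that global-average-pools the deepest features and
  predicts the normalized tissue-class distribution of the whole patch.

Training minimizes the unweighted sum of three objectives: per-pixel
categorical cross-entropy, a dice-distance loss averaged over the classes
present in the annotation, and the mean squared error between the predicted
and true patch-level tissue distributions,

    L = L_CCE + L_DDL + L_MSE.

Because Alpha-Dropout sits in the encoder, the same trained network yields a
stochastic predictor at inference time: repeated dropout-active forward
passes sample plausible segmentations, whose per-pixel variance highlights
uncertain regions (see :mod:`histonet.inference`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from . import stain as stain_mod
from .layers import (
    Adam,
    AlphaDropout,
    BilinearUpsample,
    Conv2d,
    Dense,
    SELU,
    softmax,
    softmax_backward,
)
from .palette import N_CLASSES

__all__ = [
    "NetConfig",
    "TrainConfig",
    "LossBreakdown",
    "HistoNet",
    "build_model",
    "forward",
    "true_distribution",
    "loss_total",
    "train",
    "save_model",
    "load_model",
    "TrainingDivergedError",
]

_EPS_CCE = 1e-7
_EPS_DICE = 1e-6


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``levels`` reduce stages halve the spatial resolution each, so input
    patches must have sides divisible by ``2**levels``.  ``compression_widths``
    sets the per-level channel count of the semantic head and balances coarse
    against detailed information.
    """

    in_channels: int = 3
    n_classes: int = N_CLASSES
    levels: int = 4
    base_width: int = 32
    bottleneck_factor: int = 4
    blocks_per_level: int = 2
    compression_widths: tuple[int, ...] = (8, 12, 16, 24)
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if len(self.compression_widths) != self.levels:
            raise ValueError("compression_widths needs exactly `levels` entries")
        if min(self.compression_widths) < 1 or self.base_width < 1:
            raise ValueError("all widths must be >= 1")
        if self.bottleneck_factor < 1 or self.blocks_per_level < 1:
            raise ValueError("bottleneck_factor and blocks_per_level must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay: float = 1e-6
    batch_size: int = 4
    epochs: int = 10
    seed: int = 0
    l2_regularization: bool = True
    augment: bool = True
    translate_max: int = 4
    stain_magnitude: float = 0.5
    stain_augment: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


@dataclass(frozen=True)
class LossBreakdown:
    """The three loss terms (nats / dice distance / squared error) and their sum."""

    cce: float
    ddl: float
    mse: float

    @property
    def total(self) -> float:
        return self.cce + self.ddl + self.mse


class _Bottleneck:
    """Residual compress-convolve-expand block concluded by SELU."""

    def __init__(self, width: int, factor: int, rng: np.random.Generator) -> None:
        mid = max(1, width // factor)
        self.c1 = Conv2d(width, mid, 1, rng=rng)
        self.s1 = SELU()
        self.c2 = Conv2d(mid, mid, 3, pad=1, rng=rng)
        self.s2 = SELU()
        self.c3 = Conv2d(mid, width, 1, rng=rng)
        self.s3 = SELU()

    def params(self):
        return self.c1.params() + self.c2.params() + self.c3.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        r = self.c3.forward(self.s2.forward(self.c2.forward(self.s1.forward(self.c1.forward(x)))))
        return self.s3.forward(x + r)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.s3.backward(g)
        gr = self.c1.backward(self.s1.backward(self.c2.backward(self.s2.backward(self.c3.backward(g)))))
        return g + gr


class HistoNet:
    """The segmentation model; see the module docstring for the topology."""

    def __init__(self, config: NetConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.reduces: list[Conv2d] = []
        self.dropouts: list[AlphaDropout] = []
        self.reduce_selus: list[SELU] = []
        self.blocks: list[list[_Bottleneck]] = []
        cin = config.in_channels
        for lvl in range(config.levels):
            width = config.base_width * 2**lvl
            self.reduces.append(Conv2d(cin, width, 3, stride=2, pad=1, rng=rng))
            self.reduce_selus.append(SELU())
            self.dropouts.append(AlphaDropout(config.dropout_rate))
            self.blocks.append(
                [
                    _Bottleneck(width, config.bottleneck_factor, rng)
                    for _ in range(config.blocks_per_level)
                ]
            )
            cin = width
        self.compress: list[Conv2d] = [
            Conv2d(config.base_width * 2**lvl, cw, 1, rng=rng)
            for lvl, cw in enumerate(config.compression_widths)
        ]
        self.classifier = Conv2d(sum(config.compression_widths), config.n_classes, 1, rng=rng)
        self.dist_head = Dense(config.base_width * 2 ** (config.levels - 1), config.n_classes, rng=rng)
        self._ups: list[BilinearUpsample] = []
        self._deep_hw: tuple[int, int] | None = None

    # ------------------------------------------------------------------ utils
    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        ps: list[tuple[np.ndarray, np.ndarray]] = []
        for lvl in range(self.config.levels):
            ps += self.reduces[lvl].params()
            for blk in self.blocks[lvl]:
                ps += blk.params()
        for c in self.compress:
            ps += c.params()
        ps += self.classifier.params()
        ps += self.dist_head.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(w.size for w, _ in self.parameters()))

    # ---------------------------------------------------------------- forward
    def forward(
        self,
        x: np.ndarray,
        stochastic: bool = False,
        rng: np.random.Generator | int | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Run the network.

        Parameters
        ----------
        x:
            ``(H, W, 3)`` image in [0, 1] or an ``(N, 3, H, W)`` batch.
        stochastic:
            If True, Alpha-Dropout is active and the prediction is a sample;
            otherwise the pass is deterministic.
        rng:
            Seed or Generator for the dropout masks (stochastic mode only).

        Returns
        -------
        probs : (N, n_classes, H, W) per-pixel class probabilities
        dist : (N, n_classes) predicted patch tissue distribution
        """
        x = _as_batch(x, self.config.in_channels)
        h, w = x.shape[2], x.shape[3]
        div = 2**self.config.levels
        if h % div or w % div:
            raise ValueError(
                f"spatial dims ({h}, {w}) must be divisible by 2^levels = {div}"
            )
        drop_rng: np.random.Generator | None = None
        if stochastic and self.config.dropout_rate > 0:
            drop_rng = (
                rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
            )
        feats: list[np.ndarray] = []
        cur = x.astype(np.float32)
        for lvl in range(self.config.levels):
            cur = self.reduces[lvl].forward(cur)
            cur = self.dropouts[lvl].forward(cur, drop_rng)
            cur = self.reduce_selus[lvl].forward(cur)
            for blk in self.blocks[lvl]:
                cur = blk.forward(cur)
            feats.append(cur)
        self._ups = [BilinearUpsample((h, w)) for _ in range(self.config.levels)]
        heads = [
            self._ups[lvl].forward(self.compress[lvl].forward(feats[lvl]))
            for lvl in range(self.config.levels)
        ]
        cat = np.concatenate(heads, axis=1)
        z_sem = self.classifier.forward(cat)
        probs = softmax(z_sem, axis=1)
        deep = feats[-1]
        self._deep_hw = deep.shape[2:]
        pooled = deep.mean(axis=(2, 3))
        z_dist = self.dist_head.forward(pooled)
        dist = softmax(z_dist, axis=1)
        self._probs, self._dist = probs, dist
        return probs, dist

    def backward(self, gz_sem: np.ndarray, gz_dist: np.ndarray) -> None:
        """Backpropagate gradients w.r.t. the two heads' logits."""
        cfg = self.config
        g_pooled = self.dist_head.backward(gz_dist)
        dh, dw = self._deep_hw
        g_deep = np.broadcast_to(
            g_pooled[:, :, None, None] / (dh * dw),
            (g_pooled.shape[0], g_pooled.shape[1], dh, dw),
        ).astype(np.float32)
        g_cat = self.classifier.backward(gz_sem)
        g_feats: list[np.ndarray] = []
        off = 0
        for lvl in range(cfg.levels):
            cw = cfg.compression_widths[lvl]
            g_head = g_cat[:, off : off + cw]
            off += cw
            g_feats.append(self.compress[lvl].backward(self._ups[lvl].backward(g_head)))
        g = g_feats[-1] + g_deep
        for lvl in reversed(range(cfg.levels)):
            for blk in reversed(self.blocks[lvl]):
                g = blk.backward(g)
            g = self.reduce_selus[lvl].backward(g)
            g = self.dropouts[lvl].backward(g)
            g = self.reduces[lvl].backward(g)
            if lvl > 0:
                g = g + g_feats[lvl - 1]


def _as_batch(x: np.ndarray, in_channels: int = 3) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 3 and x.shape[-1] == in_channels:
        x = x.transpose(2, 0, 1)[None]
    elif x.ndim == 3 and x.shape[0] == in_channels:
        x = x[None]
    if x.ndim != 4 or x.shape[1] != in_channels:
        raise ValueError(f"expected an RGB patch or (N,{in_channels},H,W) batch")
    return x


def build_model(config: NetConfig) -> HistoNet:
    """Construct a :class:`HistoNet` with reproducible initial weights."""
    return HistoNet(config)


def forward(
    model: HistoNet,
    patch: np.ndarray,
    stochastic: bool = False,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Functional alias for :meth:`HistoNet.forward`."""
    return model.forward(patch, stochastic=stochastic, rng=seed)


# --------------------------------------------------------------------- losses
def true_distribution(annotation: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Normalized class histogram of a label map (the patch tissue distribution)."""
    ann = np.asarray(annotation)
    if ann.size == 0:
        raise ValueError("empty annotation map")
    if ann.min() < 0 or ann.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.bincount(ann.ravel(), minlength=n_classes).astype(np.float64)
    return counts / counts.sum()


def _one_hot(ann: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float32)[ann].transpose(0, 3, 1, 2)


def _loss_terms(
    probs: np.ndarray, pred_dist: np.ndarray, ann: np.ndarray
) -> tuple[LossBreakdown, np.ndarray, np.ndarray]:
    """Loss values plus the gradients w.r.t. the semantic and distribution logits."""
    n, c, h, w = probs.shape
    t = _one_hot(ann, c)
    npix = n * h * w
    p_clamped = np.clip(probs, _EPS_CCE, 1.0)
    cce = float(-(t * np.log(p_clamped)).sum() / npix)
    gz_sem = (probs - t) / npix  # softmax+CCE shortcut

    # Dice distance averaged over classes present in the annotation,
    # aggregated over the whole batch.
    present = np.flatnonzero(t.sum(axis=(0, 2, 3)) > 0)
    inter = (probs * t).sum(axis=(0, 2, 3))
    sums = probs.sum(axis=(0, 2, 3)) + t.sum(axis=(0, 2, 3))
    dice = (2.0 * inter + _EPS_DICE) / (sums + _EPS_DICE)
    ddl = float(1.0 - dice[present].mean())
    g_p = np.zeros_like(probs)
    k = len(present)
    for i in present:
        num = 2.0 * inter[i] + _EPS_DICE
        den = sums[i] + _EPS_DICE
        g_p[:, i] = -(2.0 * t[:, i] * den - num) / (k * den * den)
    gz_sem = gz_sem + softmax_backward(probs, g_p, axis=1)

    true_d = np.stack([true_distribution(a, c) for a in ann]).astype(np.float64)
    diff = pred_dist - true_d
    mse = float((diff**2).mean())
    g_q = 2.0 * diff / diff.size
    gz_dist = softmax_backward(pred_dist, g_q, axis=1)
    return LossBreakdown(cce, ddl, mse), gz_sem.astype(np.float32), gz_dist


def loss_total(
    prob_map: np.ndarray, pred_dist: np.ndarray, annotation: np.ndarray
) -> LossBreakdown:
    """Evaluate the three-term loss for given predictions and annotation.

    Accepts single patches (``(C,H,W)`` map, ``(C,)`` distribution, ``(H,W)``
    labels) or batches with a leading N axis.
    """
    probs = np.asarray(prob_map, dtype=np.float64)
    dist = np.asarray(pred_dist, dtype=np.float64)
    ann = np.asarray(annotation)
    if probs.ndim == 3:
        probs, dist, ann = probs[None], dist[None], ann[None]
    if probs.shape[0] != ann.shape[0] or probs.shape[2:] != ann.shape[1:]:
        raise ValueError("prob_map and annotation shapes are inconsistent")
    lb, _, _ = _loss_terms(probs, dist, ann)
    return lb


# ------------------------------------------------------------------- training
def _augment_pair(
    img: np.ndarray,
    ann: np.ndarray,
    rng: np.random.Generator,
    cfg: TrainConfig,
    basis: "stain_mod.StainBasis | None",
) -> tuple[np.ndarray, np.ndarray]:
    """Random 90-degree rotation, flips, periodic integer translation and a
    stain shift along the principal color components.  Geometric transforms
    are applied identically to image and labels."""
    k = int(rng.integers(4))
    img, ann = np.rot90(img, k, axes=(0, 1)), np.rot90(ann, k)
    if rng.random() < 0.5:
        img, ann = img[::-1], ann[::-1]
    if rng.random() < 0.5:
        img, ann = img[:, ::-1], ann[:, ::-1]
    if cfg.translate_max > 0:
        dy, dx = rng.integers(-cfg.translate_max, cfg.translate_max + 1, size=2)
        img = np.roll(img, (dy, dx), axis=(0, 1))
        ann = np.roll(ann, (dy, dx), axis=(0, 1))
    if basis is not None and cfg.stain_magnitude > 0:
        img = stain_mod.augment_stain(
            img,
            basis,
            (cfg.stain_magnitude,) * 3,
            seed=int(rng.integers(2**31)),
        )
    return np.ascontiguousarray(img), np.ascontiguousarray(ann)


def _evaluate(
    model: HistoNet, images: np.ndarray, anns: np.ndarray, batch_size: int
) -> tuple[LossBreakdown, float]:
    """Deterministic full-dataset loss and pixelwise macro F1."""
    cces, ddls, mses, weights = [], [], [], []
    preds = []
    for i in range(0, len(images), batch_size):
        xb = images[i : i + batch_size]
        yb = anns[i : i + batch_size]
        probs, dist = model.forward(xb, stochastic=False)
        lb = loss_total(probs, dist, yb)
        cces.append(lb.cce)
        ddls.append(lb.ddl)
        mses.append(lb.mse)
        weights.append(len(xb))
        preds.append(probs.argmax(axis=1))
    wts = np.asarray(weights, dtype=float)
    lb = LossBreakdown(
        float(np.average(cces, weights=wts)),
        float(np.average(ddls, weights=wts)),
        float(np.average(mses, weights=wts)),
    )
    y_pred = np.concatenate([p.ravel() for p in preds])
    y_true = anns.ravel()
    labels = np.unique(y_true)
    f1 = f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)
    return lb, float(f1)


def train(
    model: HistoNet,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> tuple[HistoNet, pd.DataFrame]:
    """Optimize the three-term loss with Adam and L2 weight decay.

    ``dataset`` is a list of ``(image (H,W,3) in [0,1], annotation (H,W))``
    pairs of identical shape.  Per iteration each sample receives random
    geometric augmentation and a seeded stain shift along the principal color
    components of the training data.  Returns the trained model and a history
    frame with per-epoch loss terms and pixelwise macro F1, both evaluated
    deterministically on the full training set after each epoch.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    images = np.stack([np.asarray(im, dtype=np.float32) for im, _ in dataset])
    anns = np.stack([np.asarray(an) for _, an in dataset]).astype(np.int64)
    if images.ndim != 4 or images.shape[-1] != model.config.in_channels:
        raise ValueError("images must be (H, W, 3) and share one shape")
    rng = np.random.default_rng(config.seed)
    basis = None
    if config.augment and config.stain_augment:
        pix = images.reshape(-1, images.shape[-1])
        sel = rng.choice(len(pix), size=min(len(pix), 20000), replace=False)
        basis = stain_mod.stain_basis(pix[sel])
    wd = config.weight_decay if config.l2_regularization else 0.0
    opt = Adam(model.parameters(), lr=config.learning_rate, weight_decay=wd)
    rows = []
    m = len(images)
    for epoch in range(config.epochs):
        order = rng.permutation(m)
        for start in range(0, m, config.batch_size):
            idx = order[start : start + config.batch_size]
            if config.augment:
                pairs = [
                    _augment_pair(images[i], anns[i], rng, config, basis) for i in idx
                ]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs])
            else:
                xb, yb = images[idx], anns[idx]
            xb = np.ascontiguousarray(xb.transpose(0, 3, 1, 2))
            probs, dist = model.forward(xb, stochastic=True, rng=rng)
            lb, gz_sem, gz_dist = _loss_terms(
                probs.astype(np.float64), dist.astype(np.float64), yb
            )
            if not np.isfinite(lb.total):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {lb}"
                )
            opt.zero_grad()
            model.backward(gz_sem, gz_dist.astype(np.float32))
            opt.step()
        ev_x = np.ascontiguousarray(images.transpose(0, 3, 1, 2))
        lb_eval, f1 = _evaluate(model, ev_x, anns, config.batch_size)
        rows.append(
            {
                "epoch": epoch,
                "cce": lb_eval.cce,
                "ddl": lb_eval.ddl,
                "mse": lb_eval.mse,
                "total": lb_eval.total,
                "macro_f1": f1,
            }
        )
    return model, pd.DataFrame(rows)


# --------------------------------------------------------------- persistence
def save_model(model: HistoNet, path: str | Path) -> None:
    """Write weights as NPZ with a JSON sidecar carrying the architecture."""
    path = Path(path)
    arrays = {f"p{i}": w for i, (w, _) in enumerate(model.parameters())}
    np.savez(path, **arrays)
    cfg = asdict(model.config)
    cfg["compression_widths"] = list(cfg["compression_widths"])
    sidecar = path.with_suffix(path.suffix + ".json" if path.suffix != ".npz" else ".json")
    sidecar = path.with_name(path.stem + ".json")
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_model(path: str | Path) -> HistoNet:
    path = Path(path)
    sidecar = path.with_name(path.stem + ".json")
    cfg = json.loads(sidecar.read_text())
    cfg["compression_widths"] = tuple(cfg["compression_widths"])
    model = HistoNet(NetConfig(**cfg))
    data = np.load(path)
    for i, (w, _) in enumerate(model.parameters()):
        w[...] = data[f"p{i}"]
    return model
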