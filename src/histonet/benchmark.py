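"""Deep-vs-classical benchmark on the synthetic eight-class texture set.

Builds a reproducible synthetic segmentation benchmark (textured mosaics
with rectangles and discs so every class appears in boundary-rich scenes),
trains a small HistoNet on the training split, and scores both the network
(per-pixel prediction) and the classical texture baseline (patch-granularity
prediction) by pixelwise macro F1 on the held-out mosaics.  The network's
per-pixel output resolves region boundaries that a patchwise classifier
structurally cannot, which is the scaled-down analogue of the deep-vs-
classical gap on real slides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from . import baseline as baseline_mod
from .network import HistoNet, NetConfig, TrainConfig, train
from .palette import N_CLASSES
from .synthetic_data import Disc, Rect, SyntheticLayout, synth_tissue_sample

__all__ = ["BenchmarkResult", "make_benchmark_dataset", "run_benchmark"]

#: Small CPU-trainable architecture used for the synthetic benchmark.
BENCH_NET = NetConfig(
    levels=2,
    base_width=8,
    bottleneck_factor=2,
    blocks_per_level=1,
    compression_widths=(6, 8),
    dropout_rate=0.05,
)


@dataclass
class BenchmarkResult:
    network_macro_f1: float
    baseline_macro_f1: float
    history: pd.DataFrame


def _layout(tile: int, idx: int) -> SyntheticLayout:
    """Boundary-rich layout cycling the class roles with the tile index."""
    a, b, c, d = (np.arange(4) + idx) % N_CLASSES
    rim = tile // 3
    return SyntheticLayout(
        (tile, tile),
        (
            (int(a), Rect(0, 0, tile, tile)),
            (int(b), Rect(0, 0, rim, tile)),
            (int(c), Disc(2 * tile // 3, tile // 3, tile // 6)),
            (int(d), Rect(tile // 2, 2 * tile // 3, tile // 3, tile // 4)),
        ),
    )


def make_benchmark_dataset(
    n_train: int = 24,
    n_test: int = 8,
    tile: int = 96,
    seed: int = 0,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[tuple[np.ndarray, np.ndarray]]]:
    """(train, test) lists of (image, annotation) mosaics.

    Class roles rotate with the tile index so all eight classes occur in both
    splits; train and test use disjoint noise seeds.
    """
    train_set = [
        synth_tissue_sample(_layout(tile, i), seed=seed + i) for i in range(n_train)
    ]
    test_set = [
        synth_tissue_sample(_layout(tile, 3 * i + 1), seed=seed + 10_000 + i)
        for i in range(n_test)
    ]
    return train_set, test_set


def _network_f1(model: HistoNet, test_set) -> float:
    preds, truths = [], []
    for img, ann in test_set:
        probs, _ = model.forward(img, stochastic=False)
        preds.append(probs[0].argmax(axis=0).ravel())
        truths.append(ann.ravel())
    y_pred = np.concatenate(preds)
    y_true = np.concatenate(truths)
    return float(
        f1_score(y_true, y_pred, labels=np.unique(y_true), average="macro", zero_division=0)
    )


def _baseline_f1(train_set, test_set, patch_size: int, seed: int, per_class: int) -> float:
    clf = baseline_mod.fit_patch_classifier(
        [im for im, _ in train_set],
        [an for _, an in train_set],
        classifier="rbf_svm",
        patch_size=patch_size,
        seed=seed,
        per_class=per_class,
    )
    preds, truths = [], []
    for img, ann in test_set:
        lab = baseline_mod.segment_patchwise(clf, img, patch_size)
        preds.append(lab.ravel())
        truths.append(ann.ravel())
    y_pred = np.concatenate(preds)
    y_true = np.concatenate(truths)
    return float(
        f1_score(y_true, y_pred, labels=np.unique(y_true), average="macro", zero_division=0)
    )


def run_benchmark(
    seed: int = 0,
    n_train: int = 24,
    n_test: int = 8,
    tile: int = 96,
    epochs: int = 60,
    patch_size: int = 12,
    per_class: int = 150,
) -> BenchmarkResult:
    """Train the network and the baseline on the same synthetic data and
    report held-out pixelwise macro F1 for both."""
    train_set, test_set = make_benchmark_dataset(n_train, n_test, tile, seed)
    cfg = NetConfig(**{**BENCH_NET.__dict__, "seed": seed})
    model = HistoNet(cfg)
    tc = TrainConfig(epochs=epochs, batch_size=4, seed=seed)
    model, history = train(model, train_set, tc)
    net_f1 = _network_f1(model, test_set)
    base_f1 = _baseline_f1(train_set, test_set, patch_size, seed, per_class)
    return BenchmarkResult(net_f1, base_f1, history)
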