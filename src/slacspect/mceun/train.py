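"""Training for the McEUN segmenter.

Weighted cross-entropy over per-voxel six-class targets, Adam updates,
reproducible seeding, and five-fold cross-validation: each fold trains a
freshly initialized network on the remaining folds and records its
validation loss, after which the returned network is trained on the full
set with the same schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from .network import Adam, McEUN, McEUNConfig, N_CLASSES, build_mceun

__all__ = [
    "TrainLog",
    "kfold_split",
    "inverse_frequency_weights",
    "train_mceun",
    "volumes_to_slices",
]


@dataclass
class TrainLog:
    """Per-epoch losses, fold assignments and the training seed."""

    train_loss: list = field(default_factory=list)
    val_loss: dict = field(default_factory=dict)  # fold -> [per-epoch loss]
    fold_assignments: np.ndarray | None = None
    seed: int = 0


def kfold_split(n: int, folds: int = 5, seed: int = 0) -> np.ndarray:
    """Random fold assignment of ``n`` samples; fold sizes differ by <= 1."""
    if folds < 1 or folds > n:
        raise ValueError("need 1 <= folds <= n samples")
    rng = np.random.default_rng(seed)
    assign = np.arange(n) % folds
    rng.shuffle(assign)
    return assign


def inverse_frequency_weights(targets) -> np.ndarray:
    """Class weights proportional to inverse voxel frequency, normalized to
    mean 1.  Raises if any class never occurs."""
    counts = np.zeros(N_CLASSES, dtype=np.float64)
    for y in targets:
        counts += np.bincount(np.asarray(y).ravel(), minlength=N_CLASSES)
    if np.any(counts == 0):
        missing = np.nonzero(counts == 0)[0].tolist()
        raise ValueError(f"classes {missing} absent from all targets")
    w = 1.0 / counts
    return w / w.mean()


def volumes_to_slices(
    scatter_recon: np.ndarray,
    photopeak_recon: np.ndarray,
    labels: np.ndarray,
    stride: int = 4,
    offset: int = 0,
):
    """Cut a volume triple into 2-D training pairs (x: (2,H,W), y: (H,W))."""
    x = np.stack([scatter_recon, photopeak_recon], axis=0).astype(np.float32)
    return [
        (x[:, :, :, z].copy(), np.asarray(labels[:, :, z], dtype=np.int64))
        for z in range(offset, labels.shape[2], stride)
    ]


def _epoch(
    net: McEUN,
    pairs,
    order,
    class_weights,
    opt: Adam | None,
    batch_size: int,
    rng,
    train: bool,
) -> float:
    total, nb = 0.0, 0
    for b0 in range(0, len(order), batch_size):
        idx = order[b0:b0 + batch_size]
        xb = np.stack([pairs[i][0] for i in idx])
        yb = np.stack([pairs[i][1] for i in idx])
        logits = net.forward(xb, train=train, rng=rng)
        loss = ag.weighted_softmax_ce(logits, yb, class_weights)
        if train:
            loss.backward()
            opt.step()
        total += float(loss.data)
        nb += 1
    return total / max(nb, 1)


def _fit(net, pairs, idx_train, class_weights, lr, epochs, batch_size, rng,
         idx_val=None):
    opt = Adam(net.params, lr=lr)
    tr_hist, val_hist = [], []
    idx_train = np.asarray(idx_train)
    for _ in range(epochs):
        order = idx_train[rng.permutation(len(idx_train))]
        tr_hist.append(
            _epoch(net, pairs, order, class_weights, opt, batch_size, rng, True)
        )
        if idx_val is not None and len(idx_val):
            val_hist.append(
                _epoch(net, pairs, np.asarray(idx_val), class_weights, None,
                       batch_size, rng, False)
            )
    return tr_hist, val_hist


def train_mceun(
    network: McEUN,
    pairs,
    class_weights: np.ndarray | None = None,
    lr: float = 1e-3,
    epochs: int = 15,
    batch_size: int = 4,
    seed: int = 0,
    folds: int = 5,
    run_cv: bool = True,
) -> tuple[McEUN, TrainLog]:
    """Train on 2-D slice pairs with weighted cross-entropy and Adam.

    With ``run_cv`` the five-fold cross-validation pass is executed first
    (fresh network per fold, identical schedule) and per-fold validation
    losses recorded; the returned network is then trained on all pairs.
    Fully reproducible given (seed, data, config).
    """
    pairs = list(pairs)
    if len(pairs) < folds:
        raise ValueError("need at least as many training pairs as folds")
    if class_weights is None:
        class_weights = inverse_frequency_weights([y for _, y in pairs])
    class_weights = np.asarray(class_weights, dtype=np.float64)
    log = TrainLog(seed=seed)
    log.fold_assignments = kfold_split(len(pairs), folds, seed)
    if run_cv and folds > 1:
        for f in range(folds):
            net_f = build_mceun(network.config, seed=seed + 1 + f)
            rng = np.random.default_rng((seed + 1 + f) * 7 + 1)
            tr = np.nonzero(log.fold_assignments != f)[0]
            va = np.nonzero(log.fold_assignments == f)[0]
            _, val_hist = _fit(net_f, pairs, tr, class_weights, lr, epochs,
                               batch_size, rng, idx_val=va)
            log.val_loss[f] = val_hist
    rng = np.random.default_rng(seed * 7 + 3)
    tr_hist, _ = _fit(network, pairs, np.arange(len(pairs)), class_weights,
                      lr, epochs, batch_size, rng)
    log.train_loss = tr_hist
    return network, log
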