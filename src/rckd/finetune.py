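"""Fine-tuning of a pretrained backbone for downstream tasks.

The pretraining head is replaced by a task head (linear + softmax for
classification, U-Net-style decoder for segmentation) and the model is
trained with a focal loss under a repeated-split protocol: the dataset is
split 6:2:2 for each of five folds (a different random seed per fold),
training stops early when the validation loss has not improved for a
patience window, the best-validation checkpoint is restored, and the fold
test metrics are averaged.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autograd import interpolate_bilinear, no_grad
from .csat import CSAT
from .distill import _resize_nearest
from .metrics import accuracy, ConfusionCounts

__all__ = ["FinetuneConfig", "focal_loss_classification", "focal_loss_segmentation",
           "replace_head", "split_dataset", "finetune"]

EPS = 1e-12


@dataclass
class FinetuneConfig:
    input_resolution: int = 384
    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    n_folds: int = 5
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    freeze_positional_encoding: bool = True
    split_ratio: tuple = (0.6, 0.2, 0.2)
    max_grad_norm: float | None = 1.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")


def _focal_term(p_t: Tensor, alpha: float, gamma: float) -> Tensor:
    p_t = p_t.clamp(EPS, 1.0 - EPS)
    if gamma == 0:
        return -alpha * p_t.log()
    return -alpha * (1.0 - p_t) ** gamma * p_t.log()


def focal_loss_classification(probs, true_class, alpha=0.25, gamma=2.0) -> Tensor:
    """-alpha * (1 - p_t)^gamma * log(p_t), averaged over a batch if given one.

    ``probs``: probability vector (T,) or batch (N, T); ``true_class``: class
    index or length-N index array.
    """
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    t = np.asarray(true_class)
    if p.ndim == 1:
        p = p.reshape(1, p.shape[0])
        t = t.reshape(1)
    if t.min() < 0 or t.max() >= p.shape[1]:
        raise IndexError("true_class out of range")
    p_t = p[np.arange(p.shape[0]), t]
    return _focal_term(p_t, alpha, gamma).mean()


def focal_loss_segmentation(prob_maps, true_map, alpha=0.25, gamma=2.0) -> Tensor:
    """Pixelwise focal loss averaged over all H*W pixels (and any batch).

    ``prob_maps``: (T, H, W) or (N, T, H, W) per-pixel class probabilities;
    ``true_map``: matching (H, W) or (N, H, W) class indices.
    """
    p = prob_maps if isinstance(prob_maps, Tensor) else Tensor(np.asarray(prob_maps, dtype=np.float64))
    t = np.asarray(true_map)
    if p.ndim == 3:
        p = p.reshape(1, *p.shape)
        t = t.reshape(1, *t.shape)
    if p.shape[0] != t.shape[0] or p.shape[2:] != t.shape[1:]:
        raise ValueError(f"shape mismatch: probs {p.shape} vs truth {t.shape}")
    if t.min() < 0 or t.max() >= p.shape[1]:
        raise IndexError("true_map label out of range")
    n, _, h, w = p.shape
    ni, hi, wi = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
    p_t = p[ni, t, hi, wi]
    return _focal_term(p_t, alpha, gamma).mean()


def replace_head(pretrained, task: str, n_classes: int) -> CSAT:
    """Attach a freshly initialised task head to a pretrained backbone.

    ``pretrained`` may be a headless CSAT backbone or any model exposing
    ``.backbone``.  Backbone weights are carried over bit-identically.
    ``task`` is "cls" or "seg".
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    backbone = getattr(pretrained, "backbone", pretrained)
    if not isinstance(backbone, CSAT):
        raise TypeError("expected a CSAT backbone")
    cfg = copy.deepcopy(backbone.config)
    cfg.num_classes = n_classes
    head = {"cls": "classification", "seg": "segmentation"}.get(task)
    if head is None:
        raise ValueError(f"unknown task {task!r}")
    model = CSAT(cfg, head=head)
    # fresh head init is whatever the constructor drew; now transfer backbone
    state = {name: p.data.copy() for name, p in backbone.named_parameters()}
    own = dict(model.named_parameters())
    for name, arr in state.items():
        own[name].data = arr.copy()
    return model


def split_dataset(labels, ratio=(0.6, 0.2, 0.2), seed: int = 0):
    """Stratified-by-class random split into train/val/test index lists.

    The three lists are disjoint and exhaustive; deterministic given seed.
    """
    labels = np.asarray(labels)
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 3:
            raise ValueError(f"class {c} has {len(idx)} items; need >= 3 "
                             "for a three-way split")
        idx = rng.permutation(idx)
        n = len(idx)
        n_train = int(round(ratio[0] * n))
        n_val = int(round(ratio[1] * n))
        # every split gets at least one item per class
        n_train = min(max(n_train, 1), n - 2)
        n_val = min(max(n_val, 1), n - n_train - 1)
        train += list(idx[:n_train])
        val += list(idx[n_train:n_train + n_val])
        test += list(idx[n_train + n_val:])
    return sorted(train), sorted(val), sorted(test)


def _prepare_cls(items, size):
    xs, ys = [], []
    for img, label in items:
        x = Tensor(np.asarray(img, dtype=np.float64).transpose(2, 0, 1)[None] / 255.0)
        with no_grad():
            x = interpolate_bilinear(x, size, size)
        xs.append(x.data[0])
        ys.append(int(label))
    return np.stack(xs), np.asarray(ys)


def _prepare_seg(items, size):
    xs, ys = [], []
    for img, mask in items:
        x = Tensor(np.asarray(img, dtype=np.float64).transpose(2, 0, 1)[None] / 255.0)
        with no_grad():
            x = interpolate_bilinear(x, size, size)
        xs.append(x.data[0])
        ys.append(_resize_nearest(np.asarray(mask), size))
    return np.stack(xs), np.stack(ys)


def _epoch_loss(model, X, Y, task, cfg, batch):
    """Mean focal loss over a dataset without gradient tracking."""
    tot, n = 0.0, 0
    with no_grad():
        for s in range(0, len(X), batch):
            xb, yb = Tensor(X[s:s + batch]), Y[s:s + batch]
            probs = model(xb)
            if task == "cls":
                loss = focal_loss_classification(probs, yb, cfg.focal_alpha, cfg.focal_gamma)
            else:
                loss = focal_loss_segmentation(probs, yb, cfg.focal_alpha, cfg.focal_gamma)
            tot += float(loss.data) * len(yb)
            n += len(yb)
    return tot / n


def _evaluate(model, X, Y, task, n_classes, batch):
    preds = []
    with no_grad():
        for s in range(0, len(X), batch):
            probs = model(Tensor(X[s:s + batch]))
            preds.append(probs.data.argmax(axis=1))
    preds = np.concatenate(preds)
    if task == "cls":
        return accuracy(preds, Y)
    counts = ConfusionCounts(n_classes)
    for p, t in zip(preds, Y):
        counts.update(p, t)
    return counts.mean_iou()


def finetune(pretrained, dataset, task: str, n_classes: int,
             config: FinetuneConfig | None = None) -> dict:
    """Multi-fold fine-tuning; returns per-fold test metrics and their mean.

    ``dataset``: list of (image, label) for ``task='cls'`` or
    (image, mask) for ``task='seg'``.
    """
    config = config or FinetuneConfig()
    prep = _prepare_cls if task == "cls" else _prepare_seg
    X, Y = prep(dataset, config.input_resolution)
    strat_labels = Y if task == "cls" else np.zeros(len(X), dtype=int)

    folds = []
    for fold in range(config.n_folds):
        fold_seed = config.seed + fold
        tr, va, te = split_dataset(strat_labels, config.split_ratio, fold_seed)
        if len(va) == 0:
            raise ValueError("empty validation split")
        model = replace_head(pretrained, task, n_classes)
        head_rng = np.random.default_rng(fold_seed)
        if task == "cls":
            model.fc.init_parameters(head_rng)
        else:
            model.decoder.init_parameters(head_rng)
        trainable = [p for name, p in model.named_parameters()
                     if not (config.freeze_positional_encoding and ".peg." in name)]
        opt = nn.SGD(trainable, lr=config.learning_rate,
                     momentum=config.momentum, weight_decay=config.weight_decay,
                     max_grad_norm=config.max_grad_norm)
        rng = np.random.default_rng(fold_seed)

        best_val, best_state, since_best = np.inf, None, 0
        history = []
        for epoch in range(config.max_epochs):
            order = rng.permutation(tr)
            for s in range(0, len(order), config.batch_size):
                idx = order[s:s + config.batch_size]
                xb, yb = Tensor(X[idx]), Y[idx]
                probs = model(xb)
                if task == "cls":
                    loss = focal_loss_classification(probs, yb, config.focal_alpha,
                                                     config.focal_gamma)
                else:
                    loss = focal_loss_segmentation(probs, yb, config.focal_alpha,
                                                   config.focal_gamma)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at fold {fold} epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
            val_loss = _epoch_loss(model, X[va], Y[va], task, config, config.batch_size)
            history.append(val_loss)
            if val_loss < best_val:
                best_val, best_state, since_best = val_loss, model.state_dict(), 0
            else:
                since_best += 1
            if since_best >= config.patience:
                break
        if best_state is not None:
            model.load_state_dict(best_state)
        metric = _evaluate(model, X[te], Y[te], task, n_classes, config.batch_size)
        folds.append({"fold": fold, "seed": fold_seed, "epochs_run": len(history),
                      "best_val_loss": float(best_val), "test_metric": float(metric),
                      "val_history": [float(v) for v in history]})
    mean_metric = float(np.mean([f["test_metric"] for f in folds]))
    return {"task": task, "n_classes": n_classes, "folds": folds,
            "mean_metric": mean_metric,
            "metric_name": "accuracy_percent" if task == "cls" else "mean_iou"}
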