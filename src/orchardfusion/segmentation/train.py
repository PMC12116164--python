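"""Training loop for the segmentation network.

Pixel-wise cross-entropy minimised with seeded mini-batch SGD (momentum) or
Adam; a held-out validation slice of the training scenes supplies the
validation loss curve.  Everything is deterministic given the seed (within
floating-point reduction order).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..nn import autograd as ag
from ..nn.autograd import Tensor
from ..nn.optim import SGD, Adam
from .model import DeepLabV3Plus

__all__ = ["TrainConfig", "train", "split_scenes", "prepare_image", "save_history"]


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 8
    learning_rate: float = 0.01
    split_ratio: tuple = (4, 1)     # train : test, applied by split_scenes
    seed: int = 0
    loss: str = "cross_entropy"
    momentum: float = 0.9
    optimizer: str = "sgd"          # or "adam"
    val_fraction: float = 0.1
    max_steps: int | None = None    # optional hard cap on optimisation steps

    def validate(self):
        if self.epochs < 0 or self.batch_size <= 0 or self.learning_rate < 0:
            raise ValueError("epochs/batch_size/learning_rate must be non-negative")
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must lie in [0, 1)")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        total = sum(self.split_ratio)
        if total <= 0:
            raise ValueError("split_ratio must have positive total")
        return self


def prepare_image(image: np.ndarray) -> np.ndarray:
    """HWC uint8/float image -> CHW float32 in [0, 1]."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    return np.ascontiguousarray(arr.transpose(2, 0, 1).astype(np.float32))


def split_scenes(scenes, ratio=(4, 1), seed=0):
    """Seeded shuffle split of scenes into (train, test) at `ratio`."""
    scenes = list(scenes)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scenes))
    n_train = int(round(len(scenes) * ratio[0] / sum(ratio)))
    train_idx, test_idx = order[:n_train], order[n_train:]
    return [scenes[i] for i in train_idx], [scenes[i] for i in test_idx]


def _stack(scenes):
    images = np.stack([prepare_image(s.image) for s in scenes])
    labels = np.stack([np.asarray(s.mask, dtype=np.int64) for s in scenes])
    return images, labels


def train(model: DeepLabV3Plus, scenes, tc: TrainConfig):
    """Optimise `model` on `scenes`; returns (model, history dict).

    history holds per-epoch "train_loss" and "val_loss" lists (val_loss is
    NaN when val_fraction rounds to zero scenes).
    """
    tc.validate()
    scenes = list(scenes)
    if len(scenes) < 2:
        raise ValueError("need at least 2 scenes to train")
    n_classes = model.config.n_classes
    for s in scenes:
        m = np.asarray(s.mask)
        if m.min() < 0 or m.max() >= n_classes:
            raise ValueError("scene labels outside [0, n_classes)")

    rng = np.random.default_rng(tc.seed)
    order = rng.permutation(len(scenes))
    n_val = int(round(tc.val_fraction * len(scenes)))
    val_scenes = [scenes[i] for i in order[:n_val]]
    fit_scenes = [scenes[i] for i in order[n_val:]]
    x_fit, y_fit = _stack(fit_scenes)
    x_val, y_val = _stack(val_scenes) if val_scenes else (None, None)

    params = list(model.parameters())
    if tc.optimizer == "adam":
        opt = Adam(params, lr=tc.learning_rate)
    else:
        opt = SGD(params, lr=tc.learning_rate, momentum=tc.momentum)

    history = {"train_loss": [], "val_loss": []}
    steps = 0
    for _epoch in range(tc.epochs):
        model.train()
        perm = rng.permutation(len(fit_scenes))
        epoch_losses = []
        for start in range(0, len(fit_scenes), tc.batch_size):
            if tc.max_steps is not None and steps >= tc.max_steps:
                break
            idx = perm[start:start + tc.batch_size]
            opt.zero_grad()
            loss = ag.softmax_cross_entropy(model(Tensor(x_fit[idx])), y_fit[idx])
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            steps += 1
        if not epoch_losses:
            break
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if x_val is not None:
            model.eval()
            vloss = ag.softmax_cross_entropy(model(Tensor(x_val)), y_val)
            history["val_loss"].append(vloss.item())
        else:
            history["val_loss"].append(float("nan"))
        if tc.max_steps is not None and steps >= tc.max_steps:
            break
    model.eval()
    return model, history


def save_history(history: dict, path):
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "val_loss"])
        for i, (tr, va) in enumerate(zip(history["train_loss"], history["val_loss"]), 1):
            writer.writerow([i, tr, va])
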