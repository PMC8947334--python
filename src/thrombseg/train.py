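"""Training loop and hyperparameter search for the segmentation networks.

Networks train one crop at a time (batch size 1) with Adam and a weighted
cross-entropy loss: the positive (thrombus) class is up-weighted by a
factor ``w`` because thrombus voxels are vastly outnumbered by background.
The loss is the voxel mean of -[w t log s(z) + (1 - t) log(1 - s(z))]; at
w = 1 it is plain binary cross-entropy.  The learning rate is fixed at its
initial value (no schedule).

Hyperparameters (lr, w) are chosen by seeded random search -- lr sampled
log-uniformly over (1e-4, 0.1) since the interval spans three decades, w
uniformly over (10, 50) -- scored by mean validation Dice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .boxes import pad_to_acceptable
from .metrics import dice as dice_score
from .nets import NetConfig, SegNet, build_network, predict_mask


class TrainError(RuntimeError):
    """Raised on empty datasets or divergence (non-finite loss)."""


#: One training example: box-local NCCT crop, CTA crop, and target mask.
Sample = Tuple[np.ndarray, np.ndarray, np.ndarray]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    batch_size: int = 1
    lr: float = 1e-3
    pos_weight: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.lr <= 0 or self.pos_weight <= 0:
            raise TrainError("epochs >= 1, lr > 0 and pos_weight > 0 required")


def weighted_bce(logits: np.ndarray, target: np.ndarray, w: float) -> float:
    """Weighted cross-entropy as a plain number (no graph).

    Mean over voxels of -[w t log s(z) + (1 - t) log(1 - s(z))].  A single
    positive voxel with logit 0 and w = 10 costs 10 ln 2.
    """
    value = nn.weighted_bce_loss(nn.Tensor(np.asarray(logits, dtype=float)),
                                 np.asarray(target, dtype=float), w)
    return float(value.data)


def _pad_samples(samples: Sequence[Sample], depth: int) -> List[Sample]:
    padded = []
    for ncct, cta, target in samples:
        n, rec = pad_to_acceptable(np.asarray(ncct, dtype=float), depth)
        c, _ = pad_to_acceptable(np.asarray(cta, dtype=float), depth)
        t = np.zeros(rec.padded_shape)
        sl = tuple(slice(0, s) for s in rec.original_shape)
        t[sl] = np.asarray(target, dtype=float)
        padded.append((n, c, t))
    return padded


def _val_dice(model: SegNet, samples: Sequence[Sample]) -> float:
    scores = []
    for ncct, cta, target in samples:
        pred = predict_mask(model, ncct, cta)
        target = np.asarray(target, dtype=bool)
        if not target.any() and not pred.any():
            scores.append(1.0)
        else:
            scores.append(dice_score(target, pred))
    return float(np.mean(scores))


def fit(
    model: SegNet,
    train_set: Sequence[Sample],
    cfg: TrainConfig,
    val_set: Sequence[Sample] | None = None,
) -> Tuple[SegNet, pd.DataFrame]:
    """Train ``model`` in place; returns it with the best-validation weights.

    Records per-epoch mean training loss and, when a validation set is
    given, validation loss and Dice; the parameter state with the best
    validation Dice is restored at the end.  Fully deterministic for a
    fixed seed in single-threaded execution.
    """
    if len(train_set) == 0:
        raise TrainError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    depth = model.cfg.depth
    train_padded = _pad_samples(train_set, depth)
    val_padded = _pad_samples(val_set, depth) if val_set else None
    opt = nn.Adam(model.parameters(), lr=cfg.lr)

    history = []
    best_dice = -1.0
    best_state = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_padded))
        losses = []
        for i in order:
            ncct, cta, target = train_padded[i]
            opt.zero_grad()
            logits = model.forward(ncct, cta)
            loss = nn.weighted_bce_loss(logits, target[None], cfg.pos_weight)
            if not np.isfinite(loss.data):
                raise TrainError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_padded is not None:
            vlosses = [
                float(nn.weighted_bce_loss(model.forward(n, c), t[None],
                                           cfg.pos_weight).data)
                for n, c, t in val_padded
            ]
            row["val_loss"] = float(np.mean(vlosses))
            row["val_dice"] = _val_dice(model, val_set)  # type: ignore[arg-type]
            if row["val_dice"] > best_dice:
                best_dice = row["val_dice"]
                best_state = model.state_arrays()
        history.append(row)
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, pd.DataFrame(history)


def tune(
    train_set: Sequence[Sample],
    val_set: Sequence[Sample],
    net_cfg: NetConfig,
    budget: int = 5,
    epochs: int = 10,
    lr_range: Tuple[float, float] = (1e-4, 0.1),
    w_range: Tuple[float, float] = (10.0, 50.0),
    seed: int = 0,
) -> Tuple[Tuple[float, float], pd.DataFrame]:
    """Random search over (lr, w); returns the best pair by validation Dice."""
    if budget < 1:
        raise TrainError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trials = []
    for trial in range(budget):
        lr = float(np.exp(rng.uniform(np.log(lr_range[0]), np.log(lr_range[1]))))
        w = float(rng.uniform(*w_range))
        model = build_network(net_cfg, seed=seed + trial)
        cfg = TrainConfig(epochs=epochs, lr=lr, pos_weight=w, seed=seed + trial)
        try:
            model, _ = fit(model, train_set, cfg, val_set=val_set)
            score = _val_dice(model, val_set)
        except TrainError:
            score = float("nan")  # diverged trial scores worst
        trials.append({"trial": trial, "lr": lr, "pos_weight": w, "val_dice": score})
    table = pd.DataFrame(trials)
    valid = table.dropna(subset=["val_dice"])
    if valid.empty:
        raise TrainError("every trial diverged")
    best = valid.loc[valid["val_dice"].idxmax()]
    return (float(best["lr"]), float(best["pos_weight"])), table
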