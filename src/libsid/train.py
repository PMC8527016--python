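"""Staged-learning-rate SGD with validation-threshold early stopping.

Training proceeds through an ordered list of (learning rate,
validation-accuracy threshold) stages with strictly decreasing rates
and nondecreasing thresholds.  Within a stage, plain SGD epochs run
until whole-validation accuracy (evaluation-mode batch-norm
statistics) reaches the stage threshold, or a per-stage epoch cap is
hit; then the next stage takes over.  The published four-stage
schedule uses rates 0.25, 0.124, 0.05, 0.01 with thresholds 0.84,
0.86, 0.88, 0.887.

The loss is categorical cross-entropy on softmax outputs; the
returned weights are those at the stopping epoch (no best-so-far
checkpointing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .models import Network

__all__ = [
    "StageSchedule",
    "TrainingLog",
    "TrainingDiverged",
    "published_schedule",
    "train",
    "evaluate_epoch",
]


@dataclass(frozen=True)
class StageSchedule:
    stages: tuple               # ((learning_rate, val_threshold), ...)
    max_epochs_per_stage: int = 100
    batch_size: int = 64

    def __post_init__(self):
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        lrs = [s[0] for s in self.stages]
        thr = [s[1] for s in self.stages]
        if any(lr <= 0 for lr in lrs):
            raise ValueError("learning rates must be positive")
        if any(b >= a for a, b in zip(lrs[:-1], lrs[1:])):
            raise ValueError("learning rates must be strictly decreasing")
        if any(b < a for a, b in zip(thr[:-1], thr[1:])):
            raise ValueError("thresholds must be nondecreasing")
        if self.max_epochs_per_stage < 1 or self.batch_size < 1:
            raise ValueError("epoch cap and batch size must be >= 1")


def published_schedule(max_epochs_per_stage: int = 100,
                       batch_size: int = 64) -> StageSchedule:
    """The published four-stage schedule."""
    return StageSchedule(stages=((0.25, 0.84), (0.124, 0.86),
                                 (0.05, 0.88), (0.01, 0.887)),
                         max_epochs_per_stage=max_epochs_per_stage,
                         batch_size=batch_size)


@dataclass
class TrainingLog:
    rng_seed: int
    epochs: list = field(default_factory=list)
    # each entry: dict(epoch, stage, lr, loss, cal_accuracy, val_accuracy)

    def append(self, **kw):
        self.epochs.append(kw)

    def final_validation_accuracy(self) -> float:
        return self.epochs[-1]["val_accuracy"] if self.epochs else float("nan")


class TrainingDiverged(RuntimeError):
    def __init__(self, stage: int, epoch: int):
        super().__init__(f"non-finite loss at stage {stage}, epoch {epoch}")
        self.stage = stage
        self.epoch = epoch


def evaluate_epoch(network: Network, X, y, batch_size: int = 256) -> float:
    """Fraction of argmax-of-softmax predictions that are correct."""
    if len(X) == 0:
        raise ValueError("empty data")
    pred = network.predict(X, batch_size=batch_size)
    return float((pred == np.asarray(y)).mean())


def train(network: Network, X_cal, y_cal, X_val, y_val,
          schedule: StageSchedule, rng_seed: int = 0
          ) -> tuple[Network, TrainingLog]:
    """Run the staged schedule; returns the network and its log."""
    X_cal = np.asarray(X_cal)
    y_cal = np.asarray(y_cal)
    if len(X_cal) == 0 or len(X_val) == 0:
        raise ValueError("empty data")
    rng = np.random.default_rng(rng_seed)
    log = TrainingLog(rng_seed=rng_seed)
    epoch_no = 0
    for stage_idx, (lr, threshold) in enumerate(schedule.stages):
        for _ in range(schedule.max_epochs_per_stage):
            order = rng.permutation(len(X_cal))
            losses = []
            for i in range(0, len(order), schedule.batch_size):
                idx = order[i:i + schedule.batch_size]
                logits = network.forward(X_cal[idx], train=True)
                loss, dlogits = nn.cross_entropy(logits, y_cal[idx])
                if not np.isfinite(loss):
                    raise TrainingDiverged(stage_idx, epoch_no)
                network.backward(dlogits)
                nn.sgd_step(network.parameters, lr)
                losses.append(loss)
            epoch_no += 1
            cal_acc = evaluate_epoch(network, X_cal, y_cal)
            val_acc = evaluate_epoch(network, X_val, y_val)
            log.append(epoch=epoch_no, stage=stage_idx, lr=lr,
                       loss=float(np.mean(losses)), cal_accuracy=cal_acc,
                       val_accuracy=val_acc)
            if val_acc >= threshold:
                break
    return network, log
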