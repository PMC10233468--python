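"""Training orchestration for both separation strategies.

Two strategies drive the same loop:

* ``single`` — one model per structure class, out_channels = 1, trained
  with the plain combination loss;
* ``all`` — one model emitting every class jointly, trained with the
  summation-regularized loss so the channelwise sum of outputs is
  supervised by the superimposed input.

Optimization is Adam on seeded mini-batches.  The learning rate starts
at 1e-4 and is halved whenever the validation NRMSE (full
normalization + linear-transform metric chain) has not improved for a
patience window of iterations (10,000 at full scale); the improvement
clock resets on each halving.  The best-validation checkpoint is
returned.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autograd import Adam, Tensor
from .datapipe import PatchPair, TemporalSample
from .evalmetrics import NormalizationParams, evaluate
from .network import SeparationModel
from .objective import LossWeights, combination_loss_all, combination_loss_single

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "split_train_val",
    "step_lr",
    "validate",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""

    strategy: str = "all"
    initial_lr: float = 1e-4
    lr_patience: int = 10_000
    batch_size: int = 3
    max_iterations: int = 200_000
    val_fraction: float = 0.05
    val_interval: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("single", "all"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        for name in ("lr_patience", "batch_size", "val_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


@dataclass
class TrainHistory:
    """Checkpoint-by-checkpoint training record."""

    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_nrmse: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def append(self, iteration: int, loss: float, nrmse: float, lr: float) -> None:
        self.iterations.append(int(iteration))
        self.train_loss.append(float(loss))
        self.val_nrmse.append(float(nrmse))
        self.lr.append(float(lr))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "loss": self.train_loss,
                "val_nrmse": self.val_nrmse,
                "lr": self.lr,
            }
        )


def split_train_val(
    dataset: Sequence, val_fraction: float, seed: int = 0
) -> tuple[list, list]:
    """Disjoint, exhaustive, seeded train/validation split."""
    n = len(dataset)
    if n == 0:
        raise ValueError("dataset is empty")
    n_val = int(round(n * val_fraction))
    if n_val == 0:
        raise ValueError(
            f"val_fraction {val_fraction} yields an empty validation set for n={n}"
        )
    if n_val >= n:
        raise ValueError("validation split would consume the whole dataset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [dataset[i] for i in range(n) if i not in val_idx]
    val = [dataset[i] for i in range(n) if i in val_idx]
    return train, val


def step_lr(history: TrainHistory, current_lr: float, patience: int) -> float:
    """Halve the learning rate on a validation-NRMSE plateau.

    Returns current_lr / 2 when the best validation NRMSE has not
    improved within the last ``patience`` iterations and no halving
    happened inside that window (each halving resets the clock);
    otherwise returns current_lr unchanged.
    """
    if not history.iterations:
        return current_lr
    now = history.iterations[-1]
    best = np.inf
    best_iter = history.iterations[0]
    for it, v in zip(history.iterations, history.val_nrmse):
        if v < best:
            best = v
            best_iter = it
    last_drop = history.iterations[0]
    for i in range(1, len(history.lr)):
        if history.lr[i] < history.lr[i - 1]:
            last_drop = history.iterations[i]
    if now - max(best_iter, last_drop) >= patience:
        return current_lr / 2.0
    return current_lr


def validate(
    model: SeparationModel,
    val_set: Sequence[PatchPair | TemporalSample],
    params: NormalizationParams = NormalizationParams(),
) -> float:
    """Mean validation NRMSE over pairs and channels (full metric chain)."""
    if len(val_set) == 0:
        raise ValueError("validation set is empty")
    values = []
    for i, pair in enumerate(val_set):
        pred = model(pair.input_array().astype(np.float32)).data
        try:
            report = evaluate(pred, pair.target, params)
        except ValueError as exc:
            raise ValueError(f"validation pair {i}: {exc}") from exc
        values.append(report.mean_nrmse)
    return float(np.mean(values))


def _check_compat(model: SeparationModel, dataset: Sequence, strategy: str) -> None:
    sample = dataset[0]
    c_tgt = sample.target.shape[0]
    c_in = sample.input_array().shape[0]
    if model.config.in_channels != c_in:
        raise ValueError(
            f"model expects {model.config.in_channels} input channels but the "
            f"dataset provides {c_in}"
        )
    if strategy == "single" and (c_tgt != 1 or model.config.out_channels != 1):
        raise ValueError(
            "strategy 'single' requires single-channel targets and out_channels=1; "
            f"got target channels {c_tgt}, model out_channels {model.config.out_channels}"
        )
    if strategy == "all" and model.config.out_channels != c_tgt:
        raise ValueError(
            f"strategy 'all': model out_channels {model.config.out_channels} != "
            f"target channels {c_tgt}"
        )


def train(
    model: SeparationModel,
    dataset: Sequence[PatchPair | TemporalSample],
    config: TrainConfig,
    weights: LossWeights = LossWeights(),
    norm_params: NormalizationParams = NormalizationParams(),
) -> tuple[SeparationModel, TrainHistory]:
    """Run seeded mini-batch training and return the best checkpoint.

    The returned model carries the weights of the checkpoint with the
    lowest validation NRMSE; the history records every validation
    checkpoint (iteration, train loss, validation NRMSE, lr).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    _check_compat(model, dataset, config.strategy)
    history = TrainHistory()
    if config.max_iterations == 0:
        return model, history

    train_set, val_set = split_train_val(dataset, config.val_fraction, config.seed)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    optimizer = Adam(model.parameters(), lr=config.initial_lr)

    inputs = np.stack([p.input_array() for p in train_set]).astype(np.float32)
    targets = np.stack([p.target for p in train_set]).astype(np.float32)

    best_nrmse = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    running_loss = 0.0
    n_loss = 0

    for it in range(1, config.max_iterations + 1):
        idx = rng.integers(0, len(train_set), size=config.batch_size)
        xb = Tensor(inputs[idx])
        yb = targets[idx]
        pred = model(xb)
        if config.strategy == "all":
            # the superimposed frame: the only channel in static mode, the
            # median timepoint in temporal-continuity mode
            x_sup = inputs[idx][:, inputs.shape[1] // 2]
            loss = combination_loss_all(x_sup, pred, yb, weights)
        else:
            loss = combination_loss_single(pred, yb, weights)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        running_loss += float(loss)
        n_loss += 1

        if it % config.val_interval == 0 or it == config.max_iterations:
            vn = validate(model, val_set, norm_params)
            history.append(it, running_loss / max(n_loss, 1), vn, optimizer.lr)
            running_loss, n_loss = 0.0, 0
            if vn < best_nrmse:
                best_nrmse = vn
                best_state = [a.copy() for a in model.state_arrays()]
            new_lr = step_lr(history, optimizer.lr, config.lr_patience)
            if new_lr != optimizer.lr:
                optimizer.lr = new_lr
                # reflect the drop at this checkpoint so the reset clock
                # in step_lr sees it
                history.lr[-1] = new_lr

    best_model = copy.deepcopy(model)
    best_model.load_state_arrays(best_state)
    return best_model, history
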