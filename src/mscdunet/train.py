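"""Patch-based training loop: ADAM with step-decayed learning rate.

Each iteration samples ``batch_size`` same-center patches from
randomly chosen subjects, augments them, and takes one ADAM step on
the deeply-supervised loss. The learning rate starts at ``lr`` and is
multiplied by ``lr_decay_factor`` every ``lr_decay_every`` iterations.
The sub-volume budget ``n_subvolumes`` caps the total number of
patches drawn, so the effective iteration count is
``min(iterations, n_subvolumes // batch_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_prep import AugmentParams, PatchBatch, augment, sample_patch
from .losses import LossConfig, final_loss
from .network import MSCDUNet
from .nn import Adam

__all__ = ["TrainConfig", "TrainingDivergedError", "fit"]


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    iterations: int = 18000
    lr: float = 1e-3
    lr_decay_every: int = 5000
    lr_decay_factor: float = 0.1
    batch_size: int = 4
    n_subvolumes: int = 72000
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if min(self.lr_decay_every, self.batch_size, self.n_subvolumes) <= 0:
            raise ValueError("batch/decay/budget settings must be positive")
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must lie in (0, 1)")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


def schedule_lr(tcfg: TrainConfig, step: int) -> float:
    return tcfg.lr * tcfg.lr_decay_factor ** (step // tcfg.lr_decay_every)


def fit(
    model: MSCDUNet,
    dataset,
    tcfg: TrainConfig,
    lcfg: LossConfig = None,
    augment_params: AugmentParams = None,
    log_every: int = 0,
):
    """Train ``model`` on ``dataset`` (a list of (volumes, labelmap)
    pairs, already normalized); returns (model, history DataFrame).

    Deterministic under ``tcfg.seed`` in single-threaded execution.
    """
    if lcfg is None:
        lcfg = LossConfig()
    model.fusion_weights.value = np.asarray(
        lcfg.f_init, dtype=model.fusion_weights.value.dtype
    )
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.parameters(), lr=tcfg.lr)
    patch = model.cfg.patch_size
    dtype = model.fusion_weights.value.dtype
    n_iter = min(tcfg.iterations, tcfg.n_subvolumes // tcfg.batch_size)
    model.train()
    records = []
    for step in range(n_iter):
        opt.lr = schedule_lr(tcfg, step)
        patches = []
        for _ in range(tcfg.batch_size):
            vols, labels = dataset[rng.integers(len(dataset))]
            p = sample_patch(vols, labels, patch, rng)
            if augment_params is not None:
                p = augment(p, rng, augment_params)
            patches.append(p)
        batch = PatchBatch.stack(patches)
        outputs = model.forward(batch.inputs.astype(dtype))
        total, fuse, side = final_loss(outputs, batch.targets, lcfg)
        if not np.isfinite(total.value):
            raise TrainingDivergedError(
                f"non-finite loss {total.value} at iteration {step} (lr={opt.lr:g})"
            )
        model.zero_grad()
        total.backward()
        opt.step()
        records.append(
            {
                "iteration": step,
                "lr": opt.lr,
                "loss_total": float(total.value),
                "loss_fuse": float(fuse.value),
                "loss_side": float(side.value),
            }
        )
        if log_every and (step % log_every == 0 or step == n_iter - 1):
            print(
                f"iter {step:6d} lr {opt.lr:.2e} total {total.value:.4f} "
                f"fuse {fuse.value:.4f} side {side.value:.4f}"
            )
    model.eval()
    columns = ["iteration", "lr", "loss_total", "loss_fuse", "loss_side"]
    return model, pd.DataFrame.from_records(records, columns=columns)
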