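"""Deeply-supervised loss stack.

Three side outputs (1/4, 1/2, 1/1 scale, all upsampled to the patch
resolution) each contribute a class-weighted cross-entropy term
weighted by beta_h; the fused output — the softmax of the f-weighted
sum of the side activations — contributes a fused cross-entropy term.
The total training loss is their sum. All cross-entropies are
normalized per voxel so loss magnitudes are patch-size invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import BranchOutputs
from .nn import Var, as_var
from .nn import functional as F

__all__ = [
    "LossConfig",
    "side_loss",
    "total_side_loss",
    "fuse_loss",
    "final_loss",
]


@dataclass
class LossConfig:
    """Weights of the loss stack.

    beta: per-side-output weights (3 entries); omega: per-class label
    weights (tissue classes up-weighted 2x by default); f_init: initial
    value of the learnable fusion weights.
    """

    beta: list = field(default_factory=lambda: [1.0, 1.0, 1.0])
    omega: list = field(default_factory=lambda: [1.0, 1.0, 2.0, 2.0])
    f_init: list = field(default_factory=lambda: [1.0, 1.0, 1.0])

    def __post_init__(self):
        if len(self.beta) != 3:
            raise ValueError("beta must have 3 entries (one per side output)")
        if len(self.f_init) != 3:
            raise ValueError("f_init must have 3 entries")
        if min(self.beta) < 0 or min(self.omega) < 0:
            raise ValueError("beta and omega must be non-negative")


def side_loss(logits, target, omega) -> Var:
    """Class-weighted cross-entropy of one side output, per-voxel mean."""
    lv = as_var(logits)
    target = np.asarray(target)
    if target.ndim == lv.value.ndim - 2:  # unbatched patch
        target = target[None]
        lv = _ensure_batched(lv)
    return F.weighted_cross_entropy(lv, target, omega)


def _ensure_batched(v: Var) -> Var:
    if v.value.ndim == 4:
        return Var(v.value[None], [(v, lambda g: g[0])])
    return v


def total_side_loss(side_logits, target, cfg: LossConfig) -> Var:
    """beta-weighted sum of the three side-output losses."""
    if len(side_logits) != len(cfg.beta):
        raise ValueError(
            f"{len(side_logits)} side outputs but {len(cfg.beta)} beta weights"
        )
    total = None
    for b, logits in zip(cfg.beta, side_logits):
        if b == 0:
            continue
        term = side_loss(logits, target, cfg.omega)
        term = Var(b * term.value, [(term, lambda g, _b=b: _b * g)])
        total = term if total is None else Var(
            total.value + term.value, [(total, lambda g: g), (term, lambda g: g)]
        )
    if total is None:
        return Var(np.zeros(()))
    return total


def fuse_loss(side_activations, target, f, omega) -> Var:
    """Cross-entropy of the softmax of the f-weighted activation sum."""
    fused = F.weighted_sum([as_var(a) for a in side_activations], as_var(f))
    return side_loss(fused, target, omega)


def final_loss(outputs: BranchOutputs, target, cfg: LossConfig):
    """Total loss = fused term + weighted side terms.

    Returns (total, fuse_term, side_term) as Vars; the total is the
    exact sum of the two components.
    """
    fuse = side_loss(outputs.fused_logits, target, cfg.omega)
    side = total_side_loss(outputs.side_logits, target, cfg)
    total = Var(
        fuse.value + side.value, [(fuse, lambda g: g), (side, lambda g: g)]
    )
    return total, fuse, side
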