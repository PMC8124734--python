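"""Multi-branch pooling (MP) and multi-branch dense prediction (MDP).

MP replaces a single down-sampling pool by several pooling branches
with different kernel sizes running in parallel. Every branch halves
the spatial extent (stride 2 with symmetric padding floor((k-1)/2)),
so the branch outputs can be concatenated along channels; the kernels
differ only in receptive field.

MDP reads a tensor whose channels are grouped per class into k^3
channels, one channel per spatial offset (r, s, t) in the k-cube
around a voxel. The class score at voxel (l, m, n) is the average of
the offset channels sampled at their shifted positions
(l+r-floor(k/2), m+s-floor(k/2), n+t-floor(k/2)). With k=1 this
degenerates to the identity, i.e. a plain dense prediction head.
Several k values (branches) produce one map each; the branch maps are
combined either by a learned 1x1x1 convolution over their
concatenation or by plain averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .nn import Conv3d, Module, Var, as_var
from .nn import functional as F

__all__ = ["MPConfig", "MDPConfig", "mp_forward", "mdp_branch", "mdp_forward", "MDPHead"]


@dataclass
class MPConfig:
    """Kernel sets of the two pooling stages and the pooling mode."""

    kernels_stage1: list = field(default_factory=lambda: [5, 3, 2])
    kernels_stage2: list = field(default_factory=lambda: [3, 2])
    mode: str = "max"
    downscale_factor: int = 2

    def __post_init__(self):
        for ks in (self.kernels_stage1, self.kernels_stage2):
            if not ks:
                raise ValueError("MP kernel list must be non-empty")
            if any(k < 2 for k in ks):
                raise ValueError("MP kernels must be >= 2")
        if self.mode not in ("max", "average"):
            raise ValueError(f"unknown MP mode {self.mode!r}")
        if self.downscale_factor != 2:
            raise ValueError("MP always halves the spatial extent")

    def kernels(self, stage):
        if stage == 1:
            return self.kernels_stage1
        if stage == 2:
            return self.kernels_stage2
        raise ValueError("stage must be 1 or 2")


@dataclass
class MDPConfig:
    """Branch window sizes, class count and combination rule of MDP."""

    ks: list = field(default_factory=lambda: [1, 3, 4])
    n_classes: int = 4
    combine: str = "concat_conv"
    border: str = "replicate"

    def __post_init__(self):
        if not self.ks or any(k < 1 for k in self.ks):
            raise ValueError("MDP window sizes must be >= 1")
        if self.combine not in ("concat_conv", "average"):
            raise ValueError(f"unknown MDP combine {self.combine!r}")
        if self.border not in ("replicate", "zero"):
            raise ValueError(f"unknown MDP border {self.border!r}")

    @property
    def in_channels(self):
        """Channels the head must be fed: n_classes * sum(k^3)."""
        return self.n_classes * sum(k ** 3 for k in self.ks)


def mp_forward(features, cfg: MPConfig, stage: int):
    """Apply the parallel pooling branches of one stage.

    Every branch pools with its own kernel, stride 2 and symmetric
    padding, producing identical (halved) spatial shapes; the branch
    outputs are concatenated along channels.
    """
    x = as_var(features)
    pool = F.max_pool3d if cfg.mode == "max" else F.avg_pool3d
    branches = [pool(x, k) for k in cfg.kernels(stage)]
    if len(branches) == 1:
        return branches[0]
    return F.concat(branches, axis=1)


def _shift_indices(extent, offset, border):
    """Sampling index along one axis for a window offset; None entries
    mark out-of-range positions under the zero border policy."""
    idx = np.arange(extent) + offset
    if border == "replicate":
        return np.clip(idx, 0, extent - 1), None
    valid = (idx >= 0) & (idx < extent)
    return np.clip(idx, 0, extent - 1), valid


def mdp_branch(y, k: int, border: str = "replicate"):
    """Average the k^3 offset channels of each class group at their
    shifted positions (differentiable).

    ``y`` is (batch, n_classes * k^3, D, H, W); channel
    ``class * k^3 + (r*k^2 + s*k + t)`` holds the prediction for offset
    (r, s, t). Returns (batch, n_classes, D, H, W).
    """
    yv = as_var(y)
    a = yv.value
    if a.ndim != 5:
        raise ValueError("mdp_branch expects a 5-D tensor")
    bsz, ch, d, h, w = a.shape
    k3 = k ** 3
    if ch % k3 != 0:
        raise ValueError(
            f"channel count {ch} is not divisible by k^3 = {k3}"
        )
    if border not in ("replicate", "zero"):
        raise ValueError(f"unknown border policy {border!r}")
    n_classes = ch // k3
    g = a.reshape(bsz, n_classes, k3, d, h, w)
    half = k // 2

    plans = []
    for r, s, t in product(range(k), repeat=3):
        j = r * k * k + s * k + t
        di, dv = _shift_indices(d, r - half, border)
        hi, hv = _shift_indices(h, s - half, border)
        wi, wv_ = _shift_indices(w, t - half, border)
        plans.append((j, (di, hi, wi), (dv, hv, wv_)))

    out = np.zeros((bsz, n_classes, d, h, w), dtype=a.dtype)
    for j, (di, hi, wi), valids in plans:
        term = g[:, :, j][:, :, di][:, :, :, hi][:, :, :, :, wi]
        for ax, v in enumerate(valids):
            if v is not None:
                shape = [1] * 5
                shape[2 + ax] = -1
                term = term * v.reshape(shape)
        out += term
    out /= k3

    def grad_y(go):
        gy = np.zeros_like(g)
        go = go / k3
        for j, (di, hi, wi), valids in plans:
            term = go
            for ax, v in enumerate(valids):
                if v is not None:
                    shape = [1] * 5
                    shape[2 + ax] = -1
                    term = term * v.reshape(shape)
            flat = (di[:, None, None] * h + hi[None, :, None]) * w + wi[
                None, None, :
            ]
            tgt = gy[:, :, j].reshape(bsz, n_classes, d * h * w)
            np.add.at(
                tgt,
                (slice(None), slice(None), flat.ravel()),
                term.reshape(bsz, n_classes, -1),
            )
            gy[:, :, j] = tgt.reshape(bsz, n_classes, d, h, w)
        return gy.reshape(a.shape)

    return Var(out, [(yv, grad_y)])


class MDPHead(Module):
    """MDP output head: one shifted-average branch per window size,
    combined into class logits."""

    def __init__(self, cfg: MDPConfig, rng=None, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        if cfg.combine == "concat_conv":
            if rng is None:
                raise ValueError("concat_conv combination needs an rng for its 1x1x1 conv")
            self.conv = Conv3d(len(cfg.ks) * cfg.n_classes, cfg.n_classes, 1, rng, dtype)
        else:
            self.conv = None

    def __call__(self, features):
        return mdp_forward(features, self.cfg, head=self)


def mdp_forward(features, cfg: MDPConfig, head: MDPHead | None = None):
    """Split the channel groups, run each MDP branch and combine.

    The input must carry ``cfg.in_channels`` channels: the groups for
    k1, k2, ... are laid out consecutively. ``combine='average'`` is
    stateless; ``combine='concat_conv'`` applies the learned 1x1x1
    convolution of ``head``.
    """
    x = as_var(features)
    ch = x.value.shape[1]
    if ch != cfg.in_channels:
        raise ValueError(
            f"MDP expects {cfg.in_channels} channels "
            f"(n_classes={cfg.n_classes}, ks={cfg.ks}), got {ch}"
        )
    maps = []
    off = 0
    for k in cfg.ks:
        n = cfg.n_classes * k ** 3
        sl = Var(
            x.value[:, off : off + n],
            [(x, lambda g, _o=off, _n=n, _c=ch: _pad_channels(g, _o, _n, _c))],
        )
        maps.append(mdp_branch(sl, k, cfg.border))
        off += n
    if cfg.combine == "average":
        if len(maps) == 1:
            return maps[0]
        acc = maps[0]
        for m in maps[1:]:
            acc = Var(
                acc.value + m.value,
                [(acc, lambda g: g), (m, lambda g: g)],
            )
        inv = 1.0 / len(maps)
        return Var(acc.value * inv, [(acc, lambda g: g * inv)])
    if head is None or head.conv is None:
        raise ValueError("concat_conv combination requires an MDPHead with weights")
    return head.conv(F.concat(maps, axis=1))


def _pad_channels(g, off, n, total):
    shape = list(g.shape)
    shape[1] = total
    out = np.zeros(shape, dtype=g.dtype)
    out[:, off : off + n] = g
    return out
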