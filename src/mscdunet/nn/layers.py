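"""Parameterized layers built on the autodiff core."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autodiff import Var

__all__ = ["Module", "Conv3d", "ConvTranspose3d", "BatchNorm3d", "xavier_uniform"]


def xavier_uniform(shape, fan_in, fan_out, rng, dtype):
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Module:
    """Base class: parameter collection and train/eval mode switching.

    Submodules and parameters are discovered from instance attributes in
    definition order, which keeps parameter ordering (and hence the
    optimizer state and any seeded initialization) deterministic.
    """

    def __init__(self):
        self._training = True

    def named_parameters(self, prefix=""):
        for name, attr in vars(self).items():
            if isinstance(attr, Var) and attr.requires_grad:
                yield f"{prefix}{name}", attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(f"{prefix}{name}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self):
        return int(sum(p.value.size for p in self.parameters()))

    def train(self, mode=True):
        self._training = mode
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.train(mode)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # --- checkpointing -----------------------------------------------------

    def state_arrays(self, prefix=""):
        """All persistent arrays (parameters + buffers) by name."""
        for name, p in self.named_parameters(prefix):
            yield name, p.value
        for name, buf in self._named_buffers(prefix):
            yield name, buf

    def _named_buffers(self, prefix=""):
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                yield from attr._named_buffers(f"{prefix}{name}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{prefix}{name}.{i}.")
            elif isinstance(attr, dict) and set(attr) == {"mean", "var"}:
                yield f"{prefix}{name}.mean", attr["mean"]
                yield f"{prefix}{name}.var", attr["var"]

    def load_state_arrays(self, arrays):
        own = dict(self.state_arrays())
        missing = set(own) - set(arrays)
        if missing:
            raise KeyError(f"checkpoint is missing arrays: {sorted(missing)}")
        for name, p in self.named_parameters():
            p.value = np.asarray(arrays[name]).astype(p.value.dtype)
        for name, buf in self._named_buffers():
            buf[...] = np.asarray(arrays[name])


class Conv3d(Module):
    """3x3x3 (or 1x1x1) convolution, stride 1, extent-preserving padding."""

    def __init__(self, cin, cout, k, rng, dtype=np.float32):
        super().__init__()
        k3 = k ** 3
        self.weight = Var(
            xavier_uniform((cout, cin, k, k, k), cin * k3, cout * k3, rng, dtype),
            requires_grad=True,
        )
        self.bias = Var(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return F.conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    """2x2x2 transposed convolution with stride 2 (extent doubling)."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        super().__init__()
        self.weight = Var(
            xavier_uniform((cin, cout, 2, 2, 2), cin, cout * 8, rng, dtype),
            requires_grad=True,
        )
        self.bias = Var(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return F.conv_transpose2(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, c, dtype=np.float32, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Var(np.ones(c, dtype=dtype), requires_grad=True)
        self.beta = Var(np.zeros(c, dtype=dtype), requires_grad=True)
        self.running = {
            "mean": np.zeros(c, dtype=np.float64),
            "var": np.ones(c, dtype=np.float64),
        }
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x):
        return F.batch_norm(
            x,
            self.gamma,
            self.beta,
            self.running,
            self._training,
            self.momentum,
            self.eps,
        )
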