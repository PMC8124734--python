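"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Var` wraps an ndarray together with the closures needed to
push gradients back to its parents. The engine is deliberately small:
every operator used by the segmentation network registers an explicit
backward function, and correctness is enforced by finite-difference
tests rather than by operator generality.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "as_var", "backward"]


class Var:
    """A node in the computation graph.

    Parameters
    ----------
    value : ndarray
        The forward value. Stored as-is (dtype preserved).
    parents : sequence of (Var, callable)
        Each callable maps the output gradient to that parent's
        gradient contribution. It is only invoked when the parent
        participates in differentiation.
    requires_grad : bool
        Marks trainable leaves. Interior nodes inherit the flag from
        their parents.
    """

    __slots__ = ("value", "grad", "_parents", "requires_grad")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value)
        self.grad = None
        self._parents = tuple(parents)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in self._parents
        )

    @property
    def shape(self):
        return self.value.shape

    @property
    def dtype(self):
        return self.value.dtype

    def zero_grad(self):
        self.grad = None

    def backward(self, seed=None):
        backward(self, seed)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.value.shape}, requires_grad={self.requires_grad})"


def as_var(x) -> Var:
    """Wrap ``x`` in a constant Var unless it already is one."""
    return x if isinstance(x, Var) else Var(np.asarray(x))


def _toposort(root: Var):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen and parent.requires_grad:
                stack.append((parent, False))
    return order


def backward(root: Var, seed=None):
    """Accumulate gradients of ``root`` into every reachable Var.

    ``seed`` defaults to ones (appropriate for a scalar loss).
    """
    if seed is None:
        seed = np.ones_like(root.value)
    root.grad = np.asarray(seed)
    for node in reversed(_toposort(root)):
        if node.grad is None:
            continue
        for parent, grad_fn in node._parents:
            if not parent.requires_grad:
                continue
            g = grad_fn(node.grad)
            if parent.grad is None:
                parent.grad = g
            else:
                parent.grad = parent.grad + g
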