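"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ndarray and a
closure that scatters its gradient to its parents.  Operations live in
:mod:`mrpunet.nn.functional`; each builds one graph node with a hand-written
backward pass (verified against finite differences in the test suite).
Graphs are rebuilt on every forward call, so control flow is plain Python.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """An ndarray node in a dynamically built computation graph.

    Parameters
    ----------
    data:
        Array payload. Stored as-is (callers control dtype; model weights
        are float32, gradient checks run in float64).
    requires_grad:
        Whether a gradient should be accumulated into ``.grad`` during
        :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _node(data, parents: Iterable["Tensor"], backward) -> "Tensor":
        """Create a non-leaf tensor with the given parents and backward."""
        parents = tuple(parents)
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    # -- properties ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward ------------------------------------------------------------

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Run reverse-mode accumulation from this tensor.

        ``grad`` defaults to 1 and therefore requires a scalar output (the
        usual loss case).
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topo sort; deep U-Nets overflow recursion
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.accumulate(g)
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if p._backward is None:  # leaf
                    p.accumulate(pg)
                elif id(p) in grads:
                    grads[id(p)] += pg
                else:
                    grads[id(p)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data


def as_tensor(x, dtype=np.float32) -> Tensor:
    """Wrap ``x`` as a constant (non-differentiable) Tensor."""
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))
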