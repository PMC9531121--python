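"""Layer/module abstractions on top of the autograd engine."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Parameter", "Module", "Conv2d", "Linear"]


class Parameter(Tensor):
    """A trainable tensor; ``trainable`` can be toggled to freeze it."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module system: children and parameters discovered by attribute."""

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Parameter) and id(item) not in seen:
                    seen.add(id(item))
                    yield item
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            yield p

    def set_trainable(self, trainable: bool) -> None:
        for p in self.parameters():
            p.requires_grad = trainable

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = list(self.parameters())
        if len(arrays) != len(params):
            raise ValueError(f"state mismatch: {len(arrays)} arrays for "
                             f"{len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32).copy()


class Conv2d(Module):
    """Stride-1 convolution with 'same' padding for odd kernels (He init)."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, pad: Optional[int] = None):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale,
                                           (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.pad = kernel // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias
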