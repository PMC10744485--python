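"""Convolutional building blocks on the autodiff core.

Channels-first, batch-free tensors: 2D feature maps are (C, H, W), 3D
feature maps (C, D, H, W).  He-normal initialisation throughout (the
networks are ReLU-activated).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "Conv3d", "ConvTranspose3d", "DenseBlock2d"]

DTYPE = np.float32


class Module:
    """Parameter container with torch-like ergonomics (tiny subset)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)
    return Tensor(w, requires_grad=True)


class _ConvNd(Module):
    def __init__(self, nd, c_in, c_out, kernel, stride, pad, rng, bias=True):
        kernel = (kernel,) * nd if np.isscalar(kernel) else tuple(kernel)
        self.stride = stride
        self.pad = pad
        fan_in = c_in * int(np.prod(kernel))
        self.weight = _he_init(rng, (c_out, c_in) + kernel, fan_in)
        self.bias = (
            Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv(x, self.weight, bias=self.bias, stride=self.stride, pad=self.pad)


class Conv2d(_ConvNd):
    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=1, *, rng, bias=True):
        super().__init__(2, c_in, c_out, kernel, stride, pad, rng, bias)


class Conv3d(_ConvNd):
    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=1, *, rng, bias=True):
        super().__init__(3, c_in, c_out, kernel, stride, pad, rng, bias)


class ConvTranspose3d(Module):
    """Stride-s transposed 3D convolution via zero-stuffing + plain conv.

    With kernel 4, stride 2, pad 1 it exactly doubles every spatial edge.
    """

    def __init__(self, c_in, c_out, kernel=4, stride=2, pad=1, *, rng, bias=True):
        kernel = (kernel,) * 3 if np.isscalar(kernel) else tuple(kernel)
        self.kernel = kernel
        self.stride = stride
        self.pad = pad
        fan_in = c_in * int(np.prod(kernel))
        self.weight = _he_init(rng, (c_in, c_out) + kernel, fan_in)
        self.bias = (
            Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        stuffed = ad.zero_stuff(x, self.stride)
        w = ad.flip(ad.transpose(self.weight, (1, 0, 2, 3, 4)), (2, 3, 4))
        full_pad = tuple(k - 1 - self.pad for k in self.kernel)
        y = ad.conv(stuffed, w, bias=self.bias, stride=1, pad=full_pad)
        # target extent (S-1)*stride - 2*pad + kernel; trim the overshoot
        target = tuple(
            (s - 1) * self.stride - 2 * self.pad + k
            for s, k in zip(x.shape[1:], self.kernel)
        )
        if y.shape[1:] != target:
            y = ad.crop(y, (slice(None),) + tuple(slice(0, t) for t in target))
        return y


class DenseBlock2d(Module):
    """Two 3x3 convolutions with a dense (concatenative) connection."""

    def __init__(self, c_in, c_out, *, rng):
        self.conv1 = Conv2d(c_in, c_out, rng=rng)
        self.conv2 = Conv2d(c_in + c_out, c_out, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y1 = ad.relu(self.conv1(x))
        return ad.relu(self.conv2(ad.concat([x, y1], axis=0)))
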