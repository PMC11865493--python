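"""Residual U-Net for image restoration, implemented directly in NumPy.

Architecture: a contracting path of `depth` blocks (two 3x3 convolutions +
ReLU, then 2x2 max pooling), a bottleneck, and an expansive path of `depth`
blocks (2x2 nearest-neighbour upsampling, concatenation with the
skip-connected encoder feature map, two 3x3 convolutions + ReLU).  A final
1x1 convolution produces a single channel that is added to the network
input (residual head), so the freshly initialized model is the identity and
training learns a correction field.

Every layer carries an explicit backward pass, so the model trains with
first-order optimizers without a deep-learning framework.  Convolutions are
evaluated channels-last as a sum over kernel offsets of contiguous-slab
matrix products, which keeps the working set small and the BLAS calls
large; the public interface stays (B, C, H, W).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetworkConfig", "ResidualUNet", "build_network"]


@dataclass(frozen=True)
class NetworkConfig:
    depth: int = 3
    base_filters: int = 32
    kernel: int = 3
    in_channels: int = 1
    residual_output: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd")


class Conv2D:
    """Same-padding convolution on (B, H, W, C) tensors.

    Weights are stored as (k*k, Cin, Cout): one (Cin, Cout) matrix per
    kernel offset.  Forward output is the sum over offsets of a shifted
    input slab times that matrix; backward reuses the same slabs for the
    weight gradient and scatters ``dout @ W^T`` back into the padded grid
    for the input gradient.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False, dtype=np.float32):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        if zero_init:
            self.w = np.zeros((k * k, c_in, c_out), dtype=dtype)
        else:
            self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                size=(k * k, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp = None  # padded input kept for backward

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        b, h, w, _ = x.shape
        xp = self._pad(x)
        if keep:
            self._xp, self._shape = xp, (b, h, w)
        out = None
        for idx in range(self.k * self.k):
            ki, kj = divmod(idx, self.k)
            xs = np.ascontiguousarray(xp[:, ki:ki + h, kj:kj + w, :])
            term = xs.reshape(-1, self.c_in) @ self.w[idx]
            out = term if out is None else out + term
        out += self.b
        return out.reshape(b, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w = self._shape
        d2 = np.ascontiguousarray(dout).reshape(-1, self.c_out)
        self.db += d2.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for idx in range(self.k * self.k):
            ki, kj = divmod(idx, self.k)
            xs = np.ascontiguousarray(self._xp[:, ki:ki + h, kj:kj + w, :])
            self.dw[idx] += xs.reshape(-1, self.c_in).T @ d2
            dxs = (d2 @ self.w[idx].T).reshape(b, h, w, self.c_in)
            dxp[:, ki:ki + h, kj:kj + w, :] += dxs
        self._xp = None
        p = self.k // 2
        return dxp[:, p:p + h, p:p + w, :] if p else dxp

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if keep:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if keep:
            # ties (rare on float activations) share the gradient evenly
            eq = xr == out[:, :, None, :, None, :]
            self._route = eq / eq.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout[:, :, None, :, None, :] * self._route
        b, h2, _, w2, _, c = d.shape
        return d.reshape(b, h2 * 2, w2 * 2, c)


class Upsample2:
    """2x2 nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = dout.shape
        return dout.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class ResidualUNet:
    """Depth-`d` residual U-Net; input H and W must be multiples of 2**d."""

    def __init__(self, config: NetworkConfig, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(config.seed)
        f, k, d = config.base_filters, config.kernel, config.depth

        def block(c_in, c_out):
            return [Conv2D(c_in, c_out, k, rng, dtype=dtype), ReLU(),
                    Conv2D(c_out, c_out, k, rng, dtype=dtype), ReLU()]

        self.enc = []
        c = config.in_channels
        for i in range(d):
            c_out = f * 2**i
            self.enc.append(block(c, c_out))
            c = c_out
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = block(c, f * 2**d)
        self.ups = [Upsample2() for _ in range(d)]
        self.dec = []
        c = f * 2**d
        for i in reversed(range(d)):
            c_out = f * 2**i
            self.dec.append(block(c + c_out, c_out))
            c = c_out
        # zero-initialized head: the untrained network is the identity map
        self.head = Conv2D(c, config.in_channels, 1, rng, zero_init=True, dtype=dtype)

    # -- parameter access ---------------------------------------------------
    def conv_layers(self) -> list[Conv2D]:
        convs = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            convs.extend(l for l in blk if isinstance(l, Conv2D))
        convs.append(self.head)
        return convs

    def parameters(self):
        out = []
        for conv in self.conv_layers():
            out.extend(conv.params)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def zero_grad(self) -> None:
        for conv in self.conv_layers():
            conv.dw[...] = 0.0
            conv.db[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for conv in self.conv_layers():
            out.extend([conv.w.copy(), conv.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for conv in self.conv_layers():
            conv.w[...] = next(it)
            conv.b[...] = next(it)

    # -- forward / backward -------------------------------------------------
    def _check(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (B, {self.config.in_channels}, H, W), got {x.shape}")
        m = 2**self.config.depth
        if x.shape[2] % m or x.shape[3] % m:
            raise ValueError(f"H and W must be multiples of {m}, got {x.shape[2:]}")
        return np.asarray(x, dtype=self.dtype)

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        x = self._check(x)
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # to channels-last
        inp = x
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            for layer in blk:
                x = layer.forward(x, keep)
            skips.append(x)
            x = pool.forward(x, keep)
        for layer in self.bottleneck:
            x = layer.forward(x, keep)
        for blk, up, skip in zip(self.dec, self.ups, reversed(skips)):
            x = up.forward(x, keep)
            x = np.concatenate([skip, x], axis=-1)
            for layer in blk:
                x = layer.forward(x, keep)
        out = self.head.forward(x, keep)
        if self.config.residual_output:
            out = out + inp
        if keep:
            self._skip_channels = [s.shape[-1] for s in skips]
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.ascontiguousarray(
            np.asarray(dout, dtype=self.dtype).transpose(0, 2, 3, 1))
        dx = self.head.backward(dout)
        dskips = [None] * len(self.dec)
        for i in reversed(range(len(self.dec))):
            for layer in reversed(self.dec[i]):
                dx = layer.backward(dx)
            c_skip = self._skip_channels[len(self.dec) - 1 - i]
            dskips[i] = dx[..., :c_skip]
            dx = self.ups[i].backward(dx[..., c_skip:])
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        for i in reversed(range(len(self.enc))):
            dx = self.pools[i].backward(dx)
            dx = dx + dskips[len(self.enc) - 1 - i]
            for layer in reversed(self.enc[i]):
                dx = layer.backward(dx)
        # residual head: the input gradient also receives dout, but the input
        # carries no parameters so it is only returned
        if self.config.residual_output:
            dx = dx + dout
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, keep=False)


def build_network(config: NetworkConfig | None = None, dtype=np.float32) -> ResidualUNet:
    return ResidualUNet(config or NetworkConfig(), dtype=dtype)
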