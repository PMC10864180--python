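"""Minimal volumetric U-Net on numpy with hand-written backpropagation.

A compact encoder–decoder with skip connections, sized for CPU training on
small 3D patches: two pooling levels, 3x3x3 convolutions with leaky ReLU
(slope 0.1 on the negative side — hard ReLUs can die irrecoverably in
networks this small, collapsing the output to a constant), nearest
upsampling, channel concatenation and a linear 1x1x1 output head.  Convolution
is evaluated as a strided sliding-window view contracted against the kernel
with ``tensordot`` (BLAS-backed), which keeps training of desk-scale patches
in the tens-of-seconds range on one core.

Tensors are channel-first float32: ``(C, D, H, W)``.  Spatial dimensions must
be divisible by ``2**depth`` at training time so pooling and upsampling round
trip exactly.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError


def _he_std(fan_in: float) -> float:
    return float(np.sqrt(2.0 / fan_in))


#: negative-side slope of the leaky ReLU
LEAK = 0.1


def _offsets(k: int):
    return [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]


class Conv3d:
    """Same-padded stride-1 3D convolution, optionally fused with ReLU.

    Forward and backward are expressed as single GEMMs against an im2col
    matrix built with 27 contiguous slice copies; the matrix is cached on the
    instance so the weight-gradient GEMM reuses it.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 relu: bool = True):
        fan_in = cin * k ** 3
        std = _he_std(fan_in) if relu else float(np.sqrt(1.0 / fan_in))
        self.w = rng.normal(0.0, std, (cout, cin, k, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.cin = cin
        self.cout = cout
        self.relu = relu
        self._cols = None
        self._slope = None
        self._shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(C*k^3, Nvox) matrix of padded sliding windows."""
        c, d, h, w = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
        cols = np.empty((c, k ** 3, d * h * w), dtype=np.float32)
        for m, (i, j, l) in enumerate(_offsets(k)):
            cols[:, m, :] = xp[:, i:i + d, j:j + h, l:l + w].reshape(c, -1)
        return cols.reshape(c * k ** 3, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._shape = x.shape
        c, d, h, w = x.shape
        if self.k == 1:
            self._cols = x.reshape(c, -1)
        else:
            self._cols = self._im2col(x)
        wmat = self.w.reshape(self.cout, -1)
        y = (wmat @ self._cols).reshape(self.cout, d, h, w)
        y += self.b[:, None, None, None]
        if self.relu:
            self._slope = np.where(y > 0, np.float32(1.0), np.float32(LEAK))
            np.multiply(y, self._slope, out=y)
        return y

    def backward(self, dy: np.ndarray):
        """Returns dx; leaves dw, db on the instance."""
        if self.relu:
            dy = dy * self._slope
        c, d, h, w = self._shape
        dy_mat = np.ascontiguousarray(dy, dtype=np.float32).reshape(self.cout, -1)
        self.db = dy_mat.sum(axis=1)
        self.dw = (dy_mat @ self._cols.T).reshape(self.w.shape)
        wmat = self.w.reshape(self.cout, -1)
        dcols = wmat.T @ dy_mat  # (C*k^3, Nvox)
        if self.k == 1:
            return dcols.reshape(c, d, h, w)
        # col2im: scatter-add each kernel offset back into the padded grid
        k, pad = self.k, self.k // 2
        dxp = np.zeros((c, d + 2 * pad, h + 2 * pad, w + 2 * pad),
                       dtype=np.float32)
        dcols = dcols.reshape(c, k ** 3, d, h, w)
        for m, (i, j, l) in enumerate(_offsets(k)):
            dxp[:, i:i + d, j:j + h, l:l + w] += dcols[:, m]
        return dxp[:, pad:pad + d, pad:pad + h, pad:pad + w]


class MaxPool3d:
    """2x max pooling on every spatial axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise GeometryError(f"spatial dims must be even for pooling, got {x.shape}")
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(
            c, d // 2, h // 2, w // 2, 8)
        self._arg = blocks.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(blocks, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d2, h2, w2 = dy.shape
        blocks = np.zeros((c, d2, h2, w2, 8), dtype=np.float32)
        np.put_along_axis(blocks, self._arg[..., None], dy[..., None], axis=-1)
        blocks = blocks.reshape(c, d2, h2, w2, 2, 2, 2).transpose(
            0, 1, 4, 2, 5, 3, 6)
        return np.ascontiguousarray(blocks.reshape(self._shape))


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling on every spatial axis."""
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class UNet3D:
    """Depth-2 volumetric U-Net with linear output.

    Channel plan with base ``C``: encoder ``1→C`` (full res) and ``C→2C``
    (half res), bottleneck ``2C→4C`` (quarter res), decoder convs take the
    upsampled features concatenated with the matching skip, and a 1x1x1
    linear head maps back to one channel.
    """

    def __init__(self, base_channels: int = 8, depth: int = 2, seed: int = 0):
        if depth != 2:
            raise GeometryError("this implementation is fixed at depth 2")
        rng = np.random.default_rng(seed)
        c = base_channels
        self.depth = depth
        self.base_channels = c
        self.enc0 = Conv3d(1, c, 3, rng)
        self.enc1 = Conv3d(c, 2 * c, 3, rng)
        self.bott = Conv3d(2 * c, 4 * c, 3, rng)
        self.dec1 = Conv3d(4 * c + 2 * c, 2 * c, 3, rng)
        self.dec0 = Conv3d(2 * c + c, c, 3, rng)
        self.head = Conv3d(c, 1, 1, rng, relu=False)
        self.pool0 = MaxPool3d()
        self.pool1 = MaxPool3d()
        self._convs = [self.enc0, self.enc1, self.bott,
                       self.dec1, self.dec0, self.head]

    def check_shape(self, shape):
        if any(s % (2 ** self.depth) for s in shape):
            raise GeometryError(
                f"spatial shape {tuple(shape)} must be divisible by "
                f"{2 ** self.depth} on every axis"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (D, H, W) or (1, D, H, W) float32, normalized intensities."""
        if x.ndim == 3:
            x = x[None]
        self.check_shape(x.shape[1:])
        x = np.ascontiguousarray(x, dtype=np.float32)
        d0 = self.enc0.forward(x)
        d1 = self.enc1.forward(self.pool0.forward(d0))
        b = self.bott.forward(self.pool1.forward(d1))
        u1 = upsample2(b)
        e1 = self.dec1.forward(np.concatenate([u1, d1], axis=0))
        u0 = upsample2(e1)
        e0 = self.dec0.forward(np.concatenate([u0, d0], axis=0))
        y = self.head.forward(e0)
        self._split1 = u1.shape[0]
        self._split0 = u0.shape[0]
        return y

    def __call__(self, x: np.ndarray) -> np.ndarray:
        squeeze = x.ndim == 3
        y = self.forward(x)
        return y[0] if squeeze else y

    def backward(self, dy: np.ndarray):
        """Backpropagate loss gradient dy (1, D, H, W); fills conv grads."""
        g = self.head.backward(dy)
        g = self.dec0.backward(g)
        gu0, gd0 = g[: self._split0], g[self._split0:]
        g = upsample2_backward(gu0)
        g = self.dec1.backward(g)
        gu1, gd1 = g[: self._split1], g[self._split1:]
        g = upsample2_backward(gu1)
        g = self.bott.backward(g)
        g = self.pool1.backward(g)
        g = self.enc1.backward(g + gd1)
        g = self.pool0.backward(g)
        g = self.enc0.backward(g + gd0)
        return g

    # -- parameter access -------------------------------------------------
    def parameters(self):
        """Flat list of (array, grad_attr_name, owner) for the optimizer."""
        out = []
        for i, conv in enumerate(self._convs):
            out.append((f"conv{i}_w", conv, "w", "dw"))
            out.append((f"conv{i}_b", conv, "b", "db"))
        return out

    def state_dict(self) -> dict:
        state = {}
        for name, conv, attr, _ in self.parameters():
            state[name] = getattr(conv, attr)
        return state

    def load_state_dict(self, state: dict):
        for name, conv, attr, _ in self.parameters():
            setattr(conv, attr, np.ascontiguousarray(state[name], dtype=np.float32))


class Adam:
    """Adam optimizer over a UNet3D's parameters."""

    def __init__(self, net: UNet3D, lr: float = 4e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(getattr(conv, attr))
                  for name, conv, attr, _ in net.parameters()}
        self.v = {name: np.zeros_like(getattr(conv, attr))
                  for name, conv, attr, _ in net.parameters()}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, conv, attr, gattr in self.net.parameters():
            g = getattr(conv, gattr)
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p = getattr(conv, attr)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
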