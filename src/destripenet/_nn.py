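"""Minimal convolutional-network engine on numpy.

Implements exactly what the correction network needs: 3x3 stride-1
convolutions with replicate (edge) padding, ReLU, identity-shortcut residual
blocks, manual reverse-mode gradients, and an Adam optimizer.  Convolutions
are evaluated as batched matrix products (im2col) so the heavy lifting stays
in BLAS.

All tensors are channel-first: (B, C, H, W).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "ResidualBlock", "CorrectionNet", "Adam"]

_OFFSETS = [(i, j) for i in range(3) for j in range(3)]


def _im2col(xp: np.ndarray, h: int, w: int) -> np.ndarray:
    """(B, C, H+2, W+2) edge-padded input -> (B, C*9, H*W) patch matrix."""
    b, c = xp.shape[:2]
    cols = np.empty((b, c, 9, h * w), dtype=xp.dtype)
    for k, (i, j) in enumerate(_OFFSETS):
        cols[:, :, k, :] = xp[:, :, i:i + h, j:j + w].reshape(b, c, h * w)
    return cols.reshape(b, c * 9, h * w)


def _col2im(dcols: np.ndarray, b: int, c: int, h: int, w: int) -> np.ndarray:
    """Scatter-add patch gradients back to a padded image, then fold the
    replicate-padding gradient onto the edge pixels."""
    dcols = dcols.reshape(b, c, 9, h, w)
    gp = np.zeros((b, c, h + 2, w + 2), dtype=dcols.dtype)
    for k, (i, j) in enumerate(_OFFSETS):
        gp[:, :, i:i + h, j:j + w] += dcols[:, :, k]
    # gradient of edge padding: padded border rows/cols came from the border
    gp[:, :, 1, :] += gp[:, :, 0, :]
    gp[:, :, -2, :] += gp[:, :, -1, :]
    g = gp[:, :, 1:-1, :]
    g[:, :, :, 1] += g[:, :, :, 0]
    g[:, :, :, -2] += g[:, :, :, -1]
    return g[:, :, :, 1:-1]


class Conv3x3:
    """3x3 convolution, stride 1, replicate padding 1 (shape-preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.c_in, self.c_out = c_in, c_out
        # He fan-in initialization; biases start at zero.
        std = np.sqrt(2.0 / (9 * c_in))
        self.w = rng.normal(0.0, std, size=(c_out, c_in * 9)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        if h < 3 or w < 3:
            raise ValueError(f"spatial size {h}x{w} smaller than the 3x3 kernel")
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")
        cols = _im2col(xp, h, w)
        if keep:
            self._cols, self._shape = cols, x.shape
        y = np.matmul(self.w[None], cols)  # (B, c_out, H*W)
        y += self.b[None, :, None]
        return y.reshape(b, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dyf = dy.reshape(dy.shape[0], self.c_out, h * w)
        self.gw += np.einsum("bop,bcp->oc", dyf, self._cols)
        self.gb += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T[None], dyf)
        self._cols = None
        return _col2im(dcols, b, c, h, w)

    def params(self):
        return [(self, "w", "gw"), (self, "b", "gb")]


class ResidualBlock:
    """conv -> ReLU -> conv, add identity shortcut, ReLU (post-activation)."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv3x3(channels, channels, rng, dtype)
        self.conv2 = Conv3x3(channels, channels, rng, dtype)
        self._m1 = self._m2 = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        a = self.conv1.forward(x, keep)
        m1 = a > 0
        np.multiply(a, m1, out=a)
        y = self.conv2.forward(a, keep)
        y += x
        m2 = y > 0
        np.multiply(y, m2, out=y)
        if keep:
            self._m1, self._m2 = m1, m2
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._m2
        da = self.conv2.backward(dy)
        da *= self._m1
        dx = self.conv1.backward(da)
        dx += dy  # shortcut path
        self._m1 = self._m2 = None
        return dx

    def params(self):
        return self.conv1.params() + self.conv2.params()


class CorrectionNet:
    """Head conv + ReLU, ``n_blocks`` residual blocks, linear tail conv.

    With the default widths this is the 14-convolution artifact-correction
    network: 2 standalone 3x3 convs plus 6 residual blocks of 2 convs each.
    The tail is linear because artifact coefficients are signed.
    """

    def __init__(self, c_in: int, c_hidden: int, c_out: int, n_blocks: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.head = Conv3x3(c_in, c_hidden, rng, dtype)
        self.blocks = [ResidualBlock(c_hidden, rng, dtype) for _ in range(n_blocks)]
        self.tail = Conv3x3(c_hidden, c_out, rng, dtype)
        self._mh = None

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        a = self.head.forward(x, keep)
        mh = a > 0
        np.multiply(a, mh, out=a)
        if keep:
            self._mh = mh
        for blk in self.blocks:
            a = blk.forward(a, keep)
        return self.tail.forward(a, keep)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        da = self.tail.backward(dy)
        for blk in reversed(self.blocks):
            da = blk.backward(da)
        da *= self._mh
        self._mh = None
        return self.head.backward(da)

    # -- parameter bookkeeping -------------------------------------------
    def conv_layers(self) -> list[Conv3x3]:
        layers = [self.head]
        for blk in self.blocks:
            layers += [blk.conv1, blk.conv2]
        layers.append(self.tail)
        return layers

    def params(self):
        out = []
        for layer in self.conv_layers():
            out += layer.params()
        return out

    def zero_grad(self) -> None:
        for obj, _, gname in self.params():
            getattr(obj, gname)[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(getattr(obj, name).size for obj, name, _ in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [getattr(obj, name).copy() for obj, name, _ in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        own = self.params()
        if len(state) != len(own):
            raise ValueError("state does not match network layout")
        for (obj, name, _), arr in zip(own, state):
            cur = getattr(obj, name)
            if cur.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}: {cur.shape} vs {arr.shape}")
            cur[...] = arr

    def astype(self, dtype) -> "CorrectionNet":
        for obj, name, gname in self.params():
            setattr(obj, name, getattr(obj, name).astype(dtype))
            setattr(obj, gname, getattr(obj, gname).astype(dtype))
        return self


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, net: CorrectionNet, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n)) for o, n, _ in net.params()]
        self.v = [np.zeros_like(getattr(o, n)) for o, n, _ in net.params()]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (obj, name, gname), m, v in zip(self.net.params(), self.m, self.v):
            g = getattr(obj, gname)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            getattr(obj, name)[...] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
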