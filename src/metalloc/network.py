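"""Fully-convolutional 3D segmentation network for per-voxel zinc probability.

The model maps an (8, 32, 32, 32) environment tensor to a
(1, 32, 32, 32) probability tensor.  Every layer is a same-padded 3-D
convolution with a 3-voxel (1.5 A) filter, except the fifth layer whose
16-voxel (8 A) filter aggregates long-range context; ReLU
nonlinearities are used throughout, a dropout layer (p = 0.1) sits
between the fifth and sixth layers, and a final sigmoid yields the
per-voxel probability.  Training uses binary cross-entropy with
AdaDelta and a stepped learning rate (lr = 0.5, gamma = 0.9).

The implementation is a self-contained numpy/scipy one: convolutions
(forward and backward) are evaluated in the Fourier domain on a common
zero-padded transform shape, which makes the wide fifth-layer filter no
more expensive than the narrow ones.  It is intended for desk-scale
training and inference, not for GPU-scale dataset runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as sfft

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "Metal3DNet",
    "build_network",
    "train_smoke",
    "bce_loss",
]

_GRID = 32
# Common zero-padded transform size.  48 >= 32 + 16 - 1 covers the widest
# same-padded convolution, and the circular correlations used for the
# gradients do not alias either: supports are 32 wide and lags at most
# +/- 8, so wrapped indices always land in zero padding.
_FFT = 48


@dataclass
class NetworkSpec:
    """Architecture contract of the segmentation network.

    ``hidden_channels`` are the per-layer output widths of the five
    hidden layers (the published figure does not pin them, so they are
    configurable; the defaults are sized to train on a desk CPU);
    ``filter_sizes`` must contain exactly one 16-voxel filter at the
    fifth layer.
    """

    in_channels: int = 8
    hidden_channels: tuple[int, ...] = (4, 6, 6, 4, 3)
    out_channels: int = 1
    filter_sizes: tuple[int, ...] = (3, 3, 3, 3, 16, 3)
    dropout: float = 0.1
    dropout_after_layer: int = 5  # between the 5th and 6th layers

    def __post_init__(self) -> None:
        if self.in_channels != 8 or self.out_channels != 1:
            raise ValueError("network contract is 8 channels in, 1 channel out")
        if len(self.filter_sizes) != len(self.hidden_channels) + 1:
            raise ValueError("need one filter size per layer")
        wide = [i for i, k in enumerate(self.filter_sizes) if k == 16]
        if wide != [4]:
            raise ValueError("exactly one 16-voxel filter, at the fifth layer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def channel_plan(self) -> list[tuple[int, int]]:
        widths = (self.in_channels, *self.hidden_channels, self.out_channels)
        return list(zip(widths[:-1], widths[1:]))


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults as published)."""

    learning_rate: float = 0.5
    gamma: float = 0.9  # stepped learning-rate decay factor
    lr_step_epochs: int = 1  # epochs between decay steps
    batch_size: int = 150
    epochs: int = 12
    rho: float = 0.9  # AdaDelta accumulator decay
    eps: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.gamma, self.batch_size, self.epochs,
               self.lr_step_epochs) <= 0:
            raise ValueError("all training parameters must be positive")


def _same_slices(n: int, k: int) -> tuple[int, int]:
    """Start offsets into the full convolution for same-size output and
    for the input gradient."""
    s = (k - 1) // 2
    return s, k - 1 - s


def _flip_phase(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis phase ramps turning conj(FFT(w)) into FFT(flip(w)).

    For a real kernel supported on [0, k), flipping in the spatial
    domain multiplies the conjugate spectrum by exp(-2*pi*i*f*(k-1)/L).
    Returns (full-axis ramp, half-axis ramp) for an rfftn layout.
    """
    full = np.exp(-2j * np.pi * np.arange(_FFT) * (k - 1) / _FFT)
    half = full[: _FFT // 2 + 1]
    return full.astype(np.complex64), half.astype(np.complex64)


class _ConvLayer:
    """Same-padded 3-D convolution evaluated in the Fourier domain.

    Forward caches the input spectrum and the kernel spectrum so the
    backward pass reuses them; the flipped-kernel spectrum needed for
    the input gradient is derived from the cached one by the conjugate
    phase identity rather than extra transforms.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k ** 3))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self._xf: np.ndarray | None = None
        self._wf: np.ndarray | None = None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        s, _ = _same_slices(_GRID, self.k)
        xf = sfft.rfftn(x, s=(_FFT,) * 3, axes=(-3, -2, -1))
        wf = sfft.rfftn(self.w, s=(_FFT,) * 3, axes=(-3, -2, -1))
        if keep:
            self._xf, self._wf = xf, wf
            self._x = x if self.k == 3 else None
        yf = np.einsum("bi...,oi...->bo...", xf, wf)
        y = sfft.irfftn(yf, s=(_FFT,) * 3, axes=(-3, -2, -1))
        y = y[..., s:s + _GRID, s:s + _GRID, s:s + _GRID]
        return (y + self.b[None, :, None, None, None]).astype(np.float32)

    def backward(self, grad_y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (grad_x, grad_w, grad_b); requires forward(keep=True)."""
        assert self._xf is not None and self._wf is not None
        k = self.k
        s, s2 = _same_slices(_GRID, k)
        gf = sfft.rfftn(grad_y, s=(_FFT,) * 3, axes=(-3, -2, -1))
        # input gradient: full conv of grad with flipped kernel
        full, half = _flip_phase(k)
        wf_flip = self._wf.conj() * full[:, None, None] * full[None, :, None] \
            * half[None, None, :]
        gxf = np.einsum("bo...,oi...->bi...", gf, wf_flip)
        gx = sfft.irfftn(gxf, s=(_FFT,) * 3, axes=(-3, -2, -1))
        gx = gx[..., s2:s2 + _GRID, s2:s2 + _GRID, s2:s2 + _GRID]
        if k == 3:
            # narrow filter: 27 shifted inner products are cheaper than
            # per-kernel-pair inverse transforms
            pad = np.pad(self._x, ((0, 0), (0, 0)) + ((s, k - 1 - s),) * 3)
            gw = np.empty(self.w.shape, dtype=np.float32)
            for j1 in range(k):
                for j2 in range(k):
                    for j3 in range(k):
                        win = pad[:, :,
                                  s - j1 + s:s - j1 + s + _GRID,
                                  s - j2 + s:s - j2 + s + _GRID,
                                  s - j3 + s:s - j3 + s + _GRID]
                        gw[:, :, j1, j2, j3] = np.einsum(
                            "boxyz,bixyz->oi", grad_y, win)
        else:
            # circular correlation of input with grad via the conjugate
            # spectrum; lag j - s wraps modulo the FFT size
            gwf = np.einsum("bi...,bo...->oi...", self._xf.conj(), gf)
            gw_full = sfft.irfftn(gwf, s=(_FFT,) * 3, axes=(-3, -2, -1))
            jidx = (np.arange(k) - s) % _FFT
            gw = gw_full[..., jidx[:, None, None], jidx[None, :, None],
                         jidx[None, None, :]]
        gb = grad_y.sum(axis=(0, 2, 3, 4))
        return gx.astype(np.float32), gw.astype(np.float32), gb.astype(np.float32)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(probabilities: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy over all voxels."""
    p = np.clip(probabilities, 1e-7, 1.0 - 1e-7)
    y = targets
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class Metal3DNet:
    """The buildable segmentation model.

    Call :meth:`predict` on an (8,32,32,32) array (or a batch) to get
    per-voxel zinc probabilities.
    """

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0):
        self.spec = spec or NetworkSpec()
        rng = np.random.default_rng(seed)
        self.layers = [
            _ConvLayer(c_in, c_out, k, rng)
            for (c_in, c_out), k in zip(self.spec.channel_plan, self.spec.filter_sizes)
        ]
        # negative output bias: start near-empty densities, as the
        # target class (zinc voxels) is rare
        self.layers[-1].b[:] = -2.0
        self.seed = seed

    def parameters(self) -> list[np.ndarray]:
        params = []
        for layer in self.layers:
            params.extend([layer.w, layer.b])
        return params

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits of shape (B, 1, 32, 32, 32)."""
        x = np.asarray(x, dtype=np.float32)
        squeeze = x.ndim == 4
        if squeeze:
            x = x[None]
        if x.shape[1:] != (self.spec.in_channels, _GRID, _GRID, _GRID):
            raise ValueError(f"expected (B,{self.spec.in_channels},32,32,32), "
                             f"got {x.shape}")
        self._cache = []
        h = x
        for i, layer in enumerate(self.layers):
            z = layer.forward(h, keep=train)
            last = i == len(self.layers) - 1
            if not last:
                mask_relu = z > 0
                h = z * mask_relu
                drop_mask = None
                if train and self.spec.dropout > 0 and \
                        i == self.spec.dropout_after_layer - 1:
                    assert rng is not None, "training forward needs an rng"
                    drop_mask = (rng.random(h.shape) >= self.spec.dropout)
                    h = h * drop_mask / (1.0 - self.spec.dropout)
                if train:
                    self._cache.append((mask_relu, drop_mask))
            else:
                h = z
        return h[0] if squeeze else h

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-voxel probabilities in (0, 1)."""
        return _sigmoid(self.forward(x, train=False))

    def backward(self, grad_logits: np.ndarray) -> list[np.ndarray]:
        """Gradients for every parameter, matching :meth:`parameters`."""
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        g = grad_logits.astype(np.float32)
        for i in reversed(range(len(self.layers))):
            layer = self.layers[i]
            gx, gw, gb = layer.backward(g)
            grads.append((gw, gb))
            if i > 0:
                mask_relu, drop_mask = self._cache[i - 1]
                g = gx
                if drop_mask is not None:
                    g = g * drop_mask / (1.0 - self.spec.dropout)
                g = g * mask_relu
        flat: list[np.ndarray] = []
        for gw, gb in reversed(grads):
            flat.extend([gw, gb])
        return flat


def build_network(spec: NetworkSpec | None = None, seed: int = 0) -> Metal3DNet:
    """Construct the model; the same seed gives bit-identical weights."""
    return Metal3DNet(spec=spec, seed=seed)


class _AdaDelta:
    def __init__(self, params: list[np.ndarray], rho: float, eps: float):
        self.params = params
        self.rho = rho
        self.eps = eps
        self.eg2 = [np.zeros_like(p) for p in params]
        self.ex2 = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        for p, g, eg2, ex2 in zip(self.params, grads, self.eg2, self.ex2):
            eg2 *= self.rho
            eg2 += (1 - self.rho) * g * g
            delta = -np.sqrt(ex2 + self.eps) / np.sqrt(eg2 + self.eps) * g
            ex2 *= self.rho
            ex2 += (1 - self.rho) * delta * delta
            p += lr * delta


def train_smoke(model: Metal3DNet,
                examples: Sequence[tuple[np.ndarray, np.ndarray]],
                config: TrainConfig | None = None) -> list[float]:
    """Desk-scale training loop; returns the per-epoch mean BCE loss.

    ``examples`` is a sequence of (input (8,32,32,32), target
    (1,32,32,32)) pairs.  Shapes are validated before any update.
    """
    config = config or TrainConfig()
    if not examples:
        raise ValueError("no training examples")
    for x, y in examples:
        if np.shape(x) != (model.spec.in_channels, _GRID, _GRID, _GRID):
            raise ValueError(f"bad input shape {np.shape(x)}")
        if np.shape(y) != (1, _GRID, _GRID, _GRID):
            raise ValueError(f"bad target shape {np.shape(y)}")
    xs = np.stack([np.asarray(x, dtype=np.float32) for x, _ in examples])
    ys = np.stack([np.asarray(y, dtype=np.float32) for _, y in examples])
    rng = np.random.default_rng(config.seed)
    optimizer = _AdaDelta(model.parameters(), config.rho, config.eps)
    n = len(examples)
    losses = []
    lr = config.learning_rate
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = xs[idx], ys[idx]
            logits = model.forward(xb, train=True, rng=rng)
            p = _sigmoid(logits)
            epoch_losses.append(bce_loss(p, yb))
            grad_logits = (p - yb) / p.size
            grads = model.backward(grad_logits)
            optimizer.step(grads, lr)
        losses.append(float(np.mean(epoch_losses)))
        if epoch % config.lr_step_epochs == 0:
            lr *= config.gamma
    return losses
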