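"""3D encoder-decoder segmentation network (U-Net) in pure numpy.

The network follows the standard U-Net layout: `depth` downsampling blocks,
each 2 x (convolution, dropout, instance norm, leaky ReLU) followed by
2x2x2 max pooling; a bottleneck block; and a mirrored decoder using
transposed convolutions and skip connections. Output channels pass through
independent per-class logistic activations — tracts overlap spatially, so
this is multi-label, not softmax, segmentation.

Dropout lives in the encoder blocks only and can be re-enabled at inference
to draw stochastic predictions (test-time dropout). Forward and backward
passes are implemented directly on numpy arrays (im2col convolutions),
which is ample for the desk-scale profiles this package trains.

Arrays at the public surface are channel-last (X, Y, Z, C), matching
SHVolume; internals are channel-first.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ShapeError


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    in_channels: SH coefficient channels (15 for lmax=4).
    out_channels: number of tract classes.
    depth: number of down/upsampling blocks (4 in the full-scale profile).
    base_filters: channels of the first encoder block; doubled per level.
    dropout_rate: encoder dropout probability r, also used at test time.
    negative_slope: leaky-ReLU slope on the negative side.
    """

    in_channels: int = 15
    out_channels: int = 72
    depth: int = 4
    base_filters: int = 32
    dropout_rate: float = 0.25
    negative_slope: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be positive")

    @classmethod
    def tiny(cls, out_channels: int = 3, **kw) -> "ModelConfig":
        """Desk-scale profile: depth 2, 8 base filters, 16^3 patches."""
        kw.setdefault("depth", 2)
        kw.setdefault("base_filters", 8)
        return cls(out_channels=out_channels, **kw)


class _Param:
    __slots__ = ("value", "grad", "vel", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = value
        self.grad = np.zeros_like(value)
        self.vel = np.zeros_like(value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


DTYPE = np.float32  # network compute precision


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class _Conv3:
    """3x3x3 convolution, stride 1, same padding, via im2col."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        self.cin, self.cout = cin, cout
        self.w = _Param(_he_uniform(rng, (cout, cin * 27), cin * 27), f"{name}.w")
        self.b = _Param(np.zeros(cout, dtype=DTYPE), f"{name}.b")

    @property
    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _cols(x: np.ndarray) -> np.ndarray:
        pad = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        win = sliding_window_view(pad, (3, 3, 3), axis=(1, 2, 3))
        # (C, X, Y, Z, 3, 3, 3) -> (XYZ, C*27)
        c = x.shape[0]
        return win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(-1, c * 27)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols_cache = self._cols(x)
        out = self._cols_cache @ self.w.value.T + self.b.value
        sp = x.shape[1:]
        return out.reshape(sp + (self.cout,)).transpose(3, 0, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gflat = grad.transpose(1, 2, 3, 0).reshape(-1, self.cout)
        self.w.grad += gflat.T @ self._cols_cache
        self.b.grad += gflat.sum(axis=0)
        # input gradient = convolution of grad with flipped, transposed kernel
        w = self.w.value.reshape(self.cout, self.cin, 3, 3, 3)
        w_t = w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4).reshape(
            self.cin, self.cout * 27
        )
        gcols = self._cols(grad)
        dx = gcols @ w_t.T
        return dx.reshape(grad.shape[1:] + (self.cin,)).transpose(3, 0, 1, 2)


class _Conv1:
    """1x1x1 convolution (final classifier head)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        self.cin, self.cout = cin, cout
        self.w = _Param(_he_uniform(rng, (cout, cin), cin), f"{name}.w")
        self.b = _Param(np.zeros(cout, dtype=DTYPE), f"{name}.b")

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,cxyz->oxyz", self.w.value, x) + self.b.value[
            :, None, None, None
        ]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("oxyz,cxyz->oc", grad, self._x)
        self.b.grad += grad.sum(axis=(1, 2, 3))
        return np.einsum("oc,oxyz->cxyz", self.w.value, grad)


class _Dropout:
    """Inverted dropout; active during training or when explicitly enabled."""

    params: list = []

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def forward(
        self, x: np.ndarray, active: bool, rng: np.random.Generator | None
    ) -> np.ndarray:
        if not active or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class _InstanceNorm:
    """Per-channel normalization over spatial dims with affine parameters."""

    eps = 1e-5

    def __init__(self, c: int, name: str):
        self.gamma = _Param(np.ones(c, dtype=DTYPE), f"{name}.gamma")
        self.beta = _Param(np.zeros(c, dtype=DTYPE), f"{name}.beta")

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma.value[:, None, None, None] * self._xhat + self.beta.value[
            :, None, None, None
        ]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad[0].size
        self.gamma.grad += (grad * self._xhat).sum(axis=(1, 2, 3))
        self.beta.grad += grad.sum(axis=(1, 2, 3))
        dxhat = grad * self.gamma.value[:, None, None, None]
        s1 = dxhat.sum(axis=(1, 2, 3), keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=(1, 2, 3), keepdims=True)
        return (dxhat - s1 / n - self._xhat * s2 / n) / self._std


class _LeakyReLU:
    params: list = []

    def __init__(self, slope: float):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.slope * grad, grad)


class _MaxPool2:
    params: list = []

    def __init__(self):
        self._skip_grad = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, sx, sy, sz = x.shape
        v = x.reshape(c, sx // 2, 2, sy // 2, 2, sz // 2, 2)
        out = v.max(axis=(2, 4, 6))
        self._v, self._out = v, out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mx = self._out[:, :, None, :, None, :, None]
        mask = self._v == mx
        cnt = mask.sum(axis=(2, 4, 6), keepdims=True)
        g = grad[:, :, None, :, None, :, None]
        dv = mask * g / cnt
        c, hx, _, hy, _, hz, _ = dv.shape
        return dv.reshape(c, hx * 2, hy * 2, hz * 2)


class _ConvTranspose2:
    """2x2x2 transposed convolution, stride 2 (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        self.cin, self.cout = cin, cout
        self.w = _Param(_he_uniform(rng, (cin, cout, 2, 2, 2), cin * 8), f"{name}.w")
        self.b = _Param(np.zeros(cout, dtype=DTYPE), f"{name}.b")

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = np.einsum("cxyz,coijk->oxiyjzk", x, self.w.value)
        _, sx, sy, sz = x.shape
        return out.reshape(self.cout, sx * 2, sy * 2, sz * 2) + self.b.value[
            :, None, None, None
        ]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        o, sx2, sy2, sz2 = grad.shape
        g = grad.reshape(o, sx2 // 2, 2, sy2 // 2, 2, sz2 // 2, 2)
        self.w.grad += np.einsum("cxyz,oxiyjzk->coijk", self._x, g)
        self.b.grad += grad.sum(axis=(1, 2, 3))
        return np.einsum("oxiyjzk,coijk->cxyz", g, self.w.value)


class _ConvBlock:
    """2 x (conv, dropout, instance norm, leaky ReLU)."""

    def __init__(self, cin, cout, rate, slope, rng, name):
        self.units = []
        for i, c_in in enumerate((cin, cout)):
            self.units.append(
                (
                    _Conv3(c_in, cout, rng, f"{name}.conv{i}"),
                    _Dropout(rate),
                    _InstanceNorm(cout, f"{name}.norm{i}"),
                    _LeakyReLU(slope),
                )
            )

    @property
    def params(self):
        return [p for unit in self.units for layer in unit for p in layer.params]

    def forward(self, x, dropout_active, rng):
        for conv, drop, norm, act in self.units:
            x = act.forward(
                norm.forward(drop.forward(conv.forward(x), dropout_active, rng))
            )
        return x

    def backward(self, grad):
        for conv, drop, norm, act in reversed(self.units):
            grad = conv.backward(drop.backward(norm.backward(act.backward(grad))))
        return grad


class UNet3D:
    """Model state: configuration plus the full parameter collection.

    Construct via :func:`build_model` for seeded He-uniform initialization.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = [config.base_filters * 2**i for i in range(config.depth + 1)]
        r, s = config.dropout_rate, config.negative_slope
        self.encoder = []
        cin = config.in_channels
        for i in range(config.depth):
            self.encoder.append(
                (_ConvBlock(cin, f[i], r, s, rng, f"enc{i}"), _MaxPool2())
            )
            cin = f[i]
        self.bottleneck = _ConvBlock(cin, f[config.depth], 0.0, s, rng, "bottleneck")
        self.decoder = []
        cin = f[config.depth]
        for i in reversed(range(config.depth)):
            up = _ConvTranspose2(cin, f[i], rng, f"up{i}")
            blk = _ConvBlock(2 * f[i], f[i], 0.0, s, rng, f"dec{i}")
            self.decoder.append((up, blk))
            cin = f[i]
        self.head = _Conv1(cin, config.out_channels, rng, "head")

    @property
    def params(self) -> list[_Param]:
        out = []
        for blk, _ in self.encoder:
            out += blk.params
        out += self.bottleneck.params
        for up, blk in self.decoder:
            out += up.params + blk.params
        out += self.head.params
        return out

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[3] != self.config.in_channels:
            raise ShapeError(
                f"expected (X, Y, Z, {self.config.in_channels}) input, got {x.shape}"
            )
        step = 2**self.config.depth
        if any(s % step for s in x.shape[:3]):
            raise ShapeError(
                f"spatial sides {x.shape[:3]} must be divisible by 2^depth={step}"
            )

    def forward(
        self,
        patch: np.ndarray,
        dropout_active: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Run the network on an (X, Y, Z, M) patch.

        Returns (X, Y, Z, N) per-class probabilities in (0, 1). When
        ``dropout_active`` the encoder dropout layers resample masks, making
        the output stochastic (test-time dropout).
        """
        self._check_input(patch)
        if dropout_active and self.config.dropout_rate > 0 and rng is None:
            rng = np.random.default_rng()
        h = np.ascontiguousarray(patch.transpose(3, 0, 1, 2), dtype=DTYPE)
        skips = []
        for blk, pool in self.encoder:
            h = blk.forward(h, dropout_active, rng)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h, dropout_active, rng)
        for (up, blk), skip in zip(self.decoder, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=0)
            h = blk.forward(h, dropout_active, rng)
        logits = self.head.forward(h)
        self._probs = 1.0 / (1.0 + np.exp(-logits))
        return self._probs.transpose(1, 2, 3, 0)

    def backward(self, dprobs: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(probabilities)."""
        g = (dprobs.transpose(3, 0, 1, 2) * self._probs * (1.0 - self._probs)).astype(DTYPE)
        g = self.head.backward(g)
        for (up, blk), (enc_blk, pool) in zip(reversed(self.decoder), self.encoder):
            g = blk.backward(g)
            n_skip = g.shape[0] // 2
            g_skip, g_up = g[:n_skip], g[n_skip:]
            g = up.backward(g_up)
            pool._skip_grad = g_skip  # re-joined when unwinding the encoder
        g = self.bottleneck.backward(g)
        for blk, pool in reversed(self.encoder):
            g = pool.backward(g)
            g = g + pool._skip_grad
            pool._skip_grad = None
            g = blk.backward(g)

    # --- checkpointing -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params:
            p.value[...] = state[p.name]

    def save(self, path) -> None:
        import json

        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "UNet3D":
        import json

        with np.load(path) as z:
            cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
            model = cls(cfg, seed=0)
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return model


def build_model(config: ModelConfig, seed: int = 0) -> UNet3D:
    """Build a U-Net with He-uniform initialized weights (reproducible)."""
    return UNet3D(config, seed)
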