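"""3-D encoder–decoder (U-Net) for CT → ventilation translation.

The encoder repeats a block of two 3×3×3 convolutions (stride 1, pad 1),
each followed by a leaky ReLU (α = 0.30) and a dropout layer, then a
2×2×2 max-pool; feature maps double at every down-step.  The decoder
mirrors it with 2×2×2 stride-2 transposed convolutions that halve the
feature maps, concatenation with the matching encoder features, and the
same double-convolution block.  A final 1×1×1 convolution with a ReLU
produces the single-channel, non-negative ventilation map.  L2 weight
regularization (1.0e−4) applies to every convolution kernel.

``depth`` and ``base_filters`` are configuration, not constants: the same
code serves full-scale (128³, depth 4) and desk-scale (32³, depth 2)
experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn

__all__ = ["NetConfig", "UNet3D", "build_unet", "forward", "save_checkpoint", "load_checkpoint"]


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``input_shape`` must be divisible by ``2**depth`` so the pooling /
    upsampling ladder closes exactly.
    """

    input_shape: tuple[int, int, int] = (128, 128, 128)
    depth: int = 4
    base_filters: int = 16
    leaky_alpha: float = 0.30
    dropout_rate: float = 0.50
    l2_weight: float = 1.0e-4
    final_activation: str = "relu"

    def __post_init__(self) -> None:
        if isinstance(self.input_shape, int):
            self.input_shape = (self.input_shape,) * 3
        self.input_shape = tuple(int(s) for s in self.input_shape)
        if any(s % 2**self.depth for s in self.input_shape):
            raise ValueError(
                f"input_shape {self.input_shape} must be divisible by 2**depth = {2**self.depth}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.leaky_alpha <= 0:
            raise ValueError("leaky_alpha must be > 0")
        if self.final_activation != "relu":
            raise ValueError("only a ReLU output activation is supported")


def _double_conv(cin, cout, cfg, rng):
    return [
        _nn.Conv3d(cin, cout, rng),
        _nn.LeakyReLU(cfg.leaky_alpha),
        _nn.Dropout(cfg.dropout_rate),
        _nn.Conv3d(cout, cout, rng),
        _nn.LeakyReLU(cfg.leaky_alpha),
        _nn.Dropout(cfg.dropout_rate),
    ]


class UNet3D:
    """The network handle: configuration, weights, forward and backward pass."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.base_filters
        self.enc_blocks, self.pools = [], []
        cin = 1
        for level in range(config.depth):
            cout = f * 2**level
            self.enc_blocks.append(_double_conv(cin, cout, config, rng))
            self.pools.append(_nn.MaxPool3d())
            cin = cout
        self.bottleneck = _double_conv(cin, f * 2**config.depth, config, rng)
        self.ups, self.dec_blocks = [], []
        for level in reversed(range(config.depth)):
            cout = f * 2**level
            self.ups.append(_nn.TransposedConv3d(cout * 2, cout, rng))
            self.dec_blocks.append(_double_conv(cout * 2, cout, config, rng))
        self.out_conv = _nn.Conv1x1(f, 1, rng)
        self.out_act = _nn.ReLU()
        # fallback stream for training-mode dropout when no rng is passed
        self._rng = np.random.default_rng(rng.integers(0, 2**31 - 1))

    # -- layer bookkeeping -------------------------------------------------
    def _layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.pools
        yield from self.bottleneck
        yield from self.ups
        for blk in self.dec_blocks:
            yield from blk
        yield self.out_conv

    def parameters(self) -> list[np.ndarray]:
        return [p for lyr in self._layers() for p in lyr.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for lyr in self._layers() for g in lyr.grads]

    def regularization_flags(self) -> list[bool]:
        return [r for lyr in self._layers() for r in getattr(lyr, "regularized", [])]

    def zero_grads(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Map a normalized CT volume to a ventilation volume.

        ``training=True`` activates dropout (both for optimization and for
        Monte-Carlo dropout sampling); the pass is then stochastic under
        ``rng``.  With ``training=False`` the pass is deterministic.
        """
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        if x.shape[1:] != self.config.input_shape:
            raise ValueError(
                f"input spatial shape {x.shape[1:]} != configured {self.config.input_shape}"
            )
        x = np.ascontiguousarray(x, dtype=_nn._DT)
        if training and rng is None:
            rng = self._rng
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for lyr in blk:
                x = lyr.forward(x, training, rng)
            skips.append(x)
            x = pool.forward(x, training, rng)
        for lyr in self.bottleneck:
            x = lyr.forward(x, training, rng)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, training, rng)
            self._skip_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            for lyr in blk:
                x = lyr.forward(x, training, rng)
        x = self.out_conv.forward(x, training, rng)
        x = self.out_act.forward(x, training, rng)
        return x[0] if squeeze else x

    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients for one sample's output gradient."""
        if gy.ndim == 3:
            gy = gy[None]
        g = self.out_act.backward(np.ascontiguousarray(gy, dtype=_nn._DT))
        g = self.out_conv.backward(g)
        skip_grads = []
        for up, blk, nskip in zip(
            reversed(self.ups), reversed(self.dec_blocks), reversed(self._skip_channels)
        ):
            for lyr in reversed(blk):
                g = lyr.backward(g)
            skip_grads.append(g[:nskip])
            g = up.backward(g[nskip:])
        for lyr in reversed(self.bottleneck):
            g = lyr.backward(g)
        # skip_grads[0] belongs to the shallowest encoder level; walk deep→shallow
        for blk, pool, sg in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g) + sg
            for lyr in reversed(blk):
                g = lyr.backward(g)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w


def build_unet(cfg: NetConfig, seed: int = 0) -> UNet3D:
    """Construct a seeded, randomly initialized network for ``cfg``."""
    return UNet3D(cfg, seed=seed)


def forward(net: UNet3D, ct: np.ndarray, training_mode: bool = False, rng=None) -> np.ndarray:
    """Functional wrapper around :meth:`UNet3D.forward`."""
    return net.forward(ct, training=training_mode, rng=rng)


def save_checkpoint(net: UNet3D, path) -> None:
    """Serialize weights plus the embedded :class:`NetConfig` to one file."""
    arrays = {f"w{i:03d}": w for i, w in enumerate(net.parameters())}
    np.savez(path, __config__=json.dumps(asdict(net.config)), **arrays)


def load_checkpoint(path) -> UNet3D:
    with np.load(path, allow_pickle=False) as data:
        cfg = NetConfig(**json.loads(str(data["__config__"])))
        net = UNet3D(cfg, seed=0)
        weights = [data[f"w{i:03d}"] for i in range(len(net.parameters()))]
    net.set_weights(weights)
    return net
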