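"""The 3-D residual UNet for soft soma segmentation.

Topology: a 7^3 stem convolution and one residual block, then ``n_levels``
encoder levels (residual blocks at 16*2^l filters, 2x max-pooling between
levels), a bottleneck level, and a mirrored decoder using 2x transposed
convolutions with concatenated skip connections.  All residual blocks use
full pre-activation ordering (norm -> ReLU -> conv); the head emits logits
whose sigmoid is the predicted soft field in (0, 1).
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from .config import NetworkConfig
from .layers import Conv3d, ConvTranspose3d, GroupNorm, MaxPool3d, ReLU, ResidualBlock


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class UNet3D:
    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        L = cfg.n_levels
        r = cfg.res_blocks_per_level
        k = cfg.body_kernel

        self.stem = Conv3d(1, f, cfg.stem_kernel, rng)
        self.stem_block = ResidualBlock(f, f, k, rng)

        self.enc_levels = []
        ch = f
        for l in range(L):
            cout = f * 2**l
            blocks = [ResidualBlock(ch if b == 0 else cout, cout, k, rng) for b in range(r)]
            self.enc_levels.append(blocks)
            ch = cout
        self.pools = [MaxPool3d() for _ in range(L)]

        bott = f * 2**L
        self.bottleneck = [ResidualBlock(ch if b == 0 else bott, bott, k, rng) for b in range(r)]

        self.upconvs = []
        self.dec_levels = []
        ch = bott
        for l in reversed(range(L)):
            cout = f * 2**l
            self.upconvs.append(ConvTranspose3d(ch, cout, rng))
            blocks = [ResidualBlock(2 * cout if b == 0 else cout, cout, k, rng) for b in range(r)]
            self.dec_levels.append(blocks)
            ch = cout

        self.head_gn = GroupNorm(f)
        self.head_relu = ReLU()
        self.head_conv = Conv3d(f, 1, 1, rng)

    # -- plumbing -------------------------------------------------------

    def _all_layers(self):
        layers = [self.stem, self.stem_block]
        for blocks in self.enc_levels:
            layers.extend(blocks)
        layers.extend(self.bottleneck)
        for up, blocks in zip(self.upconvs, self.dec_levels):
            layers.append(up)
            layers.extend(blocks)
        layers.extend([self.head_gn, self.head_conv])
        return layers

    def params(self):
        out = []
        for i, layer in enumerate(self._all_layers()):
            out.extend((f"layer{i}.{n}", v, g) for n, v, g in layer.params())
        return out

    @property
    def parameter_count(self) -> int:
        return int(sum(v.size for _, v, _ in self.params()))

    def zero_grad(self):
        for _, _, g in self.params():
            g[...] = 0.0

    def check_input_shape(self, shape):
        d = self.cfg.divisor
        if any(s % d for s in shape):
            raise ValueError(
                f"input shape {tuple(shape)} must be divisible by {d} "
                f"(= 2^{self.cfg.n_levels} for {self.cfg.n_levels} pooling levels)"
            )

    # -- forward / backward --------------------------------------------

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """``x`` is a (D, H, W) normalised volume; returns (D, H, W) logits."""
        self.check_input_shape(x.shape)
        h = x[None].astype(np.float32)
        h = self.stem.forward(h)
        h = self.stem_block.forward(h)
        self._skips = []
        for blocks, pool in zip(self.enc_levels, self.pools):
            for b in blocks:
                h = b.forward(h)
            self._skips.append(h)
            h = pool.forward(h)
        for b in self.bottleneck:
            h = b.forward(h)
        self._concat_channels = []
        for up, blocks in zip(self.upconvs, self.dec_levels):
            h = up.forward(h)
            skip = self._skips.pop()
            self._concat_channels.append(h.shape[0])
            h = np.concatenate([h, skip], axis=0)
            for b in blocks:
                h = b.forward(h)
        h = self.head_gn.forward(h)
        h = self.head_relu.forward(h)
        h = self.head_conv.forward(h)
        return h[0]

    def backward(self, dlogits: np.ndarray):
        dy = dlogits[None].astype(np.float32)
        dy = self.head_conv.backward(dy)
        dy = self.head_relu.backward(dy)
        dy = self.head_gn.backward(dy)
        dskips = []
        for up, blocks, cch in zip(
            reversed(self.upconvs), reversed(self.dec_levels), reversed(self._concat_channels)
        ):
            for b in reversed(blocks):
                dy = b.backward(dy)
            dskips.append(dy[cch:])
            dy = up.backward(dy[:cch])
        for b in reversed(self.bottleneck):
            dy = b.backward(dy)
        # dskips were collected decoder-order (shallowest level last applied,
        # hence first appended); the encoder unwinds deepest-first
        for pool, blocks in zip(reversed(self.pools), reversed(self.enc_levels)):
            dy = pool.backward(dy)
            dy = dy + dskips.pop()
            for b in reversed(blocks):
                dy = b.backward(dy)
        dy = self.stem_block.backward(dy)
        self.stem.backward(dy)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass mapping a normalised volume to a field in (0, 1)."""
        return _sigmoid(self.forward_logits(x))

    # -- persistence ----------------------------------------------------

    def save(self, path):
        state = {
            "config": self.cfg.to_dict(),
            "params": {n: v.copy() for n, v, _ in self.params()},
        }
        with Path(path).open("wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path) -> "UNet3D":
        with Path(path).open("rb") as fh:
            state = pickle.load(fh)
        model = cls(NetworkConfig(**state["config"]))
        for n, v, _ in model.params():
            v[...] = state["params"][n]
        return model


def build_unet(cfg: NetworkConfig) -> tuple[UNet3D, int]:
    """Build the UNet; returns (model, exact parameter count)."""
    model = UNet3D(cfg)
    return model, model.parameter_count
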