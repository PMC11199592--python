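"""Network and training configuration."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class NetworkConfig:
    """Architecture and schedule of the segmentation UNet.

    The full profile mirrors the production design: four encoder/decoder
    levels of three full-pre-activation residual blocks each, 16 base
    filters doubling per level, a 7^3 stem convolution, 3^3 body kernels,
    sigmoid head, SGD with cosine-decay warm restarts for 2000 epochs.
    ``scaled_down_config`` gives a desk-scale profile for small phantoms.
    """

    n_levels: int = 4
    res_blocks_per_level: int = 3
    base_filters: int = 16
    stem_kernel: int = 7
    body_kernel: int = 3
    epochs: int = 2000
    lr_max: float = 0.1
    lr_min: float = 1e-4
    momentum: float = 0.9
    restart_period: int = 100  # epochs per cosine cycle
    ema_decay: float = 0.0     # 0 = off; ~0.995 smooths single-crop SGD noise
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.stem_kernel % 2 == 0 or self.body_kernel % 2 == 0:
            raise ValueError("kernels must be odd for 'same' convolutions")

    @property
    def divisor(self) -> int:
        """Input spatial dims must be divisible by this (2^n_levels)."""
        return 2**self.n_levels

    def to_dict(self) -> dict:
        return asdict(self)


def scaled_down_config(**overrides) -> NetworkConfig:
    """Desk-scale profile: 2 levels, 8 base filters, short schedule."""
    kw = dict(
        n_levels=2,
        res_blocks_per_level=2,
        base_filters=8,
        epochs=120,
        restart_period=60,
        lr_max=0.05,
        ema_decay=0.995,
    )
    kw.update(overrides)
    return NetworkConfig(**kw)
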