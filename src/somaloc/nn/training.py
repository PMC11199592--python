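"""Training loop: BCE on logits, SGD with momentum, cosine warm restarts."""

from __future__ import annotations

import numpy as np

from ..core import Volume
from .config import NetworkConfig
from .ops import percentile_normalize
from .unet import UNet3D, _sigmoid


def bce_loss(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient.

    Computed as softplus(z) − y·z (numerically stable); gradient is
    (sigmoid(z) − y)/N.
    """
    z = logits.astype(np.float64)
    softplus = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))), np.log1p(np.exp(z)))
    loss = float(np.mean(softplus - target * z))
    grad = ((_sigmoid(logits) - target) / logits.size).astype(np.float32)
    return loss, grad


def cosine_warm_restart_lr(epoch: int, lr_max: float, lr_min: float, period: int) -> float:
    """Cosine decay from lr_max to lr_min, restarting every ``period`` epochs.

    At each restart boundary the learning rate returns to its maximum.
    """
    t = epoch % period
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * t / period))


class TrainingDiverged(RuntimeError):
    pass


def _prepare_pairs(pairs):
    prepared = []
    for vol, target in pairs:
        x = vol.data if isinstance(vol, Volume) else np.asarray(vol)
        y = target.data if isinstance(target, Volume) else np.asarray(target)
        if x.shape != y.shape:
            raise ValueError(f"volume/target shape mismatch: {x.shape} vs {y.shape}")
        prepared.append((percentile_normalize(x), y.astype(np.float32)))
    return prepared


def train(
    model: UNet3D,
    pairs: list,
    cfg: NetworkConfig | None = None,
    crop_shape: tuple | None = None,
    flip_augment: bool = False,
    callback=None,
) -> list[float]:
    """Train in place on (volume, soft target) pairs; returns the loss history.

    Inputs are percentile-normalised to [0, 1] per volume.  One epoch is
    one pass over the pairs (optionally random-cropped to ``crop_shape``
    and, with ``flip_augment``, randomly mirrored along each axis — the
    scene statistics are mirror-symmetric); updates are per-sample SGD with
    momentum, learning rate scheduled by cosine decay with warm restarts.
    Deterministic for a fixed config seed.  Raises
    :class:`TrainingDiverged` on a NaN loss with the epoch and learning
    rate in the message.
    """
    cfg = cfg or model.cfg
    if not pairs:
        raise ValueError("training requires at least one (volume, target) pair")
    data = _prepare_pairs(pairs)
    rng = np.random.default_rng(cfg.seed + 7)
    velocity = {n: np.zeros_like(v) for n, v, _ in model.params()}
    ema = (
        {n: v.copy() for n, v, _ in model.params()}
        if cfg.ema_decay > 0 else None
    )
    history = []
    for epoch in range(cfg.epochs):
        lr = cosine_warm_restart_lr(epoch, cfg.lr_max, cfg.lr_min, cfg.restart_period)
        epoch_loss = 0.0
        order = rng.permutation(len(data))
        for idx in order:
            x, y = data[idx]
            if crop_shape is not None and tuple(crop_shape) != x.shape:
                off = [rng.integers(0, s - c + 1) for s, c in zip(x.shape, crop_shape)]
                sl = tuple(slice(o, o + c) for o, c in zip(off, crop_shape))
                x, y = x[sl], y[sl]
            if flip_augment:
                axes = tuple(int(a) for a in np.nonzero(rng.integers(0, 2, size=3))[0])
                if axes:
                    x = np.ascontiguousarray(np.flip(x, axes))
                    y = np.ascontiguousarray(np.flip(y, axes))
            model.zero_grad()
            logits = model.forward_logits(x)
            loss, dlogits = bce_loss(logits, y)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} (lr={lr:.4g}); "
                    "lower lr_max or check target range"
                )
            model.backward(dlogits)
            for n, v, g in model.params():
                vel = velocity[n]
                vel *= cfg.momentum
                vel -= lr * g
                v += vel
                if ema is not None:
                    e = ema[n]
                    e *= cfg.ema_decay
                    e += (1.0 - cfg.ema_decay) * v
            epoch_loss += loss
        history.append(epoch_loss / len(data))
        if callback is not None:
            callback(epoch, history[-1], lr)
    if ema is not None:
        # Polyak-averaged weights: smoother than the last SGD iterate
        for n, v, _ in model.params():
            v[...] = ema[n]
    return history
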