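"""Tiled inference with linear feathering on overlaps.

Volumes larger than a comfortable forward pass are predicted tile by tile;
overlapping tile predictions are blended with a separable linear ramp so
that different tilings agree away from volume borders.
"""

from __future__ import annotations

import numpy as np

from ..core import Volume
from .ops import percentile_normalize
from .unet import UNet3D


def _tile_weights(tile_shape, overlap, at_low_edge, at_high_edge) -> np.ndarray:
    """Per-tile blending weights: trimmed margins plus linear feathering.

    Interior tile faces contribute nothing within ``overlap // 2`` voxels of
    the face (predictions there are boundary-corrupted) and ramp linearly
    over the rest of the overlap; faces flush with the volume border keep
    full weight.  With the trim at least the model's receptive field, any
    two tilings agree exactly away from the volume borders.
    """
    ws = []
    for size, ov, low, high in zip(tile_shape, overlap, at_low_edge, at_high_edge):
        w = np.ones(size)
        trim = ov // 2
        ramp = ov - trim
        edge = np.concatenate([
            np.zeros(trim),
            np.linspace(1.0 / (ramp + 1), 1.0, ramp, endpoint=False) if ramp else np.empty(0),
        ])
        if ov > 0 and not low:
            w[:ov] = edge
        if ov > 0 and not high:
            w[-ov:] = edge[::-1]
        ws.append(w)
    return ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]


def predict_soft(
    model: UNet3D,
    vol: Volume | np.ndarray,
    tile_shape: tuple | None = None,
    overlap: int = 8,
    normalize: bool = True,
) -> Volume:
    """Predict the soft field of a whole volume, tiling if necessary.

    ``tile_shape`` defaults to the whole volume; a tile larger than the
    volume falls back to a single padded tile, cropped afterwards.
    Normalisation is applied once to the full volume so tiles share the
    same intensity scale.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    voxel = vol.voxel_size_um if isinstance(vol, Volume) else None
    x = percentile_normalize(data) if normalize else data.astype(np.float32)
    shape = np.asarray(x.shape)

    if tile_shape is None:
        tile_shape = tuple(x.shape)
    tile = np.asarray(tile_shape)
    d = model.cfg.divisor
    if np.any(tile % d):
        raise ValueError(f"tile shape {tile_shape} must be divisible by {d}")

    if np.any(tile >= shape):
        # single padded tile
        padded_shape = np.maximum(np.ceil(shape / d).astype(int) * d, tile)
        pad = [(0, int(p - s)) for p, s in zip(padded_shape, shape)]
        out = model.predict(np.pad(x, pad, mode="reflect"))
        out = out[: shape[0], : shape[1], : shape[2]]
        return Volume(out) if voxel is None else Volume(out, voxel)

    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    step = tile - overlap
    ov3 = (overlap, overlap, overlap)
    acc = np.zeros(x.shape, dtype=np.float64)
    wacc = np.zeros(x.shape, dtype=np.float64)
    starts = [
        sorted({min(int(s), int(ax - t)) for s in range(0, int(ax), int(st))})
        for ax, t, st in zip(shape, tile, step)
    ]
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                origin = (z0, y0, x0)
                sl = tuple(slice(o, o + t) for o, t in zip(origin, tile))
                weights = _tile_weights(
                    tile, ov3,
                    [o == 0 for o in origin],
                    [o + t == s for o, t, s in zip(origin, tile, shape)],
                )
                pred = model.predict(x[sl])
                acc[sl] += pred * weights
                wacc[sl] += weights
    out = (acc / np.maximum(wacc, 1e-12)).astype(np.float32)
    return Volume(out) if voxel is None else Volume(out, voxel)
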