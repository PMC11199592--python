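"""Low-level 3-D convolution ops (float32, stride 1, zero 'same' padding).

The forward/weight-gradient/input-gradient trio is expressed through one
im2col routine: the input gradient of a same-convolution is itself a
same-convolution of the output gradient with spatially flipped,
channel-transposed weights.  im2col patches are materialised in z-chunks to
bound peak memory.
"""

from __future__ import annotations

import numpy as np

_CHUNK_BYTES = 64 * 1024 * 1024  # peak im2col buffer per chunk


def _z_chunks(depth: int, bytes_per_plane: int):
    step = max(1, _CHUNK_BYTES // max(bytes_per_plane, 1))
    for z0 in range(0, depth, step):
        yield z0, min(depth, z0 + step)


def conv3d_same(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """``x`` (Cin, D, H, W) * ``weight`` (Cout, Cin, k, k, k) -> (Cout, D, H, W).

    Two execution paths: shifted-slice GEMMs (one small matrix product per
    kernel offset — fastest for multi-channel inputs, avoids the im2col
    gather) and classic z-chunked im2col (better for few-channel inputs
    such as the stem, where per-offset GEMMs degenerate to K=1).
    """
    cout, cin, k, _, _ = weight.shape
    assert x.shape[0] == cin, (x.shape, weight.shape)
    p = k // 2
    _, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    if cin >= 4:
        out = np.zeros((cout, d * h * w), dtype=np.float32)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    sub = np.ascontiguousarray(
                        xp[:, dz:dz + d, dy:dy + h, dx:dx + w]
                    ).reshape(cin, -1)
                    out += weight[:, :, dz, dy, dx] @ sub
        out = out.reshape(cout, d, h, w)
    else:
        wmat = weight.reshape(cout, cin * k * k * k).T  # (cin*k^3, cout)
        out = np.empty((cout, d, h, w), dtype=np.float32)
        bytes_per_plane = h * w * cin * k * k * k * 4
        for z0, z1 in _z_chunks(d, bytes_per_plane):
            # windows over the padded block covering output planes [z0, z1)
            block = xp[:, z0:z1 + 2 * p]
            win = np.lib.stride_tricks.sliding_window_view(block, (k, k, k), axis=(1, 2, 3))
            cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
                (z1 - z0) * h * w, cin * k * k * k
            )
            res = cols @ wmat  # (n, cout)
            out[:, z0:z1] = res.T.reshape(cout, z1 - z0, h, w)
    if bias is not None:
        out += bias[:, None, None, None]
    return out


def conv3d_same_grad_weight(x: np.ndarray, dy: np.ndarray, k: int) -> np.ndarray:
    """Gradient of conv3d_same wrt weight: returns (Cout, Cin, k, k, k)."""
    cin, d, h, w = x.shape
    cout = dy.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    if cin >= 4:
        grad = np.empty((cout, cin, k, k, k), dtype=np.float32)
        dyf = dy.reshape(cout, -1)
        for dz in range(k):
            for dyy in range(k):
                for dx in range(k):
                    sub = np.ascontiguousarray(
                        xp[:, dz:dz + d, dyy:dyy + h, dx:dx + w]
                    ).reshape(cin, -1)
                    grad[:, :, dz, dyy, dx] = dyf @ sub.T
        return grad
    grad = np.zeros((cout, cin * k * k * k), dtype=np.float32)
    bytes_per_plane = h * w * cin * k * k * k * 4
    for z0, z1 in _z_chunks(d, bytes_per_plane):
        block = xp[:, z0:z1 + 2 * p]
        win = np.lib.stride_tricks.sliding_window_view(block, (k, k, k), axis=(1, 2, 3))
        cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
            (z1 - z0) * h * w, cin * k * k * k
        )
        dyc = dy[:, z0:z1].reshape(cout, -1)  # (cout, n)
        grad += dyc @ cols
    return grad.reshape(cout, cin, k, k, k)


def conv3d_same_grad_input(dy: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Gradient of conv3d_same wrt input: same-conv of dy with flipped weights."""
    wt = np.ascontiguousarray(
        weight[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
    )  # (Cin, Cout, k, k, k)
    return conv3d_same(dy, wt)


def percentile_normalize(data: np.ndarray, p_low: float = 0.5, p_high: float = 99.5) -> np.ndarray:
    """Clip to the [p_low, p_high] percentile range and rescale to [0, 1].

    Per-volume normalisation absorbing the extreme slab-to-slab intensity
    shifts of light-sheet acquisitions.
    """
    lo, hi = np.percentile(data, [p_low, p_high])
    if hi <= lo:
        return np.zeros_like(data, dtype=np.float32)
    return ((np.clip(data, lo, hi) - lo) / (hi - lo)).astype(np.float32)
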