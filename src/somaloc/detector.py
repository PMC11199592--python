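"""Difference-of-Gaussians blob detection on soft prediction fields.

The response is G_sigma_small * f − G_(ratio*sigma_small) * f (separable
Gaussian filters, reflective boundary, truncation at 4 sigma).  Detections
are strict local maxima over a 3^3 neighbourhood above a response
threshold; centers closer than a merge distance are reduced greedily by
descending response, dropping the weaker one so detections stay on
response peaks.  The four tunables — the small sigma, the sigma ratio, the
response threshold and the merge distance — are exactly the degrees of
freedom exposed to the hyperparameter tuner.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import CellCenters, Volume


@dataclass
class DoGParams:
    """Tunables of the blob detector.

    ``threshold_mode`` selects how ``response_threshold`` is applied:
    "absolute" compares raw DoG responses, "relative" rescales the cutoff
    by the field's robust peak response (99.9th percentile) — since the
    DoG is linear this makes detection invariant to the overall amplitude
    of the prediction, which varies between slabs the model is more or
    less confident on.
    """

    sigma_small: float = 1.5    # voxels
    ratio: float = 1.6          # sigma_large / sigma_small
    response_threshold: float = 0.05
    merge_distance: float = 4.0 # voxels
    threshold_mode: str = "absolute"

    def __post_init__(self):
        if self.threshold_mode not in ("absolute", "relative"):
            raise ValueError("threshold_mode must be 'absolute' or 'relative'")
        if self.sigma_small <= 0:
            raise ValueError("sigma_small must be > 0")
        if self.ratio <= 1:
            raise ValueError("ratio must be > 1")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _field(data) -> np.ndarray:
    return data.data if isinstance(data, Volume) else np.asarray(data, dtype=float)


def dog_response(field, p: DoGParams) -> np.ndarray:
    """Band-pass response G_small*f − G_large*f (same shape as input)."""
    f = _field(field)
    small = ndimage.gaussian_filter(f, p.sigma_small, mode="reflect", truncate=4.0)
    large = ndimage.gaussian_filter(f, p.ratio * p.sigma_small, mode="reflect", truncate=4.0)
    return small - large


def local_maxima(resp: np.ndarray, threshold: float) -> np.ndarray:
    """Voxel indices of local maxima over a 3^3 neighbourhood above threshold.

    A voxel qualifies when it equals the neighbourhood maximum; plateau ties
    are broken lexicographically in (z, y, x) scan order, keeping the first
    voxel of each connected plateau.
    """
    mx = ndimage.maximum_filter(resp, size=3, mode="reflect")
    cand = (resp >= mx) & (resp > threshold)
    if not cand.any():
        return np.empty((0, 3), dtype=int)
    # resolve plateaus: among 26-connected candidates of equal value keep the
    # first voxel in scan order
    lab, n = ndimage.label(cand, structure=np.ones((3, 3, 3), dtype=int))
    keep = []
    flat = np.argwhere(cand)
    if n == len(flat):
        return flat
    first = {}
    for idx in flat:  # argwhere is already in scan order
        l = lab[tuple(idx)]
        if l not in first:
            first[l] = idx
            keep.append(idx)
    return np.asarray(keep, dtype=int)


def detect_centers(field, p: DoGParams) -> CellCenters:
    """Detect blob centers: DoG response → local maxima → greedy merge.

    Output is sorted by response, descending; merging repeatedly drops the
    lower-response member of any pair closer than ``merge_distance``.
    """
    resp = dog_response(field, p)
    thr = p.response_threshold
    if p.threshold_mode == "relative":
        scale = float(np.percentile(resp, 99.9))
        if scale <= 0:
            return CellCenters(np.empty((0, 3)), space="voxel")
        thr = p.response_threshold * scale
    peaks = local_maxima(resp, thr)
    if len(peaks) == 0:
        return CellCenters(np.empty((0, 3)), space="voxel")
    values = resp[tuple(peaks.T)]
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0], -values))
    peaks, values = peaks[order], values[order]

    if p.merge_distance > 0 and len(peaks) > 1:
        tree = cKDTree(peaks)
        alive = np.ones(len(peaks), dtype=bool)
        # peaks are in descending response order: a peak survives unless a
        # stronger surviving peak is within merge_distance
        for k in range(len(peaks)):
            if not alive[k]:
                continue
            for j in tree.query_ball_point(peaks[k], p.merge_distance):
                # "closer than" is strict; KD-tree ball query is inclusive
                if j == k or not alive[j]:
                    continue
                if np.linalg.norm(peaks[j] - peaks[k]) >= p.merge_distance:
                    continue
                if values[j] < values[k] or (values[j] == values[k] and j > k):
                    alive[j] = False
        peaks, values = peaks[alive], values[alive]

    return CellCenters(peaks.astype(float), space="voxel")
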