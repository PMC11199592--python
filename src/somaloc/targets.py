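"""Training labels from point annotations.

Light-sheet images of NeuN-stained tissue do not resolve membranes, so the
voxel-level target for segmentation is *soft*: each annotated soma becomes a
unit-peak 3-D Gaussian sphere whose width adapts to the nearest neighbour so
that spheres never overlap.  Hard instance labels (for tools that need them)
are derived by thresholding the soft mask at 0.006 and labelling connected
components; 2-D maximum-intensity-projection slices and plane-wise stitching
support the 2-D-model adaptation.

The width rule is sigma_i = clip(d_i / kappa, low, high) with d_i the
distance (voxels) to the nearest other center and kappa = 2*sqrt(2*ln(1/0.006))
~= 6.398: two equal-sigma cells at distance d then have tangent 0.006-level
support spheres (radius 3.199*sigma each), which makes the fixed 0.006
instance threshold consistent by construction.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label

from .core import CellCenters, Volume
from .phantom import _add_gaussian_bumps

#: soft-mask level at which instance supports are cut
INSTANCE_THRESHOLD = 0.006
#: kappa = 2*sqrt(2*ln(1/0.006)); support radius of a sigma-Gaussian at the
#: 0.006 level is (kappa/2)*sigma ~= 3.199*sigma
KAPPA = 2.0 * np.sqrt(2.0 * np.log(1.0 / INSTANCE_THRESHOLD))
#: sigma bounds in voxels
SIGMA_BOUNDS = (1.0, 3.5)


def support_radius(sigma: float, threshold: float = INSTANCE_THRESHOLD) -> float:
    """Radius (voxels) where a unit-peak Gaussian of width ``sigma`` crosses
    ``threshold``: sigma * sqrt(2 ln(1/threshold))."""
    return float(sigma * np.sqrt(2.0 * np.log(1.0 / threshold)))


def compute_sigmas(
    centers: CellCenters,
    bounds: tuple = SIGMA_BOUNDS,
    anisotropy=None,
) -> np.ndarray:
    """Per-cell Gaussian widths adapted to nearest-neighbour distance.

    Returns an ``(n, 3)`` array of per-axis sigmas (voxels).  An isolated
    cell gets the upper bound; otherwise sigma_i = clip(d_i/kappa, low, high)
    where d_i is the voxel-space distance to the closest other center.
    ``anisotropy`` optionally rescales sigma per axis (z, y, x); default
    isotropic.
    """
    low, high = bounds
    if not (0 < low < high):
        raise ValueError(f"bounds must satisfy 0 < low < high, got {bounds!r}")
    pts = centers.points
    if len(pts) == 0:
        raise ValueError("compute_sigmas requires at least one center")
    if len(pts) == 1:
        sig = np.array([high])
    else:
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        sig = np.clip(d[:, 1] / KAPPA, low, high)
    scale = np.ones(3) if anisotropy is None else np.broadcast_to(np.asarray(anisotropy, float), (3,))
    return sig[:, None] * scale[None, :]


def render_soft_mask(centers: CellCenters, sigmas, shape) -> Volume:
    """Render unit-peak Gaussian spheres; overlaps combined by maximum.

    The max combination preserves peak-1 normalisation at every annotated
    center, as required by a sigmoid/binary-cross-entropy training head.
    """
    shape = tuple(int(s) for s in shape)
    pts = centers.points
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.ndim == 1:
        sigmas = sigmas[:, None] * np.ones((1, 3))
    grid = np.zeros(shape)
    trunc = support_radius(1.0)  # render out to the 0.006 support
    for c, s in zip(pts, sigmas):
        lo = np.maximum(np.floor(c - trunc * s).astype(int), 0)
        hi = np.minimum(np.ceil(c + trunc * s).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz = np.arange(lo[0], hi[0])[:, None, None]
        yy = np.arange(lo[1], hi[1])[None, :, None]
        xx = np.arange(lo[2], hi[2])[None, None, :]
        r2 = (
            (zz - c[0]) ** 2 / s[0] ** 2
            + (yy - c[1]) ** 2 / s[1] ** 2
            + (xx - c[2]) ** 2 / s[2] ** 2
        )
        sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(sub, np.exp(-0.5 * r2), out=sub)
    return Volume(grid)


def make_soft_target(centers: CellCenters, shape, bounds=SIGMA_BOUNDS, anisotropy=None):
    """Convenience: sigmas + rendered soft mask for one annotated volume."""
    sigmas = compute_sigmas(centers, bounds=bounds, anisotropy=anisotropy)
    return render_soft_mask(centers, sigmas, shape), sigmas


def soft_to_instance(soft: Volume | np.ndarray, threshold: float = INSTANCE_THRESHOLD) -> np.ndarray:
    """Threshold a soft mask and label 26-connected components 1..K.

    26-connectivity avoids splitting the diagonal shells of discretised
    spheres on an isotropic grid.  Labels are re-numbered consecutively in
    scan order of each component's first voxel.
    """
    grid = soft.data if isinstance(soft, Volume) else np.asarray(soft)
    binary = grid > threshold
    labels = cc_label(binary, connectivity=3)  # 26-connectivity in 3-D
    return labels.astype(np.int32)


def make_mip_slices(vol: Volume | np.ndarray, window: int = 9, stride: int = 1):
    """Per-plane maximum-intensity projections over a z-window.

    Slice ``i`` is the voxelwise max over planes ``[i-w, i+w] ∩ [0, depth)``
    with ``w = window // 2``; one output per input plane (stride 1 default).
    """
    if window % 2 != 1:
        raise ValueError(f"window must be odd, got {window}")
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    depth = data.shape[0]
    w = window // 2
    out = []
    for i in range(0, depth, stride):
        lo, hi = max(0, i - w), min(depth, i + w + 1)
        out.append(data[lo:hi].max(axis=0))
    return out


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def stitch_planewise_masks(per_plane, iou_threshold: float = 0.3):
    """Merge per-plane 2-D instance masks into 3-D instances.

    Objects in *consecutive* planes are linked when their intersection-over-
    union exceeds ``iou_threshold``; links are closed transitively with
    union-find.  When one object overlaps several candidates above
    threshold, the highest IOU wins (ties by lowest candidate id).  Each 3-D
    instance yields one center: the centroid of its voxel set.

    Returns ``(labels_3d, centers)`` with labels 1..K and voxel-space
    centroids.
    """
    per_plane = [np.asarray(p) for p in per_plane]
    shape2d = per_plane[0].shape
    for k, p in enumerate(per_plane):
        if p.shape != shape2d:
            raise ValueError(f"plane {k} shape {p.shape} != plane 0 shape {shape2d}")

    # global ids for every (plane, local label)
    objects = []  # (plane, local_label)
    index = {}
    for z, p in enumerate(per_plane):
        for lab in np.unique(p):
            if lab == 0:
                continue
            index[(z, lab)] = len(objects)
            objects.append((z, lab))
    uf = _UnionFind(len(objects))

    for z in range(len(per_plane) - 1):
        a, b = per_plane[z], per_plane[z + 1]
        labs_a = [l for l in np.unique(a) if l != 0]
        labs_b = sorted(l for l in np.unique(b) if l != 0)
        for la in labs_a:
            mask_a = a == la
            best = None
            for lb in labs_b:
                mask_b = b == lb
                inter = np.count_nonzero(mask_a & mask_b)
                if inter == 0:
                    continue
                union = np.count_nonzero(mask_a | mask_b)
                iou = inter / union
                if iou > iou_threshold and (best is None or iou > best[0]):
                    best = (iou, lb)
            if best is not None:
                uf.union(index[(z, la)], index[(z + 1, best[1])])

    # relabel roots 1..K in scan order
    root_ids = {}
    labels_3d = np.zeros((len(per_plane),) + shape2d, dtype=np.int32)
    for (z, lab), gid in index.items():
        root = uf.find(gid)
        if root not in root_ids:
            root_ids[root] = 0  # placeholder, ordered later
    # deterministic ordering: by first (plane, label) appearance
    ordered = sorted(root_ids, key=lambda r: objects[r])
    root_ids = {r: k + 1 for k, r in enumerate(ordered)}
    for (z, lab), gid in index.items():
        labels_3d[z][per_plane[z] == lab] = root_ids[uf.find(gid)]

    centers = []
    for k in range(1, len(ordered) + 1):
        vox = np.argwhere(labels_3d == k)
        centers.append(vox.mean(axis=0))
    return labels_3d, CellCenters(np.asarray(centers).reshape(-1, 3), space="voxel")
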