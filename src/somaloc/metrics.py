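"""Localization evaluation by minimum-weight bipartite matching.

Predicted centers Ŷ = {ŷ_1..ŷ_m} are paired with ground-truth centers
Y = {y_1..y_n} by solving the minimum-weight matching on the complete
bipartite graph with Euclidean weights w_ij = ||y_i − ŷ_j||_2 (micrometres).
A matched prediction is a true positive when its pair distance is smaller
than 15 um; a pair at or above 15 um contributes one false positive and one
false negative; unmatched predictions are false positives and unmatched
ground truth false negatives.  Precision P = TP/(TP+FP), recall
R = TP/(TP+FN) and F1 = 2PR/(P+R) are reported as percentages.

Edge effects dominate object-wise metrics near volume borders, so points
inside a 6-voxel (21.6 um at 3.6 um/voxel) frame around the borders are
removed after matching and before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import CellCenters

MAX_MATCH_DIST_UM = 15.0
BORDER_FRAME_VOXELS = 6


@dataclass
class RawMatching:
    """Output of the assignment solver, before the TP distance criterion."""

    pairs: np.ndarray          # (k, 2) int: (gt index, pred index)
    distances_um: np.ndarray   # (k,) pair distances
    unmatched_gt: np.ndarray   # indices into gt
    unmatched_pred: np.ndarray # indices into pred


@dataclass
class MatchReport:
    """Counts and retrieval metrics of one evaluation (percent scale)."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    pairs: list = field(default_factory=list)  # (gt idx, pred idx, dist um) of TPs
    excluded_gt: int = 0
    excluded_pred: int = 0
    degenerate: bool = False  # one or both sets empty after exclusion


def match_centers(gt: CellCenters, pred: CellCenters, voxel_size_um=None) -> RawMatching:
    """Minimum-total-weight matching of gt against predictions.

    Both sets must share a coordinate space; voxel-space inputs require
    ``voxel_size_um`` to convert distances to micrometres.  The solver runs
    on the complete bipartite graph (no distance pre-cutoff): |pairs| =
    min(|gt|, |pred|), surplus points stay unmatched.
    """
    if gt.space != pred.space:
        raise ValueError(f"coordinate spaces differ: gt={gt.space!r} pred={pred.space!r}")
    if gt.space == "voxel":
        if voxel_size_um is None:
            raise ValueError("voxel-space centers require voxel_size_um")
        g = gt.to_um(voxel_size_um).points
        p = pred.to_um(voxel_size_um).points
    else:
        g, p = gt.points, pred.points

    n, m = len(g), len(p)
    if n == 0 or m == 0:
        return RawMatching(
            np.empty((0, 2), dtype=int), np.empty(0),
            np.arange(n), np.arange(m),
        )
    cost = np.linalg.norm(g[:, None, :] - p[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    order = np.argsort(rows, kind="stable")  # deterministic (gt, pred) ordering
    rows, cols = rows[order], cols[order]
    pairs = np.stack([rows, cols], axis=1)
    dists = cost[rows, cols]
    unmatched_gt = np.setdiff1d(np.arange(n), rows)
    unmatched_pred = np.setdiff1d(np.arange(m), cols)
    return RawMatching(pairs, dists, unmatched_gt, unmatched_pred)


def match_total_weight_bruteforce(gt_um: np.ndarray, pred_um: np.ndarray) -> float:
    """Exhaustive minimum matching weight over all injective assignments.

    Independent oracle for small instances (feasible up to ~8 points/side).
    """
    from itertools import permutations

    g, p = np.asarray(gt_um, float), np.asarray(pred_um, float)
    n, m = len(g), len(p)
    if n == 0 or m == 0:
        return 0.0
    k = min(n, m)
    cost = np.linalg.norm(g[:, None, :] - p[None, :, :], axis=2)
    best = np.inf
    small, large, transposed = (range(n), range(m), False) if n <= m else (range(m), range(n), True)
    for subset in combinations(large, k):
        for perm in permutations(subset):
            w = sum(
                cost[i, j] if not transposed else cost[j, i]
                for i, j in zip(small, perm)
            )
            best = min(best, w)
    return float(best)


def exclude_border(
    gt: CellCenters,
    pred: CellCenters,
    raw: RawMatching,
    shape,
    frame_voxels: int = BORDER_FRAME_VOXELS,
) -> tuple[RawMatching, int, int]:
    """Drop gt/pred points lying in the border frame; dissolve their pairs.

    A point with any voxel coordinate < frame or >= axis_len − frame is
    removed.  A pair whose partner is removed dissolves: the surviving
    interior point becomes unmatched (so it counts FP/FN downstream) —
    leaving a dangling matched partner would double-count.
    Returns the filtered matching plus (excluded gt, excluded pred) counts.
    """
    shape = np.asarray(shape)
    if np.any(2 * frame_voxels >= shape):
        raise ValueError(
            f"frame {frame_voxels} leaves no interior for shape {tuple(shape)}"
        )

    def interior(points):
        return np.all((points >= frame_voxels) & (points < shape - frame_voxels), axis=1)

    keep_gt = interior(gt.points)
    keep_pred = interior(pred.points)

    pairs, dists, un_g, un_p = [], [], [], []
    for (i, j), d in zip(raw.pairs, raw.distances_um):
        gi, pj = keep_gt[i], keep_pred[j]
        if gi and pj:
            pairs.append((i, j))
            dists.append(d)
        elif gi:
            un_g.append(i)
        elif pj:
            un_p.append(j)
    un_g.extend(i for i in raw.unmatched_gt if keep_gt[i])
    un_p.extend(j for j in raw.unmatched_pred if keep_pred[j])

    filtered = RawMatching(
        np.asarray(pairs, dtype=int).reshape(-1, 2),
        np.asarray(dists, dtype=float),
        np.asarray(sorted(un_g), dtype=int),
        np.asarray(sorted(un_p), dtype=int),
    )
    return filtered, int(np.count_nonzero(~keep_gt)), int(np.count_nonzero(~keep_pred))


def classify_matches(raw: RawMatching, max_dist_um: float = MAX_MATCH_DIST_UM) -> MatchReport:
    """Apply the distance criterion and compute P/R/F1 (percent).

    Strict inequality: a pair at exactly ``max_dist_um`` is NOT a true
    positive — it contributes one FP and one FN.  Degenerate conventions:
    both sets empty → perfect agreement on "nothing" (P=R=F1=100, flagged);
    exactly one side empty → F1 = 0 (flagged).
    """
    is_tp = raw.distances_um < max_dist_um
    tp = int(np.count_nonzero(is_tp))
    bad_pairs = int(np.count_nonzero(~is_tp))
    fp = bad_pairs + len(raw.unmatched_pred)
    fn = bad_pairs + len(raw.unmatched_gt)

    n_gt, n_pred = tp + fn, tp + fp
    degenerate = n_gt == 0 or n_pred == 0
    if n_gt == 0 and n_pred == 0:
        precision = recall = f1 = 100.0
    else:
        precision = 100.0 * tp / n_pred if n_pred else 0.0
        recall = 100.0 * tp / n_gt if n_gt else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0

    tp_pairs = [
        (int(i), int(j), float(d))
        for (i, j), d, ok in zip(raw.pairs, raw.distances_um, is_tp)
        if ok
    ]
    return MatchReport(tp, fp, fn, precision, recall, f1, tp_pairs, degenerate=degenerate)


def evaluate(
    gt: CellCenters,
    pred: CellCenters,
    shape,
    voxel_size_um,
    max_dist_um: float = MAX_MATCH_DIST_UM,
    frame_voxels: int = BORDER_FRAME_VOXELS,
) -> MatchReport:
    """Canonical entry point: match → border exclusion → classification.

    ``gt`` and ``pred`` are voxel-space centers of one volume of the given
    ``shape``; ``voxel_size_um`` converts pair distances to micrometres.
    """
    gt_v = gt.to_voxel(voxel_size_um)
    pred_v = pred.to_voxel(voxel_size_um)
    raw = match_centers(gt_v, pred_v, voxel_size_um)
    filtered, ex_g, ex_p = exclude_border(gt_v, pred_v, raw, shape, frame_voxels)
    report = classify_matches(filtered, max_dist_um)
    report.excluded_gt, report.excluded_pred = ex_g, ex_p
    return report


def f1_from_percent(precision: float, recall: float) -> float:
    """F1 (percent) from precision and recall on the percent scale."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def annotator_coherence(
    annotation_sets: list,
    shape,
    voxel_size_um,
    pairs: list | None = None,
    **eval_kwargs,
):
    """Pairwise F1 between annotation sets of the same volume.

    ``pairs`` designates which unordered index pairs to compare (default
    all); the first set of each pair plays the ground-truth role.  Returns
    a list of ``(i, j, f1)`` plus the mean ± sample SD of the F1 values —
    the intra/inter annotator coherence summary.
    """
    if len(annotation_sets) < 2:
        raise ValueError("need at least two annotation sets")
    if pairs is None:
        pairs = list(combinations(range(len(annotation_sets)), 2))
    rows = []
    for i, j in pairs:
        rep = evaluate(annotation_sets[i], annotation_sets[j], shape, voxel_size_um, **eval_kwargs)
        rows.append((i, j, rep.f1))
    f1s = np.array([r[2] for r in rows])
    sd = float(np.std(f1s, ddof=1)) if len(f1s) > 1 else float("nan")
    return rows, float(f1s.mean()), sd


def stereology_crop_alignment(
    pred_on_large: CellCenters,
    box_origin,
    box_shape,
    large_shape,
    shift_voxels: int = 3,
) -> CellCenters:
    """Select predictions aligned with a stereology annotation box.

    Stereological annotations exclude cells overlapping the bottom-right
    border of the annotation box, so predictions made on a larger volume
    are kept only inside the box translated by ``shift_voxels`` toward the
    origin on each axis, with half-open bounds [lo, hi).
    """
    origin = np.asarray(box_origin, dtype=float)
    bshape = np.asarray(box_shape, dtype=float)
    large = np.asarray(large_shape, dtype=float)
    lo = origin - shift_voxels
    hi = lo + bshape
    if np.any(lo < 0) or np.any(hi > large):
        raise ValueError(
            f"shifted box [{lo}, {hi}) exceeds the large volume {tuple(large_shape)}"
        )
    pts = pred_on_large.points
    keep = np.all((pts >= lo) & (pts < hi), axis=1)
    labels = pred_on_large.labels[keep] if pred_on_large.labels is not None else None
    return CellCenters(pts[keep], space=pred_on_large.space, labels=labels)
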