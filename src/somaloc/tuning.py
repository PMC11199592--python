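"""DoG hyperparameter tuning against validation F1.

The objective is the mean localization F1 (15 um criterion, border frame
excluded) of :func:`somaloc.detector.detect_centers` over one or more
validation volumes with ground-truth centers, maximised by the in-package
tree-structured Parzen estimator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import CellCenters, Volume
from .detector import DoGParams, detect_centers
from .metrics import evaluate
from .tpe import SearchDim, TPEOptimizer

DEFAULT_SEARCH_SPACE = [
    SearchDim("sigma_small", 0.8, 4.0),
    SearchDim("ratio", 1.1, 2.5),
    SearchDim("response_threshold", 1e-4, 0.5, log=True),
    SearchDim("merge_distance", 2.0, 12.0),
]


def tune_dog(
    fields: list,
    gt_centers: list[CellCenters],
    voxel_size_um,
    search_space: list[SearchDim] | None = None,
    budget: int = 100,
    seed: int = 0,
    max_dist_um: float = 15.0,
    frame_voxels: int = 6,
    threshold_mode: str = "absolute",
    objective: str = "mean",
    trial_log_path=None,
) -> tuple[DoGParams, list]:
    """Tune DoG parameters on validation volumes; returns (params, trials).

    ``fields`` are predicted soft fields (or raw volumes), ``gt_centers``
    the matching voxel-space annotations.  The returned parameter set is
    the evaluated trial with the highest validation F1 — the mean over
    volumes by default, or the minimum (``objective="min"``) when the
    parameters must hold up on every volume rather than on average.  The
    trial sequence is deterministic under a fixed seed and optionally
    persisted as JSON lines.
    """
    if len(fields) == 0 or len(fields) != len(gt_centers):
        raise ValueError("need >= 1 validation volume with matching ground truth")
    space = DEFAULT_SEARCH_SPACE if search_space is None else search_space
    shapes = [f.shape if isinstance(f, Volume) else np.asarray(f).shape for f in fields]

    def objective(params: dict) -> float:
        p = DoGParams(**params, threshold_mode=threshold_mode)
        f1s = []
        for field, gt, shape in zip(fields, gt_centers, shapes):
            pred = detect_centers(field, p)
            rep = evaluate(
                gt, pred, shape, voxel_size_um,
                max_dist_um=max_dist_um, frame_voxels=frame_voxels,
            )
            f1s.append(rep.f1)
        return float(np.min(f1s)) if objective == "min" else float(np.mean(f1s))

    opt = TPEOptimizer(space, seed=seed, n_startup=min(10, budget))
    best = opt.optimize(objective, budget)

    if trial_log_path is not None:
        with Path(trial_log_path).open("w") as fh:
            for t in opt.trials:
                fh.write(json.dumps({"number": t.number, "value": t.value, **t.params}) + "\n")
    return DoGParams(**best.params, threshold_mode=threshold_mode), opt.trials
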