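"""End-to-end experiment orchestration with leave-one-slab-out evaluation.

An experiment generates K phantom slabs with per-slab gain/offset/noise
variation (emulating the covariate shift between independently acquired
tissue slabs), then for each split trains the UNet on the K−1 remaining
slabs, tunes the DoG detector against those slabs' predictions, and
evaluates once on the left-out slab.  Per-slab match reports, a density
table and a summary JSON land in the run directory; two runs from one
config snapshot produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .detector import DoGParams, detect_centers
from .metrics import evaluate
from .nn import NetworkConfig, UNet3D, predict_soft, train
from .phantom import PhantomConfig, generate_slab, slab_variants
from .stereology import FractionatorDesign, aggregate_layer, sample_fractionator
from .targets import make_soft_target
from .tuning import tune_dog

log = logging.getLogger("somaloc.pipeline")


def _default_network() -> NetworkConfig:
    # desk-scale profile: many cheap small-crop SGD steps beat few large
    # ones; with two training slabs each epoch takes two steps
    from .nn import scaled_down_config

    return scaled_down_config(epochs=1400, restart_period=700, lr_max=0.1, ema_decay=0.995)


@dataclasses.dataclass
class RunConfig:
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    network: NetworkConfig = dataclasses.field(default_factory=_default_network)
    n_slabs: int = 3
    tune_budget: int = 30
    crop_shape: tuple | None = (16, 16, 16)
    # tiled prediction keeps group-norm statistics close to the training
    # crops'; whole-volume forward passes shift them and cost recall
    tile_shape: tuple | None = (32, 32, 32)
    max_dist_um: float = 15.0
    frame_voxels: int = 6
    seed: int = 0

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple, np.ndarray)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            if isinstance(obj, (np.floating, float)):
                return float(obj)
            return obj

        return clean(dataclasses.asdict(self))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serialisable: {type(o)}")


def run_experiment(cfg: RunConfig, run_dir) -> dict:
    """Run the full leave-one-slab-out experiment; returns the summary dict.

    Every stage is seeded from ``cfg.seed``; the config snapshot, per-slab
    reports and the summary are persisted under ``run_dir``.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))

    if cfg.n_slabs < 3:
        raise ValueError("leave-one-slab-out needs >= 3 slabs (train/tune/eval)")

    log.info("generating %d phantom slabs", cfg.n_slabs)
    slabs = []
    for k, slab_cfg in enumerate(slab_variants(cfg.phantom, cfg.n_slabs, seed=cfg.seed)):
        vol, centers = generate_slab(slab_cfg)
        soft, _ = make_soft_target(centers, vol.shape)
        slabs.append({"volume": vol, "centers": centers, "soft": soft})
        log.info("slab %d: %d cells, gain %.2f", k, len(centers), slab_cfg.slab_gain)

    per_slab = []
    for held_out in range(cfg.n_slabs):
        # train on all K-1 remaining slabs; DoG is tuned on one of them
        # (at desk scale a disjoint tuning slab would leave a single
        # training slab and no coverage of the inter-slab intensity range)
        fit_ids = [k for k in range(cfg.n_slabs) if k != held_out]
        log.info("split %d: train+tune on %s, eval %d", held_out, fit_ids, held_out)

        net_cfg = dataclasses.replace(cfg.network, seed=cfg.seed + held_out)
        model = UNet3D(net_cfg)
        pairs = [(slabs[k]["volume"], slabs[k]["soft"]) for k in fit_ids]
        history = train(model, pairs, net_cfg, crop_shape=cfg.crop_shape)

        tune_preds = [predict_soft(model, slabs[k]["volume"], cfg.tile_shape) for k in fit_ids]
        params, _ = tune_dog(
            tune_preds, [slabs[k]["centers"] for k in fit_ids],
            cfg.phantom.voxel_size_um,
            budget=cfg.tune_budget, seed=cfg.seed + 100 + held_out,
            max_dist_um=cfg.max_dist_um, frame_voxels=cfg.frame_voxels,
            trial_log_path=run_dir / f"split{held_out}_trials.jsonl",
        )

        eval_pred = predict_soft(model, slabs[held_out]["volume"], cfg.tile_shape)
        detections = detect_centers(eval_pred, params)
        report = evaluate(
            slabs[held_out]["centers"], detections,
            slabs[held_out]["volume"].shape, cfg.phantom.voxel_size_um,
            max_dist_um=cfg.max_dist_um, frame_voxels=cfg.frame_voxels,
        )
        model.save(run_dir / f"split{held_out}_model.pkl")
        entry = {
            "held_out_slab": held_out,
            "n_gt": len(slabs[held_out]["centers"]),
            "n_pred": len(detections),
            "precision": report.precision,
            "recall": report.recall,
            "f1": report.f1,
            "final_train_loss": history[-1],
            "dog_params": params.to_dict(),
        }
        per_slab.append(entry)
        (run_dir / f"split{held_out}_report.json").write_text(
            json.dumps(entry, indent=2, default=_json_default)
        )
        log.info("split %d: P=%.1f R=%.1f F1=%.1f", held_out, report.precision, report.recall, report.f1)

    # density bookkeeping on the held-out detections vs ground truth
    densities = []
    voxel = cfg.phantom.voxel_size_um
    for held_out, entry in enumerate(per_slab):
        vol = slabs[held_out]["volume"]
        extent_um = np.asarray(vol.shape) * voxel
        region = (np.zeros(3), extent_um)
        design = FractionatorDesign(
            frame_um=(extent_um[1], extent_um[2]),
            grid_um=(extent_um[1], extent_um[2]),
            disector_height_um=extent_um[0],
            region=region,
        )
        gt_um = slabs[held_out]["centers"].to_um(voxel)
        res_gt = sample_fractionator(gt_um, design)
        vol_mm3 = float(np.prod(extent_um)) / 1e9
        densities.append({
            "slab": held_out,
            "true": res_gt.density_per_mm3,
            "predicted": entry["n_pred"] / vol_mm3,
        })

    summary = {
        "per_slab": per_slab,
        "f1_mean": float(np.mean([e["f1"] for e in per_slab])),
        "f1_sd": float(np.std([e["f1"] for e in per_slab], ddof=1)),
        "densities": densities,
        "seed": cfg.seed,
    }
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_default))
    return summary


def report(run_dir) -> str:
    """Human-readable tables from a completed run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        missing = [p for p in ("config.yaml", "summary.json") if not (run_dir / p).exists()]
        return "incomplete run; missing artifacts: " + ", ".join(missing)
    summary = json.loads(summary_path.read_text())
    lines = ["slab   Prec(%)  Rec(%)   F1(%)"]
    for e in summary["per_slab"]:
        lines.append(
            f"{e['held_out_slab']:>4}   {e['precision']:6.1f}  {e['recall']:6.1f}  {e['f1']:6.1f}"
        )
    f1s = [e["f1"] for e in summary["per_slab"]]
    mean, sd = aggregate_layer(f1s)
    sd_txt = f"{sd:.1f}" if np.isfinite(sd) else "NA"
    lines.append(f"mean   F1 = {mean:.1f} +/- {sd_txt}")
    return "\n".join(lines)
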