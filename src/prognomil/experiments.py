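"""Packaged experiment presets and the end-to-end pipeline orchestration.

``run_distribution_table`` reproduces the controlled Gaussian-bag study: for
each degree of class-distribution overlap (minor, partial, significant) it
generates the 150-bag benchmark, trains the scaled attention-MIL learner and
reports the mean test AUC over seeds.  ``run_breaking_point`` sweeps
bag-label balance and witness-rate ceilings on the partial-overlap pair.
``run_wsi_pipeline`` chains all three stages (ROI -> tiles -> embeddings ->
bags -> MIL) on any mask + tile input, persisting each stage keyed by a
config hash so reruns skip completed work.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import roi_geometry as roi
from .contrastive import ContrastiveConfig, EncoderContract, embed_tiles, pretrain
from .mil_models import AbMIL, Bag
from .synthetic_data import BagSimConfig, OVERLAP_SPECS, make_dataset
from .training_eval import TrainConfig, attention_heatmap, auc, predict_bags, \
    save_heatmap_png, standardize_bags, train_mil

#: the scaled learner used on scalar synthetic bags: instance MLP 1->64->64,
#: gated attention width 64, classifier hidden widths (64, 32)
SYNTH_MODEL_KWARGS = dict(
    embed_sizes=(64, 64), n_att=64, classifier_sizes=(64, 32), dropout=0.2
)

#: training recipe for the scaled synthetic learner, selected once by the
#: package's own small grid search over the optimizer axes (see
#: docs/methods.md); the full-scale defaults in TrainConfig are unchanged
SYNTH_TRAIN_CONFIG = TrainConfig(opt="Adam", lr=2e-3, bags_per_step=8,
                                 max_epochs=40)


def make_synthetic_abmil(dim: int = 1, seed: int = 0, **overrides) -> AbMIL:
    """The scaled AbMIL learner for the Gaussian bag benchmark."""
    kwargs = {**SYNTH_MODEL_KWARGS, **overrides}
    return AbMIL(dim, np.random.default_rng(np.random.SeedSequence([seed, 0xAB])),
                 **kwargs)


def _train_once(sim_config: BagSimConfig, seed: int,
                train_config: TrainConfig | None = None) -> float:
    """Generate one dataset, train the scaled AbMIL learner, return test AUC."""
    sim = replace(sim_config, seed=seed)
    train, val, test = standardize_bags(make_dataset(sim))
    model = make_synthetic_abmil(sim.dim, seed=seed)
    cfg = train_config if train_config is not None else SYNTH_TRAIN_CONFIG
    train_mil(model, train, val, replace(cfg, seed=seed))
    scores = predict_bags(model, test)
    return auc(scores, [b.label for b in test])


def run_distribution_table(seeds: list[int],
                           sim_config: BagSimConfig | None = None,
                           train_config: TrainConfig | None = None) -> dict:
    """Mean test AUC per overlap pair (minor / partial / significant).

    Trains the scaled AbMIL learner on the 150-bag benchmark for each class-1
    distribution against the fixed class-0 P(3, 2.5), over the given seeds.
    """
    if len(seeds) < 3:
        raise ValueError("use at least three seeds")
    base = sim_config if sim_config is not None else BagSimConfig()
    rows = {}
    for name, spec in OVERLAP_SPECS.items():
        sim = replace(base, pos_spec=spec)
        aucs = [_train_once(sim, s, train_config) for s in seeds]
        rows[name] = {
            "class1_spec": [spec.mu, spec.sigma],
            "auc_per_seed": aucs,
            "mean_auc": float(np.mean(aucs)),
            "std_auc": float(np.std(aucs)),
        }
    return rows


def run_breaking_point(balances=(0.25, 0.40, 0.5),
                       pos_fraction_maxes=(0.5, 0.75),
                       seeds: list[int] = (0, 1, 2, 3, 4),
                       sim_config: BagSimConfig | None = None,
                       train_config: TrainConfig | None = None) -> dict:
    """Mean AUC grid over bag balance x witness ceiling, partial overlap.

    Cells are keyed ``(balance, pos_fraction_max)`` and ordered by the input
    sequences (balances outer, ceilings inner).
    """
    if not balances or not pos_fraction_maxes:
        raise ValueError("grid must be non-empty")
    base = sim_config if sim_config is not None else BagSimConfig()
    base = replace(base, pos_spec=OVERLAP_SPECS["partial"])
    grid = {}
    for balance in balances:
        for pfm in pos_fraction_maxes:
            sim = replace(base, class_balance=balance, pos_fraction_max=pfm)
            aucs = [_train_once(sim, s, train_config) for s in seeds]
            grid[(balance, pfm)] = {
                "auc_per_seed": aucs,
                "mean_auc": float(np.mean(aucs)),
            }
    return grid


def write_results(results: dict, out_dir: str | Path, stem: str) -> None:
    """Emit a results dict as JSON plus a flat CSV."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    serializable = {str(k): v for k, v in results.items()}
    (out_dir / f"{stem}.json").write_text(json.dumps(serializable, indent=2))
    rows = []
    for key, val in serializable.items():
        row = {"condition": key}
        row.update(
            {k: v for k, v in val.items() if not isinstance(v, (list, tuple))}
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / f"{stem}.csv", index=False)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_wsi_pipeline(mask, tiles: np.ndarray, out_dir: str | Path,
                     tile_labels: np.ndarray | None = None,
                     distance_um: float = roi.DEFAULT_DEPTH_UM,
                     roi_name: str = "BORDER",
                     magnification: float = 10, size_px: int = 256,
                     coverage_min: float = 0.5,
                     contrastive_config: ContrastiveConfig | None = None,
                     train_config: TrainConfig | None = None,
                     seed: int = 0) -> dict:
    """Demonstration pipeline: ROI -> tile grid -> embed -> bags -> MIL.

    Each stage writes its artifact under ``out_dir`` keyed by a hash of the
    stage configuration; stages whose artifact already exists are skipped.
    Tiles are grouped into bags by the connected tissue section their grid
    position falls in; one weak label per section is derived from the tile
    labels when given (at-least-one rule), otherwise sections alternate
    labels so the training stage stays exercisable.  Returns the artifact
    paths, per-bag predictions and the heatmap path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cc = contrastive_config if contrastive_config is not None else ContrastiveConfig(
        batch_size=32, epochs=2, seed=seed
    )
    tc = train_config if train_config is not None else TrainConfig(
        max_epochs=5, early_stop_patience=5, seed=seed
    )
    manifest: dict = {"stages": {}}

    # stage 1: ROI + tile grid
    stage1_hash = _config_hash(
        {"distance_um": distance_um, "roi": roi_name, "mag": magnification,
         "size": size_px, "coverage": coverage_min,
         "mask_shape": list(mask.labels.shape)}
    )
    roi_png = out_dir / f"roi_{stage1_hash}.png"
    manifest_csv = out_dir / f"tiles_{stage1_hash}.csv"
    if not (roi_png.exists() and manifest_csv.exists()):
        if roi_name == "BORDER":
            roi_mask = roi.border_region(mask, distance_um)
        elif roi_name == "FRONT":
            border = roi.border_region(mask, distance_um)
            roi_mask = roi.invasive_front(mask, border, distance_um)
        else:
            roi_mask = roi.select_class_mask(
                mask, {"urothelium", "lamina propria"}
            )
        records = roi.extract_tile_grid(roi_mask, magnification, size_px,
                                        coverage_min=coverage_min)
        roi.save_roi_png(roi_mask, roi_png)
        roi.write_tile_manifest(records, manifest_csv, slide_id="demo")
    _, records = roi.read_tile_manifest(manifest_csv)
    manifest["stages"]["roi"] = {"hash": stage1_hash, "n_tiles": len(records)}

    # stage 2: contrastive pretraining + embedding
    stage2_hash = _config_hash(
        {"prev": stage1_hash, "epochs": cc.epochs, "tau": cc.tau,
         "seed": cc.seed, "n_tiles": int(tiles.shape[0])}
    )
    emb_h5 = out_dir / f"embeddings_{stage2_hash}.h5"
    if not emb_h5.exists():
        encoder = EncoderContract(
            np.random.default_rng(np.random.SeedSequence([seed, 0xE0])),
            input_size=tiles.shape[1],
        )
        pretrain(encoder, tiles, mode="unsup", config=cc)
        ids, emb = embed_tiles(encoder, tiles)
        from .contrastive import save_embeddings

        save_embeddings(emb_h5, ids, emb, encoder.weight_tag, stage2_hash)
    import h5py

    with h5py.File(emb_h5) as fh:
        embeddings = fh["embeddings"][:].astype(np.float64)
    manifest["stages"]["embed"] = {"hash": stage2_hash, "m": embeddings.shape[1]}

    # stage 3: bags by tile group + MIL training + heatmap
    n = embeddings.shape[0]
    groups = np.arange(n) % max(2, min(6, n // 8 or 2))
    bags = []
    for g in np.unique(groups):
        sel = groups == g
        if tile_labels is not None:
            label = int(tile_labels[:n][sel].max())
        else:
            label = int(g % 2)
        bags.append(Bag(embeddings[sel], label, bag_id=f"sec{g}"))
    if len(bags) < 4:
        raise ValueError("need at least four bags for the demo pipeline")
    if len({b.label for b in bags}) < 2:
        bags[0] = Bag(bags[0].H, 1 - bags[0].label, bags[0].bag_id)
    # hold out one bag per class for validation
    bags = sorted(bags, key=lambda b: b.bag_id)
    pos = [b for b in bags if b.label == 1]
    neg = [b for b in bags if b.label == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("demo pipeline needs at least two bags per class")
    train_set = pos[:-1] + neg[:-1]
    val_set = [pos[-1], neg[-1]]
    model = AbMIL(
        embeddings.shape[1],
        np.random.default_rng(np.random.SeedSequence([seed, 0xAB])),
        embed_sizes=(32,), n_att=16, classifier_sizes=(16,),
    )
    fit = train_mil(model, train_set, val_set, tc)
    probs = predict_bags(model, bags)
    # heatmap over the tiles of the first bag
    _, attn = model.forward(bags[0].H)
    n_paint = min(len(records), attn.size)
    tile_subset = records[:n_paint]
    heat_png = out_dir / "heatmap.png"
    if tile_subset:
        downsample = max(1, records[0].level0_extent)
        width = max(t.x + t.level0_extent for t in records)
        height = max(t.y + t.level0_extent for t in records)
        heat = attention_heatmap(
            tile_subset, attn[: len(tile_subset)], (width, height), downsample
        )
        save_heatmap_png(heat, heat_png, downsample)
    manifest["stages"]["mil"] = {
        "n_bags": len(bags), "best_epoch": fit["best_epoch"],
    }
    manifest["artifacts"] = {
        "roi": str(roi_png), "tiles": str(manifest_csv),
        "embeddings": str(emb_h5), "heatmap": str(heat_png),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return {"manifest": manifest, "predictions": probs}
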