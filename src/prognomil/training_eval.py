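"""Training loop, metrics, Monte-Carlo-dropout inference and heatmaps.

MIL models are trained with the focal Tversky loss under SGD (lr 1e-2 by
default), sampling ``n_b`` instances per bag per step as a regularizer, with
early stopping on validation AUC (patience 30 epochs) and restoration of the
best-epoch weights.  Validation and test AUC are always computed on full,
unsampled bags.  AUC is the Mann-Whitney pairwise concordance probability;
sensitivity and specificity are reported at the Youden-optimal validation
threshold.  Monte-Carlo dropout (5 runs at 5% by default) samples the
predictive variability at inference time.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .mil_models import Bag, FTLConfig, NestedBag, _ftl_graph
from .nn import stack_rows, SGD as SGDOpt, Adam as AdamOpt
from .roi_geometry import TileRecord

#: sentinel meaning "use all L instances of the bag"
ALL_INSTANCES = -1

#: probability clipping inside the training loss only (keeps the focal
#: exponent's gradient finite when the sigmoid saturates)
_CLIP = 1e-6


@dataclass
class TrainConfig:
    """MIL training hyperparameters (defaults from the hyperparameter search)."""

    lr: float = 1e-2
    opt: str = "SGD"
    n_b: int = 64
    d_r: float = 0.2
    early_stop_patience: int = 30
    max_epochs: int = 60
    bags_per_step: int = 16
    ftl: FTLConfig = field(default_factory=FTLConfig)
    seed: int = 0

    def __post_init__(self):
        if self.opt not in ("SGD", "Adam"):
            raise ValueError("opt must be 'SGD' or 'Adam'")
        if self.n_b != ALL_INSTANCES and self.n_b < 1:
            raise ValueError("n_b must be >= 1 or the all-instances sentinel")


@dataclass
class EvalResult:
    """Metrics of one or more evaluation runs."""

    auc: float
    sensitivity: float
    specificity: float
    per_run: list[float] = field(default_factory=list)
    mean: float | None = None
    std: float | None = None


def sample_bag_instances(bag: Bag, n_b: int, rng: np.random.Generator) -> Bag:
    """Uniform without-replacement sub-bag of n_b instances (whole bag if
    L <= n_b or n_b is the all-instances sentinel)."""
    if n_b == ALL_INSTANCES or bag.n_instances <= n_b:
        return bag
    idx = rng.choice(bag.n_instances, size=n_b, replace=False)
    return Bag(
        bag.H[idx],
        bag.label,
        bag.bag_id,
        None if bag.instance_labels is None else bag.instance_labels[idx],
    )


def _sample_nested(nested: NestedBag, n_b: int, rng: np.random.Generator) -> NestedBag:
    """Per-region without-replacement sampling, at least one tile per region."""
    total = sum(r.shape[0] for r in nested.regions)
    if n_b == ALL_INSTANCES or total <= n_b:
        return nested
    regions = []
    for r in nested.regions:
        keep = max(1, int(round(n_b * r.shape[0] / total)))
        if r.shape[0] > keep:
            idx = rng.choice(r.shape[0], size=keep, replace=False)
            r = r[idx]
        regions.append(r)
    return NestedBag(regions, nested.label, nested.bag_id)


def _forward(model, bag, training, rng):
    if isinstance(bag, NestedBag):
        out = model.forward(bag, training=training, rng=rng)
    else:
        out = model.forward(bag.H, training=training, rng=rng)
    return out[0]


def predict_bags(model, bags: list, dropout_rate: float | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Inference probabilities for a list of (possibly nested) bags."""
    if (
        dropout_rate is None
        and hasattr(model, "forward_many")
        and getattr(model, "n_clinical", 0) == 0
        and all(isinstance(b, Bag) for b in bags)
    ):
        return model.forward_many([b.H for b in bags])[0]
    probs = []
    for bag in bags:
        if isinstance(bag, NestedBag):
            p = model.forward(bag, training=dropout_rate is not None, rng=rng,
                              dropout_rate=dropout_rate)[0]
        else:
            p = model.forward(bag.H, training=dropout_rate is not None, rng=rng,
                              dropout_rate=dropout_rate)[0]
        probs.append(float(p.data))
    return np.asarray(probs)


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney concordance, ties count 1/2)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def youden_threshold(scores, labels) -> float:
    """Operating point maximizing sensitivity + specificity - 1."""
    fpr, tpr, thresholds = roc_curve(np.asarray(labels), np.asarray(scores))
    return float(thresholds[np.argmax(tpr - fpr)])


def sensitivity_specificity(scores, labels, threshold: float) -> tuple[float, float]:
    scores = np.asarray(scores)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    tp = (pred & labels).sum()
    tn = (~pred & ~labels).sum()
    sens = tp / max(1, labels.sum())
    spec = tn / max(1, (~labels).sum())
    return float(sens), float(spec)


def standardize_bags(splits: tuple[list, ...]) -> tuple[list, ...]:
    """Standardize instance features to zero mean / unit sd of the train split.

    The first element of ``splits`` is the training set; its per-dimension
    statistics are applied to every split.  Centering matters for
    low-dimensional instance features whose raw offset would leave most
    first-layer ReLU units inactive.
    """
    def _stack(bag):
        return (
            np.concatenate(bag.regions) if isinstance(bag, NestedBag) else bag.H
        )

    X = np.concatenate([_stack(b) for b in splits[0]])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    out = []
    for part in splits:
        fixed = []
        for b in part:
            if isinstance(b, NestedBag):
                fixed.append(
                    NestedBag(
                        [(r - mu) / sd for r in b.regions], b.label, b.bag_id,
                        b.region_instance_labels,
                    )
                )
            else:
                fixed.append(Bag((b.H - mu) / sd, b.label, b.bag_id,
                                 b.instance_labels))
        out.append(fixed)
    return tuple(out)


def train_mil(model, train_bags: list, val_bags: list,
              config: TrainConfig | None = None) -> dict:
    """Train a MIL model with FTL, early-stopping on validation AUC.

    Bags are processed in minibatches of ``bags_per_step``; each bag
    contributes one probability from an ``n_b``-instance sub-bag, and the
    focal Tversky loss over the minibatch drives one optimizer step.
    Validation AUC is computed each epoch on full bags; the best-epoch
    weights are restored at the end.  Returns a history dict with per-epoch
    loss and validation AUC, the best epoch and the epochs actually run.
    """
    config = config if config is not None else TrainConfig()
    if not train_bags or not val_bags:
        raise ValueError("train and validation splits must be non-empty")
    train_ids = {b.bag_id for b in train_bags}
    if train_ids & {b.bag_id for b in val_bags}:
        raise ValueError("train and validation bag ids overlap")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7121]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD0]))
    params = model.parameters()
    opt = (
        SGDOpt(params, lr=config.lr)
        if config.opt == "SGD"
        else AdamOpt(params, lr=config.lr)
    )
    val_labels = np.asarray([b.label for b in val_bags])
    history = {"loss": [], "val_auc": []}
    best_auc, best_epoch, best_state = -np.inf, -1, model.get_state()
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_bags))
        epoch_losses = []
        for start in range(0, len(order), config.bags_per_step):
            chunk = order[start:start + config.bags_per_step]
            probs, labels = [], []
            for i in chunk:
                bag = train_bags[i]
                if isinstance(bag, NestedBag):
                    sub = _sample_nested(bag, config.n_b, rng)
                else:
                    sub = sample_bag_instances(bag, config.n_b, rng)
                probs.append(_forward(model, sub, True, drop_rng))
                labels.append(bag.label)
            p = stack_rows(probs)
            # clip inside the training loss only; see module docstring
            p = p * (1.0 - 2 * _CLIP) + _CLIP
            loss = _ftl_graph(p, np.asarray(labels, dtype=float), config.ftl)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_scores = predict_bags(model, val_bags)
        val_auc = auc(val_scores, val_labels)
        history["loss"].append(float(np.mean(epoch_losses)))
        history["val_auc"].append(val_auc)
        if val_auc > best_auc:
            best_auc, best_epoch, best_state = val_auc, epoch, model.get_state()
        elif epoch - best_epoch > config.early_stop_patience:
            break
    model.set_state(best_state)
    return {
        "history": history,
        "best_epoch": best_epoch,
        "best_val_auc": best_auc,
        "n_epochs": len(history["loss"]),
    }


def evaluate(model, bags: list, threshold: float | None = None,
             val_bags: list | None = None) -> EvalResult:
    """AUC plus sensitivity/specificity at a Youden-optimal threshold.

    The operating point is chosen on ``val_bags`` when provided (the honest
    protocol), otherwise on the evaluation bags themselves.
    """
    labels = np.asarray([b.label for b in bags])
    scores = predict_bags(model, bags)
    if threshold is None:
        if val_bags is not None:
            vs = predict_bags(model, val_bags)
            threshold = youden_threshold(vs, [b.label for b in val_bags])
        else:
            threshold = youden_threshold(scores, labels)
    sens, spec = sensitivity_specificity(scores, labels, threshold)
    return EvalResult(auc(scores, labels), sens, spec)


def mc_dropout_predict(model, bag, runs: int = 5, rate: float = 0.05,
                       seed: int = 0) -> dict:
    """Monte-Carlo dropout: repeated stochastic forwards with dropout active."""
    seqs = np.random.SeedSequence([seed, 0x3C]).spawn(runs)
    ys = []
    for seq in seqs:
        run_rng = np.random.default_rng(seq)
        if rate == 0.0:
            ys.append(predict_bags(model, [bag])[0])
        else:
            ys.append(predict_bags(model, [bag], dropout_rate=rate, rng=run_rng)[0])
    ys = np.asarray(ys)
    return {"runs": ys, "mean": float(ys.mean()), "std": float(ys.std())}


# ---------------------------------------------------------------------------
# grid search


def run_grid_search(space: dict[str, list], model_factory, train_bags, val_bags,
                    budget: int | None = None,
                    base_config: TrainConfig | None = None,
                    seed: int = 0) -> list[dict]:
    """Exhaustive (optionally budgeted) hyperparameter search by val AUC.

    ``space`` maps TrainConfig field names (plus optional ``n_att`` /
    ``classifier_sizes`` consumed by ``model_factory``) to candidate values;
    enumeration is the cross product in insertion order.  Returns configs
    ranked by validation AUC, earlier enumeration winning ties.
    """
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("search space must be non-empty")
    base = base_config if base_config is not None else TrainConfig()
    keys = list(space)
    combos = list(itertools.product(*(space[k] for k in keys)))
    if budget is not None and budget < len(combos):
        sub_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D]))
        pick = sorted(sub_rng.choice(len(combos), size=budget, replace=False))
        combos = [combos[i] for i in pick]
    results = []
    for rank_order, combo in enumerate(combos):
        overrides = dict(zip(keys, combo))
        model_kwargs = {
            k: overrides.pop(k)
            for k in ("n_att", "classifier_sizes", "embed_sizes")
            if k in overrides
        }
        ftl_kwargs = {
            {"alpha_l": "alpha", "gamma_l": "gamma"}[k]: overrides.pop(k)
            for k in ("alpha_l", "gamma_l")
            if k in overrides
        }
        config = replace(base, **overrides)
        if ftl_kwargs:
            config = replace(config, ftl=replace(base.ftl, **ftl_kwargs))
        model = model_factory(**model_kwargs)
        fit = train_mil(model, train_bags, val_bags, config)
        results.append(
            {
                "params": dict(zip(keys, combo)),
                "val_auc": fit["best_val_auc"],
                "order": rank_order,
            }
        )
    return sorted(results, key=lambda r: (-r["val_auc"], r["order"]))


# ---------------------------------------------------------------------------
# attention heatmaps


def attention_heatmap(tile_records: list[TileRecord], attention: np.ndarray,
                      slide_dims: tuple[int, int], downsample: int,
                      ) -> np.ma.MaskedArray:
    """Paint per-slide min-max-normalized attention into tile footprints.

    Returns a masked float raster at ``slide_dims / downsample``; pixels not
    covered by any tile are masked (transparent).
    """
    attention = np.asarray(attention, dtype=float)
    if len(tile_records) != attention.size:
        raise ValueError("attention length must match tile records")
    lo, hi = attention.min(), attention.max()
    norm = np.zeros_like(attention) if hi == lo else (attention - lo) / (hi - lo)
    width, height = slide_dims
    raster = np.zeros((height // downsample, width // downsample), dtype=float)
    covered = np.zeros_like(raster, dtype=bool)
    for tile, value in zip(tile_records, norm):
        x0 = tile.x // downsample
        y0 = tile.y // downsample
        ext = max(1, tile.level0_extent // downsample)
        raster[y0:y0 + ext, x0:x0 + ext] = value
        covered[y0:y0 + ext, x0:x0 + ext] = True
    return np.ma.MaskedArray(raster, mask=~covered)


def save_heatmap_png(heatmap: np.ma.MaskedArray, path: str | Path,
                     downsample: int = 1, origin: tuple[int, int] = (0, 0)) -> None:
    """Write the heatmap as a grayscale+alpha PNG with a JSON sidecar."""
    from PIL import Image

    values = (np.clip(heatmap.filled(0.0), 0, 1) * 255).astype(np.uint8)
    alpha = np.where(heatmap.mask, 0, 255).astype(np.uint8)
    Image.fromarray(np.stack([values, alpha], axis=-1), mode="LA").save(path)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps({"downsample": downsample, "origin": list(origin)})
    )
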