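"""Synthetic inputs for every stage of the pipeline.

The centerpiece is the controlled Gaussian bag benchmark: bags of scalar
(or low-dimensional) instances drawn from a negative-class distribution
P(mu=3, sigma=2.5) and, in positive bags, partially from a positive-class
distribution whose overlap with the negative one is tuned through (mu,
sigma) — minor P(-3,1), partial P(0,2) and significant P(2,1.5) overlap.
150 bags balanced between classes, split 90/30/30, with 3000-7000 instances
per bag and a per-bag witness fraction drawn uniformly below one half, are
the study conditions under which a bag classifier's breakdown as overlap
grows is measured.

The module also generates nested bags (instances grouped into regions) for
the two-level attention model, known-geometry tissue masks for the ROI
oracles, and procedurally textured tile images for contrastive smoke tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mil_models import Bag, NestedBag
from .roi_geometry import SegmentationMask

#: canonical class coding used by all synthetic masks
SYNTH_CLASS_MAP = {
    0: "background",
    1: "urothelium",
    2: "lamina propria",
    3: "muscle",
    4: "blood",
    5: "damage",
}


@dataclass(frozen=True)
class GaussianSpec:
    """An isotropic normal instance distribution P(mu, sigma)."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


#: the three matching class-1 distributions, by degree of overlap with class 0
NEGATIVE_SPEC = GaussianSpec(3.0, 2.5)
OVERLAP_SPECS = {
    "minor": GaussianSpec(-3.0, 1.0),
    "partial": GaussianSpec(0.0, 2.0),
    "significant": GaussianSpec(2.0, 1.5),
}


@dataclass(frozen=True)
class BagSimConfig:
    """Full specification of a synthetic Gaussian bag experiment.

    Defaults are the benchmark's study conditions: 150 bags balanced between
    classes, split 90/30/30 into train/validation/test, bag sizes uniform on
    [3000, 7000], witness fraction per positive bag uniform on
    (0, pos_fraction_max] with pos_fraction_max = 0.5, scalar instances.
    """

    n_bags: int = 150
    class_balance: float = 0.5
    split: tuple[int, int, int] = (90, 30, 30)
    bag_size_range: tuple[int, int] = (3000, 7000)
    pos_fraction_max: float = 0.5
    neg_spec: GaussianSpec = NEGATIVE_SPEC
    pos_spec: GaussianSpec = OVERLAP_SPECS["partial"]
    label_rule: str = "MIL_1+"
    t: float = 0.5
    dim: int = 1
    seed: int = 0

    def __post_init__(self):
        if sum(self.split) != self.n_bags:
            raise ValueError("split must sum to n_bags")
        if not 0 < self.pos_fraction_max <= 1:
            raise ValueError("pos_fraction_max must be in (0, 1]")
        if self.label_rule not in ("MIL_1+", "MIL_t+"):
            raise ValueError(f"unknown label rule {self.label_rule!r}")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")


def draw_instances(spec: GaussianSpec, n: int, dim: int,
                   rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. draws from P(mu, sigma), per-dimension independent."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return rng.normal(spec.mu, spec.sigma, size=(n, dim))


def make_bag(config: BagSimConfig, is_positive: bool,
             rng: np.random.Generator, bag_id: str = "bag") -> Bag:
    """One bag: all-negative draws, or a witness fraction of positive draws.

    Positive bags receive ``floor(f * N)`` positive instances (at least one)
    with f uniform on (0, pos_fraction_max]; with the default maximum of 0.5
    every positive bag has strictly fewer positive than negative instances
    almost surely.  Latent per-instance labels are retained for diagnostics.
    """
    lo, hi = config.bag_size_range
    n = int(rng.integers(lo, hi + 1))
    if not is_positive:
        h = draw_instances(config.neg_spec, n, config.dim, rng)
        labels = np.zeros(n, dtype=np.int64)
    else:
        f = rng.uniform(0.0, config.pos_fraction_max)
        n_pos = max(1, int(np.floor(f * n)))
        h = np.concatenate(
            [
                draw_instances(config.pos_spec, n_pos, config.dim, rng),
                draw_instances(config.neg_spec, n - n_pos, config.dim, rng),
            ]
        )
        labels = np.concatenate(
            [np.ones(n_pos, dtype=np.int64), np.zeros(n - n_pos, dtype=np.int64)]
        )
        perm = rng.permutation(n)
        h, labels = h[perm], labels[perm]
    y = label_bag(labels, config.label_rule, config.t)
    return Bag(H=h, label=y, bag_id=bag_id, instance_labels=labels)


def label_bag(instance_labels: np.ndarray, rule: str, t: float = 0.5) -> int:
    """Weak bag label from latent instance labels.

    ``MIL_1+``: positive iff at least one positive instance (the standard
    MIL convention).  ``MIL_t+``: positive iff the positive fraction strictly
    exceeds ``t``.
    """
    instance_labels = np.asarray(instance_labels)
    if rule == "MIL_1+":
        return int(instance_labels.sum() >= 1)
    if rule == "MIL_t+":
        if instance_labels.size == 0:
            return 0
        return int(instance_labels.mean() > t)
    raise ValueError(f"unknown label rule {rule!r}")


def _stratified_split(bags: list[Bag], split: tuple[int, int, int],
                      rng: np.random.Generator) -> tuple[list[Bag], list[Bag], list[Bag]]:
    pos = [b for b in bags if b.label == 1]
    neg = [b for b in bags if b.label == 0]
    rng.shuffle(pos)
    rng.shuffle(neg)
    n = len(bags)
    out: list[list[Bag]] = [[], [], []]
    # allocate each class proportionally to the split sizes, largest remainder
    for group in (pos, neg):
        quotas = [s * len(group) / n for s in split]
        counts = [int(np.floor(q)) for q in quotas]
        rem = len(group) - sum(counts)
        order = np.argsort([c - q for c, q in zip(counts, quotas)])
        for i in order[:rem]:
            counts[i] += 1
        start = 0
        for i, c in enumerate(counts):
            out[i].extend(group[start:start + c])
            start += c
    for part in out:
        rng.shuffle(part)
    return out[0], out[1], out[2]


def make_dataset(config: BagSimConfig) -> tuple[list[Bag], list[Bag], list[Bag]]:
    """Generate the full bag dataset and its stratified train/val/test split."""
    rng = np.random.default_rng(config.seed)
    n_pos = int(round(config.n_bags * config.class_balance))
    if n_pos == 0 or n_pos == config.n_bags:
        raise ValueError("class balance infeasible for n_bags")
    flags = [True] * n_pos + [False] * (config.n_bags - n_pos)
    bags = [
        make_bag(config, flag, rng, bag_id=f"bag{i:04d}")
        for i, flag in enumerate(flags)
    ]
    return _stratified_split(bags, config.split, rng)


def make_nested_dataset(config: BagSimConfig,
                        regions_per_bag_range: tuple[int, int] = (2, 6),
                        pos_region_concentration: float = 1.0,
                        ) -> tuple[list[NestedBag], list[NestedBag], list[NestedBag]]:
    """Nested bags: instances partitioned into K regions with localized signal.

    Each flat bag's instances are split into K regions (K uniform on the given
    range).  In positive bags a fraction ``pos_region_concentration`` of the
    positive instances is concentrated into a single randomly chosen region,
    creating region-level signal for the two-level attention model; the rest
    are spread uniformly.
    """
    lo, hi = regions_per_bag_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid regions_per_bag_range")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x4E455354]))
    splits = make_dataset(config)
    out = []
    for part in splits:
        nested_part = []
        for bag in part:
            n = bag.H.shape[0]
            k = int(rng.integers(lo, hi + 1))
            assign = rng.integers(0, k, size=n)
            pos_idx = np.flatnonzero(bag.instance_labels == 1)
            if pos_idx.size and pos_region_concentration > 0:
                target = int(rng.integers(0, k))
                n_conc = int(round(pos_region_concentration * pos_idx.size))
                conc = rng.choice(pos_idx, size=n_conc, replace=False)
                assign[conc] = target
            # every region non-empty: reassign empties from the largest region
            for region in range(k):
                if not (assign == region).any():
                    donor = np.bincount(assign, minlength=k).argmax()
                    assign[np.flatnonzero(assign == donor)[0]] = region
            regions = [bag.H[assign == region] for region in range(k)]
            nested_part.append(
                NestedBag(
                    regions=regions,
                    label=bag.label,
                    bag_id=bag.bag_id,
                    region_instance_labels=[
                        bag.instance_labels[assign == region] for region in range(k)
                    ],
                )
            )
        out.append(nested_part)
    return out[0], out[1], out[2]


# ---------------------------------------------------------------------------
# synthetic tissue masks (fixtures with analytically known ROI geometry)


def synth_tissue_mask(layout: str, size: int, pixel_size_um: float,
                      rng: np.random.Generator | None = None) -> SegmentationMask:
    """Known-geometry tissue masks for exercising the ROI operations.

    ``halfplane``: urothelium on the top half, lamina propria on the bottom —
    the BORDER band around the interface is analytic.  ``ribbon``: a
    urothelium band over lamina propria with muscle below, all one section —
    FRONT is non-empty wherever muscle is within the dilation radius.
    ``two-sections``: two tissue blobs separated by background, muscle only in
    the second — FRONT must be empty in the muscle-free section.
    """
    if size > 512:
        raise ValueError("synthetic masks are capped at 512 px for test speed")
    labels = np.zeros((size, size), dtype=np.uint8)
    if layout == "halfplane":
        labels[: size // 2, :] = 1
        labels[size // 2:, :] = 2
    elif layout == "ribbon":
        third = size // 3
        labels[:third, :] = 1
        labels[third: 2 * third, :] = 2
        labels[2 * third:, :] = 3
    elif layout == "two-sections":
        gap = max(4, size // 8)
        half = (size - gap) // 2
        # section A (left): urothelium over lamina propria, no muscle
        labels[: size // 2, :half] = 1
        labels[size // 2:, :half] = 2
        # section B (right): urothelium / lamina propria / muscle
        third = size // 3
        labels[:third, half + gap:] = 1
        labels[third: 2 * third, half + gap:] = 2
        labels[2 * third:, half + gap:] = 3
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return SegmentationMask(labels, dict(SYNTH_CLASS_MAP), pixel_size_um)


def random_tissue_mask(size: int, pixel_size_um: float,
                       rng: np.random.Generator) -> SegmentationMask:
    """Random blobby multi-class mask for oracle-equivalence property tests."""
    labels = np.zeros((size, size), dtype=np.uint8)
    n_blobs = int(rng.integers(2, 7))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_blobs):
        cls = int(rng.integers(1, 6))
        cy, cx = rng.integers(0, size, size=2)
        radius = int(rng.integers(size // 8, size // 3))
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        labels[blob] = cls
    return SegmentationMask(labels, dict(SYNTH_CLASS_MAP), pixel_size_um)


# ---------------------------------------------------------------------------
# bag persistence (HDF5 schema shared with the MIL stage)


def save_bags(path, splits: dict[str, list], config: BagSimConfig | None = None) -> None:
    """Write bag splits to HDF5: per split, flat instance matrix plus per-row
    bag/region indices and per-bag labels; the generating config is embedded
    as a YAML attribute."""
    import h5py
    import yaml

    with h5py.File(path, "w") as fh:
        for split_name, bags in splits.items():
            grp = fh.create_group(split_name)
            flat, bag_idx, region_idx, inst_labels = [], [], [], []
            bag_ids, bag_labels = [], []
            for i, bag in enumerate(bags):
                regions = bag.regions if isinstance(bag, NestedBag) else [bag.H]
                inst = (
                    bag.region_instance_labels
                    if isinstance(bag, NestedBag) and bag.region_instance_labels
                    else None
                )
                for k, region in enumerate(regions):
                    flat.append(region)
                    bag_idx.append(np.full(region.shape[0], i, dtype=np.int64))
                    region_idx.append(np.full(region.shape[0], k, dtype=np.int64))
                    if inst is not None:
                        inst_labels.append(inst[k])
                if not isinstance(bag, NestedBag) and bag.instance_labels is not None:
                    inst_labels.append(bag.instance_labels)
                bag_ids.append(bag.bag_id)
                bag_labels.append(bag.label)
            grp.create_dataset(
                "embeddings", data=np.concatenate(flat).astype(np.float32)
            )
            grp.create_dataset("bag_index", data=np.concatenate(bag_idx))
            grp.create_dataset("region_id", data=np.concatenate(region_idx))
            if inst_labels:
                grp.create_dataset(
                    "instance_label", data=np.concatenate(inst_labels)
                )
            grp.create_dataset(
                "bag_id", data=np.asarray(bag_ids, dtype=h5py.string_dtype())
            )
            grp.create_dataset("bag_label", data=np.asarray(bag_labels, dtype=np.int64))
        if config is not None:
            fh.attrs["config_yaml"] = yaml.safe_dump(
                {
                    **{
                        k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in config.__dict__.items()
                        if not isinstance(v, GaussianSpec)
                    },
                    "neg_spec": [config.neg_spec.mu, config.neg_spec.sigma],
                    "pos_spec": [config.pos_spec.mu, config.pos_spec.sigma],
                }
            )


def load_bags(path, nested: bool = False) -> dict[str, list]:
    """Read bag splits written by :func:`save_bags`."""
    import h5py

    out: dict[str, list] = {}
    with h5py.File(path, "r") as fh:
        for split_name, grp in fh.items():
            emb = grp["embeddings"][:].astype(np.float64)
            bag_idx = grp["bag_index"][:]
            region_idx = grp["region_id"][:]
            bag_ids = [s.decode() for s in grp["bag_id"][:]]
            bag_labels = grp["bag_label"][:]
            inst = grp["instance_label"][:] if "instance_label" in grp else None
            bags = []
            for i, (bid, y) in enumerate(zip(bag_ids, bag_labels)):
                sel = bag_idx == i
                if nested:
                    regions = [
                        emb[sel & (region_idx == k)]
                        for k in np.unique(region_idx[sel])
                    ]
                    bags.append(NestedBag(regions, int(y), bid))
                else:
                    bags.append(
                        Bag(
                            emb[sel], int(y), bid,
                            None if inst is None else inst[sel],
                        )
                    )
            out[split_name] = bags
    return out


# ---------------------------------------------------------------------------
# synthetic tiles (contrastive smoke-test fixture)


def synth_tiles(n_per_class: int, rng: np.random.Generator,
                n_classes: int = 2, size: int = 224,
                noise: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Procedurally textured RGB tiles separable by simple statistics.

    Each class has a disjoint base-intensity range plus a class-specific
    sinusoidal grating; pixel noise is additive Gaussian.  Returns
    ``(images, labels)`` with images uint8 of shape (n, size, size, 3).
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    images, labels = [], []
    yy, xx = np.mgrid[0:size, 0:size]
    for cls in range(n_classes):
        base_lo = 30 + cls * (200 // n_classes)
        base_hi = base_lo + max(1, 200 // n_classes - 40)
        freq = 2 * np.pi * (cls + 1) * 4 / size
        grating = 15.0 * np.sin(freq * xx + 0.5 * freq * yy)
        for _ in range(n_per_class):
            base = rng.uniform(base_lo, base_hi)
            img = base + grating + rng.normal(0, noise, size=(size, size))
            img = np.clip(img, 0, 255)
            images.append(np.repeat(img[:, :, None], 3, axis=2).astype(np.uint8))
            labels.append(cls)
    if not images:
        return (np.zeros((0, size, size, 3), dtype=np.uint8),
                np.zeros(0, dtype=np.int64))
    return np.stack(images), np.asarray(labels, dtype=np.int64)
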