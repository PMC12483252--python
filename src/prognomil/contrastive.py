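"""Contrastive tile-feature learning: NT-Xent, supervised contrastive and
multi-task objectives, augmentation, pretraining and tile embedding.

Given a batch of N images, two augmented views of each are encoded by the
feature extractor G and projected by an MLP head F into l2-normalized
vectors z.  The normalized temperature-scaled cross-entropy (NT-Xent) loss
for the 2N projections is

    Lc = -(1/2N) sum_i log[ exp(sim(z_i, z_i') / tau)
                            / sum_{j != i} exp(sim(z_i, z_j) / tau) ]

where z_i' is the view paired with z_i and tau a temperature (0.07 by
default).  The supervised variant replaces the single positive with the set
P(i) of same-label projections, averaging the log-ratio over P(i) per anchor
and over the 2N anchors.  (The printed form of the supervised loss carries
z_i' in the numerator; this implementation follows the P(i)-sum semantics,
i.e. the positive z_p appears in the numerator — see docs/methods.md.)
The multi-task objective is the weighted sum alpha_c * Lc + alpha_ce * Lce
with a cross-entropy classification head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from . import nn
from .nn import Tensor

NEG_INF = -1e9


@dataclass
class ContrastiveConfig:
    """Training recipe for contrastive pretraining."""

    tau: float = 0.07
    alpha_c: float = 1.0
    alpha_ce: float = 0.5
    batch_size: int = 128
    epochs: int = 10
    learning_rate: float = 1e-4
    augmentation: str = "default"
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.alpha_c < 0 or self.alpha_ce < 0:
            raise ValueError("loss scale factors must be non-negative")


@dataclass
class ProjectionBatch:
    """2N paired projection vectors: rows [z_1..z_N, z'_1..z'_N].

    ``labels`` (length N, shared within a pair) are required by the
    supervised loss.  Rows are l2-normalized on construction.
    """

    z1: np.ndarray
    z2: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.z1 = l2_normalize(np.atleast_2d(np.asarray(self.z1, dtype=np.float64)))
        self.z2 = l2_normalize(np.atleast_2d(np.asarray(self.z2, dtype=np.float64)))
        if self.z1.shape != self.z2.shape:
            raise ValueError("paired views must have identical shapes")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).reshape(-1)
            if self.labels.size != self.n_pairs:
                raise ValueError("need one label per pair")

    @property
    def n_pairs(self) -> int:
        return self.z1.shape[0]

    @property
    def z(self) -> np.ndarray:
        """All 2N rows, anchors first then their partners."""
        return np.concatenate([self.z1, self.z2], axis=0)

    def partner_index(self) -> np.ndarray:
        n = self.n_pairs
        return np.concatenate([np.arange(n, 2 * n), np.arange(n)])

    def anchor_labels(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("batch carries no labels")
        return np.concatenate([self.labels, self.labels])


def l2_normalize(z: np.ndarray, axis: int = -1) -> np.ndarray:
    norms = np.linalg.norm(z, axis=axis, keepdims=True)
    if (norms == 0).any():
        raise ValueError("cannot l2-normalize a zero vector")
    return z / norms


def cosine_similarity(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """sim(z_i, z_j) = z_i . z_j / (||z_i|| ||z_j||), in [-1, 1]."""
    z_i = np.asarray(z_i, dtype=np.float64).reshape(-1)
    z_j = np.asarray(z_j, dtype=np.float64).reshape(-1)
    ni, nj = np.linalg.norm(z_i), np.linalg.norm(z_j)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(z_i @ z_j / (ni * nj), -1.0, 1.0))


def _masked_log_softmax(z: Tensor, tau: float) -> Tensor:
    """Row-wise log-softmax of the similarity matrix with the diagonal removed."""
    sim = (z @ z.T) * (1.0 / tau)
    n = sim.data.shape[0]
    mask = Tensor(np.where(np.eye(n, dtype=bool), NEG_INF, 0.0))
    sim = sim + mask
    return sim - sim.logsumexp(axis=1, keepdims=True)


def _nt_xent_graph(z: Tensor, partner: np.ndarray, tau: float) -> Tensor:
    logp = _masked_log_softmax(z, tau)
    n2 = z.data.shape[0]
    pick = np.zeros((n2, n2))
    pick[np.arange(n2), partner] = 1.0
    return -(logp * Tensor(pick)).sum() * (1.0 / n2)


def nt_xent_loss(batch: ProjectionBatch, tau: float = 0.07) -> float:
    """NT-Xent loss averaged over all 2N anchors with the 1/(2N) prefactor.

    Self-similarity is excluded from the denominator; a single pair (N = 1)
    has no negatives and yields a loss of exactly zero.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    return float(_nt_xent_graph(Tensor(batch.z), batch.partner_index(), tau).data)


def _supcon_graph(z: Tensor, labels: np.ndarray, tau: float) -> Tensor:
    n2 = z.data.shape[0]
    logp = _masked_log_softmax(z, tau)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    sizes = same.sum(axis=1)
    valid = sizes > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} anchor(s) without same-class partner skipped",
            stacklevel=3,
        )
    if not valid.any():
        raise ValueError("no anchor has a same-class partner")
    weights = np.zeros((n2, n2))
    weights[valid] = same[valid] / sizes[valid, None]
    return -(logp * Tensor(weights)).sum() * (1.0 / n2)


def supcon_loss(batch: ProjectionBatch, tau: float = 0.07) -> float:
    """Supervised contrastive loss with per-anchor averaging over P(i).

    Each anchor's -log softmax ratios are averaged over its positive set
    P(i) = {p != i : y_p = y_i}; the per-anchor terms are then averaged over
    the 2N anchors.  Anchors with empty P(i) are skipped with a warning.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    if batch.labels is None:
        raise ValueError("supervised contrastive loss requires labels")
    return float(
        _supcon_graph(Tensor(batch.z), batch.anchor_labels(), tau).data
    )


def multitask_loss(l_c: float, l_ce: float, alpha_c: float = 1.0,
                   alpha_ce: float = 0.5) -> float:
    """Weighted multi-task sum alpha_c * Lc + alpha_ce * Lce."""
    return alpha_c * l_c + alpha_ce * l_ce


# ---------------------------------------------------------------------------
# augmentation


def augment(image: np.ndarray, policy: str = "default",
            seed: int | np.random.Generator = 0) -> np.ndarray:
    """One stochastic augmented view of an H x W x 3 image.

    The default policy draws a vertical flip, horizontal flip, 90-degree
    rotation, a small affine perturbation (translation/shear up to a few
    percent) and channelwise color jitter.  Deterministic under (policy,
    seed); two draws with different seeds give the two views of a pair.
    ``policy='identity'`` returns the image unchanged.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if policy == "identity":
        return image.copy()
    if policy != "default":
        raise ValueError(f"unknown augmentation policy {policy!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = image.astype(np.float64)
    if rng.random() < 0.5:  # flip (vertical)
        out = out[::-1]
    if rng.random() < 0.5:  # flop (horizontal)
        out = out[:, ::-1]
    k = int(rng.integers(0, 4))  # rotation by multiples of 90 degrees
    out = np.rot90(out, k)
    # small affine: translation and shear
    tform = AffineTransform(
        translation=rng.uniform(-3, 3, size=2),
        shear=rng.uniform(-0.05, 0.05),
    )
    out = warp(out, tform.inverse, mode="reflect", preserve_range=True)
    # color jitter: channelwise brightness/contrast scaling
    gain = rng.uniform(0.9, 1.1, size=3)
    bias = rng.uniform(-10, 10, size=3)
    out = out * gain + bias
    return np.clip(out, 0, 255).astype(image.dtype)


# ---------------------------------------------------------------------------
# encoder contract


class EncoderContract(nn.Module):
    """Feature extractor G, projection head F and classifier head C.

    ``G`` pools the image onto a coarse grid and maps it through an MLP to an
    M-dimensional feature h; ``F`` projects h to the contrastive space (l2
    normalization happens in the loss); ``C`` produces class logits for the
    cross-entropy / multi-task modes.  ``weight_tag`` records the training
    mode that produced the current weights (imagenet-style init is tagged
    ``thetaI``; contrastive/supcon/cross-entropy/multi-task training retag to
    ``thetaC`` / ``thetaSC`` / ``thetaCE`` / ``thetaMULTI``).
    """

    def __init__(self, rng: np.random.Generator, feature_dim: int = 64,
                 projection_dim: int = 32, n_classes: int = 2,
                 pool_grid: int = 8, input_size: int = 224):
        self.pool_grid = pool_grid
        self.input_size = input_size
        in_dim = pool_grid * pool_grid * 3
        self.G = nn.MLP([in_dim, 2 * feature_dim, feature_dim], rng)
        self.F = nn.MLP([feature_dim, feature_dim, projection_dim], rng)
        self.C = nn.MLP([feature_dim, n_classes], rng)
        self.feature_dim = feature_dim
        self.weight_tag = "thetaI"

    # -- preprocessing -------------------------------------------------------
    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """Resize-by-pooling to the coarse grid and scale to roughly [-1, 1]."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        n, h, w, _ = images.shape
        g = self.pool_grid
        # mean-pool onto a g x g grid (h, w need not be multiples of g)
        ys = (np.arange(h) * g // h)
        xs = (np.arange(w) * g // w)
        pooled = np.zeros((n, g, g, 3))
        counts = np.zeros((g, g, 1))
        np.add.at(counts, (ys[:, None], xs[None, :]), 1.0)
        for c in range(3):
            acc = np.zeros((n, g, g))
            np.add.at(acc.transpose(1, 2, 0), (ys[:, None], xs[None, :]),
                      images[..., c].transpose(1, 2, 0))
            pooled[..., c] = acc / counts[..., 0]
        return (pooled.reshape(n, -1) - 127.5) / 127.5

    def features(self, images: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        return self.G(Tensor(self.preprocess(images)), training=training, rng=rng)

    def project(self, h: Tensor) -> Tensor:
        z = self.F(h)
        norms = (z * z).sum(axis=1, keepdims=True) ** 0.5
        return z / norms

    def logits(self, h: Tensor) -> Tensor:
        return self.C(h)


# ---------------------------------------------------------------------------
# pretraining


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = logits - logits.logsumexp(axis=1, keepdims=True)
    n, c = logits.data.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


PRETRAIN_TAGS = {
    "unsup": "thetaC",
    "supcon": "thetaSC",
    "ce": "thetaCE",
    "multitask": "thetaMULTI",
}


def pretrain(encoder: EncoderContract, tiles: np.ndarray,
             labels: np.ndarray | None = None, mode: str = "unsup",
             config: ContrastiveConfig | None = None) -> dict:
    """Train the encoder with the requested contrastive / supervised objective.

    Modes: ``unsup`` (NT-Xent), ``supcon`` (supervised contrastive), ``ce``
    (cross-entropy on the classifier head) and ``multitask``
    (alpha_c * NT-Xent + alpha_ce * cross-entropy).  Labeled modes require
    per-tile labels.  Returns a history dict with the per-epoch mean loss;
    the encoder is updated in place and retagged.
    """
    config = config if config is not None else ContrastiveConfig()
    if mode not in PRETRAIN_TAGS:
        raise ValueError(f"unknown pretraining mode {mode!r}")
    if mode in ("supcon", "ce", "multitask") and labels is None:
        raise ValueError(f"mode {mode!r} requires tile labels")
    tiles = np.asarray(tiles)
    n = tiles.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    aug_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA0]))
    opt = nn.Adam(encoder.parameters(), lr=config.learning_rate)
    history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size < 2:
                continue
            v1 = np.stack([augment(tiles[i], seed=aug_rng) for i in idx])
            v2 = np.stack([augment(tiles[i], seed=aug_rng) for i in idx])
            batch_labels = labels[idx] if labels is not None else None
            loss = _pretrain_step_loss(encoder, v1, v2, batch_labels, mode,
                                       config, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
    if config.epochs > 0:
        encoder.weight_tag = PRETRAIN_TAGS[mode]
    return {"loss": history, "weight_tag": encoder.weight_tag}


def _pretrain_step_loss(encoder, v1, v2, batch_labels, mode, config, rng):
    both = np.concatenate([v1, v2], axis=0)
    h = encoder.features(both, training=True, rng=rng)
    if mode == "ce":
        return _cross_entropy(
            encoder.logits(h), np.concatenate([batch_labels, batch_labels])
        )
    z = encoder.project(h)
    n = v1.shape[0]
    partner = np.concatenate([np.arange(n, 2 * n), np.arange(n)])
    if mode == "unsup":
        return _nt_xent_graph(z, partner, config.tau)
    if mode == "supcon":
        anchor_labels = np.concatenate([batch_labels, batch_labels])
        return _supcon_graph(z, anchor_labels, config.tau)
    # multitask
    l_c = _nt_xent_graph(z, partner, config.tau)
    l_ce = _cross_entropy(
        encoder.logits(h), np.concatenate([batch_labels, batch_labels])
    )
    return l_c * config.alpha_c + l_ce * config.alpha_ce


def embed_tiles(encoder: EncoderContract, tiles: np.ndarray,
                tile_ids: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Deterministic inference-mode embeddings, one M-vector per tile."""
    tiles = np.asarray(tiles)
    if tile_ids is None:
        tile_ids = [f"tile{i:06d}" for i in range(tiles.shape[0])]
    if len(tile_ids) != tiles.shape[0]:
        raise ValueError("tile_ids length must match tile count")
    h = encoder.features(tiles, training=False)
    return list(tile_ids), h.data.astype(np.float32)


def save_embeddings(path, tile_ids: list[str], embeddings: np.ndarray,
                    weight_tag: str, config_hash: str = "") -> None:
    """Persist embeddings with provenance to HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("embeddings", data=np.asarray(embeddings, dtype=np.float32))
        fh.create_dataset(
            "tile_ids", data=np.asarray(tile_ids, dtype=h5py.string_dtype())
        )
        fh.attrs["weight_tag"] = weight_tag
        fh.attrs["M"] = embeddings.shape[1]
        fh.attrs["config_hash"] = config_hash
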