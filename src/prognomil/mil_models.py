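"""Bag-level classifiers: pooling baselines, gated-attention MIL, nested MIL.

A bag H = {h_l, l=1..L} of instance embeddings carries one weak label y per
patient/slide.  The gated attention mechanism scores each instance as

    a_i = softmax_i( w^T ( tanh(V h_i) * sigmoid(U h_i) ) )

and the bag embedding A.H = sum_i a_i h_i is classified by an MLP.  The
nested variant (NMIA) applies the same mechanism twice: tile-level attention
pools each region's tiles into a region embedding, region-level attention
pools regions into the slide embedding.  w, V and U live in an attention
space of width ``n_att`` (4096 in the full-scale configuration; much smaller
for the scalar synthetic benchmark).

The focal Tversky loss used for training weighs false negatives via alpha
and focuses on hard examples via the 1/gamma exponent:

    TI_c = TP_c / (TP_c + alpha * FN_c + (1 - alpha) * FP_c)
    FTL  = sum_c (1 - TI_c)^(1/gamma)

computed on soft counts, so it is exactly zero at perfect one-hot
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


# ---------------------------------------------------------------------------
# containers


@dataclass
class Bag:
    """L instance embeddings (L x M) with one weak binary label."""

    H: np.ndarray
    label: int
    bag_id: str = "bag"
    instance_labels: np.ndarray | None = None
    tile_ids: list[str] | None = None

    def __post_init__(self):
        self.H = np.atleast_2d(np.asarray(self.H, dtype=np.float64))
        if self.H.shape[0] < 1:
            raise ValueError("a bag needs at least one instance")

    @property
    def n_instances(self) -> int:
        return self.H.shape[0]

    @property
    def dim(self) -> int:
        return self.H.shape[1]


@dataclass
class NestedBag:
    """K non-empty regions of tile embeddings with one weak bag label."""

    regions: list[np.ndarray]
    label: int
    bag_id: str = "bag"
    region_instance_labels: list[np.ndarray] | None = None

    def __post_init__(self):
        if len(self.regions) < 1:
            raise ValueError("a nested bag needs at least one region")
        self.regions = [np.atleast_2d(np.asarray(r, dtype=np.float64)) for r in self.regions]
        if any(r.shape[0] == 0 for r in self.regions):
            raise ValueError("every region must be non-empty")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def flatten(self) -> Bag:
        return Bag(np.concatenate(self.regions, axis=0), self.label, self.bag_id)


@dataclass
class FTLConfig:
    """Focal Tversky loss parameters (defaults from the hyperparameter search)."""

    alpha: float = 0.9
    gamma: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


# ---------------------------------------------------------------------------
# gated attention


class GatedAttention(nn.Module):
    """The gated attention block: parameters w (n_att,1), V and U (n_att x M)."""

    def __init__(self, m_dim: int, n_att: int, rng: np.random.Generator):
        self.V = nn.Linear(m_dim, n_att, rng)
        self.U = nn.Linear(m_dim, n_att, rng)
        self.w = nn.Linear(n_att, 1, rng)
        self.n_att = n_att

    def scores(self, H: Tensor) -> Tensor:
        """Unnormalized attention scores, one per instance (L x 1)."""
        return self.w((self.V(H)).tanh() * (self.U(H)).sigmoid())

    def __call__(self, H: Tensor) -> Tensor:
        """Softmax-normalized attention over the L instances (L,)."""
        return self.scores(H).reshape(-1).softmax(axis=-1)


def gated_attention(H: np.ndarray, params: GatedAttention) -> np.ndarray:
    """Attention weights for a bag; non-negative and summing to one."""
    H = np.atleast_2d(H)
    return params(Tensor(H)).data


def attend_pool(H, a) -> Tensor:
    """Attention-weighted bag embedding A.H (a convex combination of rows)."""
    H = Tensor.as_tensor(H)
    a = Tensor.as_tensor(a)
    return a.reshape(1, -1) @ H


def mean_pool(H: np.ndarray) -> np.ndarray:
    """Elementwise mean over instances."""
    return np.atleast_2d(H).mean(axis=0)


def max_pool(H: np.ndarray) -> np.ndarray:
    """Elementwise max over instances."""
    return np.atleast_2d(H).max(axis=0)


def majority_vote(instance_probs: np.ndarray, threshold: float = 0.5) -> int:
    """Bag positive iff a strict majority of instances scores above threshold.

    Exact ties are resolved to the negative class.
    """
    p = np.asarray(instance_probs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("instance probabilities must lie in [0, 1]")
    return int((p > threshold).sum() > p.size / 2)


# ---------------------------------------------------------------------------
# models


class AbMIL(nn.Module):
    """Attention-based MIL: instance MLP -> gated attention -> classifier.

    ``embed_sizes`` maps raw instance features into the embedding space the
    attention operates on (identity when empty); ``classifier_sizes`` are the
    hidden widths of the bag-level MLP head, which ends in a single logit.
    ``n_clinical`` widens the classifier input for concatenated clinical
    codes.
    """

    def __init__(self, in_dim: int, rng: np.random.Generator,
                 embed_sizes: tuple[int, ...] = (64, 64),
                 n_att: int = 64,
                 classifier_sizes: tuple[int, ...] = (64, 32),
                 dropout: float = 0.2,
                 n_clinical: int = 0):
        sizes = (in_dim, *embed_sizes)
        self.embed = nn.MLP(list(sizes), rng, dropout=0.0) if embed_sizes else None
        m_dim = embed_sizes[-1] if embed_sizes else in_dim
        self.attention = GatedAttention(m_dim, n_att, rng)
        self.classifier = nn.MLP(
            [m_dim + n_clinical, *classifier_sizes, 1], rng, dropout=dropout
        )
        self.m_dim = m_dim
        self.n_clinical = n_clinical

    def _embed(self, H: Tensor, training: bool, rng) -> Tensor:
        if self.embed is None:
            return H
        # hidden activations with ReLU on every embedding layer
        x = H
        for layer in self.embed.layers:
            x = layer(x).relu()
        return x

    def forward(self, H: np.ndarray, clinical: np.ndarray | None = None,
                training: bool = False,
                rng: np.random.Generator | None = None,
                dropout_rate: float | None = None) -> tuple[Tensor, np.ndarray]:
        """Bag probability and attention weights for one bag (L x in_dim)."""
        H = np.atleast_2d(np.asarray(H, dtype=np.float64))
        if H.shape[0] < 1:
            raise ValueError("empty bag")
        if dropout_rate is not None:
            old = self.classifier.dropout.rate
            self.classifier.dropout.rate = dropout_rate
        try:
            x = self._embed(Tensor(H), training, rng)
            a = self.attention(x)
            pooled = attend_pool(x, a)
            if self.n_clinical:
                if clinical is None:
                    raise ValueError("model expects a clinical vector")
                pooled = fuse_clinical(pooled, np.asarray(clinical, dtype=np.float64))
            logit = self.classifier(pooled, training=training, rng=rng)
            prob = logit.reshape(()).sigmoid()
        finally:
            if dropout_rate is not None:
                self.classifier.dropout.rate = old
        return prob, a.data


    def forward_many(self, H_list: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
        """Vectorized inference over many bags (no dropout, no graph).

        Concatenates all instances, runs the embedding / attention maths once
        and resolves the per-bag softmax with segmented reductions.  Matches
        :meth:`forward` in inference mode; the equivalence is covered by the
        test suite.
        """
        if self.n_clinical:
            raise ValueError("vectorized path does not support clinical fusion")
        sizes = np.asarray([np.atleast_2d(h).shape[0] for h in H_list])
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        seg = np.repeat(np.arange(len(H_list)), sizes)
        f32 = np.float32  # single precision for the wide instance sweep
        X = np.concatenate([np.atleast_2d(h) for h in H_list]).astype(f32)
        if self.embed is not None:
            for layer in self.embed.layers:
                X = np.maximum(X @ layer.W.data.astype(f32) + layer.b.data.astype(f32), 0.0)
        att = self.attention
        gate = np.tanh(X @ att.V.W.data.astype(f32) + att.V.b.data.astype(f32))
        gate *= _sigmoid(X @ att.U.W.data.astype(f32) + att.U.b.data.astype(f32))
        scores = (gate @ att.w.W.data.astype(f32) + att.w.b.data.astype(f32)).ravel()
        scores = scores.astype(np.float64)
        m = np.maximum.reduceat(scores, offsets)
        e = np.exp(scores - m[seg])
        denom = np.add.reduceat(e, offsets)
        a = e / denom[seg]
        pooled = np.add.reduceat(a[:, None] * X, offsets, axis=0)
        h = pooled
        for layer in self.classifier.layers[:-1]:
            h = np.maximum(h @ layer.W.data + layer.b.data, 0.0)
        last = self.classifier.layers[-1]
        logits = (h @ last.W.data + last.b.data).ravel()
        probs = _sigmoid(logits)
        attn = [a[o:o + s] for o, s in zip(offsets, sizes)]
        return probs, attn


def _sigmoid(x: np.ndarray) -> np.ndarray:
    z = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + z), z / (1.0 + z))


class NMIA(nn.Module):
    """Nested MIL with attention: tiles -> regions -> slide.

    Tile-level gated attention pools each region's tile embeddings into a
    region embedding; a separate region-level gated attention pools region
    embeddings into the slide embedding fed to the classifier.
    """

    def __init__(self, in_dim: int, rng: np.random.Generator,
                 embed_sizes: tuple[int, ...] = (64, 64),
                 n_att: int = 64,
                 classifier_sizes: tuple[int, ...] = (64, 32),
                 dropout: float = 0.2,
                 n_clinical: int = 0):
        sizes = (in_dim, *embed_sizes)
        self.embed = nn.MLP(list(sizes), rng, dropout=0.0) if embed_sizes else None
        m_dim = embed_sizes[-1] if embed_sizes else in_dim
        self.tile_attention = GatedAttention(m_dim, n_att, rng)
        self.region_attention = GatedAttention(m_dim, n_att, rng)
        self.classifier = nn.MLP(
            [m_dim + n_clinical, *classifier_sizes, 1], rng, dropout=dropout
        )
        self.m_dim = m_dim
        self.n_clinical = n_clinical

    def _embed(self, H: Tensor) -> Tensor:
        if self.embed is None:
            return H
        x = H
        for layer in self.embed.layers:
            x = layer(x).relu()
        return x

    def forward(self, nested: NestedBag, clinical: np.ndarray | None = None,
                training: bool = False,
                rng: np.random.Generator | None = None,
                dropout_rate: float | None = None,
                ) -> tuple[Tensor, np.ndarray, list[np.ndarray]]:
        """Slide probability, region attention and per-region tile attention."""
        if dropout_rate is not None:
            old = self.classifier.dropout.rate
            self.classifier.dropout.rate = dropout_rate
        try:
            region_embeddings = []
            tile_attentions = []
            for region in nested.regions:
                x = self._embed(Tensor(np.atleast_2d(region)))
                a = self.tile_attention(x)
                region_embeddings.append(attend_pool(x, a))
                tile_attentions.append(a.data)
            R = nn.concat(region_embeddings, axis=0)  # K x m_dim
            a_region = self.region_attention(R)
            pooled = attend_pool(R, a_region)
            if self.n_clinical:
                if clinical is None:
                    raise ValueError("model expects a clinical vector")
                pooled = fuse_clinical(pooled, np.asarray(clinical, dtype=np.float64))
            logit = self.classifier(pooled, training=training, rng=rng)
            prob = logit.reshape(()).sigmoid()
        finally:
            if dropout_rate is not None:
                self.classifier.dropout.rate = old
        return prob, a_region.data, tile_attentions


class PooledMIL(nn.Module):
    """Baseline aggregator: mean or max pooling of instances, then classify."""

    def __init__(self, in_dim: int, rng: np.random.Generator, how: str = "mean",
                 classifier_sizes: tuple[int, ...] = (64, 32), dropout: float = 0.2):
        if how not in ("mean", "max"):
            raise ValueError("how must be 'mean' or 'max'")
        self.how = how
        self.classifier = nn.MLP([in_dim, *classifier_sizes, 1], rng, dropout=dropout)

    def forward(self, H: np.ndarray, clinical=None, training: bool = False,
                rng: np.random.Generator | None = None,
                dropout_rate: float | None = None) -> tuple[Tensor, np.ndarray]:
        H = Tensor(np.atleast_2d(np.asarray(H, dtype=np.float64)))
        pooled = H.mean(axis=0, keepdims=True) if self.how == "mean" else H.max(
            axis=0, keepdims=True
        )
        logit = self.classifier(pooled, training=training, rng=rng)
        L = H.data.shape[0]
        return logit.reshape(()).sigmoid(), np.full(L, 1.0 / L)


def abmil_forward(bag: Bag, model: AbMIL,
                  clinical: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Inference-mode AbMIL forward: probability in [0,1] plus attention."""
    prob, a = model.forward(bag.H, clinical=clinical, training=False)
    return float(prob.data), a


def nmia_forward(nested: NestedBag, model: NMIA,
                 clinical: np.ndarray | None = None,
                 ) -> tuple[float, np.ndarray, list[np.ndarray]]:
    """Inference-mode NMIA forward: probability, region and tile attention."""
    prob, a_region, a_tiles = model.forward(nested, clinical=clinical, training=False)
    return float(prob.data), a_region, a_tiles


# ---------------------------------------------------------------------------
# clinical variables


#: default integer coding schema for the eight clinical variables
DEFAULT_CLINICAL_SCHEMA: dict[str, dict[str, int]] = {
    "gender": {"male": 0, "female": 1},
    "age": {},  # numeric, passed through as integer years
    "smoking": {"non-smoker": 0, "smoker": 1, "ex-smoker": 2},
    "grade": {"low": 0, "high": 1},
    "stage": {"Ta": 0, "T1": 1, "T2": 2},
    "cis": {"no": 0, "yes": 1},
    "size": {"<3cm": 0, ">=3cm": 1},
    "focality": {"unifocal": 0, "multifocal": 1},
}

MISSING_CODE = -1


@dataclass
class ClinicalVector:
    """Integer-coded clinical variables in schema order."""

    h_var: np.ndarray
    schema: dict[str, dict[str, int]]

    def __post_init__(self):
        self.h_var = np.asarray(self.h_var, dtype=np.int64)
        if self.h_var.size != len(self.schema):
            raise ValueError("h_var length must equal schema size")


class ClinicalValidationError(ValueError):
    pass


def encode_clinical(record: dict, schema: dict[str, dict[str, int]] | None = None,
                    ) -> ClinicalVector:
    """Integer-code a clinical record (e.g. 0 for non-smoker, 1 for smoker).

    Missing values are coded with the sentinel -1.  Categories not present in
    the schema raise a validation error naming the offending field.  Numeric
    variables (empty category map) are cast to int directly.
    """
    schema = schema if schema is not None else DEFAULT_CLINICAL_SCHEMA
    codes = []
    for var, categories in schema.items():
        value = record.get(var)
        if value is None:
            codes.append(MISSING_CODE)
        elif not categories:
            codes.append(int(value))
        else:
            if value not in categories:
                raise ClinicalValidationError(
                    f"value {value!r} for field {var!r} is not in the schema"
                )
            codes.append(categories[value])
    return ClinicalVector(np.asarray(codes), schema)


def fuse_clinical(bag_embedding, h_var: np.ndarray) -> Tensor:
    """Concatenate clinical codes onto the bag embedding: [A.H, h_var]."""
    bag_embedding = Tensor.as_tensor(bag_embedding)
    h_var = np.asarray(h_var, dtype=np.float64).reshape(1, -1)
    if h_var.size == 0:
        return bag_embedding
    flat = bag_embedding.reshape(1, -1)
    return nn.concat([flat, Tensor(h_var)], axis=1)


# ---------------------------------------------------------------------------
# focal Tversky loss


def _ftl_graph(probs: Tensor, labels: np.ndarray, config: FTLConfig) -> Tensor:
    """Differentiable two-class focal Tversky loss on soft counts."""
    y1 = np.asarray(labels, dtype=np.float64).reshape(-1)
    y0 = 1.0 - y1
    p1 = probs.reshape(-1)
    p0 = 1.0 - p1
    loss_terms = []
    for p, y in ((p1, y1), (p0, y0)):
        yt = Tensor(y)
        tp = (p * yt).sum()
        fn = ((1.0 - p) * yt).sum()
        fp = (p * Tensor(1.0 - y)).sum()
        # vanishing smoothing guards the 0/0 case of a class absent from the
        # batch and predicted absent; it keeps TI = 1 exactly at perfection
        s = 1e-12
        ti = (tp + s) / (tp + config.alpha * fn + (1.0 - config.alpha) * fp + s)
        loss_terms.append((1.0 - ti) ** (1.0 / config.gamma))
    return loss_terms[0] + loss_terms[1]


def focal_tversky_loss(probs: np.ndarray, labels: np.ndarray,
                       config: FTLConfig | None = None) -> float:
    """Focal Tversky loss of class-1 probabilities against binary labels.

    Soft counts per class c: TP_c, FN_c, FP_c; Tversky index
    TI_c = TP_c / (TP_c + alpha*FN_c + (1-alpha)*FP_c); the loss is
    sum_c (1 - TI_c)^(1/gamma).  Exactly zero when predictions equal the
    one-hot labels; reduces to the plain Tversky loss at gamma = 1.
    """
    config = config if config is not None else FTLConfig()
    p = np.asarray(probs, dtype=np.float64).reshape(-1)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels).reshape(-1)
    if p.shape != y.shape:
        raise ValueError("probs and labels must have matching shapes")
    out = _ftl_graph(Tensor(p), y, config)
    return float(out.data)
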