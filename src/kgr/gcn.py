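"""Relational graph convolution models: R-GCN and CompGCN.

Both models are encoder/decoder link predictors trained full-graph with the
normalized binary cross-entropy loss

    L = -(1 / ((1 + ω) |ε̂|)) Σ_{(h,r,t,y)} [ y log l(s) + (1-y) log(1-l(s)) ]

where ω is the number of negatives per positive, |ε̂| the number of positive
edges, and l the logistic sigmoid.

* **R-GCN** updates node states per relation channel,
  ``x_i ← σ( Σ_r Σ_{j∈N_i^r} (1/c_{i,r}) W_r x_j + W_0 x_i )`` with
  ``c_{i,r} = |N_i^r|``, and decodes triples with DistMult over the encoded
  states.
* **CompGCN** composes neighbor states with relation embeddings,
  ``x_i ← f( Σ_{(j,k)} W_{λ(k)} φ(x_j, y_k) )`` with direction-specific
  weights for original / inverse / self-loop edges, a per-layer relation
  projection ``y_k ← W_rel y_k``, composition φ ∈ {subtraction,
  multiplication, circular correlation}, and a ConvE decoder.

Message passing is evaluated through per-channel row-normalized sparse
adjacency matrices; the test suite verifies it against a dense
block-matrix oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from ._autodiff import Adam, Tensor, spmm
from .core import KnowledgeGraph
from .kge import _sample_negative_indices, score_distmult

__all__ = [
    "RGCNParams",
    "CompGCNParams",
    "ConvEConfig",
    "ConvEDecoder",
    "LossSpec",
    "GCNTrainConfig",
    "GCNModel",
    "circular_correlation",
    "rgcn_forward",
    "rgcn_score",
    "compgcn_forward",
    "conve_score",
    "bce_link_loss",
    "train_gcn",
]

COMPOSITIONS = ("sub", "mult", "corr")


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------


def _adjacency_arrays(
    kg: KnowledgeGraph, include_inverse: bool
) -> tuple[int, list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Raw per-channel (row, col, triple-index) arrays for adjacency builds."""
    n_rel = len(kg.relations)
    n_ch = 2 * n_rel if include_inverse else n_rel
    rows: list[list[int]] = [[] for _ in range(n_ch)]
    cols: list[list[int]] = [[] for _ in range(n_ch)]
    tids: list[list[int]] = [[] for _ in range(n_ch)]
    for tid, (h, r, t) in enumerate(kg.triples):
        hi, ti, ri = kg.entity_index(h), kg.entity_index(t), kg.relation_index(r)
        rows[ri].append(ti)
        cols[ri].append(hi)
        tids[ri].append(tid)
        if include_inverse:
            rows[n_rel + ri].append(hi)
            cols[n_rel + ri].append(ti)
            tids[n_rel + ri].append(tid)
    return (
        n_ch,
        [np.asarray(x, dtype=int) for x in rows],
        [np.asarray(x, dtype=int) for x in cols],
        [np.asarray(x, dtype=int) for x in tids],
    )


def _masked_adjacency(
    n: int,
    arrays: tuple[int, list[np.ndarray], list[np.ndarray], list[np.ndarray]],
    keep: np.ndarray | None = None,
    normalize: bool = True,
) -> list[sp.csr_matrix]:
    """Assemble (optionally edge-masked) normalized adjacency matrices."""
    n_ch, rows, cols, tids = arrays
    mats = []
    for c in range(n_ch):
        r, co = rows[c], cols[c]
        if keep is not None and r.size:
            m = keep[tids[c]]
            r, co = r[m], co[m]
        A = sp.csr_matrix((np.ones(r.size), (r, co)), shape=(n, n))
        if normalize:
            deg = np.asarray(A.sum(axis=1)).ravel()
            inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
            A = sp.csr_matrix(sp.diags(inv) @ A)
        mats.append(A)
    return mats


def _channel_adjacency(
    kg: KnowledgeGraph, include_inverse: bool, normalize: bool = True
) -> list[sp.csr_matrix]:
    """Per-channel sparse adjacency, rows normalized by 1/|N_i^c|.

    Channel c aggregates, for node i, the neighbors reached by relation c:
    original channels collect in-neighbors (messages flow h → t along the
    edge), inverse channels (if enabled) collect out-neighbors.
    """
    n = len(kg.entities)
    n_rel = len(kg.relations)
    n_ch = 2 * n_rel if include_inverse else n_rel
    rows: list[list[int]] = [[] for _ in range(n_ch)]
    cols: list[list[int]] = [[] for _ in range(n_ch)]
    for (h, r, t) in kg.triples:
        hi, ti, ri = kg.entity_index(h), kg.entity_index(t), kg.relation_index(r)
        rows[ri].append(ti)
        cols[ri].append(hi)
        if include_inverse:
            rows[n_rel + ri].append(hi)
            cols[n_rel + ri].append(ti)
    mats = []
    for c in range(n_ch):
        A = sp.csr_matrix(
            (np.ones(len(rows[c])), (rows[c], cols[c])), shape=(n, n)
        )
        if normalize:
            deg = np.asarray(A.sum(axis=1)).ravel()
            inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
            A = sp.diags(inv) @ A
        mats.append(sp.csr_matrix(A))
    return mats


# ---------------------------------------------------------------------------
# R-GCN
# ---------------------------------------------------------------------------


@dataclass
class RGCNParams:
    """Weights of an R-GCN encoder.

    ``rel_weights[l]`` has shape (n_channels, d_l, d_{l+1}); channels are
    the graph's relations, followed by their inverses when
    ``include_inverse`` is set (inverse channels let sources of edges receive
    messages too).  ``self_weights[l]`` is the self-loop matrix W_0.
    """

    rel_weights: list[np.ndarray]
    self_weights: list[np.ndarray]
    include_inverse: bool = True
    activation: str = "relu"  # applied after every layer
    dropout_rate: float = 0.2

    @property
    def num_layers(self) -> int:
        return len(self.self_weights)


def _act(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "tanh":
        return x.tanh()
    if name == "identity":
        return x
    raise ValueError(f"unknown activation {name!r}")


def _rgcn_forward_t(
    A: Sequence[sp.csr_matrix],
    X: Tensor,
    rel_w: Sequence[Tensor],
    self_w: Sequence[Tensor],
    activation: str,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> Tensor:
    h = X
    n_layers = len(self_w)
    for l in range(n_layers):
        agg = h @ self_w[l]
        for c, A_c in enumerate(A):
            if A_c.nnz == 0:
                continue
            agg = agg + spmm(A_c, h) @ _channel_weight(rel_w[l], c)
        h = _act(agg, activation)
        if training and dropout > 0 and rng is not None:
            h = h.dropout(dropout, rng, training=True)
    return h


def _channel_weight(w: Tensor, c: int) -> Tensor:
    d_in, d_out = w.shape[1], w.shape[2]
    base = c * d_in * d_out
    idx = base + np.arange(d_in * d_out).reshape(d_in, d_out)
    return w.take_flat(idx)


def rgcn_forward(
    kg: KnowledgeGraph, params: RGCNParams, node_states: np.ndarray
) -> np.ndarray:
    """Encode node states through the R-GCN layers (evaluation mode).

    Isolated nodes receive only their self-loop term.
    """
    A = _channel_adjacency(kg, params.include_inverse)
    X = Tensor(np.asarray(node_states, float))
    rel_w = [Tensor(w) for w in params.rel_weights]
    self_w = [Tensor(w) for w in params.self_weights]
    return _rgcn_forward_t(A, X, rel_w, self_w, params.activation).data


def rgcn_score(
    node_states: np.ndarray,
    relation_vectors: np.ndarray,
    h: int | np.ndarray,
    r: int | np.ndarray,
    t: int | np.ndarray,
) -> np.ndarray | float:
    """DistMult decoder over encoded node states."""
    s = score_distmult(node_states[h], relation_vectors[r], node_states[t])
    return s


# ---------------------------------------------------------------------------
# CompGCN
# ---------------------------------------------------------------------------


def circular_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular cross-correlation φ(a, b)_i = Σ_j a_j b_{(j+i) mod d}.

    Correlating the unit impulse with any vector returns that vector
    (φ(δ₀, b) = b), which is the identity property the composition relies
    on.  Computed via FFT for vectors, matching the index-arithmetic
    definition exactly up to floating-point rounding.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError("circular correlation requires equal dimensions")
    return np.fft.irfft(np.conj(np.fft.rfft(a, axis=-1)) * np.fft.rfft(b, axis=-1), n=a.shape[-1], axis=-1)


def _corr_matrix_idx(d: int) -> np.ndarray:
    # B[i, j] = y[(i + j) mod d]  so that  corr(a, y) = B @ a ... built as
    # a gather on the flat relation vector
    i = np.arange(d)[:, None]
    j = np.arange(d)[None, :]
    return (i + j) % d


@dataclass
class CompGCNParams:
    """Weights of a CompGCN encoder.

    Per layer: three direction-specific matrices (original, inverse,
    self-loop) and one relation projection.  Relation states cover the
    graph's relations, their inverses, and one self-loop relation, in that
    order.
    """

    dir_weights: list[np.ndarray]  # each (3, d_l, d_{l+1})
    rel_projections: list[np.ndarray]  # each (d_l, d_{l+1})
    composition: str = "corr"
    activation: str = "tanh"
    normalize: bool = True
    feature_dropout: float = 0.1
    layer_dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.composition not in COMPOSITIONS:
            raise ValueError(f"composition must be one of {COMPOSITIONS}")

    @property
    def num_layers(self) -> int:
        return len(self.rel_projections)


def _compose_agg(
    A_c: sp.csr_matrix | None,
    has_nb: np.ndarray,
    X: Tensor,
    y: Tensor,
    composition: str,
    d: int,
) -> Tensor:
    """Aggregate φ(x_j, y) over each node's channel-c neighborhood.

    φ is linear in its first argument for all three compositions, so the
    neighborhood sum/mean commutes with it: compose the aggregated neighbor
    state with the relation vector directly.  ``A_c=None`` means the
    identity (self-loop channel).
    """
    AX = X if A_c is None else spmm(A_c, X)
    if composition == "sub":
        return AX - Tensor(has_nb[:, None]) * y
    if composition == "mult":
        return AX * y
    B = y.take_flat(_corr_matrix_idx(d))  # (d, d)
    return AX @ B.transpose()


def _compgcn_forward_t(
    A: Sequence[sp.csr_matrix],
    X: Tensor,
    Y: Tensor,
    dir_w: Sequence[Tensor],
    rel_proj: Sequence[Tensor],
    composition: str,
    activation: str,
    n_rel: int,
    feature_dropout: float = 0.0,
    layer_dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> tuple[Tensor, Tensor]:
    n = X.shape[0]
    has_nb = [
        (np.asarray(A_c.sum(axis=1)).ravel() > 0).astype(float) for A_c in A
    ]
    h, y = X, Y
    for l in range(len(rel_proj)):
        d_in = h.shape[1]
        if training and feature_dropout > 0 and rng is not None:
            h = h.dropout(feature_dropout, rng, training=True)
        agg = None
        for c, A_c in enumerate(A):
            if A_c.nnz == 0:
                continue
            w = _dir_weight(dir_w[l], 0 if c < n_rel else 1)
            yk = _rel_row(y, c, d_in)
            term = _compose_agg(A_c, has_nb[c], h, yk, composition, d_in) @ w
            agg = term if agg is None else agg + term
        # self-loop: φ(x_i, y_self) with its own weight matrix
        y_self = _rel_row(y, 2 * n_rel, d_in)
        w_self = _dir_weight(dir_w[l], 2)
        self_term = _compose_agg(None, np.ones(n), h, y_self, composition, d_in) @ w_self
        agg = self_term if agg is None else agg + self_term
        h = _act(agg, activation)
        if training and layer_dropout > 0 and rng is not None:
            h = h.dropout(layer_dropout, rng, training=True)
        y = y @ rel_proj[l]
    return h, y


def _dir_weight(w: Tensor, k: int) -> Tensor:
    d_in, d_out = w.shape[1], w.shape[2]
    idx = k * d_in * d_out + np.arange(d_in * d_out).reshape(d_in, d_out)
    return w.take_flat(idx)


def _rel_row(y: Tensor, k: int, d: int) -> Tensor:
    return y.take_flat(k * d + np.arange(d))


def compgcn_forward(
    kg: KnowledgeGraph,
    params: CompGCNParams,
    node_states: np.ndarray,
    rel_states: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode node and relation states through the CompGCN layers.

    ``rel_states`` must hold 2|R| + 1 rows: the graph's relations, their
    inverses, then the self-loop relation.
    """
    n_rel = len(kg.relations)
    if rel_states.shape[0] != 2 * n_rel + 1:
        raise ValueError("rel_states must have 2*|relations| + 1 rows")
    A = _channel_adjacency(kg, include_inverse=True, normalize=params.normalize)
    h, y = _compgcn_forward_t(
        A,
        Tensor(np.asarray(node_states, float)),
        Tensor(np.asarray(rel_states, float)),
        [Tensor(w) for w in params.dir_weights],
        [Tensor(w) for w in params.rel_projections],
        params.composition,
        params.activation,
        n_rel,
    )
    return h.data, y.data


# ---------------------------------------------------------------------------
# ConvE decoder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvEConfig:
    """Shape of the ConvE decoder: 2-D reshape, filters, dropout rates."""

    map_height: int
    map_width: int
    n_filters: int = 8
    kernel: int = 3
    hidden_dropout: float = 0.3
    feature_dropout: float = 0.3

    @staticmethod
    def for_dim(d: int, n_filters: int = 8, kernel: int = 3) -> "ConvEConfig":
        mh = int(math.sqrt(d))
        while d % mh:
            mh -= 1
        return ConvEConfig(map_height=mh, map_width=d // mh, n_filters=n_filters, kernel=kernel)

    def validate(self, d: int) -> None:
        if self.map_height * self.map_width != d:
            raise ValueError(
                f"reshape {self.map_height}x{self.map_width} does not factor dimension {d}"
            )
        if 2 * self.map_height < self.kernel or self.map_width < self.kernel:
            raise ValueError("stacked maps smaller than the convolution kernel")


@dataclass
class ConvEDecoder:
    """Parameters of the ConvE decoder (filters, projection, biases)."""

    cfg: ConvEConfig
    filters: np.ndarray  # (F, k*k)
    filter_bias: np.ndarray  # (F,)
    proj: np.ndarray  # (P*F, d)
    proj_bias: np.ndarray  # (d,)
    bias: float = 0.0


def _im2col_idx(H: int, W: int, k: int) -> np.ndarray:
    oh, ow = H - k + 1, W - k + 1
    pos = (np.arange(oh)[:, None] * W + np.arange(ow)[None, :]).ravel()  # (P,)
    ker = (np.arange(k)[:, None] * W + np.arange(k)[None, :]).ravel()  # (k*k,)
    return pos[:, None] + ker[None, :]  # (P, k*k)


def _conve_score_t(
    h: Tensor,
    r: Tensor,
    t: Tensor,
    filters: Tensor,
    filter_bias: Tensor,
    proj: Tensor,
    proj_bias: Tensor,
    bias: Tensor,
    cfg: ConvEConfig,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> Tensor:
    B = h.shape[0]
    d = h.shape[1]
    cfg.validate(d)
    H, W = 2 * cfg.map_height, cfg.map_width
    stacked = h.concat(r, axis=1)  # (B, 2d) == flattened (H, W) maps
    base = _im2col_idx(H, W, cfg.kernel)  # (P, k*k)
    idx = (np.arange(B)[:, None, None] * (H * W)) + base[None, :, :]
    cols = stacked.take_flat(idx)  # (B, P, k*k)
    fmap = (cols @ filters.transpose()) + filter_bias  # (B, P, F)
    fmap = fmap.relu()
    if training and rng is not None:
        fmap = fmap.dropout(cfg.feature_dropout, rng, training=True)
    P = base.shape[0]
    flat = fmap.reshape(B, P * cfg.n_filters)
    hidden = (flat @ proj) + proj_bias  # (B, d)
    hidden = hidden.relu()
    if training and rng is not None:
        hidden = hidden.dropout(cfg.hidden_dropout, rng, training=True)
    return (hidden * t).sum(axis=-1) + bias


def conve_score(
    node_states: np.ndarray,
    rel_states: np.ndarray,
    h: int | np.ndarray,
    r: int | np.ndarray,
    t: int | np.ndarray,
    decoder: ConvEDecoder,
) -> np.ndarray:
    """ConvE triple score in evaluation mode (dropout disabled).

    Reshapes the head and relation states to 2-D maps, stacks them, applies
    the convolution + ReLU, projects the flattened feature maps back to the
    embedding dimension, and takes the inner product with the tail state.
    """
    h = np.atleast_1d(np.asarray(h))
    r = np.atleast_1d(np.asarray(r))
    t = np.atleast_1d(np.asarray(t))
    out = _conve_score_t(
        Tensor(node_states[h]),
        Tensor(rel_states[r]),
        Tensor(node_states[t]),
        Tensor(decoder.filters),
        Tensor(decoder.filter_bias),
        Tensor(decoder.proj),
        Tensor(decoder.proj_bias),
        Tensor(decoder.bias),
        decoder.cfg,
    )
    return out.data


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossSpec:
    """Normalization constants of the printed cross-entropy loss."""

    neg_ratio: int
    edge_count: int

    def __post_init__(self) -> None:
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")
        if self.edge_count < 1:
            raise ValueError("edge_count must be >= 1")


def bce_link_loss(scores: np.ndarray, labels: np.ndarray, spec: LossSpec) -> float:
    """Normalized binary cross-entropy over scored triples.

    ``-(1/((1+ω)|ε̂|)) Σ [y log l(s) + (1-y) log(1-l(s))]`` with the sigmoid
    clamped away from {0, 1} by 1e-12.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    p = np.clip(1.0 / (1.0 + np.exp(-s)), 1e-12, 1.0 - 1e-12)
    total = np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(-total / ((1 + spec.neg_ratio) * spec.edge_count))


def _bce_loss_t(s_pos: Tensor, s_neg: Tensor, spec: LossSpec) -> Tensor:
    # -log l(s) = softplus(-s);  -log(1 - l(s)) = softplus(s)
    total = (-s_pos).softplus().sum() + s_neg.softplus().sum()
    return total * (1.0 / ((1 + spec.neg_ratio) * spec.edge_count))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GCNTrainConfig:
    """Training configuration shared by R-GCN and CompGCN."""

    learning_rate: float = 0.01
    hidden_dim: int = 100
    num_layers: int = 1
    num_bases: int = 0  # 0 = full per-relation weights; >0 = basis sharing
    epochs: int = 100
    neg_ratio: int = 20
    composition: str = "corr"
    activation: str = "identity"  # linear encoder: best LP default here
    encoder_dropout: float = 0.2
    edge_dropout: float = 0.0
    decoder_l2: float = 0.01
    input_l2: float = 0.0
    feature_dropout: float = 0.1
    layer_dropout: float = 0.3
    conve: ConvEConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim <= 0 or self.num_layers < 1:
            raise ValueError("hidden_dim and num_layers must be positive")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")


class GCNModel:
    """Trained encoder/decoder pair with the uniform plausibility API."""

    def __init__(
        self,
        model: str,
        entities: list[str],
        relations: list[str],
        node_states: np.ndarray,
        rel_vectors: np.ndarray,
        decoder: ConvEDecoder | None = None,
        encoder_params: RGCNParams | CompGCNParams | None = None,
        loss_history: list[float] | None = None,
    ) -> None:
        self.model = model
        self.entities = entities
        self.relations = relations
        self.node_states = node_states
        self.rel_vectors = rel_vectors
        self.decoder = decoder
        self.encoder_params = encoder_params
        self.loss_history = loss_history or []
        self._eidx = {e: i for i, e in enumerate(entities)}
        self._ridx = {r: i for i, r in enumerate(relations)}

    def plausibility_idx(self, h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
        if self.model == "rgcn":
            return np.atleast_1d(rgcn_score(self.node_states, self.rel_vectors, h, r, t))
        assert self.decoder is not None
        return conve_score(self.node_states, self.rel_vectors, h, r, t, self.decoder)

    def plausibility(
        self, heads: Sequence[str], relations: Sequence[str], tails: Sequence[str]
    ) -> np.ndarray:
        h = np.array([self._eidx[x] for x in heads])
        r = np.array([self._ridx[x] for x in relations])
        t = np.array([self._eidx[x] for x in tails])
        return self.plausibility_idx(h, r, t)


def _xavier(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    bound = np.sqrt(6.0 / (shape[-2] + shape[-1]))
    return rng.uniform(-bound, bound, size=shape)


def train_gcn(kg: KnowledgeGraph, model: str, cfg: GCNTrainConfig) -> GCNModel:
    """Full-graph training of an R-GCN or CompGCN link predictor.

    Every epoch re-encodes the graph, draws fresh filtered negatives at
    ``cfg.neg_ratio`` per positive, scores positives and negatives with the
    decoder, and takes one Adam step on the printed cross-entropy loss.
    R-GCN additionally applies dropout 0.2 inside the encoder and an L2
    penalty 0.01 on the decoder's relation vectors; CompGCN uses feature /
    layer dropout 0.1 / 0.3 in the encoder and dropout 0.3 on the ConvE
    hidden and feature maps.  Fully deterministic under ``cfg.seed``.
    """
    if model not in ("rgcn", "compgcn"):
        raise ValueError("model must be 'rgcn' or 'compgcn'")
    if len(kg) == 0:
        raise ValueError("cannot train on an empty graph")
    rng = np.random.default_rng(cfg.seed)
    ents, rels = kg.entities, kg.relations
    n, n_rel, d = len(ents), len(rels), cfg.hidden_dim

    pos = list(kg.triples)
    H = np.array([kg.entity_index(h) for h, _, _ in pos])
    R = np.array([kg.relation_index(r) for _, r, _ in pos])
    T = np.array([kg.entity_index(t) for _, _, t in pos])
    spec = LossSpec(neg_ratio=cfg.neg_ratio, edge_count=len(pos))

    X0 = Tensor.param(_xavier(rng, (n, d)))
    if model == "rgcn":
        A = _channel_adjacency(kg, include_inverse=True)
        n_ch = len(A)
        if cfg.num_bases > 0:
            bases = [Tensor.param(_xavier(rng, (cfg.num_bases, d, d))) for _ in range(cfg.num_layers)]
            coeffs = [Tensor.param(rng.normal(scale=1.0 / np.sqrt(cfg.num_bases), size=(n_ch, cfg.num_bases))) for _ in range(cfg.num_layers)]
            base_params = [*bases, *coeffs]
        else:
            bases = coeffs = None
            base_params = [Tensor.param(_xavier(rng, (n_ch, d, d))) for _ in range(cfg.num_layers)]
        self_w = [Tensor.param(_xavier(rng, (d, d))) for _ in range(cfg.num_layers)]
        dec_rel = Tensor.param(_xavier(rng, (n_rel, d)))
        dec_bias = Tensor.param(np.zeros(1))
        params = [X0, *base_params, *self_w, dec_rel, dec_bias]
        conve = None

        def layer_weights() -> list[Tensor]:
            if bases is None:
                return base_params
            # W_r = sum_b a_rb V_b, materialized per layer as an (n_ch, d, d)
            # tensor through a basis-mixing matmul
            out = []
            for l in range(cfg.num_layers):
                mixed = (coeffs[l] @ bases[l].reshape(cfg.num_bases, d * d)).reshape(n_ch, d, d)
                out.append(mixed)
            return out
    else:
        A = _channel_adjacency(kg, include_inverse=True, normalize=True)
        dir_w = [Tensor.param(_xavier(rng, (3, d, d))) for _ in range(cfg.num_layers)]
        rel_proj = [Tensor.param(_xavier(rng, (d, d))) for _ in range(cfg.num_layers)]
        Y0 = Tensor.param(_xavier(rng, (2 * n_rel + 1, d)))
        conve_cfg = cfg.conve or ConvEConfig.for_dim(d)
        conve_cfg.validate(d)
        P = (2 * conve_cfg.map_height - conve_cfg.kernel + 1) * (
            conve_cfg.map_width - conve_cfg.kernel + 1
        )
        filters = Tensor.param(_xavier(rng, (conve_cfg.n_filters, conve_cfg.kernel**2)))
        filter_bias = Tensor.param(np.zeros(conve_cfg.n_filters))
        proj = Tensor.param(_xavier(rng, (P * conve_cfg.n_filters, d)))
        proj_bias = Tensor.param(np.zeros(d))
        bias = Tensor.param(np.zeros(1))
        params = [X0, *dir_w, *rel_proj, Y0, filters, filter_bias, proj, proj_bias, bias]
        conve = conve_cfg

    opt = Adam(params, lr=cfg.learning_rate)
    arrays = _adjacency_arrays(kg, include_inverse=True) if model == "rgcn" else None
    losses: list[float] = []
    for epoch in range(cfg.epochs):
        nh, nr, nt = _sample_negative_indices(kg, H, R, T, cfg.neg_ratio, rng, rels, ents)
        opt.zero_grad()
        if model == "rgcn":
            A_ep = A
            if cfg.edge_dropout > 0:
                keep = rng.random(len(pos)) >= cfg.edge_dropout
                A_ep = _masked_adjacency(n, arrays, keep)
            states = _rgcn_forward_t(
                A_ep, X0, layer_weights(), self_w, cfg.activation, cfg.encoder_dropout, rng, training=True
            )
            s_pos = (states.take_rows(H) * dec_rel.take_rows(R) * states.take_rows(T)).sum(axis=-1) + dec_bias
            s_neg = (states.take_rows(nh) * dec_rel.take_rows(nr) * states.take_rows(nt)).sum(axis=-1) + dec_bias
            loss = _bce_loss_t(s_pos, s_neg, spec) + cfg.decoder_l2 * dec_rel.pow(2).sum()
            if cfg.input_l2 > 0:
                loss = loss + cfg.input_l2 * X0.pow(2).sum()
        else:
            states, rel_states = _compgcn_forward_t(
                A,
                X0,
                Y0,
                dir_w,
                rel_proj,
                cfg.composition,
                "tanh",
                n_rel,
                cfg.feature_dropout,
                cfg.layer_dropout,
                rng,
                training=True,
            )
            s_pos = _conve_score_t(
                states.take_rows(H), rel_states.take_rows(R), states.take_rows(T),
                filters, filter_bias, proj, proj_bias, bias, conve, rng, training=True,
            )
            s_neg = _conve_score_t(
                states.take_rows(nh), rel_states.take_rows(nr), states.take_rows(nt),
                filters, filter_bias, proj, proj_bias, bias, conve, rng, training=True,
            )
            loss = _bce_loss_t(s_pos, s_neg, spec)
        if not np.isfinite(loss.data).all():
            raise RuntimeError(f"training diverged at epoch {epoch}")
        loss.backward()
        opt.step()
        losses.append(loss.item())

    # final evaluation-mode encoding
    if model == "rgcn":
        rel_w = layer_weights()
        states = _rgcn_forward_t(A, X0, rel_w, self_w, cfg.activation)
        enc = RGCNParams(
            rel_weights=[w.data.copy() for w in rel_w],
            self_weights=[w.data.copy() for w in self_w],
            include_inverse=True,
            activation=cfg.activation,
            dropout_rate=cfg.encoder_dropout,
        )
        return GCNModel(
            "rgcn", list(ents), list(rels), states.data, dec_rel.data.copy(),
            encoder_params=enc, loss_history=losses,
        )
    states, rel_states = _compgcn_forward_t(
        A, X0, Y0, dir_w, rel_proj, cfg.composition, "tanh", n_rel
    )
    enc = CompGCNParams(
        dir_weights=[w.data.copy() for w in dir_w],
        rel_projections=[w.data.copy() for w in rel_proj],
        composition=cfg.composition,
        feature_dropout=cfg.feature_dropout,
        layer_dropout=cfg.layer_dropout,
    )
    decoder = ConvEDecoder(
        cfg=conve,
        filters=filters.data.copy(),
        filter_bias=filter_bias.data.copy(),
        proj=proj.data.copy(),
        proj_bias=proj_bias.data.copy(),
        bias=float(bias.data[0]),
    )
    return GCNModel(
        "compgcn", list(ents), list(rels), states.data, rel_states.data.copy(),
        decoder=decoder, encoder_params=enc, loss_history=losses,
    )
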