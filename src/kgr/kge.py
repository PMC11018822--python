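"""Knowledge-graph embedding models: TransE, RotatE, DistMult, ComplEX.

Score conventions follow the originals:

* TransE   ``s(h,r,t) = ||h + r - t||_p``      (distance; lower is better)
* RotatE   ``s(h,r,t) = ||h ∘ r - t||``        (complex rotation; lower is better)
* DistMult ``s(h,r,t) = hᵀ diag(r) t``          (higher is better)
* ComplEX  ``s(h,r,t) = Re(hᵀ diag(r) conj(t))``(higher is better)

The uniform model API exposes *plausibility*, which is the negated distance
for the translational models, so that every model ranks candidates in
descending order.

Training uses margin-based ranking loss for the translational models and
pointwise logistic loss with L2 regularization for the semantic-matching
models, optimized by Adagrad (the workhorse of the large-scale KGE
toolkits; plain SGD and Adam are available through the config).  Negatives
are drawn by corrupting the head
or the tail of each positive (never both), with filtering: a corruption that
reproduces a known triple is rejected.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._autodiff import SGD, Adagrad, Adam, Tensor
from .core import KnowledgeGraph

__all__ = [
    "EmbeddingTable",
    "KGETrainConfig",
    "KGEModel",
    "score_transe",
    "score_rotate",
    "score_distmult",
    "score_complex",
    "sample_negatives",
    "train_kge",
    "save_embeddings",
    "load_embeddings",
]

KGE_MODELS = ("TransE", "RotatE", "DistMult", "ComplEX")
_UNIT_MODULUS_TOL = 1e-6


# ---------------------------------------------------------------------------
# Score functions (pure numpy; vectorized over the leading axes)
# ---------------------------------------------------------------------------


def _check_dims(*vecs: np.ndarray) -> None:
    dims = {v.shape[-1] for v in vecs}
    if len(dims) != 1:
        raise ValueError(f"embedding dimension mismatch: {sorted(dims)}")


def score_transe(h: np.ndarray, r: np.ndarray, t: np.ndarray, p: int = 2):
    """Translational distance ||h + r - t||_p.  Lower = more plausible."""
    h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
    _check_dims(h, r, t)
    diff = h + r - t
    if p == 1:
        return np.abs(diff).sum(axis=-1)
    return np.sqrt((diff**2).sum(axis=-1))


def score_rotate(h: np.ndarray, r: np.ndarray, t: np.ndarray):
    """Rotation distance ||h ∘ r - t|| in complex space.  Lower = better.

    Relation entries must lie on the unit circle (each entry is a pure
    phase); deviations beyond tolerance are rejected.
    """
    h, r, t = np.asarray(h, complex), np.asarray(r, complex), np.asarray(t, complex)
    _check_dims(h, r, t)
    if np.abs(np.abs(r) - 1.0).max() > _UNIT_MODULUS_TOL:
        raise ValueError("RotatE relation entries must have unit modulus")
    diff = h * r - t
    return np.sqrt((diff.real**2 + diff.imag**2).sum(axis=-1))


def score_distmult(h: np.ndarray, r: np.ndarray, t: np.ndarray):
    """Trilinear product hᵀ diag(r) t; symmetric in h and t.  Higher = better."""
    h, r, t = np.asarray(h, float), np.asarray(r, float), np.asarray(t, float)
    _check_dims(h, r, t)
    return (h * r * t).sum(axis=-1)


def score_complex(h: np.ndarray, r: np.ndarray, t: np.ndarray):
    """Re(hᵀ diag(r) conj(t)); asymmetric in general.  Higher = better."""
    h, r, t = np.asarray(h, complex), np.asarray(r, complex), np.asarray(t, complex)
    _check_dims(h, r, t)
    return (h * r * np.conj(t)).sum(axis=-1).real


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingTable:
    """Learned entity and relation vectors for one model.

    ``entity_vectors``/``relation_vectors`` are real float arrays for TransE
    and DistMult and complex arrays for RotatE and ComplEX (RotatE relation
    entries are unit-modulus phases).
    """

    model: str
    d: int
    entities: list[str]
    relations: list[str]
    entity_vectors: np.ndarray
    relation_vectors: np.ndarray
    norm_order: int = 2
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.entity_vectors).all() or not np.isfinite(
            self.relation_vectors
        ).all():
            raise ValueError("embeddings must be finite")
        self._eidx = {e: i for i, e in enumerate(self.entities)}
        self._ridx = {r: i for i, r in enumerate(self.relations)}

    def entity_index(self, e: str) -> int:
        return self._eidx[e]

    def relation_index(self, r: str) -> int:
        return self._ridx[r]


class KGEModel:
    """Uniform plausibility API over an :class:`EmbeddingTable`.

    ``plausibility`` is higher for more plausible triples for every model
    (negated distance for TransE/RotatE).
    """

    def __init__(self, table: EmbeddingTable):
        self.table = table

    def plausibility_idx(self, h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
        E, R = self.table.entity_vectors, self.table.relation_vectors
        he, re_, te = E[h], R[r], E[t]
        m = self.table.model
        if m == "TransE":
            return -score_transe(he, re_, te, p=self.table.norm_order)
        if m == "RotatE":
            return -score_rotate(he, re_, te)
        if m == "DistMult":
            return score_distmult(he, re_, te)
        if m == "ComplEX":
            return score_complex(he, re_, te)
        raise ValueError(f"unknown model {m!r}")

    def plausibility(
        self, heads: Sequence[str], relations: Sequence[str], tails: Sequence[str]
    ) -> np.ndarray:
        h = np.array([self.table.entity_index(x) for x in heads])
        r = np.array([self.table.relation_index(x) for x in relations])
        t = np.array([self.table.entity_index(x) for x in tails])
        return np.atleast_1d(self.plausibility_idx(h, r, t))


@dataclass(frozen=True)
class KGETrainConfig:
    """Training configuration for the embedding models."""

    model: str = "TransE"
    learning_rate: float = 0.1
    hidden_dim: int = 100
    regularization_coeff: float = 1e-6
    batch_size: int = 1000
    neg_ratio: int = 20
    epochs: int = 100
    norm_order: int = 2
    margin: float = 1.0
    optimizer: str = "adagrad"  # "adagrad" | "adam" | "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in KGE_MODELS:
            raise ValueError(f"model must be one of {KGE_MODELS}")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if self.norm_order not in (1, 2):
            raise ValueError("norm_order must be 1 or 2")
        if self.optimizer not in ("adagrad", "adam", "sgd"):
            raise ValueError("optimizer must be 'adagrad', 'adam' or 'sgd'")


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------


def sample_negatives(
    kg: KnowledgeGraph,
    positives: Sequence[tuple[str, str, str]],
    ratio: int,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
) -> list[tuple[str, str, str]]:
    """Draw ``ratio`` filtered corruptions per positive triple.

    Each negative differs from its positive in head xor tail, and is absent
    from the graph.  Output order groups the ``ratio`` negatives of each
    positive consecutively, reproducibly under the seed.
    """
    if len(kg.entities) <= 1:
        raise ValueError("need more than one entity to corrupt triples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ents = kg.entities
    n_ent = len(ents)
    negatives: list[tuple[str, str, str]] = []
    for h, r, t in positives:
        got = 0
        tries = 0
        while got < ratio:
            if tries >= max_tries * ratio:
                raise RuntimeError(
                    f"could not find {ratio} valid corruptions for {(h, r, t)}; "
                    "the graph is too dense for this negative ratio -- lower it"
                )
            tries += 1
            corrupt_head = rng.random() < 0.5
            e = ents[int(rng.integers(n_ent))]
            cand = (e, r, t) if corrupt_head else (h, r, e)
            if cand == (h, r, t) or kg.contains_triple(*cand):
                continue
            negatives.append(cand)
            got += 1
    return negatives


def _encode(h: np.ndarray, r: np.ndarray, t: np.ndarray, n_ent: int, n_rel: int) -> np.ndarray:
    return (h.astype(np.int64) * n_rel + r) * n_ent + t


def _sample_negative_indices(
    kg: KnowledgeGraph,
    heads: np.ndarray,
    rels: np.ndarray,
    tails: np.ndarray,
    ratio: int,
    rng: np.random.Generator,
    rel_names: list[str],
    ent_names: list[str],
    max_rounds: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized filtered corruption on index arrays (training fast path)."""
    n = len(heads) * ratio
    h = np.repeat(heads, ratio).copy()
    r = np.repeat(rels, ratio)
    t = np.repeat(tails, ratio).copy()
    pending = np.arange(n)
    n_ent, n_rel = len(ent_names), len(rel_names)
    known = np.sort(
        _encode(
            np.array([kg.entity_index(a) for a, _, _ in kg.triples]),
            np.array([kg.relation_index(b) for _, b, _ in kg.triples]),
            np.array([kg.entity_index(c) for _, _, c in kg.triples]),
            n_ent,
            n_rel,
        )
    )
    base_h = np.repeat(heads, ratio)
    base_t = np.repeat(tails, ratio)
    for _ in range(max_rounds):
        if pending.size == 0:
            break
        side = rng.random(pending.size) < 0.5
        repl = rng.integers(n_ent, size=pending.size)
        h[pending] = np.where(side, repl, h[pending])
        t[pending] = np.where(~side, repl, t[pending])
        codes = _encode(h[pending], r[pending], t[pending], n_ent, n_rel)
        pos = np.searchsorted(known, codes)
        pos = np.minimum(pos, known.size - 1)
        bad = known[pos] == codes
        # a rejected draw resets the corrupted side back to the positive
        rej = pending[bad]
        h[rej] = base_h[rej]
        t[rej] = base_t[rej]
        pending = rej
    if pending.size:
        raise RuntimeError("could not complete filtered negative sampling; lower the ratio")
    return h, r, t


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _xavier(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    bound = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-bound, bound, size=shape)


def _init_params(cfg: KGETrainConfig, n_ent: int, n_rel: int, rng: np.random.Generator):
    d = cfg.hidden_dim
    if cfg.model == "TransE":
        ent = Tensor.param(_xavier(rng, (n_ent, d)))
        rel = Tensor.param(_xavier(rng, (n_rel, d)))
    elif cfg.model == "RotatE":
        ent = Tensor.param(_xavier(rng, (n_ent, 2 * d)))  # [re | im]
        rel = Tensor.param(rng.uniform(0.0, 2.0 * np.pi, size=(n_rel, d)))  # phases
    elif cfg.model == "DistMult":
        ent = Tensor.param(_xavier(rng, (n_ent, d)))
        rel = Tensor.param(_xavier(rng, (n_rel, d)))
    else:  # ComplEX
        ent = Tensor.param(_xavier(rng, (n_ent, 2 * d)))
        rel = Tensor.param(_xavier(rng, (n_rel, 2 * d)))
    return ent, rel


def _distance_tensor(cfg: KGETrainConfig, ent: Tensor, rel: Tensor, h, r, t) -> Tensor:
    d = cfg.hidden_dim
    if cfg.model == "TransE":
        diff = ent.take_rows(h) + rel.take_rows(r) - ent.take_rows(t)
        if cfg.norm_order == 1:
            return diff.abs().sum(axis=-1)
        return (diff.pow(2).sum(axis=-1) + 1e-12).sqrt()
    # RotatE: entity rows are [re | im] halves, relations are phase vectors
    he, te = ent.take_rows(h), ent.take_rows(t)
    theta = rel.take_rows(r)
    c, s = theta.cos(), theta.sin()
    h_re = he.take_flat(_half_idx(he.shape[0], d, 0, 2 * d))
    h_im = he.take_flat(_half_idx(he.shape[0], d, d, 2 * d))
    t_re = te.take_flat(_half_idx(te.shape[0], d, 0, 2 * d))
    t_im = te.take_flat(_half_idx(te.shape[0], d, d, 2 * d))
    rot_re = h_re * c - h_im * s
    rot_im = h_re * s + h_im * c
    dre = rot_re - t_re
    dim = rot_im - t_im
    return (dre.pow(2).sum(axis=-1) + dim.pow(2).sum(axis=-1) + 1e-12).sqrt()


def _half_idx(n: int, d: int, start: int, row: int) -> np.ndarray:
    rows = np.arange(n)[:, None] * row
    cols = np.arange(start, start + d)[None, :]
    return rows + cols


def _match_score_tensor(cfg: KGETrainConfig, ent: Tensor, rel: Tensor, h, r, t) -> Tensor:
    d = cfg.hidden_dim
    if cfg.model == "DistMult":
        return (ent.take_rows(h) * rel.take_rows(r) * ent.take_rows(t)).sum(axis=-1)
    he, re_, te = ent.take_rows(h), rel.take_rows(r), ent.take_rows(t)
    n = he.shape[0]
    hr = he.take_flat(_half_idx(n, d, 0, 2 * d))
    hi = he.take_flat(_half_idx(n, d, d, 2 * d))
    rr = re_.take_flat(_half_idx(n, d, 0, 2 * d))
    ri = re_.take_flat(_half_idx(n, d, d, 2 * d))
    tr = te.take_flat(_half_idx(n, d, 0, 2 * d))
    ti = te.take_flat(_half_idx(n, d, d, 2 * d))
    # Re(h r conj(t)) expanded over real/imaginary parts
    return ((hr * rr - hi * ri) * tr + (hr * ri + hi * rr) * ti).sum(axis=-1)


def train_kge(kg: KnowledgeGraph, cfg: KGETrainConfig) -> EmbeddingTable:
    """Train one embedding model on the full triple set of ``kg``.

    Fresh filtered negatives are drawn every epoch at ``cfg.neg_ratio`` per
    positive.  Translational models minimize margin ranking loss and have
    their entity vectors L2-normalized after every update (the classical
    constraint preventing trivial distance collapse); semantic-matching
    models minimize the pointwise logistic loss plus L2 regularization.
    Everything is driven by ``cfg.seed``; two runs with the same seed return
    identical embeddings.
    """
    if len(kg) == 0:
        raise ValueError("cannot train on an empty graph")
    rng = np.random.default_rng(cfg.seed)
    ent_names, rel_names = kg.entities, kg.relations
    ent, rel = _init_params(cfg, len(ent_names), len(rel_names), rng)
    pos = list(kg.triples)
    H = np.array([kg.entity_index(h) for h, _, _ in pos])
    R = np.array([kg.relation_index(r) for _, r, _ in pos])
    T = np.array([kg.entity_index(t) for _, _, t in pos])

    translational = cfg.model in ("TransE", "RotatE")
    opt_cls = {"adagrad": Adagrad, "adam": Adam, "sgd": SGD}[cfg.optimizer]
    opt = opt_cls([ent, rel], lr=cfg.learning_rate)
    losses: list[float] = []

    def normalize_entities() -> None:
        if cfg.model == "TransE":
            norms = np.linalg.norm(ent.data, axis=1, keepdims=True)
            ent.data /= np.maximum(norms, 1e-12)

    normalize_entities()
    for epoch in range(cfg.epochs):
        nh, nr, nt = _sample_negative_indices(
            kg, H, R, T, cfg.neg_ratio, rng, rel_names, ent_names
        )
        perm = rng.permutation(len(H))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(H), cfg.batch_size):
            b = perm[start : start + cfg.batch_size]
            nb = (b[:, None] * cfg.neg_ratio + np.arange(cfg.neg_ratio)[None, :]).ravel()
            opt.zero_grad()
            if translational:
                d_pos = _distance_tensor(cfg, ent, rel, H[b], R[b], T[b])
                d_neg = _distance_tensor(cfg, ent, rel, nh[nb], nr[nb], nt[nb])
                # pair each positive with its own negatives
                d_pos_rep = _repeat(d_pos, cfg.neg_ratio)
                loss = (d_pos_rep - d_neg + cfg.margin).relu().mean()
            else:
                s_pos = _match_score_tensor(cfg, ent, rel, H[b], R[b], T[b])
                s_neg = _match_score_tensor(cfg, ent, rel, nh[nb], nr[nb], nt[nb])
                loss = (
                    (-s_pos).softplus().sum() + s_neg.softplus().sum()
                ) * (1.0 / (len(b) * (1 + cfg.neg_ratio)))
                loss = loss + cfg.regularization_coeff * (
                    ent.pow(2).sum() + rel.pow(2).sum()
                )
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            loss.backward()
            opt.step()
            normalize_entities()
            epoch_loss += loss.item()
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))

    return _to_table(cfg, ent_names, rel_names, ent.data, rel.data, losses)


def _repeat(t: Tensor, k: int) -> Tensor:
    n = t.data.shape[0]
    idx = np.repeat(np.arange(n), k)
    return t.take_flat(idx)


def _to_table(
    cfg: KGETrainConfig,
    ent_names: list[str],
    rel_names: list[str],
    ent_data: np.ndarray,
    rel_data: np.ndarray,
    losses: list[float],
) -> EmbeddingTable:
    d = cfg.hidden_dim
    if cfg.model in ("TransE", "DistMult"):
        ev, rv = ent_data.copy(), rel_data.copy()
    elif cfg.model == "RotatE":
        ev = ent_data[:, :d] + 1j * ent_data[:, d:]
        rv = np.exp(1j * rel_data)
    else:
        ev = ent_data[:, :d] + 1j * ent_data[:, d:]
        rv = rel_data[:, :d] + 1j * rel_data[:, d:]
    return EmbeddingTable(
        model=cfg.model,
        d=d,
        entities=list(ent_names),
        relations=list(rel_names),
        entity_vectors=ev,
        relation_vectors=rv,
        norm_order=cfg.norm_order,
        loss_history=losses,
    )


# ---------------------------------------------------------------------------
# Serialization (header JSON + per-row TSV)
# ---------------------------------------------------------------------------


def save_embeddings(table: EmbeddingTable, directory: str | os.PathLike[str]) -> None:
    os.makedirs(directory, exist_ok=True)
    is_complex = np.iscomplexobj(table.entity_vectors)
    header = {
        "model": table.model,
        "d": table.d,
        "complex": bool(is_complex),
        "norm_order": table.norm_order,
        "n_entities": len(table.entities),
        "n_relations": len(table.relations),
    }
    with open(os.path.join(directory, "header.json"), "w", encoding="utf-8") as fh:
        json.dump(header, fh, indent=2)

    def dump(path: str, names: list[str], vecs: np.ndarray) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, row in zip(names, vecs):
                if is_complex:
                    vals = [f"{v.real:.17g},{v.imag:.17g}" for v in row]
                else:
                    vals = [f"{v:.17g}" for v in row]
                fh.write(name + "\t" + "\t".join(vals) + "\n")

    dump(os.path.join(directory, "entity_vectors.tsv"), table.entities, table.entity_vectors)
    dump(os.path.join(directory, "relation_vectors.tsv"), table.relations, table.relation_vectors)


def load_embeddings(directory: str | os.PathLike[str]) -> EmbeddingTable:
    with open(os.path.join(directory, "header.json"), encoding="utf-8") as fh:
        header = json.load(fh)

    def parse(path: str, is_complex: bool) -> tuple[list[str], np.ndarray]:
        names, rows = [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                names.append(parts[0])
                if is_complex:
                    rows.append(
                        [complex(float(p.split(",")[0]), float(p.split(",")[1])) for p in parts[1:]]
                    )
                else:
                    rows.append([float(p) for p in parts[1:]])
        return names, np.array(rows)

    ents, ev = parse(os.path.join(directory, "entity_vectors.tsv"), header["complex"])
    rels, rv = parse(os.path.join(directory, "relation_vectors.tsv"), header["complex"])
    return EmbeddingTable(
        model=header["model"],
        d=header["d"],
        entities=ents,
        relations=rels,
        entity_vectors=ev,
        relation_vectors=rv,
        norm_order=header.get("norm_order", 2),
    )
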