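"""Graph preprocessing: rule filters, G² specificity scoring, budgeted pruning.

Literature-derived predication graphs contain generic hub concepts
("Disease", "Cells") and unspecific triples whose endpoints co-occur with
almost everything.  Preprocessing proceeds in three stages:

1. **Rule filters** — drop triples touching generic concepts or excluded
   semantic groups, and keep only a whitelist of predicate types relevant
   for link prediction.
2. **Specificity scoring** — per triple, combine normalized endpoint degrees
   with the G² log-likelihood-ratio association statistic over a 2x2x2
   contingency table of (subject, predicate, object) occurrence, then prune
   the highest-scoring (least specific) triples down to a target budget.
3. **Verification hook** — an arbitrary boolean predicate over triples,
   standing in for sentence-level triple verification models whose weights
   are external to this package.

Every stage returns a subgraph of its input, so the pipeline is monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .core import KnowledgeGraph, Predication

__all__ = [
    "DEFAULT_RELATION_WHITELIST",
    "DEFAULT_EXCLUDED_GROUPS",
    "FilterConfig",
    "ContingencyTable",
    "TripleScore",
    "apply_rule_filters",
    "node_degrees",
    "contingency_from_stream",
    "g2_statistic",
    "combined_scores",
    "prune_to_budget",
    "triple_filter_hook",
    "preprocess",
]

#: The fifteen predicate types retained for link prediction, in decreasing
#: corpus frequency.  User-overridable: corpora differ.
DEFAULT_RELATION_WHITELIST = (
    "COEXISTS_WITH",
    "INTERACTS_WITH",
    "AFFECTS",
    "TREATS",
    "CAUSES",
    "ASSOCIATED_WITH",
    "INHIBITS",
    "STIMULATES",
    "DISRUPTS",
    "AUGMENTS",
    "PRODUCES",
    "PREDISPOSES",
    "PREVENTS",
    "COMPLICATES",
    "MANIFESTATION_OF",
)

#: Semantic groups unlikely to support intervention discovery.
DEFAULT_EXCLUDED_GROUPS = ("Activities & Behaviors", "Concepts & Ideas")


@dataclass(frozen=True)
class FilterConfig:
    """Configuration of the rule-filtering and pruning stages."""

    generic_concepts: frozenset[str] = frozenset()
    excluded_groups: frozenset[str] = frozenset(DEFAULT_EXCLUDED_GROUPS)
    relation_whitelist: frozenset[str] = frozenset(DEFAULT_RELATION_WHITELIST)
    budget: int = 1_800_000
    degree_mode: str = "pair"  # "pair": (head out, tail in); "hub": max of the two

    def __post_init__(self) -> None:
        if not self.relation_whitelist:
            raise ValueError("relation_whitelist must be nonempty")
        if self.budget <= 0:
            raise ValueError("budget must be positive")
        if self.degree_mode not in ("pair", "hub"):
            raise ValueError("degree_mode must be 'pair' or 'hub'")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2x2 observed counts over predication instances.

    Axis order is (subject matches, predicate matches, object matches);
    index 0 means "present", 1 means "absent", so ``n[0, 0, 0]`` counts
    instances asserting exactly the triple under study.
    """

    n: np.ndarray  # shape (2, 2, 2), nonnegative integers

    def __post_init__(self) -> None:
        arr = np.asarray(self.n)
        if arr.shape != (2, 2, 2):
            raise ValueError("contingency table must be 2x2x2")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(np.asarray(self.n).sum())


@dataclass(frozen=True)
class TripleScore:
    """Degree and association components of a triple's specificity score."""

    k_in: float
    k_out: float
    g2: float
    combined: float


def apply_rule_filters(kg: KnowledgeGraph, cfg: FilterConfig) -> KnowledgeGraph:
    """Stage-1 rule filtering: generic concepts, excluded groups, whitelist."""
    if not (cfg.relation_whitelist & set(kg.relations)):
        raise ValueError(
            "relation whitelist shares no predicate with the graph; "
            "filtering would produce an empty graph"
        )
    generic = cfg.generic_concepts

    def keep(hrt: tuple[str, str, str]) -> bool:
        h, r, t = hrt
        if r not in cfg.relation_whitelist:
            return False
        if h in generic or t in generic:
            return False
        if kg.meta[h].semantic_group in cfg.excluded_groups:
            return False
        if kg.meta[t].semantic_group in cfg.excluded_groups:
            return False
        return True

    return kg.subgraph(keep)


def node_degrees(kg: KnowledgeGraph) -> dict[str, tuple[int, int]]:
    """Per-entity (in-degree, out-degree) over distinct triples."""
    deg = {e: [0, 0] for e in kg.entities}
    for h, r, t in kg.triples:
        deg[t][0] += 1
        deg[h][1] += 1
    return {e: (d[0], d[1]) for e, d in deg.items()}


def contingency_from_stream(
    preds: Sequence[Predication], head: str, relation: str, tail: str
) -> ContingencyTable:
    """Observation table for one triple over a predication stream.

    Each instance is classified on three binary axes: does its subject match
    ``head``, its predicate match ``relation``, its object match ``tail``.
    """
    if not preds:
        raise ValueError("predication stream must be nonempty")
    n = np.zeros((2, 2, 2), dtype=np.int64)
    for p in preds:
        i = 0 if p.subject_id == head else 1
        j = 0 if p.predicate == relation else 1
        k = 0 if p.object_id == tail else 1
        n[i, j, k] += 1
    return ContingencyTable(n=n)


def g2_statistic(tab: ContingencyTable) -> float:
    """G² log-likelihood-ratio statistic for mutual independence.

    ``G² = 2 Σ_ijk n_ijk log(n_ijk / m_ijk)`` with the expected counts
    ``m_ijk = n_i·· n_·j· n_··k / T²`` built from the one-way marginals,
    i.e. the classical likelihood-ratio test of independence of the three
    axes (4 degrees of freedom on a 2x2x2 table).  Cells with ``n_ijk = 0``
    contribute nothing (the 0·log 0 = 0 convention).
    """
    n = np.asarray(tab.n, dtype=float)
    T = n.sum()
    if T <= 0:
        raise ValueError("total count must be positive")
    a = n.sum(axis=(1, 2))  # subject marginal
    b = n.sum(axis=(0, 2))  # predicate marginal
    c = n.sum(axis=(0, 1))  # object marginal
    m = np.einsum("i,j,k->ijk", a, b, c) / (T * T)
    mask = n > 0
    if (m[mask] <= 0).any():
        raise ValueError("zero expected count with positive observed count")
    g2 = 2.0 * float(np.sum(n[mask] * np.log(n[mask] / m[mask])))
    return g2


def combined_scores(
    kg: KnowledgeGraph,
    degrees: Mapping[str, tuple[int, int]] | None = None,
    g2_by_triple: Mapping[tuple[str, str, str], float] | None = None,
    degree_mode: str = "pair",
) -> dict[tuple[str, str, str], TripleScore]:
    """Per-triple specificity score: min-max-normalized k_in + k_out + G².

    Higher scores flag less specific triples (hub endpoints, weak
    association).  A component that is constant across the population
    contributes zero for every triple.
    """
    if degrees is None:
        degrees = node_degrees(kg)
    if g2_by_triple is None:
        g2_by_triple = g2_from_graph_counts(kg)
    keys = list(kg.triples)
    if not keys:
        return {}
    k_out = np.empty(len(keys))
    k_in = np.empty(len(keys))
    g2 = np.empty(len(keys))
    for idx, (h, r, t) in enumerate(keys):
        head_out = degrees[h][1]
        tail_in = degrees[t][0]
        if degree_mode == "hub":
            hub = max(head_out, tail_in)
            k_out[idx] = hub
            k_in[idx] = hub
        else:
            k_out[idx] = head_out
            k_in[idx] = tail_in
        g2[idx] = g2_by_triple[(h, r, t)]

    def minmax(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    combined = minmax(k_in) + minmax(k_out) + minmax(g2)
    return {
        k: TripleScore(k_in=float(k_in[i]), k_out=float(k_out[i]), g2=float(g2[i]), combined=float(combined[i]))
        for i, k in enumerate(keys)
    }


def g2_from_graph_counts(kg: KnowledgeGraph) -> dict[tuple[str, str, str], float]:
    """G² per triple type from the graph's own instance counts.

    Builds, for each triple, the 2x2x2 occurrence table over all instances
    recorded in the graph (one virtual instance per unit of multiplicity)
    without materializing the stream: marginals are derived from per-subject,
    per-predicate and per-object instance totals.
    """
    subj_tot: dict[str, int] = {}
    pred_tot: dict[str, int] = {}
    obj_tot: dict[str, int] = {}
    pair_sp: dict[tuple[str, str], int] = {}
    pair_so: dict[tuple[str, str], int] = {}
    pair_po: dict[tuple[str, str], int] = {}
    T = 0
    for (h, r, t), info in kg.triples.items():
        c = info.count
        T += c
        subj_tot[h] = subj_tot.get(h, 0) + c
        pred_tot[r] = pred_tot.get(r, 0) + c
        obj_tot[t] = obj_tot.get(t, 0) + c
        pair_sp[(h, r)] = pair_sp.get((h, r), 0) + c
        pair_so[(h, t)] = pair_so.get((h, t), 0) + c
        pair_po[(r, t)] = pair_po.get((r, t), 0) + c
    out: dict[tuple[str, str, str], float] = {}
    for (h, r, t), info in kg.triples.items():
        n111 = info.count
        ns = subj_tot[h]
        np_ = pred_tot[r]
        no = obj_tot[t]
        n110 = pair_sp[(h, r)] - n111
        n101 = pair_so[(h, t)] - n111
        n011 = pair_po[(r, t)] - n111
        n100 = ns - n111 - n110 - n101
        n010 = np_ - n111 - n110 - n011
        n001 = no - n111 - n101 - n011
        n000 = T - (n111 + n110 + n101 + n011 + n100 + n010 + n001)
        tab = ContingencyTable(
            n=np.array(
                [[[n111, n110], [n101, n100]], [[n011, n010], [n001, n000]]],
                dtype=np.int64,
            )
        )
        out[(h, r, t)] = g2_statistic(tab)
    return out


def prune_to_budget(
    kg: KnowledgeGraph,
    scores: Mapping[tuple[str, str, str], TripleScore],
    budget: int,
) -> KnowledgeGraph:
    """Keep the ``budget`` lowest-combined-score (most specific) triples.

    Ties break deterministically on (score, head, relation, tail).
    """
    if budget < 0:
        raise ValueError("budget must be nonnegative")
    if budget >= len(kg):
        return kg.subgraph(lambda _: True)
    ranked = sorted(kg.triples, key=lambda k: (scores[k].combined, k))
    keep = set(ranked[:budget])
    return kg.subgraph(lambda k: k in keep)


def triple_filter_hook(
    kg: KnowledgeGraph,
    predicate: Callable[[tuple[str, str, str]], bool] | None = None,
) -> KnowledgeGraph:
    """Apply an external boolean verification filter over triples.

    The default hook keeps everything.  If the hook raises, the offending
    triple is identified in the error.
    """
    if predicate is None:
        return kg.subgraph(lambda _: True)
    decisions: dict[tuple[str, str, str], bool] = {}
    for key in kg.triples:
        try:
            decisions[key] = bool(predicate(key))
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise RuntimeError(f"triple filter hook failed on {key}") from exc
    return kg.subgraph(lambda k: decisions[k])


def preprocess(
    kg: KnowledgeGraph,
    cfg: FilterConfig,
    hook: Callable[[tuple[str, str, str]], bool] | None = None,
    report: dict | None = None,
) -> KnowledgeGraph:
    """Run all three preprocessing stages; optionally log per-stage counts."""
    n0 = len(kg)
    kg1 = apply_rule_filters(kg, cfg)
    scores = combined_scores(kg1, degree_mode=cfg.degree_mode)
    kg2 = prune_to_budget(kg1, scores, cfg.budget)
    kg3 = triple_filter_hook(kg2, hook)
    if report is not None:
        report.update(
            {
                "input_triples": n0,
                "after_rule_filters": len(kg1),
                "after_budget_prune": len(kg2),
                "after_hook": len(kg3),
            }
        )
    return kg3
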