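"""Evaluation: time-sliced splits, filtered-corruption ranking, metrics.

Time slicing asks whether links first attested *after* a cutoff date can be
predicted from links attested before it: triples are ordered
chronologically and cut into contiguous train/validation/test slices (8:1:1
by default), with the effective cut dates reported as outputs.

Ranking follows the filtered-corruption protocol: for each true test triple
a batch of negatives is drawn by replacing its head or tail, excluding any
replacement that reproduces a known triple; all candidates are scored and
the true triple's 1-based rank is recorded (ties resolved by the mean-rank
convention).  MR, MRR and Hits@k derive from the rank list; AUROC/AUPR from
the pooled positive and negative scores.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .core import KnowledgeGraph

__all__ = [
    "TimeSplit",
    "RankingResult",
    "MetricReport",
    "Scorer",
    "chronological_split",
    "split_by_dates",
    "build_ground_truth_testset",
    "rank_triple",
    "evaluate_ranking",
    "metrics_from_ranks",
    "curves_from_scores",
]


class Scorer(Protocol):
    """Anything exposing the uniform plausibility API (higher = better)."""

    def plausibility(
        self, heads: Sequence[str], relations: Sequence[str], tails: Sequence[str]
    ) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSplit:
    """Chronological train/validation/test partition of a triple set."""

    train: tuple[tuple[str, str, str], ...]
    valid: tuple[tuple[str, str, str], ...]
    test: tuple[tuple[str, str, str], ...]
    cut_dates: tuple[datetime.date, datetime.date]


def _sorted_triples(kg: KnowledgeGraph) -> list[tuple[str, str, str]]:
    # stable order: attestation date first, then the triple itself as a
    # deterministic tie-break, so permuting the input rows changes nothing
    return sorted(kg.triples, key=lambda k: (kg.info(*k).first_date, k))


def chronological_split(
    kg: KnowledgeGraph, ratios: tuple[int, int, int] = (8, 1, 1)
) -> TimeSplit:
    """Split the graph chronologically into contiguous slices by count.

    The effective cut dates (date of the last train triple and the last
    validation triple) are reported as outputs, not taken as inputs.
    """
    if any(r < 0 for r in ratios) or sum(ratios) <= 0:
        raise ValueError("ratios must be nonnegative and sum to a positive value")
    order = _sorted_triples(kg)
    n = len(order)
    if n == 0:
        raise ValueError("cannot split an empty graph")
    total = sum(ratios)
    n_train = int(n * ratios[0] / total)
    n_valid = int(n * (ratios[0] + ratios[1]) / total) - n_train
    train = tuple(order[:n_train])
    valid = tuple(order[n_train : n_train + n_valid])
    test = tuple(order[n_train + n_valid :])
    cut1 = kg.info(*train[-1]).first_date if train else kg.info(*order[0]).first_date
    cut2 = kg.info(*valid[-1]).first_date if valid else cut1
    return TimeSplit(train=train, valid=valid, test=test, cut_dates=(cut1, cut2))


def split_by_dates(
    kg: KnowledgeGraph, cut1: datetime.date, cut2: datetime.date
) -> TimeSplit:
    """Date-driven split: train ≤ cut1 < valid ≤ cut2 < test."""
    if cut1 > cut2:
        raise ValueError("cut dates must be ordered")
    order = _sorted_triples(kg)
    train = tuple(k for k in order if kg.info(*k).first_date <= cut1)
    valid = tuple(k for k in order if cut1 < kg.info(*k).first_date <= cut2)
    test = tuple(k for k in order if kg.info(*k).first_date > cut2)
    return TimeSplit(train=train, valid=valid, test=test, cut_dates=(cut1, cut2))


def build_ground_truth_testset(
    head_ids: Sequence[str],
    relation: str,
    tail_id: str,
    kg: KnowledgeGraph,
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Construct (head, relation, tail) test triples from a head list.

    One triple per distinct head; heads absent from the graph vocabulary are
    dropped and returned separately for reporting.
    """
    if not head_ids:
        raise ValueError("head list must be nonempty")
    seen: dict[str, None] = {}
    for h in head_ids:
        seen.setdefault(h)
    triples = [(h, relation, tail_id) for h in seen if kg.has_entity(h)]
    dropped = [h for h in seen if not kg.has_entity(h)]
    return triples, dropped


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankingResult:
    """Rank of one true triple against its filtered corruption batch."""

    triple: tuple[str, str, str]
    rank: int
    candidates: int
    side: str  # "head" or "tail"

    def __post_init__(self) -> None:
        if not (1 <= self.rank <= self.candidates):
            raise ValueError("rank must lie in [1, candidates]")


def _mean_rank(true_score: float, other_scores: np.ndarray) -> int:
    """1-based rank with the mean-rank tie convention, rounded half up."""
    better = int(np.sum(other_scores > true_score))
    tied = int(np.sum(other_scores == true_score))
    # tied group occupies positions better+1 .. better+tied+1; its mean is
    # better + 1 + tied/2
    mean_pos = better + 1 + tied / 2.0
    return int(np.floor(mean_pos + 0.5))


def rank_triple(
    model: Scorer,
    kg: KnowledgeGraph,
    triple: tuple[str, str, str],
    n_negatives: int = 100,
    side: str = "tail",
    seed: int | np.random.Generator = 0,
) -> RankingResult:
    """Rank one true triple against ``n_negatives`` filtered corruptions.

    Corruptions replace the chosen side with entities drawn without
    replacement from those that do not form a known triple (and are not the
    triple's own entity); an error is raised if fewer than ``n_negatives``
    valid replacements exist.
    """
    if side not in ("head", "tail"):
        raise ValueError("side must be 'head' or 'tail'")
    h, r, t = triple
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if side == "head":
        valid = [e for e in kg.entities if e != h and not kg.contains_triple(e, r, t)]
    else:
        valid = [e for e in kg.entities if e != t and not kg.contains_triple(h, r, e)]
    if len(valid) < n_negatives:
        raise RuntimeError(
            f"only {len(valid)} valid corruptions exist for {triple} on the {side} side"
        )
    chosen = list(rng.choice(np.array(valid, dtype=object), size=n_negatives, replace=False))
    if side == "head":
        neg_scores = model.plausibility(chosen, [r] * n_negatives, [t] * n_negatives)
    else:
        neg_scores = model.plausibility([h] * n_negatives, [r] * n_negatives, chosen)
    true_score = float(model.plausibility([h], [r], [t])[0])
    return RankingResult(
        triple=triple,
        rank=_mean_rank(true_score, np.asarray(neg_scores)),
        candidates=n_negatives + 1,
        side=side,
    )


def evaluate_ranking(
    model: Scorer,
    kg: KnowledgeGraph,
    test_triples: Iterable[tuple[str, str, str]],
    n_negatives: int = 100,
    sides: tuple[str, ...] = ("head", "tail"),
    seed: int = 0,
) -> list[RankingResult]:
    """Rank every test triple on each requested corruption side."""
    rng = np.random.default_rng(seed)
    results: list[RankingResult] = []
    for triple in test_triples:
        for side in sides:
            results.append(rank_triple(model, kg, triple, n_negatives, side, rng))
    return results


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricReport:
    """Ranking and threshold-sweep metrics of one evaluation run."""

    mr: float
    mrr: float
    hits1: float
    hits3: float
    hits10: float
    auroc: float | None = None
    aupr: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "MR": self.mr,
            "MRR": self.mrr,
            "Hits@1": self.hits1,
            "Hits@3": self.hits3,
            "Hits@10": self.hits10,
            "AUROC": self.auroc,
            "AUPR": self.aupr,
        }


def metrics_from_ranks(ranks: Sequence[int] | Sequence[RankingResult]) -> MetricReport:
    """MR, MRR and Hits@{1,3,10} from a rank list."""
    vals = [r.rank if isinstance(r, RankingResult) else int(r) for r in ranks]
    if not vals:
        raise ValueError("rank list must be nonempty")
    arr = np.asarray(vals, float)
    return MetricReport(
        mr=float(arr.mean()),
        mrr=float((1.0 / arr).mean()),
        hits1=float((arr <= 1).mean()),
        hits3=float((arr <= 3).mean()),
        hits10=float((arr <= 10).mean()),
    )


def curves_from_scores(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ROC and PR curves with their areas from pooled plausibility scores.

    Returns (roc_points, pr_points, auroc, aupr) where roc_points has
    columns (fpr, tpr) and pr_points has columns (recall, precision).
    AUROC equals the normalized Mann-Whitney U statistic (ties counted
    half); AUPR is the step-interpolated average precision.
    """
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    prec, rec, _ = precision_recall_curve(y, s)
    auroc = float(roc_auc_score(y, s))
    aupr = float(average_precision_score(y, s))
    return np.column_stack([fpr, tpr]), np.column_stack([rec, prec]), auroc, aupr
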