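"""End-to-end planted-link recovery benchmark on the synthetic corpus.

One benchmark run generates the default synthetic knowledge graph (500
entities, 5,000 triples, TransE latent structure, 10% noise, 20 planted
mechanisms with 10 held-out PREVENTS closures), trains a TransE and an
R-GCN link predictor on the emitted graph, ranks the held-out closures
against 100 filtered corruptions per side, and measures how many held-out
intervention heads land in the top decile of their class's candidate table
scored by the better-performing model.

The training configurations are fixed here so that the benchmark is a
single reproducible study; they are the package defaults scaled to this
problem size (dimensions 64/32, 300 epochs, Adam).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import build_graph
from .discovery import score_candidates
from .evaluation import MetricReport, curves_from_scores, evaluate_ranking, metrics_from_ranks
from .gcn import GCNTrainConfig, train_gcn
from .kge import KGEModel, KGETrainConfig, sample_negatives, train_kge
from .synthetic import SynthConfig, generate

__all__ = ["BenchmarkResult", "run_planted_benchmark"]

TRANSE_CFG = dict(
    model="TransE",
    hidden_dim=64,
    epochs=300,
    batch_size=1024,
    learning_rate=0.01,
    optimizer="adam",
    margin=1.0,
    neg_ratio=20,
)

RGCN_CFG = dict(
    hidden_dim=32,
    num_layers=1,
    activation="identity",
    epochs=300,
    learning_rate=0.01,
    neg_ratio=20,
)

N_EVAL_NEGATIVES = 100


@dataclass
class BenchmarkResult:
    seed: int
    n_entities: int
    n_triples: int
    n_heldout: int
    transe: MetricReport
    rgcn: MetricReport
    transe_auroc: float
    transe_aupr: float
    candidate_ranks: list[tuple[str, int, int]]  # (npi, rank, class size)
    top_decile_fraction: float


def _candidate_recovery(model, kg, heldout) -> list[tuple[str, int, int]]:
    out = []
    for npi, rel, dis in heldout:
        table = score_candidates(model, kg, kg.meta[npi].npi_class, dis, relation=rel)
        rank = int(table.loc[table.npi_id == npi, "rank"].iloc[0])
        out.append((npi, rank, len(table)))
    return out


def run_planted_benchmark(seed: int) -> BenchmarkResult:
    """Run the full planted-link recovery study for one generator seed."""
    cfg = SynthConfig(seed=seed)
    preds, gt = generate(cfg)
    kg = build_graph(preds, meta=gt.meta)

    transe = KGEModel(train_kge(kg, KGETrainConfig(seed=seed + 100, **TRANSE_CFG)))
    rgcn = train_gcn(kg, "rgcn", GCNTrainConfig(seed=seed + 100, **RGCN_CFG))

    res_t = evaluate_ranking(
        transe, kg, gt.heldout_prevents, n_negatives=N_EVAL_NEGATIVES, seed=seed + 200
    )
    res_g = evaluate_ranking(
        rgcn, kg, gt.heldout_prevents, n_negatives=N_EVAL_NEGATIVES, seed=seed + 200
    )
    rep_t = metrics_from_ranks(res_t)
    rep_g = metrics_from_ranks(res_g)

    # score-level discrimination: held-out positives vs their filtered
    # corruptions, pooled over queries
    pos_scores = transe.plausibility(
        [h for h, _, _ in gt.heldout_prevents],
        [r for _, r, _ in gt.heldout_prevents],
        [t for _, _, t in gt.heldout_prevents],
    )
    negs = sample_negatives(kg, gt.heldout_prevents, ratio=20, seed=seed + 300)
    neg_scores = transe.plausibility(
        [h for h, _, _ in negs], [r for _, r, _ in negs], [t for _, _, t in negs]
    )
    _, _, auroc, aupr = curves_from_scores(pos_scores, neg_scores)

    # the better-ranking model scores the candidate tables (the workflow
    # promotes the winning model to the discovery stage)
    best = transe if rep_t.hits10 >= rep_g.hits10 else rgcn
    ranks = _candidate_recovery(best, kg, gt.heldout_prevents)
    in_decile = sum(1 for _, r, n in ranks if r <= math.ceil(0.1 * n))

    return BenchmarkResult(
        seed=seed,
        n_entities=len(kg.entities),
        n_triples=len(kg),
        n_heldout=len(gt.heldout_prevents),
        transe=rep_t,
        rgcn=rep_g,
        transe_auroc=auroc,
        transe_aupr=aupr,
        candidate_ranks=ranks,
        top_decile_fraction=in_decile / len(ranks),
    )
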