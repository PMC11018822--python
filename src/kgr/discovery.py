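"""Candidate intervention ranking and closed-discovery mechanism mining.

*Open discovery*: fix the relation (PREVENTS by default) and the tail (the
target disease), score every non-pharmacological-intervention node of a
class (dietary supplements, DS, or complementary and integrative health
practices, CIH) as head, drop triples already present in the graph, and
rank the rest by model plausibility.  The reported "probability" column is
a per-class min-max normalization of the plausibility score — an
order-preserving rescaling to [0, 1], not a calibrated posterior.

*Closed discovery*: for a fixed intervention/disease pair, enumerate
two-hop mechanism paths matching a relation-constrained discovery pattern,
subject to a negation clause (the direct intervention-PREVENTS-disease link
must be unknown).  DS candidates use the constrained pattern
INHIBITS|INTERACTS_WITH followed by AFFECTS|CAUSES|PREDISPOSES|
ASSOCIATED_WITH; CIH candidates leave both hops unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import KnowledgeGraph
from .evaluation import Scorer

__all__ = [
    "DiscoveryPattern",
    "MechanismPath",
    "DS_PATTERN",
    "CIH_PATTERN",
    "score_candidates",
    "match_pattern",
    "mine_mechanisms",
    "paths_to_frame",
]


@dataclass(frozen=True)
class DiscoveryPattern:
    """Two-hop relation template with a negation clause.

    ``hop1_relations``/``hop2_relations`` constrain the predicates of the
    intervention→intermediate and intermediate→disease hops; ``None`` means
    any predicate.  The negation clause asserts that
    (intervention, negation_relation, disease) must NOT already be known.
    """

    head_class: str  # "DS" or "CIH"
    hop1_relations: frozenset[str] | None
    hop2_relations: frozenset[str] | None
    negation_relation: str = "PREVENTS"

    def __post_init__(self) -> None:
        if self.head_class not in ("DS", "CIH"):
            raise ValueError("head_class must be 'DS' or 'CIH'")


DS_PATTERN = DiscoveryPattern(
    head_class="DS",
    hop1_relations=frozenset({"INHIBITS", "INTERACTS_WITH"}),
    hop2_relations=frozenset({"AFFECTS", "CAUSES", "PREDISPOSES", "ASSOCIATED_WITH"}),
)

CIH_PATTERN = DiscoveryPattern(head_class="CIH", hop1_relations=None, hop2_relations=None)


@dataclass(frozen=True)
class MechanismPath:
    """An intervention→intermediate→disease path matching a pattern."""

    intervention_id: str
    intermediate_id: str
    disease_id: str
    hop1_predicate: str
    hop2_predicate: str
    hop1_doc_ids: tuple[str, ...] = ()
    hop2_doc_ids: tuple[str, ...] = ()


def score_candidates(
    model: Scorer,
    kg: KnowledgeGraph,
    npi_class: str,
    disease_id: str,
    relation: str = "PREVENTS",
) -> pd.DataFrame:
    """Rank every NPI node of a class as head of (npi, relation, disease).

    Triples already present in the graph are excluded (only novel links are
    of interest).  Columns: npi_id, npi_class, score, probability, rank;
    rows sorted by descending score with deterministic id tie-break.
    """
    if not kg.has_entity(disease_id):
        raise ValueError(f"disease {disease_id!r} not in the graph vocabulary")
    npis = kg.npi_entities(npi_class)
    if not npis:
        raise ValueError(f"no NPI nodes of class {npi_class!r} in the graph")
    novel = [e for e in npis if not kg.contains_triple(e, relation, disease_id)]
    if not novel:
        return pd.DataFrame(columns=["npi_id", "npi_class", "score", "probability", "rank"])
    scores = model.plausibility(novel, [relation] * len(novel), [disease_id] * len(novel))
    scores = np.asarray(scores, float)
    lo, hi = scores.min(), scores.max()
    prob = np.ones_like(scores) if hi == lo else (scores - lo) / (hi - lo)
    frame = pd.DataFrame(
        {"npi_id": novel, "npi_class": npi_class, "score": scores, "probability": prob}
    )
    frame = frame.sort_values(
        ["score", "npi_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def match_pattern(
    kg: KnowledgeGraph,
    pattern: DiscoveryPattern,
    intervention_id: str,
    disease_id: str,
) -> list[MechanismPath]:
    """Enumerate all two-hop paths matching the pattern's relation sets.

    Returns the empty list when the negation triple exists.  Paths are
    deduplicated by (intermediate, hop1 predicate, hop2 predicate) and
    returned in deterministic sorted order.
    """
    if kg.contains_triple(intervention_id, pattern.negation_relation, disease_id):
        return []
    hop1_rels = kg.relations if pattern.hop1_relations is None else [
        r for r in kg.relations if r in pattern.hop1_relations
    ]
    hop2_rels = kg.relations if pattern.hop2_relations is None else [
        r for r in kg.relations if r in pattern.hop2_relations
    ]
    found: dict[tuple[str, str, str], MechanismPath] = {}
    for r1 in hop1_rels:
        for mid in kg.neighbors_out(intervention_id, r1):
            for r2 in hop2_rels:
                if not kg.contains_triple(mid, r2, disease_id):
                    continue
                key = (mid, r1, r2)
                if key in found:
                    continue
                found[key] = MechanismPath(
                    intervention_id=intervention_id,
                    intermediate_id=mid,
                    disease_id=disease_id,
                    hop1_predicate=r1,
                    hop2_predicate=r2,
                    hop1_doc_ids=kg.info(intervention_id, r1, mid).doc_ids,
                    hop2_doc_ids=kg.info(mid, r2, disease_id).doc_ids,
                )
    return [found[k] for k in sorted(found)]


def mine_mechanisms(
    kg: KnowledgeGraph,
    candidates: pd.DataFrame,
    disease_id: str,
    top_n: int = 10,
    patterns: Mapping[str, DiscoveryPattern] | None = None,
) -> dict[str, list[MechanismPath]]:
    """Apply the class-appropriate pattern to the top-ranked candidates.

    DS candidates use the constrained pattern, CIH the unconstrained one
    (overridable via ``patterns``).  Candidates beyond ``top_n`` are
    ignored; a shorter table is processed in full.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    patterns = patterns or {"DS": DS_PATTERN, "CIH": CIH_PATTERN}
    out: dict[str, list[MechanismPath]] = {}
    for _, row in candidates.head(top_n).iterrows():
        pattern = patterns[row["npi_class"]]
        out[row["npi_id"]] = match_pattern(kg, pattern, row["npi_id"], disease_id)
    return out


def paths_to_frame(paths_by_candidate: Mapping[str, Sequence[MechanismPath]]) -> pd.DataFrame:
    """Flatten mined paths into a table for export."""
    rows = []
    for cand, paths in paths_by_candidate.items():
        for p in paths:
            rows.append(
                {
                    "intervention": p.intervention_id,
                    "hop1_predicate": p.hop1_predicate,
                    "intermediate": p.intermediate_id,
                    "hop2_predicate": p.hop2_predicate,
                    "disease": p.disease_id,
                    "doc_ids": "|".join((*p.hop1_doc_ids, *p.hop2_doc_ids)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "intervention",
            "hop1_predicate",
            "intermediate",
            "hop2_predicate",
            "disease",
            "doc_ids",
        ],
    )
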