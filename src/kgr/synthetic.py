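"""Synthetic literature-like knowledge graphs with planted structure.

The generator emulates the shape of a biomedical predication corpus:

* typed entities — Drugs, Diseases, Genes/Proteins, dietary supplements
  (DS, D-prefixed identifiers) and complementary/integrative health
  practices (CIH);
* fifteen predicate types with a strongly imbalanced frequency profile
  matching a large literature-derived graph (COEXISTS_WITH ≈ 33% of edges
  down to MANIFESTATION_OF ≈ 0.2%);
* per-instance provenance (document identifier, publication date drawn
  uniformly over a configurable range);
* latent low-rank structure: entity/relation vectors are drawn first and
  the emitted triples are the best-scoring type-compatible candidate pairs
  under a TransE or DistMult latent model, with a configurable fraction
  replaced by uniform noise;
* planted two-hop mechanisms (NPI-INHIBITS-Gene, Gene-CAUSES-Disease) whose
  direct (NPI, PREVENTS, Disease) closures are partially held out of the
  emitted graph — the recovery targets for link-prediction evaluation.

Everything is driven by one seed; the same configuration yields a
byte-identical predication stream.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import EntityMeta, Predication
from .filtering import ContingencyTable, DEFAULT_RELATION_WHITELIST

__all__ = [
    "TABLE_PROFILE",
    "TYPE_COMPATIBILITY",
    "SynthConfig",
    "GroundTruth",
    "generate",
    "ContingencyConfig",
    "independent_joint",
    "emit_contingency_stream",
    "sample_contingency_table",
]

#: Relation frequency profile (proportions of the emitted triple budget),
#: following the relation imbalance of a large literature-derived graph.
TABLE_PROFILE: dict[str, float] = {
    "COEXISTS_WITH": 0.3268,
    "INTERACTS_WITH": 0.2059,
    "AFFECTS": 0.0952,
    "TREATS": 0.0893,
    "CAUSES": 0.0749,
    "ASSOCIATED_WITH": 0.0453,
    "INHIBITS": 0.0385,
    "STIMULATES": 0.0276,
    "DISRUPTS": 0.0228,
    "AUGMENTS": 0.0215,
    "PRODUCES": 0.0215,
    "PREDISPOSES": 0.0133,
    "PREVENTS": 0.0120,
    "COMPLICATES": 0.0035,
    "MANIFESTATION_OF": 0.0019,
}

ENTITY_TYPES = ("Drug", "Disease", "Gene", "DS", "CIH")

#: Which (head type, tail type) pairs each predicate may connect.  This is a
#: package construction standing in for the semantic-network constraints a
#: curated vocabulary would impose; it is configuration-visible.
TYPE_COMPATIBILITY: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "COEXISTS_WITH": (("Drug", "DS", "Gene"), ("Drug", "DS", "Gene")),
    "INTERACTS_WITH": (("Drug", "DS", "CIH", "Gene"), ("Drug", "DS", "Gene")),
    "AFFECTS": (("Drug", "DS", "CIH", "Gene"), ("Disease", "Gene")),
    "TREATS": (("Drug", "DS", "CIH"), ("Disease",)),
    "CAUSES": (("Drug", "Gene", "Disease"), ("Disease",)),
    "ASSOCIATED_WITH": (("Drug", "DS", "CIH", "Gene"), ("Disease",)),
    "INHIBITS": (("Drug", "DS", "CIH", "Gene"), ("Gene",)),
    "STIMULATES": (("Drug", "DS", "CIH", "Gene"), ("Gene",)),
    "DISRUPTS": (("Drug", "DS"), ("Gene", "Disease")),
    "AUGMENTS": (("Drug", "DS", "Gene"), ("Gene", "Disease")),
    "PRODUCES": (("Drug", "DS", "Gene"), ("Drug", "Gene")),
    "PREDISPOSES": (("Drug", "Gene", "Disease"), ("Disease",)),
    "PREVENTS": (("Drug", "DS", "CIH"), ("Disease",)),
    "COMPLICATES": (("Disease",), ("Disease",)),
    "MANIFESTATION_OF": (("Disease",), ("Disease",)),
}

_GROUP_OF = {
    "Drug": ("phsu", "Chemicals & Drugs"),
    "Disease": ("dsyn", "Disorders"),
    "Gene": ("gngm", "Genes & Molecular Sequences"),
    "DS": ("phsu", "Chemicals & Drugs"),
    "CIH": ("topp", "Procedures"),
}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic corpus.

    Defaults are sized so that every model in this package trains in
    minutes on one CPU while keeping the relation imbalance and typed
    structure of the real corpora the pipeline targets.
    """

    n_entities: Mapping[str, int] = field(
        default_factory=lambda: {"Drug": 150, "Disease": 100, "Gene": 150, "DS": 50, "CIH": 50}
    )
    relation_profile: Mapping[str, float] = field(default_factory=lambda: dict(TABLE_PROFILE))
    latent_model: str = "TransE"
    latent_dim: int = 32
    n_triples: int = 5000
    noise_fraction: float = 0.1
    date_range: tuple[datetime.date, datetime.date] = (
        datetime.date(2015, 1, 1),
        datetime.date(2022, 12, 31),
    )
    n_planted_mechanisms: int = 20
    n_heldout_prevents: int = 10
    min_planted_degree: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.relation_profile.values()) - 1.0) > 1e-9:
            raise ValueError("relation_profile proportions must sum to 1")
        if not (0.0 <= self.noise_fraction < 1.0):
            raise ValueError("noise_fraction must lie in [0, 1)")
        if self.n_heldout_prevents > self.n_planted_mechanisms:
            raise ValueError("cannot hold out more closures than planted mechanisms")
        if self.latent_model not in ("TransE", "DistMult"):
            raise ValueError("latent_model must be 'TransE' or 'DistMult'")
        for rel in self.relation_profile:
            if rel not in TYPE_COMPATIBILITY:
                raise ValueError(f"no type-compatibility rule for relation {rel!r}")


@dataclass
class GroundTruth:
    """What the generator knows and the trained models must recover."""

    entities: list[str]
    entity_type: dict[str, str]
    meta: dict[str, EntityMeta]
    latent_entities: np.ndarray
    latent_relations: dict[str, np.ndarray]
    latent_model: str
    planted_mechanisms: list[tuple[str, str, str]]  # (npi, gene, disease)
    heldout_prevents: list[tuple[str, str, str]]
    emitted_triples: list[tuple[str, str, str]]


def _entity_ids(cfg: SynthConfig) -> tuple[list[str], dict[str, str]]:
    prefix = {"Drug": "C1", "Disease": "C2", "Gene": "C3", "DS": "DC4", "CIH": "C5"}
    ids: list[str] = []
    type_of: dict[str, str] = {}
    for typ in ENTITY_TYPES:
        for i in range(int(cfg.n_entities.get(typ, 0))):
            cid = f"{prefix[typ]}{i:06d}"
            ids.append(cid)
            type_of[cid] = typ
    return ids, type_of


def _latent_score(
    model: str, E: np.ndarray, rvec: np.ndarray, hi: np.ndarray, ti: np.ndarray
) -> np.ndarray:
    """Plausibility (higher = better) of candidate pairs under the latents."""
    if model == "TransE":
        return -np.linalg.norm(E[hi] + rvec - E[ti], axis=-1)
    return (E[hi] * rvec * E[ti]).sum(axis=-1)


def _quotas(cfg: SynthConfig) -> dict[str, int]:
    """Largest-remainder allocation of the triple budget to relations."""
    raw = {r: p * cfg.n_triples for r, p in cfg.relation_profile.items()}
    base = {r: int(v) for r, v in raw.items()}
    short = cfg.n_triples - sum(base.values())
    order = sorted(raw, key=lambda r: (raw[r] - base[r], r), reverse=True)
    for r in order[:short]:
        base[r] += 1
    return base


def generate(cfg: SynthConfig) -> tuple[list[Predication], GroundTruth]:
    """Sample a predication stream plus its generating ground truth."""
    for rel, (hts, tts) in TYPE_COMPATIBILITY.items():
        if rel in cfg.relation_profile and cfg.relation_profile[rel] > 0:
            if not any(cfg.n_entities.get(t, 0) > 0 for t in hts) or not any(
                cfg.n_entities.get(t, 0) > 0 for t in tts
            ):
                raise ValueError(f"relation {rel!r} has no entities of a required type")
    rng = np.random.default_rng(cfg.seed)
    ids, type_of = _entity_ids(cfg)
    idx_of = {e: i for i, e in enumerate(ids)}
    by_type = {t: np.array([idx_of[e] for e in ids if type_of[e] == t], dtype=int) for t in ENTITY_TYPES}

    # latent structure
    E = rng.normal(size=(len(ids), cfg.latent_dim))
    E /= np.linalg.norm(E, axis=1, keepdims=True)
    rels = list(cfg.relation_profile)
    R = {r: rng.normal(scale=0.5 / np.sqrt(cfg.latent_dim), size=cfg.latent_dim) for r in rels}

    def candidate_pairs(rel: str) -> tuple[np.ndarray, np.ndarray]:
        hts, tts = TYPE_COMPATIBILITY[rel]
        hi = np.concatenate([by_type[t] for t in hts if by_type[t].size]) if hts else np.array([], int)
        ti = np.concatenate([by_type[t] for t in tts if by_type[t].size]) if tts else np.array([], int)
        H, T = np.meshgrid(hi, ti, indexing="ij")
        H, T = H.ravel(), T.ravel()
        keep = H != T
        return H[keep], T[keep]

    # emit the best-scoring type-compatible triples per relation quota
    quotas = _quotas(cfg)
    triples: dict[tuple[str, str, str], None] = {}
    for rel in rels:
        q = quotas[rel]
        if q == 0:
            continue
        H, T = candidate_pairs(rel)
        s = _latent_score(cfg.latent_model, E, R[rel], H, T)
        order = np.argsort(-s, kind="stable")
        got = 0
        for k in order:
            if got >= q:
                break
            trip = (ids[int(H[k])], rel, ids[int(T[k])])
            if trip in triples:
                continue
            triples[trip] = None
            got += 1

    # replace a fraction with uniform random typed triples (noise)
    keys = list(triples)
    n_noise = int(round(cfg.noise_fraction * len(keys)))
    if n_noise:
        victims = rng.choice(len(keys), size=n_noise, replace=False)
        for v in victims:
            old = keys[int(v)]
            rel = old[1]
            H, T = candidate_pairs(rel)
            while True:
                k = int(rng.integers(H.size))
                trip = (ids[int(H[k])], rel, ids[int(T[k])])
                if trip not in triples:
                    break
            del triples[old]
            triples[trip] = None

    # planted mechanisms: the strongest latent PREVENTS pairs per NPI class,
    # restricted to interventions with enough corpus attestation to be
    # learnable, closed through the gene that best supports both hops
    degree: dict[str, int] = {e: 0 for e in ids}
    for h, _, t in triples:
        degree[h] += 1
        degree[t] += 1
    prevents_vec = R["PREVENTS"]
    planted: list[tuple[str, str, str]] = []  # (npi, gene, disease)
    dis = by_type["Disease"]
    genes = by_type["Gene"]
    per_class = {
        "DS": (cfg.n_planted_mechanisms + 1) // 2,
        "CIH": cfg.n_planted_mechanisms // 2,
    }
    for klass in ("DS", "CIH"):
        heads = by_type[klass]
        if heads.size == 0 or per_class[klass] == 0:
            continue
        H, T = np.meshgrid(heads, dis, indexing="ij")
        s = _latent_score(cfg.latent_model, E, prevents_vec, H.ravel(), T.ravel())
        order = np.argsort(-s, kind="stable")
        eligible = [
            k for k in order if degree[ids[int(H.ravel()[k])]] >= cfg.min_planted_degree
        ]
        if len(eligible) < per_class[klass]:  # fall back to best-attested rest
            rest = sorted(
                (k for k in order if k not in set(eligible)),
                key=lambda k: -degree[ids[int(H.ravel()[k])]],
            )
            eligible = eligible + rest
        seen_npi: set[str] = set()
        picked = 0
        for k in eligible:
            if picked >= per_class[klass]:
                break
            npi_i, dis_i = int(H.ravel()[k]), int(T.ravel()[k])
            if ids[npi_i] in seen_npi:  # one mechanism per intervention
                continue
            seen_npi.add(ids[npi_i])
            g_scores = _latent_score(
                cfg.latent_model, E, R["INHIBITS"], np.full(genes.size, npi_i), genes
            ) + _latent_score(cfg.latent_model, E, R["CAUSES"], genes, np.full(genes.size, dis_i))
            gene_i = int(genes[int(np.argmax(g_scores))])
            planted.append((ids[npi_i], ids[gene_i], ids[dis_i]))
            picked += 1

    # interleave classes so the held-out set covers both
    ds_first = [m for m in planted if type_of[m[0]] == "DS"]
    cih_first = [m for m in planted if type_of[m[0]] == "CIH"]
    interleaved: list[tuple[str, str, str]] = []
    for a, b in zip(ds_first, cih_first):
        interleaved.extend((a, b))
    longer = ds_first if len(ds_first) > len(cih_first) else cih_first
    interleaved.extend(longer[min(len(ds_first), len(cih_first)):])
    planted = interleaved
    heldout = [(m[0], "PREVENTS", m[2]) for m in planted[: cfg.n_heldout_prevents]]
    heldout_set = set(heldout)

    # plant the mechanism hop-triples and the closures; held-out closures
    # are removed from the emitted graph
    for npi, gene, disease in planted:
        triples.setdefault((npi, "INHIBITS", gene))
        triples.setdefault((gene, "CAUSES", disease))
    for npi, rel, disease in ((m[0], "PREVENTS", m[2]) for m in planted):
        if (npi, rel, disease) not in heldout_set:
            triples.setdefault((npi, rel, disease))
    for trip in heldout:
        triples.pop(trip, None)

    # provenance: instance multiplicities, documents, dates
    span = (cfg.date_range[1] - cfg.date_range[0]).days
    preds: list[Predication] = []
    doc_counter = 0
    for h, r, t in triples:
        n_inst = 1 + int(rng.binomial(2, 0.15))
        for _ in range(n_inst):
            doc_counter += 1
            date = cfg.date_range[0] + datetime.timedelta(days=int(rng.integers(span + 1)))
            preds.append(
                Predication(
                    subject_id=h,
                    predicate=r,
                    object_id=t,
                    doc_id=f"D{doc_counter:07d}",
                    pub_date=date,
                    sentence_ref=f"s{doc_counter:07d}",
                )
            )
    perm = rng.permutation(len(preds))
    preds = [preds[int(i)] for i in perm]

    meta = {
        e: EntityMeta(
            concept_id=e,
            name=f"{type_of[e].lower()}-{e}",
            semantic_type=_GROUP_OF[type_of[e]][0],
            semantic_group=_GROUP_OF[type_of[e]][1],
            npi_class=type_of[e] if type_of[e] in ("DS", "CIH") else "none",
        )
        for e in ids
    }
    gt = GroundTruth(
        entities=ids,
        entity_type=type_of,
        meta=meta,
        latent_entities=E,
        latent_relations=R,
        latent_model=cfg.latent_model,
        planted_mechanisms=planted,
        heldout_prevents=heldout,
        emitted_triples=list(triples),
    )
    return preds, gt


# ---------------------------------------------------------------------------
# Contingency streams for association-statistic testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyConfig:
    """Generating joint over (subject, predicate, object) presence.

    ``joint[i, j, k]`` is the probability that an instance falls in cell
    (i, j, k) of the 2x2x2 table, index 0 = the target term is present.
    """

    joint: tuple  # nested 2x2x2 probabilities
    n_instances: int = 1000
    subject: str = "C0000001"
    predicate: str = "TREATS"
    object_: str = "C0000002"
    seed: int = 0

    def joint_array(self) -> np.ndarray:
        arr = np.asarray(self.joint, float)
        if arr.shape != (2, 2, 2) or (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("joint must be a 2x2x2 probability table summing to 1")
        return arr


def independent_joint(p_s: float, p_p: float, p_o: float) -> tuple:
    """Joint with the three axes mutually independent."""
    ps = np.array([p_s, 1 - p_s])
    pp = np.array([p_p, 1 - p_p])
    po = np.array([p_o, 1 - p_o])
    return tuple(map(tuple, map(tuple, np.einsum("i,j,k->ijk", ps, pp, po))))  # type: ignore[arg-type]


def sample_contingency_table(
    joint: np.ndarray, n: int, rng: np.random.Generator
) -> ContingencyTable:
    """Multinomial draw of a 2x2x2 table from a generating joint."""
    counts = rng.multinomial(n, np.asarray(joint, float).ravel()).reshape(2, 2, 2)
    return ContingencyTable(n=counts)


def emit_contingency_stream(cfg: ContingencyConfig) -> list[Predication]:
    """Materialize a predication stream realizing the generating joint.

    "Absent" slots cycle through filler identifiers so absent instances do
    not accidentally re-create the target triple.
    """
    rng = np.random.default_rng(cfg.seed)
    joint = cfg.joint_array()
    cells = rng.choice(8, size=cfg.n_instances, p=joint.ravel())
    alt_rels = [r for r in DEFAULT_RELATION_WHITELIST if r != cfg.predicate]
    date = datetime.date(2020, 1, 1)
    preds: list[Predication] = []
    for idx, cell in enumerate(cells):
        i, j, k = cell >> 2 & 1, cell >> 1 & 1, cell & 1
        subj = cfg.subject if i == 0 else f"CS{idx % 7:06d}"
        rel = cfg.predicate if j == 0 else alt_rels[idx % len(alt_rels)]
        obj = cfg.object_ if k == 0 else f"CO{idx % 5:06d}"
        preds.append(
            Predication(
                subject_id=subj,
                predicate=rel,
                object_id=obj,
                doc_id=f"D{idx:07d}",
                pub_date=date,
            )
        )
    return preds
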