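"""Core data model: predications, entity metadata, and the knowledge graph.

A *predication* is one subject-predicate-object assertion extracted from a
sentence of a publication, carried together with its provenance (document
identifier and publication date).  Many predication instances may assert the
same (head, relation, tail) triple; the knowledge graph deduplicates them,
keeping the instance count and the earliest publication date per triple.

Concept identifiers are CUI-like opaque strings.  Dietary-supplement (DS)
concepts are marked by prefixing the letter ``D`` to their CUI (e.g.
``DC0633482`` for myrtol), mirroring the convention of supplement-focused
knowledge graphs.
"""

from __future__ import annotations

import csv
import datetime
import os
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Predication",
    "EntityMeta",
    "TripleInfo",
    "KnowledgeGraph",
    "Dialect",
    "PredicationParseError",
    "read_predications",
    "write_predications",
    "read_entity_meta",
    "write_entity_meta",
    "build_graph",
    "mark_ds_nodes",
    "save_graph",
    "load_graph",
]

DS_PREFIX = "D"

PREDICATION_COLUMNS = (
    "subject_id",
    "predicate",
    "object_id",
    "doc_id",
    "pub_date",
    "sentence_ref",
)

META_COLUMNS = ("concept_id", "name", "semantic_type", "semantic_group", "npi_class")

NPI_CLASSES = ("DS", "CIH", "none")


@dataclass(frozen=True, slots=True)
class Predication:
    """One extracted triple instance with provenance."""

    subject_id: str
    predicate: str
    object_id: str
    doc_id: str
    pub_date: datetime.date
    sentence_ref: str = ""

    def __post_init__(self) -> None:
        if not self.subject_id or not self.object_id:
            raise ValueError("subject_id and object_id must be non-empty")
        if not self.predicate:
            raise ValueError("predicate must be non-empty")


@dataclass(frozen=True, slots=True)
class EntityMeta:
    """Display and typing metadata for one concept."""

    concept_id: str
    name: str = ""
    semantic_type: str = ""
    semantic_group: str = ""
    npi_class: str = "none"

    def __post_init__(self) -> None:
        if self.npi_class not in NPI_CLASSES:
            raise ValueError(f"npi_class must be one of {NPI_CLASSES}, got {self.npi_class!r}")


#: Number of provenance document identifiers retained per triple.
MAX_DOC_IDS = 10


@dataclass(frozen=True, slots=True)
class TripleInfo:
    """Per-triple annotation: multiplicity, earliest attestation, provenance."""

    count: int
    first_date: datetime.date
    doc_ids: tuple[str, ...] = ()


class KnowledgeGraph:
    """Deduplicated, typed, labeled directed multigraph.

    Entities and relations are kept in first-appearance order so that any
    downstream embedding initialization is reproducible given a seed.  The
    triple store maps ``(head, relation, tail)`` to a :class:`TripleInfo`;
    membership queries are O(1), as required by filtered corruption and the
    negation clause of discovery patterns.
    """

    def __init__(
        self,
        triples: Mapping[tuple[str, str, str], TripleInfo],
        meta: Mapping[str, EntityMeta] | None = None,
        entity_order: Sequence[str] | None = None,
        relation_order: Sequence[str] | None = None,
    ) -> None:
        self._triples: dict[tuple[str, str, str], TripleInfo] = dict(triples)
        # vocabularies cover exactly the endpoints / predicates present,
        # in first-appearance order (or the caller-supplied order)
        ents: dict[str, None] = {}
        rels: dict[str, None] = {}
        if entity_order is not None:
            for e in entity_order:
                ents.setdefault(e)
        if relation_order is not None:
            for r in relation_order:
                rels.setdefault(r)
        for h, r, t in self._triples:
            ents.setdefault(h)
            rels.setdefault(r)
            ents.setdefault(t)
        touched: set[str] = set()
        used_rels: set[str] = set()
        for h, r, t in self._triples:
            touched.add(h)
            touched.add(t)
            used_rels.add(r)
        self.entities: list[str] = [e for e in ents if e in touched]
        self.relations: list[str] = [r for r in rels if r in used_rels]
        self._entity_index = {e: i for i, e in enumerate(self.entities)}
        self._relation_index = {r: i for i, r in enumerate(self.relations)}
        self.meta: dict[str, EntityMeta] = {}
        meta = meta or {}
        for e in self.entities:
            self.meta[e] = meta.get(e, EntityMeta(concept_id=e))
        self._out: dict[str, dict[str, list[str]]] = {r: {} for r in self.relations}
        self._in: dict[str, dict[str, list[str]]] = {r: {} for r in self.relations}
        for h, r, t in self._triples:
            self._out[r].setdefault(h, []).append(t)
            self._in[r].setdefault(t, []).append(h)

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(self._triples)

    def __contains__(self, hrt: tuple[str, str, str]) -> bool:
        return hrt in self._triples

    def contains_triple(self, head: str, relation: str, tail: str) -> bool:
        return (head, relation, tail) in self._triples

    def info(self, head: str, relation: str, tail: str) -> TripleInfo:
        return self._triples[(head, relation, tail)]

    @property
    def triples(self) -> dict[tuple[str, str, str], TripleInfo]:
        return self._triples

    def entity_index(self, entity: str) -> int:
        return self._entity_index[entity]

    def relation_index(self, relation: str) -> int:
        return self._relation_index[relation]

    def has_entity(self, entity: str) -> bool:
        return entity in self._entity_index

    def neighbors_out(self, head: str, relation: str) -> list[str]:
        return self._out.get(relation, {}).get(head, [])

    def neighbors_in(self, tail: str, relation: str) -> list[str]:
        return self._in.get(relation, {}).get(tail, [])

    def out_degree(self, entity: str) -> int:
        return sum(len(self._out[r].get(entity, ())) for r in self.relations)

    def in_degree(self, entity: str) -> int:
        return sum(len(self._in[r].get(entity, ())) for r in self.relations)

    def subgraph(self, keep: Callable[[tuple[str, str, str]], bool]) -> "KnowledgeGraph":
        """New graph containing the triples for which ``keep`` is true.

        Vocabulary order of surviving entities/relations is preserved.
        """
        kept = {k: v for k, v in self._triples.items() if keep(k)}
        return KnowledgeGraph(
            kept,
            meta=self.meta,
            entity_order=self.entities,
            relation_order=self.relations,
        )

    def equal_triples(self, other: "KnowledgeGraph") -> bool:
        return self._triples == other._triples

    def npi_entities(self, npi_class: str) -> list[str]:
        return [e for e in self.entities if self.meta[e].npi_class == npi_class]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class Dialect:
    """Column layout of a delimited predication file."""

    delimiter: str = "\t"
    date_format: str = "%Y-%m-%d"
    has_header: bool = True
    columns: tuple[str, ...] = PREDICATION_COLUMNS


class PredicationParseError(ValueError):
    """Raised in strict mode when any row of a predication file is malformed."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {n}: {msg}" for n, msg in errors[:20])
        more = "" if len(errors) <= 20 else f" (+{len(errors) - 20} more)"
        super().__init__(f"{len(errors)} malformed predication row(s): {lines}{more}")


def _parse_row(
    row: Sequence[str], columns: Sequence[str], date_format: str
) -> Predication:
    if len(row) < len(columns) - (1 if columns[-1] == "sentence_ref" else 0):
        raise ValueError(f"expected {len(columns)} fields, got {len(row)}")
    vals = dict(zip(columns, list(row) + [""] * (len(columns) - len(row))))
    date = datetime.datetime.strptime(vals["pub_date"].strip(), date_format).date()
    return Predication(
        subject_id=vals["subject_id"].strip(),
        predicate=vals["predicate"].strip(),
        object_id=vals["object_id"].strip(),
        doc_id=vals["doc_id"].strip(),
        pub_date=date,
        sentence_ref=vals.get("sentence_ref", "").strip(),
    )


def read_predications(
    path: str | os.PathLike[str],
    dialect: Dialect = Dialect(),
    strict: bool = True,
) -> list[Predication]:
    """Read a delimited predication file, preserving row order.

    In strict mode any malformed row (bad date, missing field, empty
    endpoint) aborts the read with a :class:`PredicationParseError` naming
    the offending line numbers; in lenient mode such rows are dropped and
    counted in the error list attached to no exception (a summary is
    returned implicitly by the shorter list).
    """
    preds: list[Predication] = []
    errors: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and dialect.has_header:
                continue
            try:
                preds.append(_parse_row(row, dialect.columns, dialect.date_format))
            except (ValueError, KeyError) as exc:
                errors.append((lineno, str(exc)))
    if errors and strict:
        raise PredicationParseError(errors)
    return preds


def write_predications(
    path: str | os.PathLike[str],
    preds: Iterable[Predication],
    dialect: Dialect = Dialect(),
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        if dialect.has_header:
            writer.writerow(dialect.columns)
        for p in preds:
            writer.writerow(
                [
                    p.subject_id,
                    p.predicate,
                    p.object_id,
                    p.doc_id,
                    p.pub_date.strftime(dialect.date_format),
                    p.sentence_ref,
                ]
            )


def read_entity_meta(path: str | os.PathLike[str]) -> dict[str, EntityMeta]:
    meta: dict[str, EntityMeta] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            m = EntityMeta(
                concept_id=row["concept_id"],
                name=row.get("name", ""),
                semantic_type=row.get("semantic_type", ""),
                semantic_group=row.get("semantic_group", ""),
                npi_class=row.get("npi_class") or "none",
            )
            if m.concept_id in meta:
                raise ValueError(f"duplicate concept_id {m.concept_id!r} in metadata")
            meta[m.concept_id] = m
    return meta


def write_entity_meta(path: str | os.PathLike[str], meta: Mapping[str, EntityMeta]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(META_COLUMNS)
        for m in meta.values():
            writer.writerow([m.concept_id, m.name, m.semantic_type, m.semantic_group, m.npi_class])


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_graph(
    preds: Iterable[Predication],
    meta: Mapping[str, EntityMeta] | None = None,
) -> KnowledgeGraph:
    """Deduplicate predication instances into a knowledge graph.

    Predicates are uppercased and trimmed on ingest; concept identifiers are
    taken verbatim.  Each distinct ``(head, relation, tail)`` keeps its
    multiplicity in the input stream and the earliest publication date (the
    date a link first became known, which time-sliced evaluation relies on).
    """
    counts: dict[tuple[str, str, str], int] = {}
    first: dict[tuple[str, str, str], datetime.date] = {}
    docs: dict[tuple[str, str, str], list[str]] = {}
    order: dict[tuple[str, str, str], None] = {}
    for p in preds:
        key = (p.subject_id, p.predicate.strip().upper(), p.object_id)
        counts[key] = counts.get(key, 0) + 1
        if key not in first or p.pub_date < first[key]:
            first[key] = p.pub_date
        ds = docs.setdefault(key, [])
        if p.doc_id:
            ds.append(p.doc_id)
        order.setdefault(key)
    # provenance capped at MAX_DOC_IDS, canonically ordered so the graph is
    # invariant to permutations of the input stream
    triples = {
        k: TripleInfo(
            count=counts[k],
            first_date=first[k],
            doc_ids=tuple(sorted(set(docs[k]))[:MAX_DOC_IDS]),
        )
        for k in order
    }
    return KnowledgeGraph(triples, meta=meta)


def _merge_info(a: TripleInfo, b: TripleInfo) -> TripleInfo:
    doc_ids = a.doc_ids + tuple(d for d in b.doc_ids if d not in a.doc_ids)
    return TripleInfo(
        count=a.count + b.count,
        first_date=min(a.first_date, b.first_date),
        doc_ids=doc_ids[:MAX_DOC_IDS],
    )


def mark_ds_nodes(kg: KnowledgeGraph, ds_ids: Iterable[str]) -> KnowledgeGraph:
    """Rename every dietary-supplement concept with the D-prefix.

    ``ds_ids`` are given in prefix-free form (``C0633482`` marks the node as
    ``DC0633482``).  Renaming is idempotent: identifiers that already carry
    the prefix are left alone.  Triples touching renamed nodes merge with any
    pre-existing D-prefixed duplicates, summing counts and keeping the
    earliest date.  If both the bare and prefixed form of a concept exist
    with conflicting metadata, the collision is reported as an error.
    """
    ds = set(ds_ids)

    def rename(e: str) -> str:
        return DS_PREFIX + e if e in ds else e

    collisions = []
    for e in ds:
        pref = DS_PREFIX + e
        if e in kg.meta and pref in kg.meta:
            a, b = kg.meta[e], kg.meta[pref]
            if (a.name, a.semantic_type, a.semantic_group) != (
                b.name,
                b.semantic_type,
                b.semantic_group,
            ):
                collisions.append((e, pref))
    if collisions:
        raise ValueError(f"conflicting metadata for DS concepts: {collisions}")

    merged: dict[tuple[str, str, str], TripleInfo] = {}
    order: list[tuple[str, str, str]] = []
    for (h, r, t), info in kg.triples.items():
        key = (rename(h), r, rename(t))
        if key in merged:
            merged[key] = _merge_info(merged[key], info)
        else:
            merged[key] = info
            order.append(key)
    new_meta: dict[str, EntityMeta] = {}
    for e, m in kg.meta.items():
        ne = rename(e)
        nm = replace(m, concept_id=ne, npi_class="DS" if ne.startswith(DS_PREFIX) and (e in ds or m.npi_class == "DS") else m.npi_class)
        if ne not in new_meta:
            new_meta[ne] = nm
    ent_order = [rename(e) for e in kg.entities]
    return KnowledgeGraph({k: merged[k] for k in order}, meta=new_meta, entity_order=ent_order, relation_order=kg.relations)


# ---------------------------------------------------------------------------
# Directory serialization: entities.tsv / relations.tsv / triples.tsv
# ---------------------------------------------------------------------------


def save_graph(kg: KnowledgeGraph, directory: str | os.PathLike[str]) -> None:
    os.makedirs(directory, exist_ok=True)
    write_entity_meta(os.path.join(directory, "entities.tsv"), kg.meta)
    with open(os.path.join(directory, "relations.tsv"), "w", encoding="utf-8") as fh:
        fh.write("relation\n")
        for r in kg.relations:
            fh.write(r + "\n")
    with open(os.path.join(directory, "triples.tsv"), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["head", "relation", "tail", "count", "first_date", "doc_ids"])
        for (h, r, t), info in kg.triples.items():
            writer.writerow(
                [h, r, t, info.count, info.first_date.isoformat(), "|".join(info.doc_ids)]
            )


def load_graph(directory: str | os.PathLike[str]) -> KnowledgeGraph:
    meta = read_entity_meta(os.path.join(directory, "entities.tsv"))
    with open(os.path.join(directory, "relations.tsv"), encoding="utf-8") as fh:
        relations = [line.strip() for line in fh.readlines()[1:] if line.strip()]
    triples: dict[tuple[str, str, str], TripleInfo] = {}
    with open(os.path.join(directory, "triples.tsv"), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            triples[(row["head"], row["relation"], row["tail"])] = TripleInfo(
                count=int(row["count"]),
                first_date=datetime.date.fromisoformat(row["first_date"]),
                doc_ids=tuple(d for d in (row.get("doc_ids") or "").split("|") if d),
            )
    return KnowledgeGraph(triples, meta=meta, entity_order=list(meta), relation_order=relations)
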