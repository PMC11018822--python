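import datetime

import numpy as np
import pytest

from kgr import EntityMeta, Predication, SynthConfig, build_graph, generate


def make_pred(s, p, o, doc="D1", date="2020-06-15", ref=""):
    return Predication(
        subject_id=s,
        predicate=p,
        object_id=o,
        doc_id=doc,
        pub_date=datetime.date.fromisoformat(date),
        sentence_ref=ref,
    )


def random_predications(rng: np.random.Generator, n: int, n_ent: int = 40, n_rel: int = 5):
    ents = [f"C{i:04d}" for i in range(n_ent)]
    rels = [f"REL{i}" for i in range(n_rel)]
    base = datetime.date(2015, 1, 1)
    preds = []
    for k in range(n):
        s, o = rng.choice(n_ent, size=2, replace=False)
        preds.append(
            Predication(
                subject_id=ents[int(s)],
                predicate=rels[int(rng.integers(n_rel))],
                object_id=ents[int(o)],
                doc_id=f"D{k:05d}",
                pub_date=base + datetime.timedelta(days=int(rng.integers(2000))),
            )
        )
    return preds


@pytest.fixture(scope="session")
def small_synth():
    """A small planted corpus shared by tests that only need realistic shape."""
    cfg = SynthConfig(
        n_entities={"Drug": 40, "Disease": 25, "Gene": 40, "DS": 15, "CIH": 15},
        n_triples=900,
        n_planted_mechanisms=8,
        n_heldout_prevents=4,
        min_planted_degree=5,
        seed=11,
    )
    preds, gt = generate(cfg)
    kg = build_graph(preds, meta=gt.meta)
    return cfg, preds, gt, kg


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
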