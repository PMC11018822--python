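# kgr — knowledge-graph link prediction for intervention repurposing

`kgr` is a toolkit for literature-based discovery of candidate
interventions: it builds a knowledge graph from biomedical *predications*
(subject–predicate–object assertions extracted from publications, with
document and date provenance), filters it down to specific, informative
triples, trains link-prediction models over it, ranks candidate
non-pharmacological interventions (dietary supplements and
complementary/integrative health practices) against a target disease, and
mines two-hop mechanistic hypotheses for the top candidates.

It is aimed at computational drug-/intervention-repurposing work where the
evidence base is extracted literature rather than curated databases.

## What it implements

**Graph construction and filtering.** Predication streams are deduplicated
into a typed directed multigraph keeping per-triple instance counts,
earliest attestation dates and provenance. Preprocessing removes generic
concepts, excluded semantic groups and non-whitelisted predicates, then
prunes the least specific triples under a combined score of min–max
normalized endpoint degrees and the G² log-likelihood-ratio statistic

    G² = 2 Σ_ijk n_ijk log(n_ijk / m_ijk),   m_ijk = n_i·· n_·j· n_··k / T²

over the 2×2×2 occurrence table of (subject, predicate, object) across
predication instances — the likelihood-ratio test of mutual independence
(χ², 4 df). A pluggable boolean hook is the seam for external
triple-verification models.

**Six link-prediction models**, all with a uniform plausibility API:
TransE `||h + r − t||`, RotatE `||h ∘ r − t||` (complex rotations),
DistMult `hᵀ diag(r) t`, ComplEX `Re(hᵀ diag(r) conj(t))`, and two
relational graph convolutional networks — R-GCN (per-relation message
passing, DistMult decoder) and CompGCN (composition-based message passing
with subtraction / multiplication / circular correlation, ConvE decoder) —
trained with 1:20 filtered negative sampling; the GCNs minimize the
normalized binary cross-entropy `−(1/((1+ω)|ε̂|)) Σ y log l(s) +
(1−y) log(1−l(s))`. Everything runs on numpy via a small, finite-difference
tested autodiff engine; no GPU or deep-learning framework is required.

**Evaluation.** Chronological (time-sliced) 8:1:1 splits, filtered-
corruption ranking with mean-rank tie handling, MR / MRR / Hits@{1,3,10},
ROC and precision–recall curves with AUROC/AUPR, and ground-truth test
sets built from user-supplied head-concept lists.

**Discovery.** Candidate tables fixing the relation (PREVENTS) and the
disease tail, excluding known links, with a per-class min–max "probability"
column; and closed-discovery pattern mining (for DS candidates:
INHIBITS|INTERACTS_WITH then AFFECTS|CAUSES|PREDISPOSES|ASSOCIATED_WITH,
with an ANDNOT clause on the direct link; for CIH: unconstrained hops).

**Synthetic corpora.** A fully seeded generator producing literature-like
predication streams: typed entities, the heavy-tailed 15-relation frequency
profile of large predication corpora, latent low-rank structure, planted
two-hop mechanisms and held-out PREVENTS closures as recovery targets.

## Worked example

```python
import kgr

cfg = kgr.SynthConfig(
    n_entities={"Drug": 60, "Disease": 40, "Gene": 60, "DS": 20, "CIH": 20},
    n_triples=1500,
    seed=7,
)
preds, truth = kgr.generate(cfg)
kg = kgr.build_graph(preds, meta=truth.meta)
print(f"graph: {len(kg.entities)} entities, {len(kg.relations)} relations, {len(kg)} triples")

table = kgr.train_kge(kg, kgr.KGETrainConfig(
    model="TransE", hidden_dim=32, epochs=150, batch_size=512,
    learning_rate=0.01, optimizer="adam", seed=7,
))
model = kgr.KGEModel(table)

results = kgr.evaluate_ranking(model, kg, truth.heldout_prevents, n_negatives=100, seed=7)
report = kgr.metrics_from_ranks(results)
print(f"held-out links: MRR={report.mrr:.3f}  Hits@10={report.hits10:.2f}  MR={report.mr:.1f}")

disease = truth.heldout_prevents[0][2]
candidates = kgr.score_candidates(model, kg, "DS", disease)
print(candidates.head(3).to_string(index=False))
```

Output:

```
graph: 199 entities, 15 relations, 1518 triples
held-out links: MRR=0.716  Hits@10=0.95  MR=3.0
   npi_id npi_class     score  probability  rank
DC4000018        DS -0.496959     1.000000     1
DC4000001        DS -0.718322     0.783933     2
DC4000005        DS -0.750083     0.752931     3
```

The generator planted ten (NPI, PREVENTS, Disease) links and withheld them
from the emitted graph; after training, each held-out link is ranked
against 100 corruptions of its head and of its tail that do not form known
triples. `MRR=0.716` / `Hits@10=0.95` say the withheld links are almost
always recovered near the top. The candidate table then scores every
dietary-supplement node as a head for `(DS, PREVENTS, disease)`, drops
already-known links, and rescales scores to [0, 1] per class — here the
top-ranked supplement (probability 1.000) is one of the planted
interventions for that disease. `kgr.mine_mechanisms` returns the
supporting two-hop paths (e.g. NPI —INHIBITS→ gene —CAUSES→ disease) with
their provenance document ids.

The same pipeline is available from a shell via the `kgr` command
(`kgr simulate / build / filter / train / eval / discover / mechanisms`);
see `kgr --help`.

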