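# Methods

`kgr` implements a literature-based-discovery workflow for repurposing
non-pharmacological interventions (NPIs): build a knowledge graph from
extracted subject–predicate–object predications, filter it for specificity,
learn link-prediction models over it, rank candidate interventions against
a target disease, and mine two-hop mechanistic hypotheses. This note
records the models, the numerical choices, and the places where the design
was genuinely open.

## Data model

A *predication* is one extracted assertion with provenance (document id,
publication date). The knowledge graph deduplicates predications into
distinct `(head, relation, tail)` triples, keeping three annotations per
triple: instance count (needed by the G² statistic), earliest publication
date (needed by time slicing — the date a link first became known), and up
to ten provenance document ids (reported with mined mechanism paths).
Entity and relation vocabularies are kept in first-appearance order so
that seeded training is reproducible. Predicates are uppercased and trimmed
on ingest; concept identifiers are taken verbatim. Dietary-supplement (DS)
concepts are marked by prefixing `D` to the concept identifier; marking is
idempotent and merges any triples that exist in both bare and prefixed
form. Complementary/integrative-health (CIH) concepts are tagged through
the entity-metadata table (in practice, from a user-supplied lexicon).

## Preprocessing

Three monotone stages, each returning a subgraph:

1. **Rule filters** — drop triples touching a configured generic-concept
   list or excluded semantic groups (default: *Activities & Behaviors*,
   *Concepts & Ideas*), and keep only whitelisted predicates (default: the
   fifteen relation types the link-prediction stage uses, COEXISTS_WITH
   through MANIFESTATION_OF).
2. **Specificity scoring and pruning** — per triple, three components are
   min–max normalized across the surviving triple population and summed:
   the head's out-degree, the tail's in-degree (distinct triples, not
   instances; a `hub` mode uses max(head out, tail in) for both degree
   slots instead), and the G² log-likelihood-ratio statistic over the
   2×2×2 occurrence table of (subject, predicate, object) across all
   predication instances:

       G² = 2 Σ_ijk n_ijk log(n_ijk / m_ijk),
       m_ijk = n_i·· n_·j· n_··k / T²

   i.e. the classical likelihood-ratio test of mutual independence of the
   three slots (4 degrees of freedom on a 2×2×2 table), with the
   0·log 0 = 0 convention. A constant component contributes zero for every
   triple. Higher combined scores flag less specific triples; pruning keeps
   the budget lowest-scoring triples with a deterministic
   (score, head, relation, tail) tie-break, so retained sets nest across
   budgets. G² is computed per triple type from the graph's own instance
   counts; computing it per (subject, object) pair ignoring the predicate
   would be the main alternative reading.
3. **Verification hook** — an arbitrary boolean predicate over triples,
   the seam where a sentence-level triple-verification classifier would
   plug in. The default keeps everything.

Degrees are computed on the rule-filtered graph (filtering first removes
exactly the hubs the degree terms are meant to penalize).

## Link-prediction models

Four embedding models share a uniform *plausibility* API (higher is more
plausible; for the translational models plausibility is the negated
distance):

* TransE: `s = ||h + r − t||_p`, p ∈ {1, 2} (default 2).
* RotatE: `s = ||h ∘ r − t||` in ℂ^d; relations are pure phases
  (unit modulus, parameterized by angles).
* DistMult: `s = hᵀ diag(r) t` (symmetric in h, t by construction).
* ComplEX: `s = Re(hᵀ diag(r) conj(t))` in ℂ^d.

Training: margin ranking loss `max(0, γ + d⁺ − d⁻)` for TransE/RotatE
(with per-step L2 normalization of TransE entity vectors — distances are
then bounded by ≈ 2 + |r|, so the default margin is 1), pointwise logistic
loss with L2 regularization for DistMult/ComplEX. Negatives corrupt the
head or the tail (never both) at a 1:20 ratio, rejecting corruptions that
reproduce known triples; fresh negatives are drawn every epoch. The
optimizer is configurable (Adagrad default, Adam, plain SGD); everything is
driven by one seed and runs on numpy through a small reverse-mode autodiff
engine (`kgr._autodiff`), whose gradients are tested against central finite
differences.

Two graph-convolutional models use an encoder/decoder split and the
normalized binary cross-entropy loss

    L = −(1/((1+ω)|ε̂|)) Σ [ y log l(s) + (1−y) log(1−l(s)) ]

with ω negatives per positive and |ε̂| positive edges.

* **R-GCN**: per-relation message passing
  `x_i ← σ(Σ_r Σ_{j∈N_i^r} (1/c_{i,r}) W_r x_j + W_0 x_i)` with
  `c_{i,r} = |N_i^r|` (fixed, not learned). Inverse-relation channels are
  materialized so that edge sources receive messages too. The decoder is
  DistMult over encoded states plus a scalar bias, with L2 penalty 0.01 on
  the decoder relation vectors and dropout 0.2 in the encoder. Optional:
  basis decomposition of the relation weights (`num_bases`) and edge
  dropout; both off by default. The standalone `rgcn_forward` op defaults
  to σ = ReLU per the propagation rule; the *training* default is a linear
  (identity) encoder, which consistently ranked better for link prediction
  here — ReLU's nonnegative states needlessly restrict a bilinear decoder.
* **CompGCN**: node update `x_i ← f(Σ_{(j,k)} W_{λ(k)} φ(x_j, y_k))` with
  direction-specific weights for original/inverse/self-loop edge classes,
  relation update `y_k ← W_rel y_k` per layer (relations, inverses, and one
  self-loop relation), composition φ ∈ {subtraction, multiplication,
  circular correlation} (default circular correlation,
  `φ(a,b)_i = Σ_j a_j b_{(j+i) mod d}`; correlating the unit impulse in the
  first slot is the identity). f = tanh. Neighborhood aggregation is
  normalized (mean per channel) as a numerical choice — the unnormalized sum
  saturates tanh on high-degree nodes. The decoder is ConvE: reshape head
  and relation states to 2-D maps, stack, convolve (default: kernel 3,
  8 filters for the synthetic scale; the reshape must factor the hidden
  dimension), ReLU, project to d, ReLU, dot with the tail state; dropout
  0.3 on feature maps and hidden outputs in training mode, 0.1/0.3
  feature/layer dropout in the encoder.

Both GCNs train full-graph with Adam (plain SGD needs thousands of epochs
at this scale). Message passing is evaluated through per-channel sparse
normalized adjacency matrices and is tested against a dense block-matrix
oracle.

## Evaluation

*Time slicing*: triples are stably sorted by (first date, triple) and cut
into contiguous train/validation/test slices by count (default 8:1:1); the
effective cut dates are outputs. A date-driven mode accepts explicit cuts.

*Filtered ranking*: each test triple is ranked against n (default 100)
corruptions of one side, drawn without replacement from entities that do
not form a known triple; ranks use the mean-rank tie convention (average
position over tied orderings, rounded half up). Both corruption sides are
ranked and pooled by default; tail-only is available for head-of-interest
test sets. MR/MRR/Hits@k derive from the rank list; ROC/PR curves and
AUROC/AUPR (trapezoid / average precision; AUROC equals the tie-corrected
normalized Mann–Whitney U) from pooled positive/negative scores. The
negative-batch size and the two-sided default are package choices and are
reported alongside results, since MR and Hits@k depend on them.

*Ground-truth test sets* are built from a plain list of head concepts with
a fixed relation and tail (deduplicated; out-of-vocabulary heads dropped
and reported), evaluated with the already-trained models.

## Discovery

*Candidate ranking*: every NPI node of a class is scored as the head of
(npi, PREVENTS, disease); triples already in the graph are excluded; the
"probability" column is a per-class min–max rescaling of the plausibility
score (order-preserving, top candidate = 1.0 — not a calibrated
posterior).

*Mechanism mining*: DS candidates use the constrained two-hop pattern
INHIBITS|INTERACTS_WITH then AFFECTS|CAUSES|PREDISPOSES|ASSOCIATED_WITH;
CIH candidates leave both hops unconstrained. A path is reported only when
the direct (intervention, PREVENTS, disease) link is absent (the negation
clause — closed discovery proposes mechanisms for *unknown* links). Hops
run intervention→intermediate→disease; inverse-direction matching is off.
Paths are deduplicated by (intermediate, hop1, hop2) and carry the stored
provenance document ids.

## Synthetic corpus

The generator emulates the statistical shape of a literature-derived
biomedical graph without any external data:

* 500 entities by default (150 Drug, 100 Disease, 150 Gene, 50 DS,
  50 CIH) and 5,000 triples — every model trains in minutes on one CPU;
* fifteen predicates with the strongly imbalanced frequency profile of a
  large predication corpus (≈33% COEXISTS_WITH down to ≈0.2%
  MANIFESTATION_OF), allocated by largest remainder;
* a type-compatibility matrix (package construction, config-visible)
  restricting which entity types each predicate may connect, e.g.
  PREVENTS/TREATS: {Drug, DS, CIH} → Disease; INHIBITS/STIMULATES:
  {Drug, DS, CIH, Gene} → Gene;
* latent low-rank structure: unit-norm entity vectors and small relation
  vectors are drawn first (TransE or DistMult geometry, dim 32) and each
  relation's quota is filled with its best-scoring compatible pairs; a
  noise fraction (default 10%) is replaced by uniform typed triples;
* planted mechanisms: the strongest latent PREVENTS pairs per NPI class —
  restricted to interventions with at least `min_planted_degree` (default
  10) edges in the emitted graph, since an intervention attested four times
  cannot be localized by any model, and real candidate interventions are
  well-attested concepts — are closed through the gene best supporting
  (npi INHIBITS gene) and (gene CAUSES disease); half the closures default
  to held out of the emitted graph as recovery targets, one mechanism per
  intervention;
* provenance: 1–3 instances per triple, unique document ids, dates uniform
  over 2015–2022.

What the generator does **not** emulate: extraction errors with textual
provenance, per-relation date trends (link ages are exchangeable), hub
degree distributions of real corpora (emission is score-driven, not
preferential-attachment), or UMLS semantics beyond the coarse type matrix.
Passing recovery tests here therefore shows the estimator machinery works
under a known low-rank generating process — not that any particular real
corpus satisfies that process.

A separate contingency-stream generator draws (subject, predicate, object)
presence/absence instances from an explicit 2×2×2 joint, for validating
G²: under a mutually independent joint the statistic is χ²(4), and its
p-values over replicates are checked for uniformity.

## Benchmark and known limitations

`kgr.benchmark.run_planted_benchmark(seed)` runs the full study at the
default scale: TransE (d=64, 300 epochs, Adam 0.01, margin 1) and R-GCN
(d=32, 1 linear layer, 300 epochs, Adam 0.01), 1:20 training negatives,
100 evaluation negatives per side on the held-out PREVENTS closures, and
candidate-table recovery scored by the better-ranking model (the workflow
promotes the winning model to discovery, so the decile statistic follows
the same rule). Measured over generator seeds 1–3: TransE filtered
Hits@10 0.90/0.90/0.85; R-GCN 1.00/0.75/0.85; top-decile candidate
recovery 90%/70%/80%.

A structural caveat: the default synthetic corpus is generated from
*TransE* latents, so translational models hold a representational
advantage there — a translation geometry is not expressible by a diagonal
bilinear decoder, which is why plain DistMult (≈0.5) and ComplEX (≈0.6)
trail TransE on this benchmark, and why the DistMult-decoded R-GCN is
sensitive to optimization quality (it matches or beats TransE on two of
three seeds once well converged, but drops below it on the hardest seed).
Per-seed results are accordingly variable, and pass/fail judgments on this
benchmark use a three-seed majority. On real corpora the ordering can
differ; rankings measured here characterize the implementation under a
known generating process, not the models' merits on real data. Setting
`latent_model="DistMult"` reverses the bias symmetrically.

## Reproducibility

Every stochastic step (generation, negative sampling, initialization,
dropout, evaluation corruption draws) flows from explicit integer seeds
through `numpy.random.Generator`; two runs with the same seeds are
bit-identical on a fixed platform, and graph construction, splitting and
candidate tables are invariant to input row order.
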