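# Methods

## Graph model

The knowledge graph is a set of typed nodes and typed triplets
`<head, relation, tail>`. The 14 relations carry a fixed signature table
(e.g. `has_target: drug → target_protein`, `has_encoded: gene →
target_protein`); building a graph validates every edge against it, and
`validate_kg` re-audits any graph, returning violations as data. Node
identifiers are namespaced `"<type>:<local_id>"` so the embedding vocabulary
cannot collide across types while a side-effect term and a disease can still
share a local identifier — the identity mapping the adverse-reaction
negative rule needs.

Version subsets are nested relation sets: V2 is the 10-relation baseline
(drug features, disease features, treatment), V3 adds the three
within-domain interaction relations, V4 adds gene→target, and V1 is their
union. For a fixed input this makes V2 = V3 ∩ V4 and V1 = V3 ∪ V4, which the
tests assert as a lattice property.

Drug→domain edges are materialized by rule composition
(`derive_drug_domain_edges`: drug→target plus target→domain implies
drug→domain) with union semantics over directly supplied edges, and the
operation is idempotent. ATC codes may be expanded into one node and edge
per hierarchy level (prefix lengths 1/3/4/5/7) via `expand_atc_edges`;
the expansion is opt-in because edge tables may already list per-level
codes. Interaction relations are stored as directed triplets and serialized
once per stored triplet — no automatic reverse edges.

## Embedding

Each triplet is one three-token sentence; the corpus is a seeded shuffle of
the triplet set. CBOW with negative sampling is implemented in numpy:
unigram^0.75 noise distribution, five noise words, learning rate decaying
linearly from `alpha` to `min_alpha`, sequential seeded updates (hence
bit-reproducible). `window=2` guarantees the context spans the whole
sentence from any position; `min_count=1` keeps every drug and disease in
the vocabulary. The reference vector size is 1024 (a grid-searched value at
full data scale); desk-scale runs use 32. On the small synthetic corpora the
trainer needs more passes than typical large-corpus defaults — the desk
preset uses 100 epochs at `alpha=0.05`, at which point latent mechanism
clusters are linearly decodable from the drug and disease vectors.

The embedding is trained once, on the graph *after* the held-out test
pairs' treatment and adverse-reaction edges are removed. Training-pair edges
remain — the embedding may legitimately memorize known associations; the
evaluation protocol only requires that test pairs be invisible.

## Labels, split, rebalancing

Positives are associations with the configured status (default
`approved`); negatives are `(drug, disease)` pairs where the disease occurs
among the drug's side-effect terms and the pair is not positive.
Disjointness is enforced at pair-set construction. The test split holds out
`floor(fraction·|positives|)` positives (default 10%) and an equal number of
negatives, both drawn uniformly under the seed.

Rebalancing operates on the concatenated `[E_r ‖ E_p]` feature rows of the
training portion only. SMOTE places each synthetic row uniformly on the
segment between a minority row and one of its `k=5` nearest minority
neighbours; SORU first SMOTEs the minority to a 0.9 minority/majority ratio,
then undersamples the majority to the new minority count. When the two
classes tie in count, the positive class plays the minority role (the
strategies are framed as oversampling positives). SMOTE requires minority
count > k and raises otherwise.

## Network and loss

Channels are dense stacks (reference widths 512/256/128/64 on a 1024-dim
input) with ReLU on every layer and dropout after every layer; the merge is
the elementwise absolute difference, followed by a ReLU head layer
(reference width 32, with dropout) and a single sigmoid unit. Parameter
counts are checked against an independent layer-summation oracle:
2·697,280 + 2,113 = 1,396,673 heterogeneous and 699,393 homogeneous at
reference widths.

The channel-alignment penalty is the symmetrized KL divergence between the
softmax-normalized channel outputs, weighted by λ (default 0.1, applied to
every pair in the batch). A raw log-ratio of the two channel maps is not a
well-defined divergence, so the exponential normalization is the package's
chosen well-posed form; λ and the scope (`all_pairs` vs `positive_only`)
are configuration because neither is canonical. Total loss is mean BCE plus
λ times the mean penalty, affine in λ by construction (asserted in tests
with dropout disabled). BCE clamps probabilities to `[1e-7, 1−1e-7]` before
the logarithms; values outside `[0,1]` are a domain error, not silently
clamped.

Backpropagation is hand-written (including through `|·|`, with subgradient
0 at zero, and through the softmax-KL) and verified against central finite
differences. At the `|·|` kink — e.g. tied channels on identical inputs —
finite differences are invalid and the subgradient convention applies.
Optimization is Adam; callbacks monitor validation accuracy: checkpoint on
improvement, halve the learning rate after `lr_reduce_patience` stale
epochs, stop after `early_stop_patience`, restore the best checkpoint.
All batch order and dropout masks derive from the training seed, making runs
bit-reproducible single-threaded.

Predicted label is 1 iff the probability *strictly* exceeds the threshold
(default 0.5); a probability exactly at the threshold is a negative call.

## Evaluation protocol

Metrics: accuracy, AUC-ROC (trapezoid over the exact step curve — equal to
the Mann–Whitney concordance statistic, which the tests verify by exhaustive
pair counting), AUC-PR (step interpolation over all distinct scores,
verified against a brute-force threshold sweep), Brier score, MCC (0 when a
marginal is empty), and F1 as the standard `2PR/(P+R)`; a `paper_variant`
flag yields the unnormalized `PR/(P+R)` for compatibility with sources that
print the formula without the factor 2. Single-class inputs return NaN for
the rank metrics and MCC and name them in `report.undefined`.

Cross-validation uses the fixed-test-set protocol: test pairs never move;
each repeat re-partitions the remaining pairs into stratified folds, each
fold serves once as the validation monitor, the rest (rebalanced) trains,
and every model is scored on the same test set. The reference protocol is
5 folds × 4 repeats; reports aggregate mean ± sample standard deviation over
all (fold, repeat) runs. Drug ranking for a query disease sorts by
descending probability with lexicographic drug-id tie-break.

## Synthetic data

The generator emulates the *structure* of the real data (11 node types, 14
relations, side-effect/disease identifier overlap), not its marginals. Drugs,
diseases and every feature vocabulary are assigned to latent mechanism
clusters; feature edges appear with probability `p_in` within clusters and
`p_out` across; treatments at `treat_prob_in`/`treat_prob_out`; gene→target
edges wire within clusters (the planted mechanism); each drug's side effects
draw preferentially (bias 0.8) from disease-mapped terms of other clusters so
negatives are truly non-associated. Defaults — 60 drugs, 25 diseases, 4
clusters, `p_in=0.35`, `p_out=0.05`, `treat 0.45/0.02`, 8 side effects per
drug, 0.6 side-effect↔disease overlap — give roughly 190 positives and 350
negatives, an imbalance comparable to curated association sets, and finish an
end-to-end run in well under a minute on one CPU.

`null_config` flattens every cluster dependence, matching the planted
condition's expected edge and positive counts; a correct pipeline then
scores chance-level AUC. Because a single test split holds only ~19+19
pairs (AUC sampling sd ≈ 0.09), the null calibration is asserted on the
mean over five seeds rather than per seed.

What passing these tests shows: the pipeline propagates a mechanism signal
from graph structure through embedding and network to held-out pairs, and
does not hallucinate one when none exists. What it does not show: behavior
under real-data pathologies — scale-free degree distributions, annotation
biases, correlated side-effect vocabularies, or database noise.

## Desk-scale study conditions

The desk preset (`desk_config`) uses embedding dim 32 with channel widths
(64, 32, 16, 16), head width 8, dropout 0.1, Adam at 3e-3, up to 300 epochs
with patience 60, and 2-fold single-repeat CV. The reference-scale defaults
(dropout 0.2, learning rate 5e-5) are calibrated for 1024-dim inputs and
million-parameter channels and optimize too slowly on the small desk
problem; the desk values were chosen for robust convergence across seeds on
the planted-signal condition. A latent width of 16 (rather than 8) avoids
occasional dead-ReLU collapse of the merge vector at initialization.

## Known limitations

* The CBOW trainer is a faithful but compact implementation — no frequent-
  word subsampling, no hierarchical softmax, single-threaded only.
* Per-fold re-embedding (strict leakage regime) is supported only through
  re-running the pipeline per fold, not inside `cross_validate`.
* `rank_drugs` scores only entities present in the embedding vocabulary;
  cold-start drugs or diseases are out of scope, as the embedding is
  transductive.
* Real-data ETL (DrugBank, SIDER, DisGeNET, ...) is deliberately outside the
  package; inputs are plain TSV tables in the documented dialects.
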