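# Methods

`cocoder` implements a human-in-the-loop (HITL) workflow for automated
clinical coding: assigning a set of diagnosis codes from a hierarchical
taxonomy (chapters → groups → assignable leaf codes) to each admission
record. Real deployments face three data regimes at once — records whose
structured short text (the clinician-written list of disease names) is
missing, records that can be cheaply but noisily auto-labelled from that
short text, and a small budget of expert-verified records. The package
models all three and the training strategy that exploits them.

## Pipeline

**Noisy auto-annotation.** Short disease-name strings are embedded by a
hashed character-n-gram bag-of-embeddings encoder trained with the
dropout-view InfoNCE objective: two stochastic encodings of the same name
form a positive pair, the other names in the batch are negatives,

ℓᵢ = −log [ exp(sim(hᵢ, hᵢ′)/τ) / Σⱼ exp(sim(hᵢ, hⱼ′)/τ) ],

with cosine similarity and τ = 0.05. Each leaf code's standard name is a
prototype; every short-text entry is assigned the argmax-cosine prototype
(one code per entry), and the union over entries is the record's noisy
label set. The entry cosine doubles as a confidence. A pretrained
sentence encoder can be substituted through the same fit/transform
surface; the default is deliberately self-contained and trains in
seconds.

**Adaptive clean annotation.** Manual coding is modelled by an oracle
that reveals gold labels. The allocator first selects a greedy cover in
which every code (by noisy labels) appears in ≥ 2 selected records, then
iterates patches that prioritise records carrying the most under-covered
codes (ties: higher auto-annotation confidence, then seeded random),
until every code has ≥ s verified records, candidates run out, or a hard
annotation budget `max_annotations` is reached. The budget matters in
experiments: without it, higher noise ratios force the allocator to
annotate more records to reach coverage, confounding noise level with
annotation effort. Default s = 35, patch size 50.

**Document encoder.** Tokens are embedded by a trainable table (chunked
through a 512-token sliding window so a contextual base encoder can slot
in), then mapped onto a word co-occurrence graph: one node per distinct
token, an edge when two tokens share any window of 3 consecutive
positions. Three rounds of gated (GRU-style) message passing over the
row-normalised adjacency propagate information; the readout gates each
node state, h_v = σ(f₁(h_v)) ⊙ tanh(f₂(h_v)), and pools by elementwise
mean plus max to give the document vector h_G. A per-label attention head
scores every token position per code (softmax over positions), yielding
both a logit per code and an explanation heatmap.

**Three-step training.** Step 1 pretrains with the unsupervised InfoNCE
loss on all texts, where the positive view is a dropout-perturbed
mean-pooled embedding of the document (standing in for a [CLS] vector;
the contract is simply two stochastic views of one document). Step 2
trains on the noisy pool with the multi-label supervised contrastive
loss: Cᵢⱼ = yᵢᵀyⱼ counts shared labels, βᵢⱼ = Cᵢⱼ / Σ_{k≠i} Cᵢₖ weights
each pair, and

L_ml = Σᵢ Σ_{j≠i} −βᵢⱼ log [ exp(−d(zᵢ,zⱼ)/τ′) / Σ_{k≠i} exp(−d(zᵢ,zₖ)/τ′) ],

with Euclidean d and τ′ = 0.05, combined as L₂ = γ·L_ml + δ·L_us
(γ = 0.5, δ = 0.02). Step 3 refines on the clean pool with
L₃ = θ·L_BCE + γ·L_ml + δ·L_us (θ = 1), where the binary cross-entropy
runs through the attention head's logits. Rows with zero label overlap
get β ≡ 0 and contribute only as negatives. Each step resumes from the
previous parameters; steps can be disabled individually to reproduce
ablations.

**kNN-optimised inference.** Clean records are embedded into a datastore
D′ = {(hᵢ, yᵢ)}. A query retrieves its k = 3 nearest entries by Euclidean
distance; weights αᵢ = softmax(−dᵢ/τ) over the retrieved set give
ŷ_kNN = Σ αᵢ yᵢ, interpolated with the model probabilities as
ŷ = λ·ŷ_kNN + (1−λ)·ŷ_Mo with λ = 0.3. Decision support is exposed as
library/CLI operations: a 0–1 emission threshold (lowering it never
removes a code), per-code attention heatmaps, and the k retrieved
references with distances, weights, and verified codes.

## Numerical and optimisation choices

- All trainable components run on a small reverse-mode autodiff engine
  over numpy (`cocoder._autodiff`), gradient-checked against central
  finite differences. Batched (padded) 3-D forward passes keep the inner
  loops in vectorised numpy.
- Adam (lr 0.001, weight decay 0.001, batch 64 as the reference
  settings) with global-norm gradient clipping at 5. Each training step
  gets a **fresh optimiser**: second-moment estimates carried across an
  objective switch are stale curvature and empirically destabilised
  step 2.
- The distance-based contrastive loss is applied to **L2-normalised**
  document representations. Unnormalised, the objective is minimised by
  inflating embedding norms (negatives pushed to infinite distance),
  which diverges; normalising bounds pairwise distances in [0, 2]. The
  loss functions themselves accept arbitrary vectors — normalisation is
  a trainer-side modelling choice.
- BCE probabilities are clamped to [1e-7, 1−1e-7]. β rows with zero mass
  are defined as all-zero rather than NaN (the continuity-preserving
  reading of an undefined normalisation).
- Softmaxes and log-sum-exps are max-shifted; max-pool gradients route to
  the first argmax on ties; distance ties at the k-boundary break by
  record id for determinism.
- Step 3 optionally keeps the epoch snapshot with the best validation
  micro-F1 (the 6:2:2 split's validation set); the experiment harness
  always passes the validation split.

## The synthetic world

Real hospital EMRs are private, so the generator emulates their
documented statistics: a three-tier taxonomy whose every code carries ≥ 2
informal name variants (truncations, abbreviations, reorderings,
vernacular suffixes); Zipf-tilted long-tailed code frequencies
(exponent 1.1, frequency span ≥ one order of magnitude); a shifted
Poisson number of codes per record with mean 4.3; chapter-affine label
co-occurrence (a later label stays in an already-used chapter with
probability 0.5, making the label-similarity weights non-degenerate);
keyword-bearing long text (3 dedicated keyword tokens per code, each
emitted with probability 0.85 by default, mixed into background
vocabulary) with two keywords tied to the specialist-condition and
auxiliary-examination sections and dropped when those sections are
absent; ~20% of records lacking the short-text section entirely; and a
default document length of 730 tokens matching the reference corpora.

The quality-control simulator corrupts exactly
round(noise_ratio × entries) short-text entries, drawn uniformly: a
*vague* error replaces a name with an informal variant of an ancestor
code, a *wrong* error with a variant of a sibling leaf, a *missing* error
deletes the entry; gold labels and long text are never touched, and an
audit trail records every corruption. An infeasible draw (no variant-
bearing ancestor/sibling) resamples the error type so the corruption
count stays exact. The default mix is uniform over the three types, and
the configured ratio covers all three (whether "missing" is counted
inside or beside the ratio is not externally fixed; we count it inside).

What passing tests on this world do **not** show: robustness to real
clinical language (tokens here are opaque strings with planted, largely
unambiguous keyword cues), coder disagreement, multilingual or
abbreviation-heavy narrative, or label sets beyond a few dozen codes.
The synthetic task is intentionally learnable so that pipeline-level
properties — ablation orderings, noise monotonicity, coverage guarantees
— are attributable to the pipeline rather than to irreducible task noise.

## Desk-scale benchmark

The end-to-end benchmark keeps the study's structure — 50 codes, 5000
records, 6:2:2 split, 30% noise, a 1:3 clean-to-noisy annotation budget
(the allocator's budget is fixed at 25% of the labelled pool in every
cell) — and scales the compute: 80-token documents, embedding dimension
16, batch 16, Adam lr 0.01, epochs (2, 4, 12) for steps 1–3. One cell
trains in roughly 40 s on one CPU; the 12-cell grid (three noise ratios ×
three seeds, plus clean-only ablations) runs in under 10 minutes. Under
these conditions the full three-step recipe beats clean-only refinement
by 0.1–0.3 micro-F1 and mean micro-F1 degrades as the injected noise
ratio rises — the qualitative signatures of the method, not its published
absolute numbers, which belong to the private corpora.

## Known limitations

- The default encoders are deliberately small; nothing prevents plugging
  a pretrained transformer, but none is bundled.
- "Same-level" corruption is read as same-parent siblings; a looser
  reading (same chapter) would widen the wrong-error pool.
- Secondary diagnoses are restricted to leaf codes; internal codes exist
  only for noise injection and chapter aggregation.
- The allocator models a single oracle coder; multi-coder scheduling and
  disagreement are out of scope.
- Step 2 can optionally mix incomplete-raw records into its unsupervised
  term (`include_raw_in_step2`, default off); they enter the supervised
  term with zero label vectors, i.e. purely as negatives.
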