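# cocoder — human-in-the-loop automated clinical coding

`cocoder` is a research toolkit for **automated clinical coding**:
assigning the set of diagnosis codes from a hierarchical taxonomy
(chapters → groups → assignable leaf codes) to each admission record of
an electronic medical record (EMR) system. It is aimed at clinical-NLP
researchers and health-informatics engineers who want to study — or
deploy pieces of — a *human-in-the-loop* coding workflow in which
automatic annotation, a small expert-verified pool, and model training
reinforce each other.

The package implements the full loop on synthetic EMR-like data (real
hospital corpora are private), end to end:

1. **Noisy auto-annotation.** A contrastively trained name encoder
   (dropout-view InfoNCE, ℓᵢ = −log e^{sim(hᵢ,hᵢ′)/τ} / Σⱼ e^{sim(hᵢ,hⱼ′)/τ})
   matches each clinician-written disease name to its nearest standard-name
   prototype, labelling a large pool cheaply but imperfectly.
2. **Adaptive clean annotation.** An allocator iteratively selects
   patches of candidate records so every code collects ≥ *s* verified
   examples with minimal workload; manual coding is simulated by a
   gold-label oracle.
3. **Three-step contrastive training** of a graph-augmented document
   encoder (word co-occurrence graph, gated message passing, gated
   mean+max readout, per-label attention): step 1 pretrains with
   unsupervised InfoNCE on all texts; step 2 trains on the noisy pool
   with a multi-label supervised contrastive loss whose pair weights are
   the row-normalised label-vector dot products,
   βᵢⱼ = yᵢᵀyⱼ / Σ_{k≠i} yᵢᵀyₖ, over a Euclidean-distance softmax;
   step 3 refines on the clean pool adding binary cross-entropy
   (L₃ = θ·L_BCE + γ·L_ml + δ·L_us with θ=1, γ=0.5, δ=0.02).
4. **kNN-optimised inference.** Clean records form a datastore
   D′ = {(hᵢ, yᵢ)}; a query's k=3 nearest entries vote with weights
   αᵢ = softmax(−dᵢ/τ), and ŷ = λ·ŷ_kNN + (1−λ)·ŷ_Mo with λ=0.3.
   Decision support — a 0–1 emission threshold, per-code attention
   heatmaps, retrieved reference cases — is exposed as library and CLI
   operations.

A controlled **quality-control simulator** injects the three documented
error families into the structured short text (*vague*: replace a name
with an ancestor-code variant; *wrong*: with a sibling-code variant;
*missing*: delete it) at an exact noise ratio, with a full audit trail —
the substrate for effort-vs-effectiveness experiments.

See `docs/methods.md` for the model details, parameter meanings and
numerical choices.

## Worked example

A 20-code world with 2000 records, 30% injected noise, and an annotation
budget of 240 records (script in prose; every stage is also a CLI
subcommand, see below):

```python
from cocoder import (GeneratorConfig, generate_taxonomy, generate_corpus,
                     split_dataset, NoiseConfig, corrupt_dataset,
                     NameSimilarityEncoder, build_prototype_index,
                     partition_corpus, AllocatorConfig, run_annotation_loop,
                     ThreeStepCoder, build_datastore, InferenceConfig,
                     predict_records, compute_metrics)

cfg = GeneratorConfig(n_codes=20, n_records=2000, doc_length_mean=80,
                      background_vocab_size=300, incomplete_fraction=0.2, seed=0)
taxonomy = generate_taxonomy(cfg)
records = generate_corpus(taxonomy, cfg)
train, val, test = split_dataset(records, seed=0)

noisy, audit = corrupt_dataset(train, taxonomy, NoiseConfig(noise_ratio=0.3, seed=1))
encoder = NameSimilarityEncoder(random_state=0).fit(
    [n for r in noisy for n in r.short_text])
parts = partition_corpus(noisy, encoder, build_prototype_index(taxonomy, encoder))
parts, _, report = run_annotation_loop(
    parts, AllocatorConfig(s=35, patch_size=40, max_annotations=240, seed=0))

coder = ThreeStepCoder(embedding_dim=16, batch_size=16, learning_rate=0.01,
                       epochs_step1=2, epochs_step2=4, epochs_step3=12,
                       random_state=0).fit_partitions(parts, taxonomy)
store = build_datastore(parts.clean_pool, parts.clean_labels, coder, taxonomy)
preds = predict_records(test, coder, store, taxonomy, InferenceConfig(k=3, lam=0.3))
```

Output of the full script:

```
corrupted 1216 of 4055 short-text entries
pools: incomplete-raw 260, noisy-labelled 940
annotation loop: status=complete, workload=206 records in 6 patches
model-only       micro-F1 0.5106  micro-AUC 0.8027  R@5 0.6018
kNN-interpolated micro-F1 0.5521  micro-AUC 0.8242  R@5 0.6349
record R000965: emitted ['C00.G0.01', 'C05.G0.01', 'C00.G0.02'], nearest reference R000870 at distance 0.128
```

Reading the numbers: 30% of the 4055 clinician-written name entries were
corrupted; 260 of the 1200 training records lack structured short text
entirely and enter only unsupervised pretraining. The allocator reached
full per-code coverage (s = 35 where support allows) after manually
coding 206 records — 22% of the labelled pool. On the held-out test
split, interpolating the model's probabilities with the 3 nearest
verified cases lifts micro-F1 from 0.51 to 0.55 and Recall@5 from 0.60
to 0.63; the last line is the decision-support view for one record: the
codes emitted at threshold 0.5 and the most similar verified reference.
At the full benchmark scale (50 codes, 5000 records) the same pipeline
reaches micro-F1 ≈ 0.85–0.9.

## Command-line interface

```bash
cocoder simulate --config gen.yaml --out data/
cocoder corrupt --in data/corpus.jsonl --taxonomy data/taxonomy.json \
        --ratio 0.3 --seed 1 --out noisy.jsonl --audit audit.jsonl
cocoder annotate-auto --in noisy.jsonl --taxonomy data/taxonomy.json --out parts/
cocoder annotate-loop --partitions parts/ --s 35 --out annotated/
cocoder train --partitions annotated/ --taxonomy data/taxonomy.json --out model/
cocoder build-datastore --model model/ --partitions annotated/ \
        --taxonomy data/taxonomy.json --out store/
cocoder predict --model model/ --datastore store/ --in data/corpus.jsonl \
        --taxonomy data/taxonomy.json --out pred.jsonl --heatmaps heat/
cocoder evaluate --pred pred.jsonl --gold data/corpus.jsonl \
        --taxonomy data/taxonomy.json --ks 5,7,9 --out report.json
cocoder sweep --config sweep.yaml --out results.csv
```

All formats are plain text: taxonomy as JSON, records as JSONL, reports
as JSON, sweep tables as CSV; model checkpoints are `.npz` arrays with a
JSON hyperparameter sidecar.

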