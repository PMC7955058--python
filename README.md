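# me2vec

Hierarchical graph-based embeddings of the three core EHR entities — medical
services, doctors, and patients — learned from timestamped patient-journey
tables, plus the standard evaluation protocols (node classification, link
prediction, binary outcomes) and a synthetic journey generator with planted,
recoverable structure.

The hierarchy is trained bottom-up:

1. **Services** — journeys are cut into non-overlapping `T`-day context
   windows; co-occurrence counts build a weighted service–service graph,
   which is embedded with biased second-order random walks (return parameter
   `p`, in–out parameter `q`) followed by skip-gram with negative sampling.
   Rare services end up far from the embedding centroid ("spatial
   isolation"), routine services crowd together.
2. **Doctors** — a single multi-head graph-attention layer aggregates each
   doctor's (frozen) service vectors, trained on the auxiliary task of
   predicting the doctor's primary specialty. Doctor vectors are initialized
   as weighted averages of their service vectors; the trained classifier
   doubles as a specialty imputer for doctors with missing labels.
3. **Patients** — the patient–service multigraph with doctor-attributed
   edges is simplified by *duplication & annotation* into a simple bipartite
   patient–hybrid graph (one hybrid node per distinct (service, doctor)
   pair, `h = W_a [s ‖ d] + b_a`). Patient vectors minimize a per-patient
   KL divergence between the edge-weight context distribution and a softmax
   over hybrids — exactly on small graphs, with degree^0.75 negative
   sampling at scale.

All training (skip-gram, the attention layer, the patient objective, Adam)
is implemented directly in numpy with hand-derived gradients, so the package
has no deep-learning framework dependency and is deterministic given seeds.

## CLI

Everything is reachable through the `me2vec` entry point:

```sh
# synthetic cohort (journeys.csv + ground_truth.csv)
me2vec simulate --seed 1 --out run/ --n-patients 500 --n-doctors 50 \
    --n-services 100 --n-specialties 5

# stage by stage
me2vec build-graph   --journeys run/journeys.csv -T 8 \
    --edges-out run/graph.tsv --vocab-out run/vocab.txt
me2vec embed-service --graph run/graph.tsv --vocab run/vocab.txt \
    --dim 128 --negatives 10 --p 1 --q 1 --seed 1 --out run/service.vec
me2vec embed-doctor  --journeys run/journeys.csv --service-emb run/service.vec \
    --heads 4 --seed 1 --out run/doctor.vec
me2vec embed-patient --journeys run/journeys.csv --service-emb run/service.vec \
    --doctor-emb run/doctor.vec --negatives 10 --seed 1 --out run/patient.vec

# evaluations
me2vec eval-nodes  --emb run/patient.vec --labels run/ground_truth.csv \
    --ratios 0.2,0.4,0.6,0.8 --repeats 10 --seed 1
me2vec eval-binary --emb run/patient.vec --labels run/ground_truth.csv --folds 10
me2vec eval-links  --journeys run/journeys.csv --patient-emb run/patient.vec \
    --doctor-emb run/doctor.vec --fraction 0.1 --seed 1

# or the whole pipeline with a manifest (bitwise-reproducible per seed)
me2vec run --seed 1 --out run/
```

Defaults follow the reference configuration: window `T = 8` days (60 for
minute-indexed data), embedding dimension 128, 10 negative samples, `K = 4`
attention heads, `p = q = 1`, Adam optimizer. Embedding files use the
word2vec text format (`"count dim"` header, one id + floats per line).

## Layout

```
src/me2vec/
  ehr_data.py          journey & embedding-table types and IO
  synthetic_ehr.py     planted-structure cohort generator
  service_graph.py     windowed co-occurrence graph
  service_embedding.py biased random walks + skip-gram (numpy)
  doctor_embedding.py  graph-attention specialty task + imputation
  patient_embedding.py duplication & annotation + KL objective
  evaluation.py        node classification / link prediction / PR-ROC / PCA
  pipeline.py, cli.py  orchestration and the `me2vec` CLI
  benchmarks.py        from-scratch acceptance computations
  optim.py, errors.py  Adam; exception hierarchy
```
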