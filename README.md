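# dreamgnn

Dual-route graph neural network for computational drug repositioning:
predicting unobserved therapeutic drug–disease associations by bipartite
link prediction, for researchers who want a rigorously evaluated,
leakage-free re-ranking of the unknown cells of a drug–disease association
matrix — including strict cold-start predictions for drugs or diseases
never seen during training.

## The model

Drugs and diseases arrive with precomputed language-model embeddings
(small molecules 1024-d, protein therapeutics 1280-d, diseases 768-d from
curated text). Drug vectors are zero-padded to a common width, stacked and
compressed by PCA to the shared width *d₀*; diseases pass through. Two
encoders then refine every node in parallel:

- **Relation-aware topology encoder** — a multilayer graph-convolutional
  matrix-completion operator on the bipartite interaction graph with two
  edge types, ℛ_known (validated associations) and ℛ_unknown (a seeded
  sample of non-edges used as negative evidence):

  h_v⁽ˡ⁺¹⁾ = σ( Σ_r Σ_{u∈𝒩_r(v)} W_r⁽ˡ⁾ h_u⁽ˡ⁾ / √(|𝒩_r(u)||𝒩_r(v)|) ),

  with each W_r⁽ˡ⁾ factorized through B shared bases, W_r⁽ˡ⁾ = Σ_b a_rb⁽ˡ⁾ V_b⁽ˡ⁾.
  The topology view is the mean over the L layer outputs,
  z^topo = (1/L) Σ_l h⁽ˡ⁾, projected to width *d*.

- **Feature-aware similarity encoder** — for each entity type, two weighted
  kNN similarity graphs (one from predefined domain scores such as Tanimoto
  fingerprints or ontology semantics, one from cosine similarity of the raw
  embeddings), each processed by its own two-layer GCN
  H⁽ˡ⁺¹⁾ = σ(Â H⁽ˡ⁾ W⁽ˡ⁾ + b⁽ˡ⁾) with Â = D^{-1/2}(A+I)D^{-1/2}, and fused:
  z^sim = Dropout(ReLU(W_fuse [h^pred ; h^feat] + b_fuse)).

The two views are combined per node by learned additive attention,
w = Softmax(W₂ tanh(W₁ Z_v)) with Z_v = [z^topo ; z^sim] ∈ ℝ^{2×d}, and
z_v = Dropout(w₁ z^topo + w₂ z^sim). A pair (i, j) is scored by a
three-layer MLP with a sigmoid on [z_i ; z_j]; training minimizes binary
cross-entropy (in logit space) over training positives plus per-epoch
resampled unknowns, with Gaussian feature perturbation (σ = 0.05) and edge
dropout (P = 0.10) as augmentation. Cold-start entities are scored by
retrieving their top-k cosine neighbors in the *original* embedding space,
forming a pseudo-query by temperature-scaled attention over the neighbors'
trained representations, and running the frozen decoder.

The network is implemented on a compact numpy reverse-mode autodiff core
(`dreamgnn.nn`) with an AdamW optimizer; gradients are validated against
finite differences in the test suite.

## Worked example

Everything runs on self-contained synthetic data with planted community
structure — no downloads:

```python
from dreamgnn import SyntheticSpec, generate, dataset_summary, run_cv, coldstart_cv
from dreamgnn.config import DreamConfig

bundle = generate(SyntheticSpec(seed=0))       # 60 drugs x 40 diseases, 3 blocks
print(dataset_summary(bundle.assoc))

config = DreamConfig.small()                   # desk-scale widths, same architecture
report = run_cv(bundle, config, seed=1)        # 10-fold, leakage-free, full negatives
print(f"AUROC {report.auroc_mean:.3f} +/- {report.auroc_sd:.3f}")
print(f"AUPRC {report.auprc_mean:.3f} +/- {report.auprc_sd:.3f}")

cold = coldstart_cv(bundle, config, mode="unseen_drug", seed=3)
print(f"cold-start AUROC {cold.auroc_mean:.3f}, AUPRC {cold.auprc_mean:.3f}")
```

prints

```
{'n_drugs': 60, 'n_diseases': 40, 'n_positives': 122, 'density': 0.050833333333333335}
AUROC 0.939 +/- 0.028
AUPRC 0.501 +/- 0.175
cold-start AUROC 0.876, AUPRC 0.252
```

The association matrix is ~5% dense, so AUPRC (baseline ≈ 0.05 for a random
ranker) is the informative headline number; AUROC 0.94 and AUPRC 0.50 mean
the model recovers most of the planted structure from held-out pairs, and
the cold-start numbers show that entities absent from every training
structure are still ranked far above chance through neighbor retrieval
alone.

The same pipeline is available from the shell:

```bash
dream synth --out data/ --seed 0
dream data summarize --assoc data/associations.tsv
dream cv --assoc data/associations.tsv --drug-emb data/drug_small_mol.tsv \
    --protein-emb data/drug_protein.tsv --disease-emb data/disease_emb.tsv \
    --drug-sim data/drug_sim.tsv --disease-sim data/disease_sim.tsv \
    --small --seed 1 --out report.json
dream coldstart --mode unseen_drug --small ...   # same data options
```

Real benchmark matrices (TSV/CSV or `.mat` containers) load through the
same `dream cv` entry point; `DreamConfig()` without the `small` preset
carries the full-scale hyperparameter defaults.

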