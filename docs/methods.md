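# Methods

## Problem setting

Given N_d drugs, N_m diseases, a binary association matrix (1 = validated
therapeutic association, 0 = unknown — not a verified negative), precomputed
per-entity embeddings and optional predefined similarity matrices, the task
is to rank the unknown cells so that true-but-unobserved associations rise
to the top. Evaluation treats every held-out unknown pair as a negative
(no subsampling), so the positive class is rare (~0.1–5%) and AUPRC is the
informative metric; AUROC is reported alongside.

## Model

### Feature harmonization

Small-molecule embeddings are zero-padded to the protein width, stacked
drug-major and reduced by PCA to `drug_dim` components (default 768;
clamped to `min(N-1, D)` with a warning on small inputs, so desk-scale
fixtures run unchanged). The PCA mean and components are stored so held-out
entities can be projected identically at cold-start time. Component signs
are fixed by making each component's largest-magnitude loading positive,
which removes the sign ambiguity of the underlying SVD across linear-algebra
backends. Disease embeddings pass through; if the clamped drug width
differs, disease vectors are zero-padded or truncated to match, since the
two entity types must share one width downstream. PCA is fit per fold on
training entities only (all entities for pair-wise CV, where embeddings are
label-free; training entities only under cold-start).

### Topology route

The bipartite interaction graph carries two relations: `known` (training
positives) and `unknown` (a uniform seeded sample of training non-edges,
1:1 with the positives by default, resampled every epoch). Messages are
normalized by the geometric mean of the endpoint degrees *under that
relation*, computed on the realized (post-edge-dropout) graph, because the
propagation rule is evaluated on the graph actually present at that step.
Nodes isolated under a relation send and receive nothing (pre-activation
exactly zero). Relation weights are basis-decomposed (B = 4 by default);
by default the drug→disease and disease→drug directions share parameters,
and the no-sharing ablation splits each relation by message-source entity
type (four effective relations). The rule itself has no bias term; biases
live in the fusion layers. All L layers (default 3) share one hidden width
(`topo_hidden`) so the layer average is well-defined; the input h⁽⁰⁾ is not
part of the average. A final linear projection maps the averaged
representation to the common view width `topo_out`.

### Similarity route

Per entity type, two weighted kNN graphs (default k = 4): one from the
predefined similarity matrix, one from cosine similarity of the raw
(pre-PCA) embeddings — the same space used for cold-start retrieval. Edge
weights are the similarity values verbatim, never binarized; negative
cosines are clipped to zero because normalization requires non-negative
weights. Symmetrization is by union (an edge survives if either endpoint
selected it), which preserves connectivity under skewed similarity
distributions; mutual-kNN is available as a flag. The predefined graph is
sparsified to the same k for architectural symmetry, with a dense
passthrough flag. Self-loops enter only through the normalization
Â = D^{-1/2}(A + I)D^{-1/2}, never as stored edges. If no predefined matrix
is supplied, the route runs on the embedding-derived graph alone.

Each graph gets its own two-layer GCN (default widths 768 → 128 at full
scale); the second layer is left linear because the fusion ReLU immediately
follows. Default parameter sharing ties the two GCNs of one entity type
(`graphs` granularity); `entity_types` additionally ties drugs and
diseases, and `none` unties everything (the no-sharing ablation).

### Fusion and decoding

Additive attention produces per-node view weights on the 2-simplex;
attention dropout (default 0.1) is applied to the per-view logits before
the softmax, so evaluation-mode weights are deterministic. The fused
embedding is the weighted sum of the views with standard (inverted)
dropout. The decoder is a three-layer MLP on the ordered concatenation
[z_drug ; z_disease] with hidden sizes (256, 64) at full scale — a standard
tapering choice, since the reference design does not pin them — and ReLU
between layers. Training loss is mean binary cross-entropy computed in
logit space with the `max(z,0) − zy + log1p(exp(−|z|))` form, so extreme
logits cannot overflow. A single dropout rate (default 0.3) serves both the
similarity fusion and the view fusion, with per-site overrides possible in
code.

### Route ablations

`topology_only` removes the similarity encoder and feeds the projected
topology view straight to the decoder (fusion degenerates to weight (1,0));
`similarity_only` is the mirror image. The four other named variants toggle
attention dropout, parameter sharing, augmentation, and pretrained-versus-
random node features.

## Training and evaluation protocol

Positives and unknowns are shuffled (seeded) and split independently into
10 near-equal folds; each fold's test set is its positives plus *all* of
its unknowns. Every fold rebuilds the training graph from training edges
only; an audit asserts that no held-out pair occurs as an edge of any
relation, and the cold-start protocol additionally asserts that held-out
entities are absent from every training structure. Optimization is AdamW
(lr 2e-3, weight decay 1e-5). Per epoch: resample the unknown edges (they
double as the loss negatives), apply Gaussian feature perturbation
(σ = 0.05) and edge dropout (P = 0.10) on the bipartite graph when
augmentation is on, then take one full-batch step.

Early stopping watches a 5% validation slice of the training positives
scored against a large fixed sample of training unknowns (≥ 200), and the
monitored quantity is validation AUROC: with only a handful of validation
positives, validation loss or AUPRC are noisy enough that checkpoint
restoration can pin to a lucky very-early epoch and ruin a fold — AUROC
ranking over a few hundred negatives is markedly more stable. The
best-validation parameters are restored. Full-scale defaults run up to
1000 epochs (patience 50); the desk-scale preset 600 (patience 60).

Cold-start uses entity-wise folds (each drug or disease held out exactly
once). Retrieval uses k = 4 neighbors and temperature τ = 0.1 by default;
the pseudo-query is formed in the fused-embedding space, because that is
the space the decoder consumes. Pairs between two held-out entities are
excluded from scoring (neither endpoint has a trained representation).
Secondary F1/recall are computed at threshold 0.5.

## Synthetic data generator

The generator emulates the benchmark inputs from one latent mechanism.
Entities belong to one of `n_blocks` communities (default 3); each entity's
latent factor is its unit-norm community centroid plus isotropic noise
N(0, noise_sigma²). Raw embeddings expose the latent factor (a random
subset of drugs, 20% by default, is tagged protein-like with extra raw
dimensions to exercise zero-padding). Predefined similarities are clipped
cosines of an independently re-noised copy of the latent factor, so the two
similarity sources are correlated but not identical. Associations are
Bernoulli with

    p_ij = sigmoid( a + signal_strength · [ cos(ℓ_i, ℓ_j) + popularity_scale · (c_i + d_j) ] ),

where c_i, d_j ~ N(0,1) are per-entity popularity offsets and the intercept
`a` is solved by root-finding so the expected density hits `assoc_density`
(default 0.05). With `signal_strength = 0` the labels are independent of
everything — an exact null dataset.

Default conditions are 60 drugs × 40 diseases, 3 blocks, 32-dim embeddings,
`noise_sigma = 0.15`, `signal_strength = 25`, `popularity_scale = 0.1`.
The noise and strength values were calibrated against two oracle analyses
of the generative model itself (not against this package's trained models):
ranking pairs by the true latent affinity (the Bayes bound) and a reference
classifier trained on features pre-smoothed by the same normalized-adjacency
propagation the GCN applies (an information bound for this architecture
class). At the chosen defaults those bounds sit near AUROC 0.95 / 0.91,
so the planted signal is genuinely recoverable by a two-layer-GCN-class
model, and the resulting operating regime (AUROC ≈ 0.9, AUPRC ≈ 0.3–0.5 at
5% density) resembles the published benchmark regime. The popularity term
plants degree heterogeneity — hub drugs and frequently indicated diseases —
which is a hallmark of the real association matrices and is invisible to
the embeddings; it is precisely the structure the topology route exists to
exploit, and it is scaled inside the signal bracket so the null dataset
stays exactly null.

What the generator does *not* emulate: real chemical-fingerprint statistics,
ontology semantics, the heavy-tailed degree distributions of curated
databases, correlated annotation noise, or any relationship between
similarity sources beyond the shared latent factor. Passing tests therefore
demonstrate that the pipeline recovers plantable low-dimensional structure
under its own protocol — not that it attains any particular accuracy on
curated benchmark data.

## Numerical choices

- σ in the topology rule is ReLU (configurable); the GCN hidden activation
  likewise.
- Similarity-matrix symmetrization tolerates asymmetry ≤ 1e-6 (averaged
  away); larger asymmetry is an error. kNN ties break toward the lower
  index; cold-start retrieval sorts stably for the same reason.
- The autodiff core computes exact gradients (checked against central
  finite differences at 1e-6); BCE is evaluated in logit space; softmax is
  shifted by the row max.
- Degenerate inputs: all-zero adjacency normalizes to the identity;
  entities with zero-norm embeddings are an error under cosine; empty
  batches are an error for loss and metrics; single-class label vectors are
  an error for AUROC/AUPRC; zero-variance differences in the paired t-test
  warn and return the sign convention (t = ±∞, or 0 when the means agree).

## Known limitations

- Full-batch training on dense matrices: fine up to a few thousand
  entities, not designed for web-scale graphs.
- The per-epoch unknown-edge resample doubles as the loss negative sample
  (ratio 1:1 by default); a known-edges-only graph mode exists
  (`unknown_edges_in_graph = False`) because the right density of
  negative-evidence edges is an open modeling question.
- Cold-start quality is bounded by how well raw-embedding cosine reflects
  functional similarity; entities whose nearest training neighbors are
  uninformative inherit their scores.
- F1/recall depend on an arbitrary 0.5 threshold and are reported as
  secondary only.
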