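# Methods

## Model and procedure

`comorbnet` treats comorbidity prediction as binary classification of
disease pairs on a protein–protein interaction network. The pipeline:

1. **Network.** The PPI network is an undirected graph over gene
   identifiers (opaque strings; no numeric semantics). Self-loops and
   duplicate edges are dropped at parse time with a warning. All analysis
   runs on the largest connected component, because the geometric
   embedding is defined only for a connected graph (disconnected
   components have no finite mutual geodesic distance). Real interactomes
   put ~99% of proteins in one component, so little is lost.

2. **Embedding.** Let **D** be the matrix of all-pairs geodesic
   distances (BFS hop counts, or Dijkstra sums of positive weights).
   Classical MDS double-centers the squared distances,
   A = −½ J D² J with J = I − n⁻¹11′, and takes the top-m eigenpairs:
   X = E_m Λ_m^{1/2}. Centered MCE applies the same machinery to
   *minimum curvilinear* distances — path lengths along the minimum
   spanning tree — which emphasize the hierarchical backbone of the
   network; ncMCE skips the centering and applies a truncated SVD to the
   MC distance matrix, X = U_m Σ_m^{1/2}. Centered MCE is the default
   method.

3. **Pathway weighting (optional).** Each edge gets weight
   w(e) = 1/(1 + freq(e)), where freq(e) counts pathways containing both
   endpoints. The transform is bounded in (0, 1], strictly decreasing in
   freq, and reduces to the unweighted case when all frequencies are
   equal — so frequently co-annotated edges are preferentially selected
   by the *minimum* spanning tree. Path lengths along the weighted MST
   sum the weights (a `use_weights` switch on the distance computation;
   weighting only the tree construction is possible by rebuilding the
   tree with unit weights).

4. **Features.** A disease pair's module is the set union of its two
   gene sets (shared genes counted once). Its fingerprint has m + 3
   entries: per-axis projections f_i = Σ_{g∈M} z_i(g), mean degree, mean
   raw betweenness centrality (unordered source–target pairs, endpoints
   excluded, unweighted shortest paths), and the mean number of
   annotated pathways per gene (genes without annotation count 0 —
   membership counts are averaged, not the number of distinct module
   pathways).

5. **Classification.** Pairs are labeled from clinical relative risk:
   at threshold 0 only RR = 0 pairs are negative (label 1 ⇔ RR > 0); at
   threshold t > 0, label 1 ⇔ RR ≥ t (canonically t = 1). Classifiers:
   linear SVM, RBF SVM (C = 3.5, γ = 1.06), polynomial SVM
   ((⟨x,x′⟩+1)⁴), 100-tree random forest. These hyperparameter values
   are adopted as fixed defaults (they were optimized for this task
   elsewhere); a config object overrides them.

6. **Evaluation.** Stratified k-fold (default 10): positives and
   negatives are shuffled and split into k near-equal subsets
   independently; fold i tests on positive subset i ∪ negative subset i.
   Metrics: precision, recall, F1, accuracy from the confusion matrix,
   and ROC AUC from ranking scores (SVM decision margin; class-1
   probability for the forest), equal to the Mann–Whitney statistic with
   0.5 credit for ties. Per-fold metric vectors can be compared with a
   two-sided paired t-test. The baseline ranks pairs by −S_AB, the
   negated nearest-neighbor module separation
   S_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩)/2.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| m (dimension) | 20 | configurable 2–50; returns diminish beyond ~13 and noise grows with m |
| RBF C, γ | 3.5, 1.06 | fixed optimized values; see feature scaling below |
| polynomial degree | 4 | fixed optimized value |
| RR threshold | 1 (or 0) | clinical convention: RR ≥ 1 ⇒ enriched co-occurrence |
| folds k | 10 | standard protocol; each class must have ≥ k members |
| pathway weight | 1/(1+freq) | bounded, monotone, unit weight when unannotated |

## Numerical choices

- **Indefinite Gram matrices.** Graph distances are generally
  non-Euclidean, so A has negative eigenvalues; they are clamped to zero
  (with a logged warning) before the square root. The `eigenvalues`
  attribute keeps the unclamped spectrum for diagnostics.
- **Sign convention.** Eigenvectors and singular vectors are
  canonicalized so the first non-zero entry of each axis is positive;
  embeddings are then invariant to node input order (nodes are always
  processed in lexicographic order).
- **ncMCE scaling.** Singular vectors are scaled by Σ^{1/2}, matching
  the Λ^{1/2} convention of the centered variants.
- **Ties.** The MST uses Kruskal with lexicographic edge tie-breaking;
  component-size ties break by smallest node label. Both make runs
  reproducible bit-for-bit.
- **Feature scaling.** Features are z-scored with statistics fitted on
  the training folds only (no leakage). A fixed kernel width γ only
  makes sense at a matching distance scale, so the scaling is exposed as
  a config switch (`standardize`).
- **Degenerate inputs.** Singleton modules have within-distance 0 by
  convention; empty gene sets are an error for degree/separation and
  project to the zero vector; single-class truth makes ROC undefined
  (reported as NaN with a warning, other metrics still computed);
  a paired t-test on identical fold vectors returns p = 1, and a
  zero-variance non-zero difference is reported as 0 (< 1e-12).

## The synthetic benchmark

The generator produces data with the statistical features the method
relies on, at a scale where everything runs on one CPU in seconds:

- **Interactome:** preferential attachment (attachment parameter 2,
  n = 2000 by default) — connected by construction, heavy-tailed degrees
  like real PPI maps. Edge count is (a−1) + (n−a)·a.
- **Pathways:** node sets of seeded random walks (each induces a
  connected subgraph), 400 sets of 5–30 genes — matching the density of
  curated human pathway collections (~0.2 pathways per protein) at this
  node count.
- **Disease pairs:** 200 pairs, half comorbid, module sizes 8–25 genes
  (bracketing typical disease modules, e.g. 13 and 24 genes for a
  leprosy/lymphoma pair). Comorbid pairs draw both modules from one
  seed's breadth-first neighborhood, share 3–6 genes, and get RR in
  [1, 10]. Non-comorbid pairs get RR < 1 with a 0.3 point mass at 0
  (clinical tables put ~17% of all pairs at RR = 0, about a third of the
  non-comorbid ones).

Three deliberate asymmetries plant the *learnable* part of the signal
while keeping raw proximity an imperfect predictor, as it is on clinical
data:

- **Comorbidity hotspots.** Comorbid seeds are drawn from a few
  disease-dense neighborhoods (3 balls of radius 2 around well-separated
  hubs); non-comorbid seeds are uniform. Position on the interactome
  therefore carries class information — exactly the association that the
  gene-randomization control (preserving |A|, |B|, |A∩B| but scattering
  positions) destroys, which is why the randomized pipeline drops to
  chance.
- **Pleiotropic shared genes.** Comorbid pairs' shared genes are sampled
  degree-biased: genes associated with two diseases at once are
  pleiotropic, and pleiotropic genes are hubs.
- **Pathway coherence.** Half of the pathway walks start at a shared
  gene of a truly comorbid pair: shared genes of comorbid diseases act
  through coherent pathways. Proximal *non-comorbid* look-alikes (30% of
  negatives) share genes too, but without pathway anchoring — so module
  separation alone misranks them while the classifier can use the
  pathway-count and positional features. This is what makes the
  S_AB baseline measurably weaker than the trained model, mirroring the
  ordering observed on real data without reproducing its exact numbers.

What the generator does **not** emulate: literature-curated association
noise, disease pairs sharing diseases across records, RR magnitudes
calibrated to prevalence models, and the size (≈13k nodes) and
clustering structure of the real interactome. Passing the benchmark
shows the pipeline recovers a planted positional/pathway signal end to
end; it does not certify performance on clinical data.

Problem sizes used by the test suite and the acceptance script: the full
benchmark (n = 2000, 200 pairs, m = 20) for the end-to-end checks, five
replicate datasets for the weighted-vs-unweighted comparison, and
300-node fixtures for unit tests. All generators are bit-reproducible
under a fixed seed.

## Known limitations

- Dense eigendecomposition holds the full n × n distance matrix in
  memory; fine to ~15k nodes, beyond that a sparse/iterative solver
  would be needed.
- The m + 3 fingerprint sums coordinates over the module, so it encodes
  module *position* and size, not spread; signals living purely in
  module compactness are invisible to it (the S_AB baseline sees those).
- Betweenness is exact Brandes on the full graph; it is the slowest
  feature step (seconds at n = 2000) and is computed once and shared
  across pairs.
- The RR thresholds treat relative risk as exact; no uncertainty on RR
  is modeled.
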