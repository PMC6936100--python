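# comorbnet

Predicting comorbid disease pairs from the geometry of the human
interactome.

Comorbidity — two diseases co-occurring in the same patients more often
than chance — leaves a genetic footprint: the gene modules of comorbid
diseases tend to overlap and sit close together on the protein–protein
interaction (PPI) network. The classical way to exploit this is the
network separation statistic

    S_AB = ⟨d_AB⟩ − (⟨d_AA⟩ + ⟨d_BB⟩) / 2,

which compares cross-module nearest-neighbor shortest-path distances with
the within-module ones (negative S_AB ⇒ overlapping modules). `comorbnet`
goes further: it embeds the interactome into an m-dimensional geometric
space and *fingerprints* each disease pair, turning comorbidity prediction
into supervised classification.

The embedding is spectral. Given the all-pairs geodesic distance matrix
**D** of the largest connected component, double centering

    A = −½ J D² J,   J = I − n⁻¹ 1 1′

yields a Gram matrix whose top-m eigenpairs give coordinates
X = E_m Λ_m^{1/2} (classical MDS / Isomap). Two minimum-curvilinear
variants measure distances along the graph's minimum spanning tree
instead: centered MCE (the default) applies the same double-center +
eigendecomposition to MST path lengths, and ncMCE applies a truncated SVD
to the MC distance matrix directly. Optionally, edges are weighted by
pathway co-membership, w(e) = 1/(1 + freq(e)), so edges whose endpoints
share many pathways are preferentially kept in the *minimum* spanning
tree.

Each disease pair (gene modules A, B) becomes an (m+3)-vector: the
projection of the union module onto each axis, f_i = Σ_{g∈A∪B} z_i(g),
plus the module's mean degree, mean betweenness centrality, and mean
number of annotated pathways per gene. An SVM (linear / RBF with C = 3.5,
γ = 1.06 / polynomial (⟨x,x′⟩+1)⁴) or a 100-tree random forest is trained
on pairs labeled by a relative-risk threshold (RR ≥ 1, or RR > 0) and
evaluated with a class-stratified 10-fold protocol (precision, recall, F1,
accuracy, ROC AUC), against the −S_AB baseline ranking.

A synthetic-data module generates scale-free interactomes, random-walk
pathway gene sets and disease-pair datasets with a planted comorbidity
signal, so the entire pipeline is testable without any external data.

## Worked example

```sh
comorbnet simulate --out data --preset benchmark --seed 5
# wrote 2000 nodes, 3997 edges, 400 pathways, 200 pairs to data

comorbnet embed --edges data/interactome.tsv --dim 20 --method mce --out emb.tsv
# embedded 2000 nodes into 20 dimensions (mce) -> emb.tsv

comorbnet featurize --edges data/interactome.tsv --embedding emb.tsv \
    --gmt data/pathways.gmt --disease-genes data/disease_genes.tsv \
    --pairs data/pairs.tsv --out features.tsv
# wrote 200 feature rows (20 + 3 columns) -> features.tsv

comorbnet baseline --edges data/interactome.tsv \
    --disease-genes data/disease_genes.tsv --pairs data/pairs.tsv \
    --out baseline.tsv
# baseline ROC AUC = 0.8723 over 200 pairs -> baseline.tsv

comorbnet evaluate --features features.tsv --classifier svm_rbf \
    --folds 10 --seed 2 --out-prefix eval
# mean ROC AUC = 0.8980 (precision 0.969, recall 0.650, F1 0.762, accuracy 0.815)
```

The classifier's cross-validated ROC AUC (0.898 here) is the probability
that a randomly drawn comorbid pair outranks a randomly drawn non-comorbid
one; it exceeds the module-separation baseline (0.872), i.e. the geometric
fingerprint carries signal that raw network proximity misses. Per-fold
metrics, ROC curve points and a summary land in `eval.folds.tsv`,
`eval.roc.tsv` and `eval.summary.txt`; runs with the same seed are
byte-identical.

The same pipeline is available as a library (`comorbnet.run_benchmark`
wires generator → embedding → features → cross-validation in one call).

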