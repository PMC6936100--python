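"""End-to-end pipelines: synthetic benchmark and file-based runs.

`run_benchmark` wires the whole method together on generated data: build
the interactome, plant disease pairs, annotate pathways, embed, featurize,
cross-validate a classifier, and score the module-separation baseline and
the two controls (label shuffling, gene randomization).  It is the single
entry point used by the acceptance experiments and the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import classify, diseases, embedding, features, network, simulate

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkResult", "embed_graph", "run_benchmark"]


@dataclass
class BenchmarkResult:
    """Metric means, per-fold table and control scores of one benchmark run."""

    mean_metrics: dict[str, float]
    fold_table: pd.DataFrame
    baseline_auc: float | None = None
    shuffled_auc: float | None = None
    randomized_auc: float | None = None
    feature_table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def auc(self) -> float:
        return self.mean_metrics["roc_auc"]


def embed_graph(
    g: nx.Graph,
    m: int,
    method: str = "mce",
    use_weights: bool = False,
) -> embedding.Embedding:
    """Dispatch to the requested embedding of a connected graph."""
    if method == "mds":
        return embedding.embed_mds(g, m, use_weights=use_weights)
    if method == "mce":
        return embedding.embed_mce(g, m, use_weights=use_weights)
    if method == "ncmce":
        return embedding.embed_ncmce(g, m, use_weights=use_weights)
    raise ValueError(f"unknown embedding method {method!r}")


def run_benchmark(
    cfg: simulate.SyntheticConfig,
    m: int = 20,
    method: str = "mce",
    weighted: bool = False,
    classifier: classify.ClassifierConfig | None = None,
    rr_threshold: float = 1.0,
    k: int = 10,
    with_baseline: bool = False,
    with_shuffled: bool = False,
    with_randomized: bool = False,
) -> BenchmarkResult:
    """Run the full pipeline on a planted-signal synthetic dataset.

    Parameters mirror the study protocol: embed with ``method`` into ``m``
    dimensions (pathway-frequency edge weights drive the MST when
    ``weighted``), fingerprint each pair with m + 3 features, label at the
    RR threshold, and run stratified k-fold cross-validation.  Optional
    extras compute the -S_AB baseline AUC, a label-shuffled control AUC and
    a gene-randomized control AUC on the same data.
    """
    classifier = classifier or classify.ClassifierConfig(seed=cfg.seed)
    g = simulate.generate_interactome(cfg)
    dgmap, pairs = simulate.generate_disease_dataset(g, cfg)
    # pathway walks anchor at the shared genes of comorbid pairs: shared
    # disease genes of truly comorbid pairs act through coherent pathways
    anchors = sorted(set().union(*(
        dgmap[p.disease_a] & dgmap[p.disease_b]
        for p in pairs if p.rr >= 1.0), set()))
    pathways = simulate.generate_pathways(g, cfg, start_nodes=anchors or None)

    g_embed = network.pathway_edge_weights(g, pathways) if weighted else g
    emb = embed_graph(g_embed, m, method=method, use_weights=weighted)

    table = features.build_feature_table(emb, g, pathways, pairs, dgmap)
    x = table[features.feature_columns(table)].to_numpy(dtype=float)
    y = classify.labels_array(pairs, rr_threshold)

    mean_metrics, fold_table = classify.cross_validate(
        x, y, classifier, k=k, seed=cfg.seed)
    result = BenchmarkResult(mean_metrics=mean_metrics, fold_table=fold_table,
                             feature_table=table)

    if with_baseline:
        d = network.all_pairs_shortest_paths(g)
        scores = diseases.sab_baseline_scores(pairs, d, dgmap)
        s = np.array([scores[p.key] for p in pairs])
        result.baseline_auc = float(roc_auc_score(y, s))
    if with_shuffled:
        rng = np.random.default_rng([cfg.seed, 7])
        y_shuf = y.copy()
        rng.shuffle(y_shuf)
        shuf_metrics, _ = classify.cross_validate(x, y_shuf, classifier, k=k,
                                                  seed=cfg.seed)
        result.shuffled_auc = shuf_metrics["roc_auc"]
    if with_randomized:
        rmap = simulate.randomize_pair_genes(dgmap, pairs, g, seed=cfg.seed)
        rtable = features.build_feature_table(emb, g, pathways, pairs, rmap)
        rx = rtable[features.feature_columns(rtable)].to_numpy(dtype=float)
        rmetrics, _ = classify.cross_validate(rx, y, classifier, k=k, seed=cfg.seed)
        result.randomized_auc = rmetrics["roc_auc"]
    return result
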