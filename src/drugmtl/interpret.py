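"""Post-hoc interpretation of learned weight matrices.

Three analyses mirror how multitask drug models are usually read out:

* hierarchical clustering of the per-drug coefficient vectors (Ward linkage
  on Euclidean distances) — drugs with a shared mechanism of action should
  merge early when the learner has captured mechanism-level structure;
* adjusted Rand index between a flat cut of that dendrogram and an external
  mechanism-of-action annotation;
* hypergeometric enrichment of the top-weighted features of a single drug's
  model against user-supplied gene sets (GMT), with the background taken as
  the model's feature universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from .data import GeneSetCollection

__all__ = [
    "ClusterResult",
    "cluster_drug_models",
    "flat_cut",
    "adjusted_rand",
    "top_feature_enrichment",
    "cluster_ari_vs_annotation",
]


@dataclass
class ClusterResult:
    """Agglomerative clustering of the columns (drugs) of a weight matrix."""

    linkage: np.ndarray  # scipy linkage matrix, (T-1) x 4
    drug_ids: list[str]
    method: str = "ward"
    metric: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.drug_ids)

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.drug_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def cluster_drug_models(W: np.ndarray, drug_ids: list[str] | None = None) -> ClusterResult:
    """Ward hierarchical clustering of drug coefficient vectors (columns of W).

    Uses Ward's minimum-variance criterion on Euclidean distances (the
    squared-distance Lance-Williams recursion, i.e. the classic hclust
    "ward" topology).  Deterministic; merge heights are non-decreasing.
    """
    W = np.asarray(W, dtype=float)
    if not np.isfinite(W).all():
        raise ValueError("weight matrix contains non-finite entries")
    if W.shape[1] < 2:
        raise ValueError("need at least 2 drugs to cluster")
    drug_ids = drug_ids or [f"drug{t}" for t in range(W.shape[1])]
    Z = hierarchy.linkage(W.T, method="ward", metric="euclidean")
    return ClusterResult(Z, list(drug_ids))


def flat_cut(result: ClusterResult, k: int) -> np.ndarray:
    """Cut the dendrogram into k flat clusters (labels 1..k, leaf order)."""
    if not 1 <= k <= result.n_leaves:
        raise ValueError(f"k must be in [1, {result.n_leaves}], got {k}")
    return hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement (permutation-model ARI)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors have different lengths")
    return float(adjusted_rand_score(labels_a, labels_b))


def cluster_ari_vs_annotation(
    W: np.ndarray,
    drug_ids: list[str],
    annotation: dict[str, str],
    k: int | None = None,
) -> tuple[float, np.ndarray, ClusterResult]:
    """Cluster W's columns, cut at k (default: number of annotated classes),
    and score agreement with the mechanism-of-action annotation by ARI.

    Only annotated drugs enter the comparison; unannotated drugs still shape
    the tree but are dropped from the ARI.
    """
    res = cluster_drug_models(W, drug_ids)
    annotated = [i for i, d in enumerate(drug_ids) if d in annotation]
    if len(annotated) < 2:
        raise ValueError("fewer than 2 annotated drugs")
    classes = [annotation[drug_ids[i]] for i in annotated]
    if k is None:
        k = len(set(classes))
    labels = flat_cut(res, k)
    ari = adjusted_rand(labels[annotated], pd.factorize(np.asarray(classes))[0])
    return ari, labels, res


def top_feature_enrichment(
    weights: np.ndarray,
    feature_ids: list[str],
    gene_sets: GeneSetCollection,
    n_top: int = 100,
    mode: str = "absolute",
) -> pd.DataFrame:
    """Hypergeometric enrichment of a model column's top-weighted features.

    ``mode='absolute'`` ranks by |weight| (the convention for dense low-rank
    models); ``mode='positive'`` ranks by signed weight and, when fewer than
    ``n_top`` features have positive weight (common for sparse models),
    tests all positive features instead.  Upper-tail hypergeometric p per
    set against the background restricted to the model's features; raw
    p-values, no multiplicity correction.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(feature_ids):
        raise ValueError("weights and feature ids have different lengths")
    if mode == "absolute":
        order = np.argsort(-np.abs(weights), kind="stable")
        selected = [feature_ids[i] for i in order[: min(n_top, len(weights))]]
    elif mode == "positive":
        pos = np.flatnonzero(weights > 0)
        order = pos[np.argsort(-weights[pos], kind="stable")]
        selected = [feature_ids[i] for i in order[:n_top]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not selected:
        raise ValueError("no features selected for enrichment")
    gs = gene_sets.restrict_background(list(feature_ids))
    background = set(gs.background)
    sel = set(selected) & background
    if not sel:
        raise ValueError("selected features do not intersect the background")
    M, n = len(background), len(sel)
    rows = []
    for name, members in gs.sets.items():
        mem = set(members) & background
        K = len(mem)
        k = len(mem & sel)
        # P(X >= k) for X ~ Hypergeom(M, K, n)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "M": M, "p": p})
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
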