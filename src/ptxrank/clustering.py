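"""Unsupervised sample clustering and cluster-vs-outcome association.

Samples are clustered on log-transformed normalized counts with correlation
distance and average linkage, and the tree is cut at K = 3 — matching the
expectation of a LUAD-enriched, a LUSC-enriched and a mixed-histology poor
response/survival (PR/S) cluster.  The candidate PR/S cluster (the one with
the highest fraction of poor-response samples) is tested for poor-response
enrichment with a one-sided Fisher exact test and compared against all other
samples by log-rank on recurrence-free survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cut_tree, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact
from sklearn.metrics import silhouette_score

from .containers import CountMatrix
from .survival import SurvivalComparison, assign_response_groups, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    sample_ids: list[str]
    assignment: np.ndarray  # cluster label per sample, 0..k-1
    linkage: np.ndarray = field(repr=False)
    k: int = 3
    silhouette: float | None = None
    identifications: np.ndarray | None = None  # nonzero proteins per sample

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.assignment) if c == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.assignment})


def cluster_samples(
    norm: CountMatrix,
    k: int = 3,
    metric: str = "correlation",
    method: str = "average",
    scale_rows: bool = True,
) -> ClusteringResult:
    """Hierarchical clustering of samples, tree cut at ``k``.

    Works on log2(x+1) transformed values, by default z-scored per protein
    (relative expression) so that sample-sample correlation reflects shared
    deviations from the cohort profile rather than the overall abundance
    distribution common to all samples.  Deterministic.
    """
    n = len(norm.sample_ids)
    if k > n:
        raise ValueError(f"cannot cut {n} samples into {k} clusters")
    logm = np.log2(norm.data.to_numpy(dtype=float) + 1.0)
    if scale_rows:
        mu = logm.mean(axis=1, keepdims=True)
        sd = logm.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        logm = (logm - mu) / sd
    X = logm.T
    dist = pdist(X, metric=metric)
    if method != "average":
        from scipy.cluster.hierarchy import linkage as _linkage

        Z = _linkage(dist, method=method)
    else:
        Z = average(dist)
    labels = cut_tree(Z, n_clusters=k).ravel()
    sil = None
    if 1 < k < n:
        try:
            sil = float(silhouette_score(X, labels, metric=metric))
        except ValueError:
            sil = None
    ident = (norm.data.to_numpy() > 0).sum(axis=0)
    return ClusteringResult(
        sample_ids=list(norm.sample_ids),
        assignment=labels,
        linkage=Z,
        k=k,
        silhouette=sil,
        identifications=ident,
    )


@dataclass
class OutcomeAssociation:
    prs_cluster: int
    fisher_p: float
    odds_ratio: float
    logrank: SurvivalComparison
    prg_fraction: dict[int, float]


def cluster_outcome_association(
    result: ClusteringResult, annotation: pd.DataFrame
) -> OutcomeAssociation:
    """Associate the poor-response-enriched cluster with outcome.

    The flagged cluster is the one with the highest PRG fraction; membership
    is crossed with PRG status in a one-sided (enrichment) Fisher exact
    test, and the cluster is compared with all other samples by log-rank on
    recurrence-free survival.
    """
    ann = assign_response_groups(annotation).set_index("sample_id")
    shared = [s for s in result.sample_ids if s in ann.index]
    if len(shared) < len(result.sample_ids):
        logger.warning(
            "%d clustered samples lack annotation and are excluded",
            len(result.sample_ids) - len(shared),
        )
    ann = ann.loc[shared]
    assignment = {s: c for s, c in zip(result.sample_ids, result.assignment)}
    clusters = np.array([assignment[s] for s in shared])
    is_prg = (ann["response_group"] == "PRG").to_numpy()

    prg_fraction = {}
    for c in np.unique(clusters):
        mask = clusters == c
        prg_fraction[int(c)] = float(is_prg[mask].mean())
    prs = max(prg_fraction, key=lambda c: (prg_fraction[c],))

    in_prs = clusters == prs
    table = [
        [int((in_prs & is_prg).sum()), int((in_prs & ~is_prg).sum())],
        [int((~in_prs & is_prg).sum()), int((~in_prs & ~is_prg).sum())],
    ]
    odds, fisher_p = fisher_exact(table, alternative="greater")

    lr = logrank_test(
        (ann.loc[in_prs, "rfs_months"].to_numpy(), ann.loc[in_prs, "event"].to_numpy().astype(bool)),
        (ann.loc[~in_prs, "rfs_months"].to_numpy(), ann.loc[~in_prs, "event"].to_numpy().astype(bool)),
        labels=("PR/S", "Rest"),
    )
    return OutcomeAssociation(
        prs_cluster=int(prs),
        fisher_p=float(fisher_p),
        odds_ratio=float(odds),
        logrank=lr,
        prg_fraction=prg_fraction,
    )


def dendrogram_newick(result: ClusteringResult) -> str:
    """Serialize the linkage tree as a Newick string with sample-id leaves."""
    tree = to_tree(result.linkage)
    names = result.sample_ids

    def rec(node) -> str:
        if node.is_leaf():
            return f"{names[node.id]}:{node.dist:.6g}"
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return f"({rec(tree.left)},{rec(tree.right)});"
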