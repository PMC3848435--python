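"""Evaluation of clusterings against known read origins.

Recall rate: for a gene G whose reads are spread over the clusters with
fractions f_1..f_K, R_G = max_k f_k — the largest part of G kept together,
i.e. how little the clustering would fragment a per-cluster assembly.

Soft clusterings are thresholded: read a belongs to every cluster whose
membership Z_{a,alpha} >= epsilon, so clusters may overlap or miss reads.
Sweeping epsilon yields an ROC-like curve: at each epsilon the "correct"
cluster for gene G is the one embracing the largest part of G's reads,
TPR is the fraction of G's reads assigned to it, and FPR the fraction
assigned to at least one other cluster (a read can count toward both).
The limits are (FPR, TPR) = (1, 1) as epsilon -> 0 and (0, 0) as
epsilon -> 1 (when no membership reaches 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "recall_rates",
    "recall_rate",
    "threshold_assign",
    "roc_curve",
    "RocCurve",
    "partition_agreement",
]


def recall_rates(assignments, labels, n_clusters: int | None = None) -> dict:
    """Per-gene recall rate R_G = max_k (fraction of G's reads in cluster k).

    Genes with zero reads are simply absent from the result.
    """
    z = np.asarray(assignments)
    labels = np.asarray(labels)
    if z.shape[0] != labels.shape[0]:
        raise ValueError("assignments and labels differ in length")
    K = n_clusters or (int(z.max()) + 1 if z.size else 0)
    out = {}
    for gene in pd.unique(labels):
        mask = labels == gene
        counts = np.bincount(z[mask], minlength=K)
        out[gene] = counts.max() / mask.sum()
    return out


def recall_rate(fractions) -> float:
    """Recall from the per-cluster fractions of one gene's reads: max f_k."""
    f = np.asarray(fractions, dtype=float)
    if f.size == 0:
        raise ValueError("empty fraction vector")
    if not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("cluster fractions must sum to 1")
    return float(f.max())


def threshold_assign(memberships, epsilon: float) -> np.ndarray:
    """Boolean (N, K) matrix: read a in cluster k iff Z_{a,k} >= epsilon.

    Rows may be all-False (epsilon above every membership) or have several
    True entries (overlapping clusters).
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must be in [0, 1]")
    Z = np.asarray(memberships, dtype=float)
    return Z >= epsilon


@dataclass
class RocCurve:
    """Threshold sweep of a soft clustering for one gene."""

    points: pd.DataFrame        # columns epsilon, fpr, tpr (epsilon NaN for endpoints)
    auc: float
    gene: object = None

    def __iter__(self):
        return iter(self.points[["fpr", "tpr"]].itertuples(index=False, name=None))


def _rates_at(assigned: np.ndarray, gene_mask: np.ndarray) -> tuple[float, float]:
    sub = assigned[gene_mask]
    n = sub.shape[0]
    counts = sub.sum(axis=0)
    correct = int(np.argmax(counts))            # ties -> lowest index
    tpr = counts[correct] / n
    others = np.ones(sub.shape[1], dtype=bool)
    others[correct] = False
    fpr = sub[:, others].any(axis=1).mean() if others.any() else 0.0
    return float(fpr), float(tpr)


def roc_curve(memberships, labels, gene, thresholds=None) -> RocCurve:
    """ROC-like curve for one gene over a membership-threshold sweep.

    By default the threshold grid is every distinct membership value plus
    {0, 1}, which traces the exact step curve.  At each epsilon the correct
    cluster is recomputed as the one holding the largest share of the
    gene's thresholded reads.  The curve is closed with the analytic
    endpoints (1, 1) and (0, 0); AUC is the trapezoid over FPR-sorted
    points.
    """
    Z = np.asarray(memberships, dtype=float)
    labels = np.asarray(labels)
    gene_mask = labels == gene
    if not gene_mask.any():
        raise ValueError(f"gene {gene!r} has no reads")
    if thresholds is None:
        thresholds = np.unique(np.concatenate([Z.ravel(), [0.0, 1.0]]))
    else:
        thresholds = np.asarray(list(thresholds), dtype=float)
        if thresholds.size == 0:
            raise ValueError("empty threshold grid")

    rows = []
    for eps in np.sort(thresholds):
        fpr, tpr = _rates_at(threshold_assign(Z, float(eps)), gene_mask)
        rows.append((float(eps), fpr, tpr))
    pts = pd.DataFrame(rows, columns=["epsilon", "fpr", "tpr"])
    endpoints = pd.DataFrame(
        {"epsilon": [np.nan, np.nan], "fpr": [1.0, 0.0], "tpr": [1.0, 0.0]}
    )
    pts = pd.concat([pts, endpoints], ignore_index=True)
    pts = pts.drop_duplicates(subset=["fpr", "tpr"]).sort_values(
        ["fpr", "tpr"], kind="stable"
    ).reset_index(drop=True)
    auc = float(np.trapezoid(pts["tpr"].to_numpy(), pts["fpr"].to_numpy()))
    return RocCurve(points=pts, auc=auc, gene=gene)


def partition_agreement(z1, z2) -> float:
    """Fraction of reads on which two hard partitions agree, after the best
    one-to-one matching of cluster labels (Hungarian algorithm)."""
    z1, z2 = np.asarray(z1), np.asarray(z2)
    if z1.shape != z2.shape:
        raise ValueError("partitions differ in length")
    k = max(z1.max(), z2.max()) + 1
    contingency = np.zeros((k, k), dtype=np.int64)
    np.add.at(contingency, (z1, z2), 1)
    rows, cols = linear_sum_assignment(-contingency)
    return float(contingency[rows, cols].sum() / z1.size)
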