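"""Bootstrap consensus clustering.

The base centroid method is run many times, each time on a random subsample
of the reads.  For every pair of reads the co-clustering distance is

    D_ij = 1 - (#runs clustering i and j together) / (#runs sampling both),

a dissimilarity in [0, 1] with zero diagonal.  An average-linkage tree is
built on D and cut into K groups for the consensus partition.  Pairs never
co-sampled get D_ij = 1 (conservative) with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cluster import ClusterConfig, ReadClusteringModel

logger = logging.getLogger("kmerclust")

__all__ = ["ConsensusResult", "consensus_cluster"]


@dataclass
class ConsensusResult:
    """Co-clustering distances, the linkage tree, and the consensus cut."""

    distance: np.ndarray          # (N, N) consensus dissimilarity
    together_counts: np.ndarray   # (N, N) runs where i, j shared a cluster
    cosampled_counts: np.ndarray  # (N, N) runs where i, j were both drawn
    linkage_matrix: np.ndarray    # scipy average-linkage encoding
    assignments: np.ndarray       # (N,) consensus clusters, 0-based
    n_runs: int
    subsample_fraction: float
    ids: list[str] | None = None

    def to_newick(self) -> str:
        """Average-linkage tree in Newick format, read IDs as leaf names."""
        from skbio.tree import TreeNode

        n = self.distance.shape[0]
        names = self.ids if self.ids is not None else [f"read{i}" for i in range(n)]
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, list(map(str, names)))
        return str(tree)

    def summary(self) -> str:
        sizes = np.bincount(self.assignments)
        return "\n".join([
            "Consensus clustering results",
            "=" * 40,
            f"reads:               {self.distance.shape[0]}",
            f"runs:                {self.n_runs}",
            f"subsample fraction:  {self.subsample_fraction}",
            f"mean distance:       {self.distance.mean():.4f}",
            "consensus cluster sizes: " + " ".join(str(s) for s in sizes),
        ])


def consensus_cluster(counts, cfg: ClusterConfig, runs: int = 20,
                      subsample_fraction: float = 0.8, *,
                      base_counts=None, ids=None) -> ConsensusResult:
    """Consensus clustering by repeated subsampled centroid runs.

    Each of ``runs`` rounds draws floor(N * subsample_fraction) reads
    without replacement (seeded from ``cfg.seed``), clusters them with the
    configured method (run ``r`` uses seed ``cfg.seed + r``), and updates
    the pair-count matrices.  The final partition cuts the average-linkage
    tree of the consensus distances into ``cfg.n_clusters`` groups.
    """
    if runs < 2:
        raise ValueError("consensus clustering needs at least 2 runs")
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")
    counts = np.asarray(counts)
    N = counts.shape[0]
    m = int(np.floor(N * subsample_fraction))
    if m < cfg.n_clusters:
        raise ValueError("subsample smaller than the number of clusters")

    rng = np.random.default_rng(cfg.seed)
    together = np.zeros((N, N), dtype=np.int64)
    cosampled = np.zeros((N, N), dtype=np.int64)
    for r in range(runs):
        idx = rng.choice(N, size=m, replace=False)
        sub_cfg = ClusterConfig(**{**cfg.__dict__, "seed": cfg.seed + r, "restarts": 1})
        sub_base = None if base_counts is None else np.asarray(base_counts)[idx]
        model = ReadClusteringModel(counts[idx], sub_cfg, base_counts=sub_base)
        res = model.fit()
        z = res.assignments if hasattr(res, "assignments") else res.hardened()
        same = (z[:, None] == z[None, :]).astype(np.int64)
        together[np.ix_(idx, idx)] += same
        cosampled[np.ix_(idx, idx)] += 1

    D = np.ones((N, N))
    seen = cosampled > 0
    D[seen] = 1.0 - together[seen] / cosampled[seen]
    if not seen.all():
        n_missed = int((~seen[np.triu_indices(N, k=1)]).sum())
        if n_missed:
            logger.warning(
                "%d read pair(s) were never co-sampled; their consensus "
                "distance is set to 1", n_missed,
            )
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)

    link = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(link, t=cfg.n_clusters, criterion="maxclust") - 1
    return ConsensusResult(
        distance=D,
        together_counts=together,
        cosampled_counts=cosampled,
        linkage_matrix=link,
        assignments=labels,
        n_runs=runs,
        subsample_fraction=subsample_fraction,
        ids=list(ids) if ids is not None else None,
    )
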