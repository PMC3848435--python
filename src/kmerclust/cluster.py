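"""Centroid-based clustering of reads by n-mer composition.

The central object is :class:`ReadClusteringModel`, built from an N x 4**n
count matrix (or directly from sequences).  ``fit()`` dispatches on the
configured method and returns a results object:

* ``em`` — hard expectation maximization under the multinomial/KL
  likelihood: the E-step assigns each read to the centroid minimizing
  D_KL(p_a | q_alpha), the M-step pools member counts (plus pseudocount)
  and renormalizes.  The distortion sum_a L_a D_KL(p_a | q_{z_a}) is
  non-increasing, so the iteration converges.
* ``soft_em`` — fractional memberships Z_{a,alpha} proportional to
  exp(-L_a D_KL(p_a | q_alpha)) (equal priors), centroids updated as
  membership-weighted pooled counts; returns a :class:`SoftPartition`.
* ``kmeans`` — Lloyd iteration on per-read simplex frequencies after
  whitening each column by its standard deviation.
* ``l2``, ``d2``, ``d2star``, ``chi2``, ``symkl`` — generic centroid
  iteration under the corresponding kernel from :mod:`kmerclust.distances`.
  l2 and d2 share the EM convergence property; d2*, chi-square and
  symmetrized KL do not, and may hit ``max_iter`` with ``converged=False``.

Hard methods stop when assignments stop changing; soft EM stops when the
largest membership change falls below ``tol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .distances import standardize, zero_order_expected_frequencies
from .kmers import KmerSpec, column_scales, count_matrix, kmer_labels

logger = logging.getLogger("kmerclust")

__all__ = [
    "ClusterConfig",
    "ReadClusteringModel",
    "HardPartition",
    "SoftPartition",
    "EmptyClusterError",
    "initialize",
    "em_hard",
    "em_soft",
    "kmeans",
    "centroid_iterate",
    "run_with_restarts",
    "distortion",
]

HARD_METHODS = ("em", "kmeans", "l2", "d2", "d2star", "chi2", "symkl")
METHODS = HARD_METHODS + ("soft_em",)


class EmptyClusterError(RuntimeError):
    """A cluster lost all its members under the strict (fail) policy."""


@dataclass(frozen=True)
class ClusterConfig:
    """Settings shared by every clustering method.

    ``pseudocount`` is added to pooled (centroid) counts so centroid
    compositions are strictly positive and the KL kernel stays finite; for
    the symmetrized-KL method it is also added to per-read counts, because
    that kernel requires mutual support.  ``empty_cluster_policy`` is either
    ``"reseed"`` (move the read farthest from its centroid into the empty
    cluster, logged) or ``"fail"`` (raise, mirroring the strict behaviour
    of plain EM).
    """

    n_clusters: int = 2
    method: str = "em"
    max_iter: int = 300
    tol: float = 1e-6
    restarts: int = 1
    seed: int = 0
    pseudocount: float = 1.0
    empty_cluster_policy: str = "reseed"

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.empty_cluster_policy not in ("fail", "reseed"):
            raise ValueError("empty_cluster_policy must be 'fail' or 'reseed'")


# --------------------------------------------------------------------------
# results objects


@dataclass
class HardPartition:
    """A hard clustering: one cluster index per read, plus diagnostics."""

    assignments: np.ndarray          # (N,) cluster indices, 0-based
    centroids: np.ndarray            # (K, 4**n) compositions (simplex, or unit norm for d2/d2star)
    distortion: float
    converged: bool
    iterations: int
    method: str
    n_clusters: int
    seed: int
    distortion_trace: list[float] = field(default_factory=list)
    pooled_counts: np.ndarray | None = None
    ids: list[str] | None = None

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_clusters)

    def summary(self) -> str:
        lines = [
            "Hard centroid clustering results",
            "=" * 40,
            f"method:      {self.method}",
            f"clusters:    {self.n_clusters}",
            f"reads:       {self.assignments.size}",
            f"distortion:  {self.distortion:.6g}",
            f"iterations:  {self.iterations}",
            f"converged:   {self.converged}",
            f"seed:        {self.seed}",
            "cluster sizes: " + " ".join(str(s) for s in self.cluster_sizes),
        ]
        return "\n".join(lines)


@dataclass
class SoftPartition:
    """A soft clustering: per-read membership probabilities over clusters."""

    memberships: np.ndarray          # (N, K), rows sum to 1
    centroids: np.ndarray            # (K, 4**n) simplex compositions
    expected_log_likelihood: float   # membership-weighted log-likelihood
    converged: bool
    iterations: int
    method: str
    n_clusters: int
    seed: int
    objective_trace: list[float] = field(default_factory=list)
    mixture_loglik_trace: list[float] = field(default_factory=list)
    penalized_loglik_trace: list[float] = field(default_factory=list)
    ids: list[str] | None = None

    def hardened(self) -> np.ndarray:
        """Hard assignments by maximal membership (ties -> lowest index)."""
        return np.argmax(self.memberships, axis=1)

    def summary(self) -> str:
        sizes = np.bincount(self.hardened(), minlength=self.n_clusters)
        lines = [
            "Soft EM clustering results",
            "=" * 40,
            f"clusters:              {self.n_clusters}",
            f"reads:                 {self.memberships.shape[0]}",
            f"expected log-lik:      {self.expected_log_likelihood:.6g}",
            f"iterations:            {self.iterations}",
            f"converged:             {self.converged}",
            f"seed:                  {self.seed}",
            "hardened cluster sizes: " + " ".join(str(s) for s in sizes),
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# internal data preparation


def _base_occurrence_matrix(n: int) -> np.ndarray:
    """(4**n, 4) matrix of how many times each base occurs in each word."""
    occ = np.zeros((4 ** n, 4), dtype=float)
    for i, w in enumerate(kmer_labels(n)):
        for b, base in enumerate("ACGT"):
            occ[i, b] = w.count(base)
    return occ


class _Data:
    """Precomputed per-read representations shared by all methods."""

    def __init__(self, counts: np.ndarray, base_counts: np.ndarray | None = None):
        C = np.asarray(counts, dtype=float)
        if C.ndim != 2:
            raise ValueError("counts must be a 2-D (reads x words) matrix")
        if np.any(C < 0):
            raise ValueError("negative counts")
        self.C = C
        self.N, self.M = C.shape
        n = int(round(np.log2(self.M) / 2))
        # word length is only recoverable for 4**n columns; it is needed by
        # the zero-order (chi2/d2star) kernels but not the others
        self.n = n if 4 ** n == self.M else None
        self.L = C.sum(axis=1)
        if np.any(self.L <= 0):
            raise ValueError("reads with zero word count; drop them before clustering")
        self.P = C / self.L[:, None]                       # simplex frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            plp = np.where(self.P > 0, self.P * np.log(self.P), 0.0)
        self.plogp = plp.sum(axis=1)                       # sum p log p per read
        norms = np.linalg.norm(C, axis=1)
        self.U = C / norms[:, None]                        # unit-norm frequencies
        if base_counts is not None:
            B = np.asarray(base_counts, dtype=float)
            if B.shape != (self.N, 4):
                raise ValueError("base_counts must be (N, 4)")
            self._B: np.ndarray | None = B
        else:
            self._B = None
        self._whitened: np.ndarray | None = None
        self._scales: np.ndarray | None = None

    @property
    def B(self) -> np.ndarray:
        """Per-read base (1-mer) counts for the zero-order kernels."""
        if self._B is None:
            if self.n is None:
                raise ValueError(
                    "zero-order kernels need base counts, but the matrix has "
                    f"{self.M} columns (not 4**n) and none were provided"
                )
            # estimate from positional marginals of the word counts
            # (exact for n = 1)
            self._B = self.C @ _base_occurrence_matrix(self.n) / self.n
        return self._B

    @property
    def W(self) -> np.ndarray:
        if self._whitened is None:
            self._scales = column_scales(self.P)
            self._whitened = self.P / self._scales
        return self._whitened


def _pool(values: np.ndarray, z: np.ndarray, K: int) -> np.ndarray:
    out = np.zeros((K, values.shape[1]), dtype=float)
    np.add.at(out, z, values)
    return out


def _rows_to_simplex(rows: np.ndarray) -> np.ndarray:
    return rows / rows.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# per-method centroid state and distance matrices


def _update_state(data: _Data, method: str, cfg: ClusterConfig, z: np.ndarray) -> dict:
    K = cfg.n_clusters
    pc = cfg.pseudocount
    state: dict = {"z": z}
    if method in ("em", "symkl"):
        pooled = _pool(data.C, z, K)
        state["pooled"] = pooled + pc
        state["q"] = _rows_to_simplex(pooled + pc)
    elif method == "l2":
        sums = _pool(data.P, z, K)
        sizes = np.bincount(z, minlength=K)[:, None]
        state["cent"] = sums / np.maximum(sizes, 1)
    elif method == "kmeans":
        sums = _pool(data.W, z, K)
        sizes = np.bincount(z, minlength=K)[:, None]
        state["cent"] = sums / np.maximum(sizes, 1)
    elif method == "d2":
        sums = _pool(data.U, z, K)
        norms = np.linalg.norm(sums, axis=1, keepdims=True)
        if np.any(norms <= 0):
            raise EmptyClusterError("zero-norm d2 centroid (empty cluster)")
        state["cent"] = sums / norms
    elif method in ("chi2", "d2star"):
        basepool = _pool(data.B, z, K) + pc
        base_freqs = basepool / basepool.sum(axis=1, keepdims=True)
        state["Q"] = np.array(
            [zero_order_expected_frequencies(f, data.n) for f in base_freqs]
        )
        state["pooled"] = _pool(data.C, z, K)
    else:  # pragma: no cover
        raise ValueError(method)
    return state


def _dist_matrix(data: _Data, method: str, cfg: ClusterConfig, state: dict) -> np.ndarray:
    if method == "em":
        return data.plogp[:, None] - data.P @ np.log(state["q"]).T
    if method == "symkl":
        pc = cfg.pseudocount
        Pp = (data.C + pc) / (data.L + data.M * pc)[:, None]
        logPp = np.log(Pp)
        q = state["q"]
        logq = np.log(q)
        return (
            (Pp * logPp).sum(axis=1)[:, None]
            - Pp @ logq.T
            - logPp @ q.T
            + (q * logq).sum(axis=1)[None, :]
        )
    if method == "l2":
        return cdist(data.P, state["cent"], metric="sqeuclidean")
    if method == "kmeans":
        return cdist(data.W, state["cent"], metric="sqeuclidean")
    if method == "d2":
        return 1.0 - data.U @ state["cent"].T
    if method == "chi2":
        A = (data.C ** 2) / data.L[:, None]
        return A @ (1.0 / state["Q"]).T - data.L[:, None]
    if method == "d2star":
        K = state["Q"].shape[0]
        D = np.empty((data.N, K))
        for k in range(K):
            Q = state["Q"][k]
            xt = standardize(state["pooled"][k], Q)
            nx = np.linalg.norm(xt)
            expected = data.L[:, None] * Q[None, :]
            Ct = (data.C - expected) / np.sqrt(expected)
            nc = np.linalg.norm(Ct, axis=1)
            cos = np.zeros(data.N)
            ok = (nc > 0) & (nx > 0)
            if nx > 0:
                cos[ok] = (Ct[ok] @ xt) / (nc[ok] * nx)
            D[:, k] = 0.5 * (1.0 - cos)
        return D
    raise ValueError(method)  # pragma: no cover


def _assigned_cost(data: _Data, method: str, D: np.ndarray, z: np.ndarray) -> float:
    per_read = D[np.arange(data.N), z]
    if method == "em":
        per_read = data.L * per_read
    return float(per_read.sum())


def _centroid_compositions(data: _Data, method: str, cfg: ClusterConfig, state: dict) -> np.ndarray:
    """Public-facing centroid compositions: simplex, or unit norm for d2/d2star."""
    if method in ("em", "symkl"):
        return state["q"]
    if method in ("l2",):
        return state["cent"]
    if method == "kmeans":
        # de-whitened mean of whitened points = plain mean of frequencies
        sizes = np.bincount(state["z"], minlength=cfg.n_clusters)[:, None]
        return _pool(data.P, state["z"], cfg.n_clusters) / np.maximum(sizes, 1)
    if method == "d2":
        return state["cent"]
    if method == "chi2":
        pooled = state["pooled"] + cfg.pseudocount
        return _rows_to_simplex(pooled)
    if method == "d2star":
        pooled = state["pooled"] + cfg.pseudocount
        return pooled / np.linalg.norm(pooled, axis=1, keepdims=True)
    raise ValueError(method)  # pragma: no cover


# --------------------------------------------------------------------------
# hard iteration


def _random_assignment(rng: np.random.Generator, N: int, K: int) -> np.ndarray:
    if N < K:
        raise ValueError(f"cannot form {K} clusters from {N} reads")
    z = rng.integers(0, K, size=N)
    # guarantee every cluster starts non-empty
    z[rng.permutation(N)[:K]] = np.arange(K)
    return z


def _fix_empty(z: np.ndarray, D: np.ndarray, K: int, policy: str) -> np.ndarray:
    sizes = np.bincount(z, minlength=K)
    empties = np.flatnonzero(sizes == 0)
    if empties.size == 0:
        return z
    if policy == "fail":
        raise EmptyClusterError(
            f"cluster(s) {empties.tolist()} became empty (policy='fail')"
        )
    z = z.copy()
    cost = D[np.arange(z.size), z].copy()
    for k in empties:
        order = np.argsort(-cost)
        for a in order:
            if sizes[z[a]] > 1:
                logger.warning(
                    "reseeding empty cluster %d with read %d (distance %.4g)",
                    k, a, cost[a],
                )
                sizes[z[a]] -= 1
                z[a] = k
                sizes[k] += 1
                cost[a] = -np.inf
                break
        else:  # pragma: no cover
            raise EmptyClusterError("cannot reseed: all clusters singleton")
    return z


def _fit_hard_once(data: _Data, cfg: ClusterConfig, seed: int, method: str) -> HardPartition:
    rng = np.random.default_rng(seed)
    K = cfg.n_clusters
    z = _random_assignment(rng, data.N, K)
    state = _update_state(data, method, cfg, z)
    D = _dist_matrix(data, method, cfg, state)
    trace = [_assigned_cost(data, method, D, z)]
    converged = False
    iterations = 0
    for it in range(1, cfg.max_iter + 1):
        z_new = np.argmin(D, axis=1)
        z_new = _fix_empty(z_new, D, K, cfg.empty_cluster_policy)
        if np.array_equal(z_new, z):
            converged = True
            break
        z = z_new
        state = _update_state(data, method, cfg, z)
        D = _dist_matrix(data, method, cfg, state)
        trace.append(_assigned_cost(data, method, D, z))
        iterations = it
        logger.debug("iter %d: distortion %.8g", it, trace[-1])
    if not converged:
        logger.warning(
            "%s clustering did not converge in %d iterations", method, cfg.max_iter
        )
        iterations = cfg.max_iter
    return HardPartition(
        assignments=z,
        centroids=_centroid_compositions(data, method, cfg, state),
        distortion=trace[-1],
        converged=converged,
        iterations=iterations,
        method=method,
        n_clusters=K,
        seed=seed,
        distortion_trace=trace,
        pooled_counts=state.get("pooled"),
    )


# --------------------------------------------------------------------------
# soft EM


def _fit_soft_once(data: _Data, cfg: ClusterConfig, seed: int) -> SoftPartition:
    rng = np.random.default_rng(seed)
    K = cfg.n_clusters
    pc = cfg.pseudocount
    z0 = _random_assignment(rng, data.N, K)
    q = _rows_to_simplex(_pool(data.C, z0, K) + pc)

    def kl_matrix(q):
        return data.plogp[:, None] - data.P @ np.log(q).T

    def posteriors(KL):
        logW = -data.L[:, None] * KL          # equal cluster priors
        logW -= logW.max(axis=1, keepdims=True)
        Z = np.exp(logW)
        Z /= Z.sum(axis=1, keepdims=True)
        return Z, logW

    KL = kl_matrix(q)
    Z, _ = posteriors(KL)
    obj_trace: list[float] = []
    ll_trace: list[float] = []
    pen_trace: list[float] = []
    converged = False
    iterations = 0
    for it in range(1, cfg.max_iter + 1):
        # M-step: membership-weighted pooled counts, pseudocounted, normalized
        q = _rows_to_simplex(Z.T @ data.C + pc)
        KL = kl_matrix(q)
        neg_ll = data.L[:, None] * KL
        obj_trace.append(float(-(Z * neg_ll).sum()))            # E[log P] at (Z, q)
        ll = float(logsumexp(-neg_ll - np.log(K), axis=1).sum())
        ll_trace.append(ll)
        # the pseudocounted M-step maximizes the Dirichlet-penalized
        # likelihood; that is the quantity EM drives monotonically upward
        pen_trace.append(ll + pc * float(np.log(q).sum()))
        # E-step
        Z_new, _ = posteriors(KL)
        delta = float(np.abs(Z_new - Z).max())
        Z = Z_new
        iterations = it
        logger.debug("soft iter %d: objective %.8g, max|dZ| %.3g", it, obj_trace[-1], delta)
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning("soft EM did not converge in %d iterations", cfg.max_iter)
    return SoftPartition(
        memberships=Z,
        centroids=q,
        expected_log_likelihood=obj_trace[-1],
        converged=converged,
        iterations=iterations,
        method="soft_em",
        n_clusters=K,
        seed=seed,
        objective_trace=obj_trace,
        mixture_loglik_trace=ll_trace,
        penalized_loglik_trace=pen_trace,
    )


# --------------------------------------------------------------------------
# the model


class ReadClusteringModel:
    """Centroid clustering model over a read-by-word count matrix.

    Parameters
    ----------
    counts : array (N, 4**n)
        Integer n-mer counts per read, lexicographic word order.  Reads
        with zero total word count are dropped with a warning (the KL
        likelihood is undefined for them); ``kept`` records the mask.
    config : ClusterConfig
    base_counts : array (N, 4), optional
        Per-read single-nucleotide counts, used by the d2* and chi-square
        kernels to form zero-order expectations.  If omitted they are
        estimated from the n-mer counts.
    ids : sequence of str, optional
        Read identifiers carried through to results and output files.
    """

    def __init__(self, counts, config: ClusterConfig | None = None, *,
                 base_counts=None, ids=None):
        counts = np.asarray(counts)
        totals = counts.sum(axis=1)
        keep = totals > 0
        if not keep.all():
            logger.warning("dropping %d read(s) with zero word count", int((~keep).sum()))
        self.kept = keep
        if ids is not None:
            ids = [i for i, k in zip(ids, keep) if k]
        if base_counts is not None:
            base_counts = np.asarray(base_counts)[keep]
        self.config = config or ClusterConfig()
        self.ids = ids
        self.data = _Data(counts[keep], base_counts=base_counts)

    @classmethod
    def from_sequences(cls, sequences, kmer_spec: KmerSpec | None = None,
                       config: ClusterConfig | None = None, ids=None):
        """Build the model from nucleotide strings, counting words and exact
        per-read base (1-mer) counts."""
        spec = kmer_spec or KmerSpec(2)
        C = count_matrix(sequences, spec)
        base_spec = KmerSpec(1, overlapping=True, stack_revcomp=spec.stack_revcomp)
        B = count_matrix(sequences, base_spec)
        return cls(C, config=config, base_counts=B, ids=ids)

    # -- fitting -----------------------------------------------------------

    def fit_single(self, seed: int | None = None) -> HardPartition | SoftPartition:
        """One run from one random initialization (no restarts)."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        if cfg.method == "symkl" and cfg.pseudocount <= 0:
            raise ValueError(
                "symmetrized-KL clustering requires a positive pseudocount: "
                "reads with one-sided zero word support have infinite distance"
            )
        if cfg.method == "soft_em":
            result = _fit_soft_once(self.data, cfg, seed)
        else:
            result = _fit_hard_once(self.data, cfg, seed, cfg.method)
        result.ids = self.ids
        return result

    def fit(self) -> HardPartition | SoftPartition:
        """Fit with ``config.restarts`` seeded restarts, keeping the best run.

        Best means minimal distortion for hard methods and maximal expected
        log-likelihood for soft EM.  Restart r uses seed ``config.seed + r``.
        """
        cfg = self.config
        best = None
        failures: list[str] = []
        for r in range(cfg.restarts):
            try:
                res = self.fit_single(cfg.seed + r)
            except EmptyClusterError as exc:
                failures.append(f"seed {cfg.seed + r}: {exc}")
                continue
            if best is None:
                best = res
            elif cfg.method == "soft_em":
                if res.expected_log_likelihood > best.expected_log_likelihood:
                    best = res
            elif res.distortion < best.distortion:
                best = res
        if best is None:
            raise EmptyClusterError(
                "all restarts failed: " + "; ".join(failures)
            )
        if failures:
            logger.warning("%d of %d restarts failed: %s",
                           len(failures), cfg.restarts, "; ".join(failures))
        return best

    def initial_centroids(self, seed: int | None = None) -> np.ndarray:
        """Centroids after random assignment plus one maximization step."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        method = "em" if cfg.method == "soft_em" else cfg.method
        z = _random_assignment(rng, self.data.N, cfg.n_clusters)
        state = _update_state(self.data, method, cfg, z)
        return _centroid_compositions(self.data, method, cfg, state)


# --------------------------------------------------------------------------
# functional surface


def initialize(counts, cfg: ClusterConfig, seed: int | None = None, **kw) -> np.ndarray:
    """Initial centroids: seeded random assignment followed by one M-step."""
    return ReadClusteringModel(counts, cfg, **kw).initial_centroids(seed)


def em_hard(counts, cfg: ClusterConfig | None = None, **kw) -> HardPartition:
    """Hard EM clustering under the multinomial/KL likelihood."""
    cfg = replace(cfg or ClusterConfig(), method="em")
    return ReadClusteringModel(counts, cfg, **kw).fit()


def em_soft(counts, cfg: ClusterConfig | None = None, **kw) -> SoftPartition:
    """Soft EM clustering: fractional memberships via the KL likelihood."""
    cfg = replace(cfg or ClusterConfig(), method="soft_em")
    return ReadClusteringModel(counts, cfg, **kw).fit()


def kmeans(counts, cfg: ClusterConfig | None = None, **kw) -> HardPartition:
    """k-means: Lloyd iteration on column-whitened simplex frequencies."""
    cfg = replace(cfg or ClusterConfig(), method="kmeans")
    return ReadClusteringModel(counts, cfg, **kw).fit()


def centroid_iterate(counts, cfg: ClusterConfig, **kw) -> HardPartition:
    """Generic centroid iteration under the l2/d2/d2star/chi2/symkl kernels."""
    if cfg.method not in ("l2", "d2", "d2star", "chi2", "symkl"):
        raise ValueError(f"centroid_iterate expects a distance kernel, got {cfg.method!r}")
    return ReadClusteringModel(counts, cfg, **kw).fit()


def run_with_restarts(counts, cfg: ClusterConfig, **kw):
    """Run the configured method ``cfg.restarts`` times and keep the best."""
    return ReadClusteringModel(counts, cfg, **kw).fit()


def distortion(counts, assignments, method: str = "em",
               pseudocount: float = 1.0, base_counts=None) -> float:
    """Distortion of a hard partition, recomputed from scratch.

    Centroids are re-derived from the assignments (pooled, pseudocounted,
    normalized per the method's convention) and the per-read costs summed:
    L_a * D_KL for ``em``; squared Euclidean distance for ``l2``/``kmeans``
    (the intra-cluster variance); the plain kernel distance otherwise.
    """
    z = np.asarray(assignments)
    K = int(z.max()) + 1
    cfg = ClusterConfig(n_clusters=K, method=method if method != "soft_em" else "em",
                        pseudocount=pseudocount)
    data = _Data(np.asarray(counts), base_counts=base_counts)
    state = _update_state(data, cfg.method, cfg, z)
    D = _dist_matrix(data, cfg.method, cfg, state)
    return _assigned_cost(data, cfg.method, D, z)
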