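"""Dissimilarities and likelihood kernels between compositions.

The clustering model treats a read's word counts c (total L) as a draw from
a multinomial with centroid composition q; up to a term that does not depend
on q, the negative log-likelihood is L * D_KL(p | q) with p = c / L.  The
remaining kernels (L2, d2, d2*, chi-square, symmetrized KL) are alternative
dissimilarities without that exact probabilistic reading.

Natural logarithms throughout; 0 * log 0 := 0.
"""

from __future__ import annotations

from functools import reduce

import numpy as np

__all__ = [
    "kl_divergence",
    "sym_kl_distance",
    "l2_distance",
    "d2_distance",
    "zero_order_expected_frequencies",
    "standardize",
    "d2star_distance",
    "chi2_distance",
    "gaussian_limit_neg_log_likelihood",
]


def _as1d(v) -> np.ndarray:
    return np.asarray(v, dtype=float).ravel()


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence sum_i p_i log(p_i / q_i).

    Both arguments are simplex compositions.  Terms with p_i = 0 contribute
    0; p_i > 0 where q_i = 0 is an infinite divergence and raises, naming
    the offending word index.
    """
    p, q = _as1d(p), _as1d(q)
    if p.shape != q.shape:
        raise ValueError("dimension mismatch")
    support = p > 0
    bad = support & (q <= 0)
    if bad.any():
        raise ValueError(
            f"infinite divergence: q is zero at word index {int(np.flatnonzero(bad)[0])} "
            "where p is positive"
        )
    ps, qs = p[support], q[support]
    return float(np.sum(ps * np.log(ps / qs)))


def sym_kl_distance(p, q) -> float:
    """Symmetrized KL divergence sum_i (p_i - q_i) log(p_i / q_i).

    Requires mutual support: a word with positive frequency on one side and
    zero on the other makes the distance infinite and raises.  Identically
    equals kl_divergence(p, q) + kl_divergence(q, p).
    """
    p, q = _as1d(p), _as1d(q)
    if p.shape != q.shape:
        raise ValueError("dimension mismatch")
    one_sided = (p > 0) != (q > 0)
    if one_sided.any():
        raise ValueError(
            f"infinite symmetrized divergence: one-sided zero support at word index "
            f"{int(np.flatnonzero(one_sided)[0])}"
        )
    both = (p > 0) & (q > 0)
    ps, qs = p[both], q[both]
    return float(np.sum((ps - qs) * np.log(ps / qs)))


def l2_distance(p, q) -> float:
    """Euclidean distance between two composition vectors."""
    p, q = _as1d(p), _as1d(q)
    if p.shape != q.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(p - q))


def d2_distance(c, q) -> float:
    """d2 dissimilarity 1 - cos(theta) between two nonzero vectors.

    Scale-invariant in both arguments; lies in [0, 1] for non-negative
    inputs and in [0, 2] in general.
    """
    c, q = _as1d(c), _as1d(q)
    nc, nq = np.linalg.norm(c), np.linalg.norm(q)
    if nc <= 0 or nq <= 0:
        raise ValueError("d2 distance undefined for a zero-norm vector")
    return float(1.0 - np.dot(c, q) / (nc * nq))


def zero_order_expected_frequencies(base_freqs, n: int) -> np.ndarray:
    """Expected n-mer frequencies Q under a zero-order Markov model.

    Q_w is the product of the single-base frequencies of the characters of
    w, over all 4**n words in lexicographic order.  (The repeated Kronecker
    product of the base-frequency 4-vector with itself yields exactly this
    ordering.)
    """
    f = _as1d(base_freqs)
    if f.shape != (4,):
        raise ValueError("base_freqs must be a 4-vector over A,C,G,T")
    if np.any(f < 0):
        raise ValueError("negative base frequency")
    if n < 1:
        raise ValueError("n must be >= 1")
    return reduce(np.kron, [f] * n)


def standardize(x, Q) -> np.ndarray:
    """Poisson-motivated standardization (observed - expected) / sqrt(expected).

    With S = sum(x), component i maps to (x_i - Q_i S) / sqrt(Q_i S).
    Components with Q_i = 0 and x_i = 0 are set to 0 (continuity); Q_i = 0
    with x_i > 0 is an error.
    """
    x, Q = _as1d(x), _as1d(Q)
    if x.shape != Q.shape:
        raise ValueError("dimension mismatch")
    S = x.sum()
    if S <= 0:
        raise ValueError("cannot standardize a zero count vector")
    bad = (Q <= 0) & (x > 0)
    if bad.any():
        raise ValueError(
            f"zero expected frequency at word index {int(np.flatnonzero(bad)[0])} "
            "with positive observed count"
        )
    expected = Q * S
    out = np.zeros_like(x, dtype=float)
    pos = expected > 0
    out[pos] = (x[pos] - expected[pos]) / np.sqrt(expected[pos])
    return out


def d2star_distance(c, x, Q) -> float:
    """d2* dissimilarity (1 - cos angle) / 2 between standardized vectors.

    Both count vectors are standardized against the same zero-order
    expectation Q (in clustering, Q comes from the cluster's pooled base
    frequencies).  Lies in [0, 1].
    """
    ct = standardize(c, Q)
    xt = standardize(x, Q)
    nc, nx = np.linalg.norm(ct), np.linalg.norm(xt)
    if nc <= 0 or nx <= 0:
        raise ValueError("degenerate standardization: zero-norm standardized vector")
    return float(0.5 * (1.0 - np.dot(ct, xt) / (nc * nx)))


def chi2_distance(c, Q) -> float:
    """Chi-square statistic of counts c against expectation Q.

    sum_i (c_i - Q_i L)**2 / (Q_i L) with L = sum(c).  Every word with
    Q_i > 0 contributes (including words with c_i = 0); Q_i = 0 with
    c_i > 0 raises.
    """
    c, Q = _as1d(c), _as1d(Q)
    if c.shape != Q.shape:
        raise ValueError("dimension mismatch")
    L = c.sum()
    if L <= 0:
        raise ValueError("chi-square distance undefined for zero total count")
    bad = (Q <= 0) & (c > 0)
    if bad.any():
        raise ValueError(
            f"zero expected frequency at word index {int(np.flatnonzero(bad)[0])} "
            "with positive observed count"
        )
    pos = Q > 0
    expected = Q[pos] * L
    return float(np.sum((c[pos] - expected) ** 2 / expected))


def gaussian_limit_neg_log_likelihood(c, q) -> float:
    """Gaussian-limit negative log-likelihood sum_i (c_i - L q_i)**2 / (2 L q_i).

    The multivariate-normal limit of the multinomial model for compositions
    close to the centroid; used as a small-perturbation oracle for
    L * D_KL(p | q), to which it agrees to first order.
    """
    c, q = _as1d(c), _as1d(q)
    if c.shape != q.shape:
        raise ValueError("dimension mismatch")
    L = c.sum()
    if L <= 0:
        raise ValueError("zero total count")
    bad = (q <= 0) & (c > 0)
    if bad.any():
        raise ValueError(
            f"infinite divergence: q is zero at word index {int(np.flatnonzero(bad)[0])} "
            "where counts are positive"
        )
    pos = q > 0
    expected = L * q[pos]
    return float(np.sum((c[pos] - expected) ** 2 / (2.0 * expected)))
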