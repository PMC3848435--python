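"""n-mer counting and composition vectors for nucleotide sequences.

A sequence is summarized by the counts of its 4**n words (n-mers) over the
alphabet A, C, G, T.  Words are indexed lexicographically with A < C < G < T,
so for n = 2 the vector order is AA, AC, AG, AT, CA, ... TT.  This order is
fixed and is the one used by every serialization in the package.

The total word count L is the number of counted word positions, not the
sequence length: for an all-ACGT sequence of length ``len``, overlapping
counting yields L = len - n + 1 and non-overlapping counting L = len // n.
Windows containing a non-ACGT character (N, ambiguity codes, ...) are
skipped deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "KmerSpec",
    "count_kmers",
    "count_matrix",
    "to_frequencies",
    "frequency_matrix",
    "whiten_columns",
    "kmer_labels",
    "reverse_complement",
]

# base -> code; anything else (incl. N) maps to -1 and invalidates its windows
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (case preserved, N kept)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerSpec:
    """Word-counting convention.

    Parameters
    ----------
    n : int
        Word length, 1..8.  The count vector has dimension 4**n.
    overlapping : bool
        Count every window (step 1) if True, else disjoint windows (step n).
    stack_revcomp : bool
        If True, the sequence and its reverse complement are counted as two
        separate strings and the counts summed; no chimeric windows span
        the junction.
    """

    n: int = 2
    overlapping: bool = True
    stack_revcomp: bool = False

    def __post_init__(self) -> None:
        if not (1 <= int(self.n) <= 8):
            raise ValueError(f"word length n must be in 1..8, got {self.n}")

    @property
    def num_words(self) -> int:
        return 4 ** self.n


def kmer_labels(n: int) -> list[str]:
    """All n-mers in the package's lexicographic (A<C<G<T) index order."""
    bases = "ACGT"
    labels = [""]
    for _ in range(n):
        labels = [w + b for w in labels for b in bases]
    return labels


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _count_codes(codes: np.ndarray, n: int, step: int) -> np.ndarray:
    m = 4 ** n
    if codes.size < n:
        return np.zeros(m, dtype=np.int64)
    win = sliding_window_view(codes, n)[::step]
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.zeros(m, dtype=np.int64)
    weights = 4 ** np.arange(n - 1, -1, -1, dtype=np.int64)
    idx = win[valid].astype(np.int64) @ weights
    return np.bincount(idx, minlength=m)


def count_kmers(sequence: str, spec: KmerSpec) -> np.ndarray:
    """Count the n-mers of ``sequence`` under ``spec``.

    Returns an integer vector of length 4**spec.n in lexicographic order;
    its sum is the total word count L.  An empty sequence (or one with no
    valid window) yields the zero vector.
    """
    codes = _encode(sequence)
    step = 1 if spec.overlapping else spec.n
    counts = _count_codes(codes, spec.n, step)
    if spec.stack_revcomp:
        rc = np.where(codes >= 0, 3 - codes, -1)[::-1]
        counts = counts + _count_codes(rc, spec.n, step)
    return counts


def count_matrix(sequences, spec: KmerSpec) -> np.ndarray:
    """Stack :func:`count_kmers` over an iterable of sequences (N x 4**n)."""
    return np.array([count_kmers(s, spec) for s in sequences], dtype=np.int64).reshape(
        -1, spec.num_words
    )


def to_frequencies(
    counts: np.ndarray, scheme: str = "simplex", pseudocount: float = 0.0
) -> np.ndarray:
    """Normalize a count vector to a composition.

    ``scheme="simplex"`` divides by the total so the result sums to 1;
    ``scheme="unit_norm"`` divides by the Euclidean norm (the convention of
    the cosine-based d2 geometry).  ``pseudocount`` is added to every
    component before normalizing; an all-zero vector with pseudocount 0 is
    a degenerate composition and raises.
    """
    v = np.asarray(counts, dtype=float) + float(pseudocount)
    if np.any(v < 0):
        raise ValueError("negative entries in count vector")
    if scheme == "simplex":
        total = v.sum()
        if total <= 0:
            raise ValueError("degenerate composition: zero total count and no pseudocount")
        return v / total
    if scheme == "unit_norm":
        norm = np.linalg.norm(v)
        if norm <= 0:
            raise ValueError("degenerate composition: zero vector cannot be unit-normalized")
        return v / norm
    raise ValueError(f"unknown scheme {scheme!r}")


def frequency_matrix(
    counts: np.ndarray, scheme: str = "simplex", pseudocount: float = 0.0
) -> np.ndarray:
    """Row-wise :func:`to_frequencies` for an N x 4**n count matrix."""
    v = np.asarray(counts, dtype=float) + float(pseudocount)
    if scheme == "simplex":
        denom = v.sum(axis=1, keepdims=True)
    elif scheme == "unit_norm":
        denom = np.linalg.norm(v, axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if np.any(denom <= 0):
        raise ValueError("degenerate composition in at least one row")
    return v / denom


def column_scales(rows: np.ndarray) -> np.ndarray:
    """Per-column standard deviations used for whitening (ddof=0).

    Columns with zero spread get scale 1 so they pass through unscaled.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("whitening requires at least 2 rows")
    std = rows.std(axis=0)
    return np.where(std > 0, std, 1.0)


def whiten_columns(rows: np.ndarray) -> np.ndarray:
    """Divide every coordinate by that coordinate's std across the rows.

    This is the preprocessing that turns plain Euclidean centroid
    clustering into k-means on composition data.  Zero-variance columns
    are left unscaled.
    """
    rows = np.asarray(rows, dtype=float)
    return rows / column_scales(rows)
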