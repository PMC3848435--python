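"""Synthetic sources and simulated reads.

Source sequences are drawn i.i.d. from per-source zero-order (single
nucleotide) composition models — the same family of models the composition
clustering itself assumes — with lengths uniform in a configurable range
(default 500..10000 bp, the typical span of mRNA reference transcripts).
The spread of GC content across sources is the dial controlling how
separable the sources are.

Reads are sampled shotgun-style: the source is chosen proportional to its
length (uniform coverage), the start position uniformly, the strand
uniformly when both strands are sequenced, and each base is substituted
with a fixed per-base error probability to a uniformly chosen different
base (no indels).  Every read keeps its true source label for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmers import reverse_complement

__all__ = [
    "SourceModel",
    "ReadSimConfig",
    "SourceSet",
    "LabeledReadSet",
    "generate_sources",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SourceModel:
    """Zero-order composition models for a set of source genes.

    ``compositions`` may give an explicit (num_sources, 4) stack of base
    frequencies over A,C,G,T; otherwise GC contents are spaced evenly over
    ``gc_range`` (with A=T and C=G within each source).
    """

    num_sources: int = 2
    length_range: tuple[int, int] = (500, 10000)
    compositions: tuple | None = None
    gc_range: tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def base_frequencies(self) -> np.ndarray:
        if self.compositions is not None:
            comp = np.asarray(self.compositions, dtype=float)
            if comp.shape != (self.num_sources, 4):
                raise ValueError("compositions must be (num_sources, 4)")
            if np.any(comp < 0) or not np.allclose(comp.sum(axis=1), 1.0):
                raise ValueError("compositions must be rows on the simplex")
            return comp
        lo, hi = self.gc_range
        if self.num_sources == 1:
            gcs = np.array([(lo + hi) / 2])
        else:
            gcs = np.linspace(lo, hi, self.num_sources)
        at = (1.0 - gcs) / 2
        gc = gcs / 2
        return np.column_stack([at, gc, gc, at])


@dataclass(frozen=True)
class ReadSimConfig:
    """Read sampling settings: substitution-only errors, no indels."""

    num_reads: int = 1000
    read_length: int = 200
    error_rate: float = 0.0
    both_strands: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


@dataclass
class SourceSet:
    """Generated source sequences with their generating compositions."""

    ids: list[str]
    sequences: list[str]
    compositions: np.ndarray

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fasta(self, path) -> None:
        _write_fasta(path, self.ids, self.sequences)


@dataclass
class LabeledReadSet:
    """Simulated reads with their true source-gene labels.

    ``starts`` and ``strands`` record where each read was sampled (strand
    ``+1`` forward, ``-1`` reverse), which makes positional diagnostics and
    exact-substring checks possible.
    """

    ids: list[str]
    sequences: list[str]
    labels: list[str]
    read_length: int = 0
    error_rate: float = 0.0
    starts: list[int] = field(default_factory=list)
    strands: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fasta(self, path) -> None:
        _write_fasta(path, self.ids, self.sequences)

    def to_fastq(self, path, quality: int = 40) -> None:
        qchar = chr(quality + 33)
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")

    def labels_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsource\n")
            for rid, lab in zip(self.ids, self.labels):
                fh.write(f"{rid}\t{lab}\n")


def _write_fasta(path, ids, seqs, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in zip(ids, seqs):
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def generate_sources(model: SourceModel) -> SourceSet:
    """Draw the source sequences of ``model``; deterministic given its seed."""
    lo, hi = model.length_range
    if lo > hi:
        raise ValueError("length_range minimum exceeds maximum")
    if lo < 1:
        raise ValueError("source length must be positive")
    rng = np.random.default_rng(model.seed)
    comps = model.base_frequencies()
    ids, seqs = [], []
    for k in range(model.num_sources):
        length = int(rng.integers(lo, hi + 1))
        codes = rng.choice(4, size=length, p=comps[k])
        ids.append(f"source{k}")
        seqs.append("".join(_BASES[codes]))
    return SourceSet(ids=ids, sequences=seqs, compositions=comps)


def simulate_reads(sources: SourceSet, cfg: ReadSimConfig) -> LabeledReadSet:
    """Sample substitution-error reads from ``sources``.

    Source picked proportional to length, start uniform, strand uniform if
    ``both_strands``; each base substituted with probability ``error_rate``
    to a uniformly chosen different base.  Read IDs encode the source as
    ``<sourceID>_<index>``.

    Sampling noise and sequencing-error noise come from two independent
    substreams of ``cfg.seed``, so runs differing only in ``error_rate``
    draw the same read positions and strands — error-rate sweeps are
    paired comparisons on identical underlying reads.
    """
    lengths = np.array([len(s) for s in sources.sequences])
    if cfg.num_reads > 0 and cfg.read_length > lengths.min():
        raise ValueError(
            f"read_length {cfg.read_length} exceeds shortest source ({lengths.min()} bp)"
        )
    rng, rng_err = (np.random.default_rng(s)
                    for s in np.random.SeedSequence(cfg.seed).spawn(2))
    ids, seqs, labels, starts, strands = [], [], [], [], []
    if cfg.num_reads == 0:
        return LabeledReadSet(ids, seqs, labels, cfg.read_length, cfg.error_rate)
    probs = lengths / lengths.sum()
    src_idx = rng.choice(len(sources), size=cfg.num_reads, p=probs)
    for i, s in enumerate(src_idx):
        seq = sources.sequences[s]
        start = int(rng.integers(0, len(seq) - cfg.read_length + 1))
        read = seq[start:start + cfg.read_length]
        strand = 1
        if cfg.both_strands and rng.integers(2) == 1:
            read = reverse_complement(read)
            strand = -1
        if cfg.error_rate > 0:
            codes = np.searchsorted(_BASES, list(read))
            hits = rng_err.random(cfg.read_length) < cfg.error_rate
            if hits.any():
                shift = rng_err.integers(1, 4, size=int(hits.sum()))
                codes[hits] = (codes[hits] + shift) % 4
            read = "".join(_BASES[codes])
        ids.append(f"{sources.ids[s]}_{i}")
        seqs.append(read)
        labels.append(sources.ids[s])
        starts.append(start)
        strands.append(strand)
    return LabeledReadSet(ids, seqs, labels, cfg.read_length, cfg.error_rate,
                          starts, strands)
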