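"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

import kmerclust as kc


def make_labeled_reads(seed, *, num_sources=2, gc_range=(0.3, 0.7), num_reads=200,
                       read_length=200, error_rate=0.0, length_range=(500, 2000)):
    """Zero-order sources plus substitution-error reads, fully seeded."""
    src = kc.generate_sources(kc.SourceModel(
        num_sources=num_sources, gc_range=gc_range,
        length_range=length_range, seed=seed))
    reads = kc.simulate_reads(src, kc.ReadSimConfig(
        num_reads=num_reads, read_length=read_length,
        error_rate=error_rate, seed=seed + 10_000))
    return src, reads


def random_simplex(rng, dim):
    return rng.dirichlet(np.ones(dim))


@pytest.fixture(scope="session")
def separated_reads():
    """200 reads from two well-separated (GC 30% vs 70%) sources."""
    return make_labeled_reads(7)


@pytest.fixture(scope="session")
def separated_counts(separated_reads):
    _, reads = separated_reads
    counts = kc.count_matrix(reads.sequences, kc.KmerSpec(2))
    return counts, np.asarray(reads.labels)


@pytest.fixture(scope="session")
def soft_result(separated_counts):
    """A converged soft-EM run on the separated two-source reads."""
    counts, labels = separated_counts
    cfg = kc.ClusterConfig(n_clusters=2, method="soft_em", seed=3)
    return kc.ReadClusteringModel(counts, cfg).fit(), labels
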