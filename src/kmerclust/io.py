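"""Reading and writing the tool's file formats.

FASTA/FASTQ input goes through Biopython (gzip handled by extension, format
auto-detected from the first character).  Outputs are plain TSV: per-read
assignments (plus one membership column per cluster for soft runs),
centroid compositions in the package's lexicographic word order, and a
key-value run-metadata file.  ``split_reads_by_cluster`` writes per-cluster
FASTA files suitable for independent assembly.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cluster import HardPartition, SoftPartition
from .kmers import kmer_labels

__all__ = [
    "read_sequences",
    "write_partition",
    "read_centroids",
    "split_reads_by_cluster",
]


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path, fmt: str = "auto") -> tuple[list[str], list[str]]:
    """Read FASTA or FASTQ (optionally gzipped) into (ids, sequences).

    ``fmt="auto"`` sniffs the first character: '>' means FASTA, '@' FASTQ.
    Sequences are uppercased; FASTQ qualities are ignored.  Empty or
    malformed files raise with the offending record named.
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        if not first:
            raise ValueError(f"{path}: empty file")
        fh.seek(0)
        if fmt == "auto":
            if first == ">":
                fmt = "fasta"
            elif first == "@":
                fmt = "fastq"
            else:
                raise ValueError(
                    f"{path}: cannot detect format from leading character {first!r}"
                )
        ids, seqs = [], []
        try:
            for rec in SeqIO.parse(fh, fmt):
                ids.append(rec.id)
                seqs.append(str(rec.seq).upper())
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed {fmt} near record {len(ids) + 1}: {exc}"
            ) from exc
    if not ids:
        raise ValueError(f"{path}: no records parsed as {fmt}")
    return ids, seqs


def write_partition(result, out_dir, ids=None) -> dict[str, Path]:
    """Write assignments, centroids and run metadata as TSV/text files.

    Returns the paths written, keyed ``assignments``/``centroids``/``info``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    soft = isinstance(result, SoftPartition)
    n = result.memberships.shape[0] if soft else result.assignments.shape[0]
    ids = list(ids) if ids is not None else (result.ids or [f"read{i}" for i in range(n)])

    frame = {"read_id": ids}
    if soft:
        frame["cluster"] = result.hardened()
        for k in range(result.n_clusters):
            frame[f"membership_{k}"] = result.memberships[:, k]
    else:
        frame["cluster"] = result.assignments
    assignments_path = out_dir / "assignments.tsv"
    pd.DataFrame(frame).to_csv(assignments_path, sep="\t", index=False, float_format="%.12g")

    n_words = result.centroids.shape[1]
    word_len = int(round(np.log2(n_words) / 2))
    cent = pd.DataFrame(result.centroids, columns=kmer_labels(word_len))
    cent.insert(0, "cluster", np.arange(result.n_clusters))
    centroids_path = out_dir / "centroids.tsv"
    cent.to_csv(centroids_path, sep="\t", index=False, float_format="%.17g")

    info = {
        "method": result.method,
        "n_clusters": result.n_clusters,
        "seed": result.seed,
        "iterations": result.iterations,
        "converged": result.converged,
    }
    if soft:
        info["expected_log_likelihood"] = f"{result.expected_log_likelihood:.12g}"
    else:
        info["distortion"] = f"{result.distortion:.12g}"
    info_path = out_dir / "run_info.txt"
    with open(info_path, "w") as fh:
        for key, val in info.items():
            fh.write(f"{key}\t{val}\n")
    return {"assignments": assignments_path, "centroids": centroids_path, "info": info_path}


def read_centroids(path) -> np.ndarray:
    """Reload a centroids TSV into a (K, 4**n) array (row order = cluster)."""
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=["cluster"]).to_numpy(dtype=float)


def split_reads_by_cluster(ids, sequences, result, out_dir,
                           epsilon: float = 0.05) -> list[Path]:
    """Write one FASTA per cluster.

    Hard partitions place each read in exactly one file.  Soft partitions
    place a read in every cluster whose membership is >= ``epsilon`` —
    possibly several files, possibly none (a warning is logged if every
    file is empty).
    """
    from .cluster import logger

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(result, HardPartition):
        member = np.zeros((len(ids), result.n_clusters), dtype=bool)
        member[np.arange(len(ids)), result.assignments] = True
    else:
        member = result.memberships >= epsilon
    paths = []
    for k in range(member.shape[1]):
        path = out_dir / f"cluster{k}.fasta"
        with open(path, "w") as fh:
            for i in np.flatnonzero(member[:, k]):
                fh.write(f">{ids[i]}\n{sequences[i]}\n")
        paths.append(path)
    if not member.any():
        logger.warning("no read reached membership %.3g: all cluster files empty", epsilon)
    return paths
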