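"""Hard base partitions of the gene set, one per (dataset, method, K).

Three deterministic-or-seeded clusterers from three different families are
provided: k-means with maximin (KA-style) initialisation, a one-dimensional
self-organising map, and Ward-linkage hierarchical clustering.  Each returns
a :class:`PartitionMatrix`, a binary K x G matrix whose columns sum to one.
Empty clusters are legal rows: the consensus layer needs a fixed K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .expression_io import ExpressionDataset

__all__ = [
    "PartitionMatrix",
    "kmeans_partition",
    "som_partition",
    "hierarchical_partition",
    "ward_linkage",
    "METHOD_ORDER",
    "write_partition",
]

#: Canonical ordering of base methods inside a consensus run.
METHOD_ORDER = ("kmeans", "som", "hc")


@dataclass(eq=False)
class PartitionMatrix:
    """Binary K x G hard-partition matrix with provenance.

    Every column sums to exactly 1 (each gene is in exactly one cluster);
    rows may be empty.
    """

    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("partition matrix must be 2-D")
        if not np.array_equal(np.unique(self.matrix), np.unique([0, 1])) and \
                not np.all((self.matrix == 0) | (self.matrix == 1)):
            raise ValueError("partition matrix must be binary")
        if not np.all(self.matrix.sum(axis=0) == 1):
            raise ValueError("every gene must belong to exactly one cluster")
        self.matrix = self.matrix.astype(np.uint8)

    @property
    def K(self) -> int:
        return self.matrix.shape[0]

    @property
    def G(self) -> int:
        return self.matrix.shape[1]

    def labels(self) -> np.ndarray:
        """0-based cluster index per gene."""
        return self.matrix.argmax(axis=0)


def _from_labels(labels: np.ndarray, K: int, provenance: dict) -> PartitionMatrix:
    M = np.zeros((K, labels.size), dtype=np.uint8)
    M[labels, np.arange(labels.size)] = 1
    return PartitionMatrix(M, provenance)


def _check_K(dataset: ExpressionDataset, K: int) -> None:
    if not 1 <= K <= dataset.n_genes:
        raise ValueError(f"K={K} out of range [1, {dataset.n_genes}]")


def _maximin_centres(X: np.ndarray, K: int) -> np.ndarray:
    """Deterministic maximin seeding: start at the largest-norm profile,
    then repeatedly add the profile farthest from all chosen centres."""
    chosen = [int((X ** 2).sum(axis=1).argmax())]
    mind = cdist(X, X[chosen[-1:]], "sqeuclidean").ravel()
    for _ in range(1, K):
        nxt = int(mind.argmax())
        chosen.append(nxt)
        np.minimum(mind, cdist(X, X[nxt:nxt + 1], "sqeuclidean").ravel(), out=mind)
    return X[chosen].astype(float).copy()


def kmeans_partition(dataset: ExpressionDataset, K: int,
                     max_iter: int = 300) -> PartitionMatrix:
    """Lloyd's k-means from the deterministic maximin initialisation.

    A cluster that empties keeps its last centroid and yields an empty row,
    preserving the fixed K the relabelling step requires.  Bit-reproducible
    on identical input.
    """
    _check_K(dataset, K)
    X = dataset.values
    centres = _maximin_centres(X, K)
    labels: np.ndarray | None = None
    for _ in range(max_iter):
        new = cdist(X, centres, "sqeuclidean").argmin(axis=1)
        if labels is not None and np.array_equal(new, labels):
            break
        labels = new
        for k in range(K):
            members = labels == k
            if members.any():
                centres[k] = X[members].mean(axis=0)
    assert labels is not None
    return _from_labels(labels, K, {"method": "kmeans", "K": K,
                                    "dataset_id": dataset.dataset_id})


def som_partition(dataset: ExpressionDataset, K: int, seed: int,
                  n_epochs: int = 200) -> PartitionMatrix:
    """Batch-trained one-dimensional self-organising map with K nodes.

    The map is a chain of K nodes initialised at a seeded random sample of
    gene profiles; each epoch assigns every gene to its best-matching node
    and moves each node to the neighbourhood-weighted mean of the assigned
    profiles, with a Gaussian neighbourhood whose width shrinks linearly
    from K/2 to 0.5.  Batch updates are order-independent, so the result is
    reproducible for a fixed seed.
    """
    _check_K(dataset, K)
    X = dataset.values
    rng = np.random.default_rng(seed)
    W = X[rng.choice(dataset.n_genes, size=K, replace=False)].astype(float).copy()
    pos = np.arange(K, dtype=float)
    sigma0, sigma1 = max(K / 2.0, 1.0), 0.5
    for t in range(n_epochs):
        frac = t / max(n_epochs - 1, 1)
        sigma = sigma0 + (sigma1 - sigma0) * frac
        bmu = cdist(X, W, "sqeuclidean").argmin(axis=1)
        H = np.exp(-((pos[:, None] - pos[None, :]) ** 2) / (2.0 * sigma ** 2))
        counts = np.bincount(bmu, minlength=K).astype(float)
        sums = np.zeros_like(W)
        np.add.at(sums, bmu, X)
        num = H @ sums
        den = H @ counts
        live = den > 0
        W[live] = num[live] / den[live, None]
    labels = cdist(X, W, "sqeuclidean").argmin(axis=1)
    return _from_labels(labels, K, {"method": "som", "K": K, "seed": seed,
                                    "dataset_id": dataset.dataset_id})


def ward_linkage(dataset: ExpressionDataset) -> np.ndarray:
    """Ward-linkage merge tree on Euclidean distances (reusable across K)."""
    return linkage(dataset.values, method="ward")


def hierarchical_partition(dataset: ExpressionDataset, K: int,
                           linkage_matrix: np.ndarray | None = None
                           ) -> PartitionMatrix:
    """Ward agglomeration cut at K clusters; deterministic.

    ``linkage_matrix`` may be supplied to reuse one merge tree across many
    K values.
    """
    _check_K(dataset, K)
    Z = ward_linkage(dataset) if linkage_matrix is None else linkage_matrix
    labels = fcluster(Z, t=K, criterion="maxclust") - 1
    return _from_labels(labels, K, {"method": "hc", "K": K,
                                    "dataset_id": dataset.dataset_id})


PARTITIONERS: dict[str, Callable] = {
    "kmeans": kmeans_partition,
    "som": som_partition,
    "hc": hierarchical_partition,
}


def write_partition(partition: PartitionMatrix, gene_ids: list[str],
                    path: str | Path) -> None:
    """Serialise as TSV: gene_id, 0-based cluster index, provenance header."""
    prov = " ".join(f"{k}={v}" for k, v in sorted(partition.provenance.items()))
    labels = partition.labels()
    with open(path, "w") as fh:
        fh.write(f"# {prov}\n")
        fh.write("gene_id\tcluster\n")
        for gid, lab in zip(gene_ids, labels):
            fh.write(f"{gid}\t{int(lab)}\n")
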