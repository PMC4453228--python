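"""Orchestration of consensus runs over the K list and delta grids.

A *type A* run mines a collection for gene subsets consistently
co-expressed in **all** datasets: for every K, base partitions from every
(dataset, method) pair are relabelled, averaged into a CoPaM, and
DTB-binarised at every delta of the grid; each binarisation contributes K
cluster records to the pool.

A *type B* run mines for subsets co-expressed in a positive dataset subset
while **poorly** co-expressed in a negative subset: the type A machinery is
applied to the two subsets separately at tightness delta+ (positives) and
delta- (negatives), and every gene assigned anywhere in the negative result
is removed from every positive cluster.  At delta- = 0 all genes are
assigned in the negatives, so every record is empty; the widest non-trivial
setting is (0, 1) and the tightest (1, epsilon) with epsilon the smallest
positive grid value.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .base_partitioning import (METHOD_ORDER, PartitionMatrix,
                                hierarchical_partition, kmeans_partition,
                                som_partition, ward_linkage)
from .consensus import build_copam, dtb_binarise, relabel_partitions
from .expression_io import ExpressionDataset

__all__ = [
    "UnclesConfig",
    "ClusterRecord",
    "ClusterPool",
    "PartitionProvider",
    "run_type_a",
    "run_type_b",
    "run_comparator",
    "pool_size",
    "COMPARATOR_K_LIST",
    "write_pool",
    "read_pool",
]

DEFAULT_K_LIST = (4, 8, 12, 16, 20, 25)
DEFAULT_DELTA_GRID = tuple(round(0.1 * i, 1) for i in range(11))
#: K sweep used when single-method comparators are run per dataset.
COMPARATOR_K_LIST = (4, 8, 12, 16, 20, 25, 50, 75, 100, 125)


@dataclass(frozen=True)
class UnclesConfig:
    """Grid configuration for a consensus run."""

    k_list: tuple[int, ...] = DEFAULT_K_LIST
    delta_grid: tuple[float, ...] = DEFAULT_DELTA_GRID
    methods: tuple[str, ...] = METHOD_ORDER
    weight_by_samples: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_list", tuple(int(k) for k in self.k_list))
        object.__setattr__(self, "delta_grid",
                           tuple(float(d) for d in self.delta_grid))
        object.__setattr__(self, "methods", tuple(self.methods))
        if not self.k_list or any(k < 1 for k in self.k_list):
            raise ValueError("k_list must contain positive integers")
        grid = self.delta_grid
        if not grid or len(set(grid)) != len(grid):
            raise ValueError("delta_grid values must be unique")
        if list(grid) != sorted(grid) or grid[0] < 0 or grid[-1] > 1:
            raise ValueError("delta_grid must be ascending within [0, 1]")
        unknown = set(self.methods) - set(METHOD_ORDER)
        if not self.methods or unknown:
            raise ValueError(f"methods must be a non-empty subset of "
                             f"{METHOD_ORDER}; unknown: {sorted(unknown)}")


@dataclass(frozen=True)
class ClusterRecord:
    """A pooled gene set with the parameters that generated it."""

    genes: frozenset[int]
    spec_type: str  # "A", "B" or "single" (comparator)
    K: int
    delta: float | None = None
    delta_plus: float | None = None
    delta_minus: float | None = None
    dataset_id: str | None = None  # comparator records only

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass(eq=False)
class ClusterPool:
    """Ordered list of cluster records with the config that produced them."""

    records: list[ClusterRecord]
    config: UnclesConfig
    spec_type: str

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def pool_size(config: UnclesConfig, spec_type: str) -> int:
    """Number of records a run will emit: |grid| * sum(K) for type A,
    |grid|^2 * sum(K) for type B (one record per cluster per grid point)."""
    total_k = sum(config.k_list)
    n_delta = len(config.delta_grid)
    if spec_type == "A":
        return n_delta * total_k
    if spec_type == "B":
        return n_delta * n_delta * total_k
    raise ValueError(f"spec_type must be 'A' or 'B', got {spec_type!r}")


def _sub_seed(master: int, dataset_id: str, method: str, K: int) -> int:
    """Deterministic per-(dataset, method, K) sub-seed below 2^31."""
    crc = zlib.crc32(dataset_id.encode())
    ss = np.random.SeedSequence([int(master), crc, METHOD_ORDER.index(method), K])
    return int(ss.generate_state(1)[0] % (2 ** 31))


class PartitionProvider:
    """Memoised access to base partitions, shared across A and B runs.

    Partitions depend only on (dataset, method, K, master seed), so one
    provider lets a type A run over all datasets and a type B run over the
    positive/negative split reuse each partition; the Ward merge tree is
    additionally cached per dataset and re-cut for every K.
    """

    def __init__(self, seed: int = 0) -> None:
        self.seed = int(seed)
        self._partitions: dict[tuple[str, str, int], PartitionMatrix] = {}
        self._linkages: dict[str, np.ndarray] = {}

    def get(self, dataset: ExpressionDataset, method: str, K: int
            ) -> PartitionMatrix:
        key = (dataset.dataset_id, method, K)
        if key not in self._partitions:
            if method == "kmeans":
                part = kmeans_partition(dataset, K)
            elif method == "som":
                part = som_partition(
                    dataset, K,
                    seed=_sub_seed(self.seed, dataset.dataset_id, "som", K))
            elif method == "hc":
                Z = self._linkages.get(dataset.dataset_id)
                if Z is None:
                    Z = ward_linkage(dataset)
                    self._linkages[dataset.dataset_id] = Z
                part = hierarchical_partition(dataset, K, linkage_matrix=Z)
            else:
                raise ValueError(f"unknown method {method!r}")
            self._partitions[key] = part
        return self._partitions[key]


def _check_collection(datasets: Sequence[ExpressionDataset]) -> None:
    if not datasets:
        raise ValueError("at least one dataset is required")
    ref = datasets[0].gene_ids
    for d in datasets[1:]:
        if d.gene_ids != ref:
            raise ValueError(
                f"dataset {d.dataset_id!r} does not share the collection's "
                "gene list")


def _copam_for(datasets: Sequence[ExpressionDataset], config: UnclesConfig,
               K: int, provider: PartitionProvider):
    parts = [provider.get(d, m, K) for d in datasets for m in config.methods]
    aligned = relabel_partitions(parts)
    weights = None
    if config.weight_by_samples:
        weights = [float(d.n_samples) for d in datasets for _ in config.methods]
    return build_copam(aligned, weights)


def run_type_a(datasets: Sequence[ExpressionDataset],
               config: UnclesConfig | None = None,
               provider: PartitionProvider | None = None) -> ClusterPool:
    """Mine gene subsets consistently co-expressed in all datasets.

    Emits K records per (K, delta) grid point, ordered by
    (K, delta, cluster index).
    """
    config = config or UnclesConfig()
    _check_collection(datasets)
    provider = provider or PartitionProvider(config.seed)
    records: list[ClusterRecord] = []
    for K in config.k_list:
        copam = _copam_for(datasets, config, K, provider)
        for delta in config.delta_grid:
            B = dtb_binarise(copam, delta)
            for k in range(K):
                records.append(ClusterRecord(
                    genes=B.cluster_genes(k), spec_type="A", K=K, delta=delta))
    return ClusterPool(records, config, "A")


def run_type_b(positives: Sequence[ExpressionDataset],
               negatives: Sequence[ExpressionDataset],
               config: UnclesConfig | None = None,
               provider: PartitionProvider | None = None) -> ClusterPool:
    """Mine subsets co-expressed in the positives but not the negatives.

    For every K and every (delta+, delta-) pair, the positive-subset
    clusters at delta+ are stripped of all genes assigned to any cluster in
    the negative-subset result at delta-.  Emits K records per grid pair,
    ordered by (K, delta+, delta-, cluster index).
    """
    config = config or UnclesConfig()
    if not positives or not negatives:
        raise ValueError("both positive and negative collections are required")
    _check_collection(list(positives) + list(negatives))
    provider = provider or PartitionProvider(config.seed)
    records: list[ClusterRecord] = []
    for K in config.k_list:
        copam_pos = _copam_for(positives, config, K, provider)
        copam_neg = _copam_for(negatives, config, K, provider)
        for dplus in config.delta_grid:
            pos = dtb_binarise(copam_pos, dplus)
            pos_sets = [pos.cluster_genes(k) for k in range(K)]
            for dminus in config.delta_grid:
                removed = frozenset(
                    np.flatnonzero(dtb_binarise(copam_neg, dminus)
                                   .assigned()).tolist())
                for k in range(K):
                    records.append(ClusterRecord(
                        genes=pos_sets[k] - removed, spec_type="B", K=K,
                        delta_plus=dplus, delta_minus=dminus))
    return ClusterPool(records, config, "B")


def run_comparator(datasets: Sequence[ExpressionDataset], method: str,
                   k_list: Sequence[int] = COMPARATOR_K_LIST,
                   seed: int = 0) -> ClusterPool:
    """Single-method harness: cluster each dataset separately at every K.

    Emits K records per (dataset, K) pair — sum(k_list) * L records in
    total — mirroring how conventional clusterers are benchmarked against
    the consensus pools.
    """
    _check_collection(datasets)
    provider = PartitionProvider(seed)
    records: list[ClusterRecord] = []
    for d in datasets:
        for K in k_list:
            part = provider.get(d, method, K)
            for k in range(K):
                records.append(ClusterRecord(
                    genes=frozenset(np.flatnonzero(part.matrix[k]).tolist()),
                    spec_type="single", K=K, dataset_id=d.dataset_id))
    cfg = UnclesConfig(k_list=tuple(k_list), methods=(method,), seed=seed)
    return ClusterPool(records, cfg, "single")


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:g}"


def write_pool(pool: ClusterPool, gene_ids: Sequence[str],
               path: str | Path) -> None:
    """Serialise a pool as TSV: record_id, type, K, deltas, size, gene ids."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "type", "K", "delta", "delta_plus",
                         "delta_minus", "dataset_id", "n_genes", "genes"])
        for i, rec in enumerate(pool.records):
            ids = ";".join(gene_ids[g] for g in sorted(rec.genes))
            writer.writerow([i, rec.spec_type, rec.K, _fmt(rec.delta),
                             _fmt(rec.delta_plus), _fmt(rec.delta_minus),
                             rec.dataset_id or "", rec.size, ids])


def read_pool(path: str | Path, gene_ids: Sequence[str]) -> ClusterPool:
    """Read a pool TSV written by :func:`write_pool`."""
    index = {g: i for i, g in enumerate(gene_ids)}
    records: list[ClusterRecord] = []
    spec_type = "A"
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            names = [g for g in row["genes"].split(";") if g]
            unknown = [g for g in names if g not in index]
            if unknown:
                raise ValueError(f"unknown gene ids in pool: {unknown[:5]}")
            spec_type = row["type"]
            records.append(ClusterRecord(
                genes=frozenset(index[g] for g in names),
                spec_type=spec_type,
                K=int(row["K"]),
                delta=float(row["delta"]) if row["delta"] else None,
                delta_plus=float(row["delta_plus"]) if row["delta_plus"] else None,
                delta_minus=(float(row["delta_minus"])
                             if row["delta_minus"] else None),
                dataset_id=row["dataset_id"] or None))
    return ClusterPool(records, UnclesConfig(), spec_type)
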