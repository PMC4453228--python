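"""Relabelling, fuzzy consensus averaging and difference-threshold binarisation.

The consensus layer aligns hard partitions from different methods and
datasets (cluster labels are arbitrary per run), averages them into a fuzzy
consensus partition matrix (CoPaM) whose entry (k, g) is the — optionally
weighted — fraction of partitions placing gene g in cluster k, and finally
binarises the CoPaM with the difference-threshold rule (DTB): a gene joins
its top cluster only if its membership there exceeds the runner-up
membership by at least delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .base_partitioning import PartitionMatrix

__all__ = [
    "FuzzyCoPaM",
    "BinaryAssignment",
    "relabel_partitions",
    "build_copam",
    "dtb_binarise",
]

#: Absolute tolerance for the inclusive membership-gap comparison; CoPaM
#: entries are sums of w_r terms, so exact grid values like 0.5 may carry
#: float rounding.
_GAP_TOL = 1e-9


@dataclass(eq=False)
class FuzzyCoPaM:
    """Fuzzy consensus partition matrix (K x G, columns sum to 1)."""

    matrix: np.ndarray
    source_count: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("CoPaM must be 2-D")
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise ValueError("CoPaM entries must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.matrix.shape[0]

    @property
    def G(self) -> int:
        return self.matrix.shape[1]


@dataclass(eq=False)
class BinaryAssignment:
    """DTB result: binary K x G matrix whose columns sum to 0 or 1."""

    matrix: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix).astype(np.uint8)
        sums = self.matrix.sum(axis=0)
        if np.any(sums > 1):
            raise ValueError("a gene may belong to at most one cluster")

    def assigned(self) -> np.ndarray:
        """Boolean mask over genes assigned to some cluster."""
        return self.matrix.any(axis=0)

    def cluster_genes(self, k: int) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.matrix[k]).tolist())


def _check_shapes(partitions: Sequence[PartitionMatrix]) -> tuple[int, int]:
    if not partitions:
        raise ValueError("no partitions given")
    K, G = partitions[0].K, partitions[0].G
    for p in partitions[1:]:
        if p.K != K or p.G != G:
            raise ValueError(
                f"all partitions must share K and G; got ({p.K},{p.G}) vs ({K},{G})"
            )
    return K, G


def relabel_partitions(partitions: Sequence[PartitionMatrix]
                       ) -> list[PartitionMatrix]:
    """Align cluster labels of all partitions to the first one.

    For each non-reference partition, the one-to-one cluster correspondence
    maximising the total shared-gene count with the reference is found by
    the Hungarian algorithm, and the partition's rows are permuted
    accordingly.  Outputs equal the inputs up to row permutation.
    """
    _check_shapes(partitions)
    ref = partitions[0]
    out = [ref]
    for p in partitions[1:]:
        overlap = ref.matrix.astype(np.int64) @ p.matrix.T.astype(np.int64)
        _, cols = linear_sum_assignment(-overlap)
        out.append(PartitionMatrix(p.matrix[cols], dict(p.provenance)))
    return out


def build_copam(aligned: Sequence[PartitionMatrix],
                weights: Sequence[float] | None = None) -> FuzzyCoPaM:
    """Average aligned partitions into a fuzzy CoPaM.

    With no weights, entry (k, g) is the fraction of partitions placing
    gene g in cluster k.  Weights (e.g. proportional to the source
    dataset's sample count) are normalised to sum to one.
    """
    K, G = _check_shapes(aligned)
    R = len(aligned)
    if weights is None:
        w = np.full(R, 1.0 / R)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.size != R:
            raise ValueError("one weight per partition required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        w = w / total
    M = np.zeros((K, G))
    for wi, p in zip(w, aligned):
        M += wi * p.matrix
    return FuzzyCoPaM(M, source_count=R, weights=w)


def dtb_binarise(copam: FuzzyCoPaM, delta: float) -> BinaryAssignment:
    """Difference-threshold binarisation with tightness ``delta`` in [0, 1].

    Gene g is assigned to its maximum-membership cluster iff the gap to the
    second-largest membership is at least delta; otherwise it is left
    unassigned.  At delta = 0 every gene is assigned (exact membership ties
    break to the lowest cluster index); at delta = 1 only unanimous genes
    (membership exactly 1) are assigned.  For K = 1 the runner-up
    membership is defined as 0.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    M = copam.matrix
    K, G = M.shape
    top = M.argmax(axis=0)  # lowest index on ties
    cols = np.arange(G)
    top_val = M[top, cols]
    if K == 1:
        second = np.zeros(G)
    else:
        tmp = M.copy()
        tmp[top, cols] = -np.inf
        second = tmp.max(axis=0)
    assigned = (top_val - second) >= (delta - _GAP_TOL)
    B = np.zeros((K, G), dtype=np.uint8)
    B[top[assigned], cols[assigned]] = 1
    return BinaryAssignment(B, delta=float(delta))
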