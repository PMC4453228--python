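"""Cluster selection by the M-N scatter-plot technique.

Every non-empty pooled cluster is placed on a plane whose horizontal axis
is a mean-squared-error dispersion metric M (smaller = tighter) and whose
vertical axis is the logarithm of the cluster's gene count N (larger =
better).  After min-max scaling both axes to [0, 1], the best cluster is
the one closest to the top-left corner (scaled M = 0, scaled N = 1).
Selection is iterated: each pick removes every cluster sharing at least
one gene with it, and the next-closest survivor is picked, yielding a
sequence of pairwise-disjoint clusters whose corner distances are
comparable across iterations because the axis scaling is computed once on
the full initial scatter.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .expression_io import ExpressionDataset
from .uncles_engine import ClusterPool, ClusterRecord

__all__ = [
    "MNPoint",
    "cluster_mse",
    "m_metric",
    "build_mn_scatter",
    "iterative_select",
    "write_mn_table",
    "plot_mn_scatter",
]


@dataclass(eq=False)
class MNPoint:
    """One cluster's coordinates on the (scaled) M-N plane."""

    record: ClusterRecord
    M: float
    N: int
    logN: float
    scaled_M: float = 0.0
    scaled_N: float = 1.0
    corner_distance: float = 0.0
    index: int = 0  # position in the source pool, used for tie-breaking


def cluster_mse(dataset: ExpressionDataset, genes) -> float:
    """Mean squared deviation of member profiles from their mean profile.

    For a cluster of N_k genes in a D-sample dataset this is
    ``sum_i ||x_i - z||^2 / (D * N_k)`` with ``z`` the average profile of
    the members.  Zero for singletons and for identical profiles.
    """
    idx = np.fromiter(genes, dtype=int)
    if idx.size == 0:
        raise ValueError("cluster_mse is undefined for an empty gene set")
    X = dataset.values[idx]
    z = X.mean(axis=0)
    return float(((X - z) ** 2).sum() / (dataset.n_samples * idx.size))


def m_metric(record: ClusterRecord,
             datasets: Sequence[ExpressionDataset]) -> float:
    """Dispersion metric M for a pooled cluster; smaller is better.

    Type A records score the mean of the per-dataset MSE over all
    datasets.  Type B records score mean MSE over the positive datasets
    minus mean MSE over the negative datasets, rewarding clusters that are
    tight in the positives and dispersed in the negatives.
    """
    if record.spec_type == "B":
        pos = [d for d in datasets if d.role == "positive"]
        neg = [d for d in datasets if d.role == "negative"]
        if not pos or not neg:
            raise ValueError("type B M metric needs positive and negative "
                             "datasets in the collection")
        return (float(np.mean([cluster_mse(d, record.genes) for d in pos]))
                - float(np.mean([cluster_mse(d, record.genes) for d in neg])))
    return float(np.mean([cluster_mse(d, record.genes) for d in datasets]))


def build_mn_scatter(pool: ClusterPool,
                     datasets: Sequence[ExpressionDataset]) -> list[MNPoint]:
    """Compute M-N coordinates and corner distances for a cluster pool.

    Empty records are excluded.  Both axes are min-max scaled over the
    included points; if an axis is constant it carries no ranking
    information and its scaled coordinate is set to the ideal value (0 for
    M, 1 for N).  The corner distance is the Euclidean distance to the
    scaled top-left corner (0, 1).
    """
    mse_cache: dict[tuple[str, frozenset[int]], float] = {}

    def cached_m(record: ClusterRecord) -> float:
        def mse(d: ExpressionDataset) -> float:
            key = (d.dataset_id, record.genes)
            if key not in mse_cache:
                mse_cache[key] = cluster_mse(d, record.genes)
            return mse_cache[key]

        if record.spec_type == "B":
            pos = [d for d in datasets if d.role == "positive"]
            neg = [d for d in datasets if d.role == "negative"]
            if not pos or not neg:
                raise ValueError("type B M metric needs positive and "
                                 "negative datasets")
            return (float(np.mean([mse(d) for d in pos]))
                    - float(np.mean([mse(d) for d in neg])))
        return float(np.mean([mse(d) for d in datasets]))

    points = [MNPoint(record=rec, M=cached_m(rec), N=rec.size,
                      logN=math.log(rec.size), index=i)
              for i, rec in enumerate(pool.records) if rec.size > 0]
    if not points:
        raise ValueError("all pooled clusters are empty; nothing to scatter")
    m_vals = np.array([p.M for p in points])
    n_vals = np.array([p.logN for p in points])
    m_range = m_vals.max() - m_vals.min()
    n_range = n_vals.max() - n_vals.min()
    for p in points:
        p.scaled_M = 0.0 if m_range == 0 else (p.M - m_vals.min()) / m_range
        p.scaled_N = 1.0 if n_range == 0 else (p.logN - n_vals.min()) / n_range
        p.corner_distance = math.hypot(p.scaled_M, 1.0 - p.scaled_N)
    return points


def iterative_select(points: Sequence[MNPoint], max_clusters: int
                     ) -> list[tuple[MNPoint, float]]:
    """Iterated corner-distance selection with overlap removal.

    Repeatedly picks the point with the smallest corner distance (ties
    broken by larger N, then smaller K, then pool order), then removes it
    and every point whose gene set intersects it, until ``max_clusters``
    picks are made or no points remain.  Returns the picks with their
    distances, in pick order; with the axis scaling held fixed the
    distance sequence is non-decreasing.
    """
    if max_clusters < 1:
        raise ValueError("max_clusters must be at least 1")
    if not points:
        raise ValueError("no points to select from")
    alive = list(points)
    picks: list[tuple[MNPoint, float]] = []
    while alive and len(picks) < max_clusters:
        best = min(alive, key=lambda p: (p.corner_distance, -p.N,
                                         p.record.K, p.index))
        picks.append((best, best.corner_distance))
        alive = [p for p in alive if not (p.record.genes & best.record.genes)]
    return picks


def write_mn_table(points: Sequence[MNPoint], path: str | Path,
                   selected: Sequence[tuple[MNPoint, float]] | None = None
                   ) -> None:
    """Export the scatter (and optional selection ranks) as TSV."""
    rank = {id(p): r + 1 for r, (p, _) in enumerate(selected or [])}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "M", "N", "scaled_M", "scaled_N",
                         "distance", "selected_rank"])
        for p in points:
            writer.writerow([p.index, f"{p.M:.6g}", p.N,
                             f"{p.scaled_M:.6g}", f"{p.scaled_N:.6g}",
                             f"{p.corner_distance:.6g}",
                             rank.get(id(p), "")])


def plot_mn_scatter(points: Sequence[MNPoint], path: str | Path,
                    selected: Sequence[tuple[MNPoint, float]] | None = None,
                    title: str = "M-N scatter") -> None:
    """Render the scatter; selected clusters are filled circles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter([p.M for p in points], [p.logN for p in points],
               marker="s", s=12, facecolors="none", edgecolors="black",
               linewidths=0.6, label="pooled clusters")
    if selected:
        ax.scatter([p.M for p, _ in selected], [p.logN for p, _ in selected],
                   marker="o", s=60, color="tab:blue", label="selected")
    ax.set_xlabel("M (dispersion metric)")
    ax.set_ylabel("log N (gene count)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
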