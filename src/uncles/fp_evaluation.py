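"""Ground-truth cluster evaluation on the F-P plane.

When the target gene set is known (as it is for planted synthetic
clusters), each discovered cluster of N genes with n true positives from a
target of m genes in a genome of M genes gets:

* a binomial-tail p-value — the probability of drawing at least n hits in
  N independent draws with hit probability m/M;
* a scaled p-value ``log(p) / log((m/M)^m)`` in [0, 1] — 1 for the
  theoretically ideal cluster (N = n = m), 0 for clusters with no hits;
* an in-cluster false-positive rate ``(N - n)/N``.

Clusters are scattered on the (FPR, scaled p) plane whose ideal corner is
(0, 1); the corner distance is at most sqrt(2) (the plot's diameter).  Two
methods' cluster pools are compared by pairing the closest halves of their
true-positive-containing clusters rank by rank and t-testing the signed
distance differences.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom, ttest_rel

__all__ = [
    "GroundTruth",
    "FPPoint",
    "ComparisonResult",
    "binomial_pvalue",
    "log_binomial_pvalue",
    "scaled_pvalue",
    "fp_point",
    "zero_fn_curve",
    "compare_methods",
    "write_fp_table",
    "read_fp_table",
    "plot_fp_scatter",
]

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class GroundTruth:
    """A target gene set inside a known genome."""

    target_genes: frozenset[str]
    genome: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_genes", frozenset(self.target_genes))
        object.__setattr__(self, "genome", tuple(self.genome))
        if not 1 <= len(self.target_genes) <= len(self.genome):
            raise ValueError("target must be non-empty and within the genome")
        missing = self.target_genes - set(self.genome)
        if missing:
            raise ValueError(f"target genes absent from genome: "
                             f"{sorted(missing)[:5]}")

    @property
    def m(self) -> int:
        return len(self.target_genes)

    @property
    def genome_size(self) -> int:
        return len(self.genome)


@dataclass(frozen=True)
class FPPoint:
    """One cluster's coordinates on the F-P plane."""

    N: int
    n: int
    p_value: float
    scaled_p: float
    fpr: float
    corner_distance: float


@dataclass(frozen=True)
class ComparisonResult:
    """Paired comparison of two methods' corner distances.

    ``mu`` is the mean signed distance difference (first minus second
    method) over rank-paired closest halves; negative values favour the
    first method.  Bounded by the plot diameter, |mu| <= sqrt(2).
    """

    mu: float
    sigma: float
    p_value: float
    n_pairs: int


def _validate_counts(genome_size: int, m: int, N: int, n: int) -> None:
    if not 1 <= m <= genome_size:
        raise ValueError(f"need 1 <= m <= genome size, got m={m}, "
                         f"genome={genome_size}")
    if not 0 <= n <= N <= genome_size:
        raise ValueError(f"need 0 <= n <= N <= genome size, got n={n}, N={N}")


def log_binomial_pvalue(genome_size: int, m: int, N: int, n: int) -> float:
    """Natural log of the binomial tail P(X >= n), X ~ Binom(N, m/M).

    Evaluated by log-sum-exp over the log binomial pmf, which stays
    accurate for the very small tails large clusters produce.
    """
    _validate_counts(genome_size, m, N, n)
    if n == 0:
        return 0.0
    p = m / genome_size
    if p >= 1.0:
        return 0.0
    j = np.arange(n, N + 1)
    return min(float(logsumexp(binom.logpmf(j, N, p))), 0.0)


def binomial_pvalue(genome_size: int, m: int, N: int, n: int) -> float:
    """Binomial tail probability of n or more true positives among N draws."""
    return float(math.exp(log_binomial_pvalue(genome_size, m, N, n)))


def scaled_pvalue(p_value: float, m: int, genome_size: int) -> float:
    """log(p) over the log of the best possible p-value ``(m/M)^m``.

    Equals 1 for the theoretically ideal cluster and 0 when p = 1 (no true
    positives).  Values are clipped to [0, 1]; exceeding the range is
    logged, as it can only arise from numerical round-off.
    """
    if not 0.0 < p_value <= 1.0:
        raise ValueError(f"p_value must lie in (0, 1], got {p_value}")
    return _scaled_from_log(math.log(p_value), m, genome_size)


def _scaled_from_log(log_p: float, m: int, genome_size: int) -> float:
    if log_p == 0.0:
        return 0.0
    denom = m * math.log(m / genome_size)
    val = log_p / denom
    if not 0.0 <= val <= 1.0:
        logger.warning("scaled p-value %.4g outside [0, 1]; clipping", val)
        val = min(max(val, 0.0), 1.0)
    return float(val)


def fp_point(cluster: Iterable[str], truth: GroundTruth) -> FPPoint:
    """Place one cluster (a set of gene ids) on the F-P plane.

    An exact match of the target sits at the ideal corner (distance 0); a
    cluster disjoint from the target sits at the worst corner (distance
    sqrt(2)).  Empty clusters are mapped to the worst corner as well so
    that they can never win a comparison.
    """
    cluster = frozenset(cluster)
    unknown = cluster - set(truth.genome)
    if unknown:
        raise ValueError(f"cluster contains unknown gene ids: "
                         f"{sorted(unknown)[:5]}")
    N = len(cluster)
    if N == 0:
        return FPPoint(N=0, n=0, p_value=1.0, scaled_p=0.0, fpr=1.0,
                       corner_distance=SQRT2)
    n = len(cluster & truth.target_genes)
    log_p = log_binomial_pvalue(truth.genome_size, truth.m, N, n)
    scaled = _scaled_from_log(log_p, truth.m, truth.genome_size)
    fpr = (N - n) / N
    return FPPoint(N=N, n=n, p_value=float(math.exp(log_p)), scaled_p=scaled,
                   fpr=fpr, corner_distance=math.hypot(fpr, 1.0 - scaled))


def zero_fn_curve(truth: GroundTruth, N_values: Sequence[int]
                  ) -> list[tuple[float, float]]:
    """The zero-false-negative boundary: points with n = m at each N >= m.

    This is the theoretical upper limit of the scaled p-value at any fixed
    FPR; as N grows the curve slides from the ideal corner (N = m) towards
    the bottom-right.
    """
    out = []
    for N in N_values:
        if N < truth.m:
            raise ValueError(f"zero-false-negative points need N >= m "
                             f"({N} < {truth.m})")
        log_p = log_binomial_pvalue(truth.genome_size, truth.m, int(N), truth.m)
        out.append(((N - truth.m) / N,
                    _scaled_from_log(log_p, truth.m, truth.genome_size)))
    return out


def compare_methods(points_a: Sequence[FPPoint],
                    points_b: Sequence[FPPoint]) -> ComparisonResult:
    """Paired comparison of two cluster pools' corner distances.

    Only clusters with at least one true positive are considered; each
    method keeps its closest 50 % (ceil) by corner distance; the two
    retained lists are sorted ascending, rank-paired and truncated to the
    shorter length; the signed differences (a minus b) are summarised by
    their mean, sample standard deviation and paired t-test p-value.
    """
    kept = []
    for label, pts in (("first", points_a), ("second", points_b)):
        with_tp = sorted(p.corner_distance for p in pts if p.n >= 1)
        if not with_tp:
            raise ValueError(f"the {label} method has no clusters with a "
                             "true positive member")
        kept.append(with_tp[:math.ceil(len(with_tp) / 2)])
    n_pairs = min(len(kept[0]), len(kept[1]))
    a = np.array(kept[0][:n_pairs])
    b = np.array(kept[1][:n_pairs])
    diffs = a - b
    mu = float(diffs.mean())
    sigma = float(diffs.std(ddof=1)) if n_pairs > 1 else 0.0
    if sigma == 0.0:
        p = 1.0 if mu == 0.0 else 0.0
    else:
        p = float(ttest_rel(a, b).pvalue)
    return ComparisonResult(mu=mu, sigma=sigma, p_value=p, n_pairs=n_pairs)


def write_fp_table(points: Sequence[FPPoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "N", "n", "fpr", "p_value", "scaled_p",
                         "distance"])
        for i, p in enumerate(points):
            writer.writerow([i, p.N, p.n, f"{p.fpr:.6g}", f"{p.p_value:.6g}",
                             f"{p.scaled_p:.6g}", f"{p.corner_distance:.6g}"])


def read_fp_table(path: str | Path) -> list[FPPoint]:
    points = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            points.append(FPPoint(
                N=int(row["N"]), n=int(row["n"]), fpr=float(row["fpr"]),
                p_value=float(row["p_value"]),
                scaled_p=float(row["scaled_p"]),
                corner_distance=float(row["distance"])))
    return points


def plot_fp_scatter(points: Sequence[FPPoint], truth: GroundTruth,
                    path: str | Path, title: str = "F-P scatter") -> None:
    """Scatter clusters on the F-P plane with the zero-false-negative curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    n_grid = np.unique(np.linspace(truth.m, truth.genome_size, 200).astype(int))
    curve = zero_fn_curve(truth, n_grid)
    ax.plot([f for f, _ in curve], [s for _, s in curve], "k-", lw=1,
            label="zero false negatives")
    ax.scatter([p.fpr for p in points], [p.scaled_p for p in points],
               marker="*", s=20, color="tab:red", label="clusters")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("false-positive rate (F)")
    ax.set_ylabel("scaled p-value (P)")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
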