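"""End-to-end convenience layer: normalise, run, select, evaluate.

These helpers wire the module-level operations together the way the CLI,
the test suite and the reproduction script use them; nothing here adds
behaviour beyond composition.
"""

from __future__ import annotations

from typing import Sequence

from .expression_io import ExpressionDataset, preprocess
from .fp_evaluation import GroundTruth, fp_point
from .mn_selection import MNPoint, build_mn_scatter, iterative_select
from .synthetic_data import SyntheticCollection
from .uncles_engine import (ClusterPool, PartitionProvider, UnclesConfig,
                            run_type_a, run_type_b)

__all__ = [
    "preprocess_collection",
    "select_best_clusters",
    "recover_planted",
    "jaccard",
]


def preprocess_collection(datasets: Sequence[ExpressionDataset]
                          ) -> list[ExpressionDataset]:
    """Apply the per-channel normalisation route to every dataset."""
    return [preprocess(d) for d in datasets]


def select_best_clusters(datasets: Sequence[ExpressionDataset],
                         config: UnclesConfig,
                         spec_type: str,
                         max_clusters: int = 1,
                         provider: PartitionProvider | None = None
                         ) -> tuple[list[tuple[MNPoint, float]],
                                    ClusterPool, list[MNPoint]]:
    """Run a type A or B sweep and pick the best clusters by M-N distance.

    Returns (picks, pool, scatter points).  For type B the positive and
    negative subsets are taken from the datasets' roles.
    """
    if spec_type == "A":
        pool = run_type_a(datasets, config, provider)
    elif spec_type == "B":
        positives = [d for d in datasets if d.role == "positive"]
        negatives = [d for d in datasets if d.role == "negative"]
        pool = run_type_b(positives, negatives, config, provider)
    else:
        raise ValueError(f"spec_type must be 'A' or 'B', got {spec_type!r}")
    points = build_mn_scatter(pool, datasets)
    picks = iterative_select(points, max_clusters)
    return picks, pool, points


def jaccard(a: frozenset, b: frozenset) -> float:
    """Jaccard similarity of two sets (1.0 when both are empty)."""
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def recover_planted(collection: SyntheticCollection,
                    config: UnclesConfig | None = None) -> dict:
    """Full recovery experiment on a synthetic collection.

    Normalises the datasets, runs both type A (all six datasets) and
    type B (positives vs negatives) sweeps over the default grids, picks
    the single best cluster of each type by the M-N technique, and scores
    each pick against its planted target (C1 for type A, C2 for type B)
    with the Jaccard index and the F-P corner distance.
    """
    config = config or UnclesConfig()
    pre = preprocess_collection(collection.datasets)
    provider = PartitionProvider(config.seed)
    out: dict = {}
    gene_ids = collection.gene_ids
    for spec_type, target in (("A", "C1"), ("B", "C2")):
        picks, pool, _ = select_best_clusters(pre, config, spec_type,
                                              max_clusters=1,
                                              provider=provider)
        best = picks[0][0].record
        best_ids = frozenset(gene_ids[g] for g in best.genes)
        truth_ids = (collection.truth_c1 if target == "C1"
                     else collection.truth_c2)
        truth = GroundTruth(target_genes=truth_ids, genome=tuple(gene_ids))
        point = fp_point(best_ids, truth)
        out[spec_type] = {
            "genes": best_ids,
            "record": best,
            "pool_size": len(pool),
            "jaccard": jaccard(best_ids, truth_ids),
            "fp": point,
        }
    return out
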