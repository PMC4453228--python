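"""Reading, validation, filtering and normalisation of expression datasets.

A collection is a list of :class:`ExpressionDataset` objects measuring the
same ordered gene list in different experiments (possibly with different
numbers of samples, platforms and biological contexts).  All downstream
consensus machinery assumes the collection has been passed through
:func:`filter_genes_by_missing` (if it had missing values) and
:func:`preprocess`, so every matrix it sees is finite, aligned and
normalised.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "filter_genes_by_missing",
    "quantile_normalise",
    "standardise_genes",
    "preprocess",
    "read_gene_list",
    "write_gene_list",
]

#: Cell contents interpreted as a missing measurement.
MISSING_TOKENS = frozenset({"", "NA", "na", "NaN", "nan", "NAN", "NULL", "null"})

ROLES = ("positive", "negative", "unspecified")
CHANNELS = ("one_channel", "two_channel", "unknown")


@dataclass(eq=False)
class ExpressionDataset:
    """One genes x samples expression matrix with its collection metadata.

    Parameters
    ----------
    dataset_id
        Stable identifier, used in provenance and for deriving sub-seeds.
    gene_ids
        Ordered gene identifiers (rows).  Identity across a collection is
        positional: every dataset of a collection must carry the same list.
    values
        Real matrix of shape ``(G, D)``, rows = genes, columns = samples or
        time points.
    role
        ``positive`` / ``negative`` membership for differential (type B)
        runs; ``unspecified`` otherwise.
    channel
        Microarray channel count; controls the normalisation route in
        :func:`preprocess` (one-channel data is quantile normalised,
        two-channel data is assumed already log-ratio normalised upstream).
    missing_mask
        Boolean matrix marking missing measurements.  Defaults to the NaN
        pattern of ``values``.
    """

    dataset_id: str
    gene_ids: list[str]
    values: np.ndarray
    role: str = "unspecified"
    channel: str = "unknown"
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.gene_ids)} gene ids"
            )
        if self.values.shape[1] < 2:
            raise ValueError("a dataset needs at least two samples")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape mismatch")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(
        self, values: np.ndarray, missing_mask: np.ndarray | None = None
    ) -> "ExpressionDataset":
        """Copy of this dataset with new values (and mask)."""
        if missing_mask is None:
            missing_mask = np.zeros_like(np.asarray(values, dtype=float), dtype=bool)
        return replace(self, values=np.asarray(values, dtype=float),
                       missing_mask=missing_mask)


def read_expression(
    path: str | Path,
    *,
    dataset_id: str | None = None,
    role: str = "unspecified",
    channel: str = "unknown",
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Read a delimited genes x samples matrix.

    The first row is a header of sample names, the first column holds gene
    identifiers, and any cell equal to one of :data:`MISSING_TOKENS` is
    recorded in the missing mask.  The delimiter defaults to ``,`` for
    ``.csv`` files and tab otherwise.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    expected: int | None = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        for lineno, raw in enumerate(reader, start=2):
            if not raw or all(not c.strip() for c in raw):
                continue
            if expected is None:
                expected = len(raw)
                if len(header) not in (expected, expected - 1):
                    raise ValueError(
                        f"{path}: header has {len(header)} fields, "
                        f"rows have {expected}"
                    )
            if len(raw) != expected:
                raise ValueError(
                    f"{path}: ragged row at line {lineno}: "
                    f"expected {expected} fields, got {len(raw)}"
                )
            gene_ids.append(raw[0].strip())
            vals, miss = [], []
            for tok in raw[1:]:
                tok = tok.strip()
                if tok in MISSING_TOKENS:
                    vals.append(np.nan)
                    miss.append(True)
                else:
                    vals.append(float(tok))
                    miss.append(False)
            rows.append(vals)
            mask_rows.append(miss)
    dupes = [g for g, c in Counter(gene_ids).items() if c > 1]
    if dupes:
        raise ValueError(f"{path}: duplicate gene ids: {', '.join(sorted(dupes))}")
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        gene_ids=gene_ids,
        values=np.array(rows, dtype=float),
        role=role,
        channel=channel,
        missing_mask=np.array(mask_rows, dtype=bool),
    )


def write_expression(dataset: ExpressionDataset, path: str | Path,
                     delimiter: str = "\t") -> None:
    """Write a dataset in the same dialect ``read_expression`` accepts."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["gene_id"] + [f"s{i+1}" for i in range(dataset.n_samples)])
        for g, gid in enumerate(dataset.gene_ids):
            row: list[str] = [gid]
            for i in range(dataset.n_samples):
                if dataset.missing_mask[g, i]:
                    row.append("NA")
                else:
                    row.append(repr(float(dataset.values[g, i])))
            writer.writerow(row)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def filter_genes_by_missing(
    collection: Sequence[ExpressionDataset],
    allowed: int | Sequence[int],
) -> tuple[list[ExpressionDataset], list[str]]:
    """Keep genes whose per-dataset missing counts are within the allowances.

    A gene survives iff in *every* dataset ``d`` its number of missing
    values is at most ``allowed[d]``.  Survivors keep their original order
    in all datasets simultaneously; their residual missing entries are
    imputed with the gene's observed mean in that dataset (neutral under
    the zero-mean standardisation applied afterwards).
    """
    if not collection:
        raise ValueError("empty collection")
    if isinstance(allowed, (int, np.integer)):
        allowed = [int(allowed)] * len(collection)
    allowed = [int(a) for a in allowed]
    if len(allowed) != len(collection):
        raise ValueError("one allowance per dataset required")
    if any(a < 0 for a in allowed):
        raise ValueError("allowances must be non-negative")
    gene_ids = collection[0].gene_ids
    for ds in collection[1:]:
        if ds.gene_ids != gene_ids:
            raise ValueError("datasets in a collection must share gene_ids")
    keep = np.ones(len(gene_ids), dtype=bool)
    for ds, a in zip(collection, allowed):
        keep &= ds.missing_mask.sum(axis=1) <= a
    if not keep.any():
        raise ValueError(
            "no genes survive the missing-value filter; relax the allowances"
        )
    survivors = [g for g, k in zip(gene_ids, keep) if k]
    out: list[ExpressionDataset] = []
    for ds in collection:
        vals = ds.values[keep].copy()
        mask = ds.missing_mask[keep]
        for g in np.flatnonzero(mask.any(axis=1)):
            row = vals[g]
            obs = ~mask[g]
            row[~obs] = row[obs].mean() if obs.any() else 0.0
        out.append(replace(ds, gene_ids=list(survivors), values=vals,
                           missing_mask=np.zeros_like(mask)))
    return out, survivors


def quantile_normalise(dataset: ExpressionDataset) -> ExpressionDataset:
    """Force every column to the mean empirical distribution.

    Each column's values are replaced by the across-column means of the
    per-rank sorted values; tied values within a column receive the mean
    of the rank-means they span, which makes the transform deterministic
    and idempotent.
    """
    if dataset.missing_mask.any():
        raise ValueError("quantile_normalise requires a complete matrix; "
                         "run filter_genes_by_missing first")
    X = dataset.values
    rank_means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(col)
        ranked[order] = rank_means
        uniq, inv = np.unique(col, return_inverse=True)
        sums = np.zeros(uniq.size)
        counts = np.zeros(uniq.size)
        np.add.at(sums, inv, ranked)
        np.add.at(counts, inv, 1.0)
        out[:, j] = (sums / counts)[inv]
    return dataset.with_values(out)


def standardise_genes(dataset: ExpressionDataset,
                      unit_sd: bool = True) -> ExpressionDataset:
    """Centre every gene row at mean 0, optionally scaling to sample sd 1.

    Constant rows cannot be scaled; they are left as zero vectors and a
    warning is emitted.
    """
    if dataset.missing_mask.any():
        raise ValueError("standardise_genes requires a complete matrix")
    X = dataset.values - dataset.values.mean(axis=1, keepdims=True)
    if unit_sd:
        sd = X.std(axis=1, ddof=1)
        flat = sd <= 0
        if flat.any():
            warnings.warn(
                f"{dataset.dataset_id}: {int(flat.sum())} constant gene row(s) "
                "left as zero vectors", stacklevel=2)
            sd = np.where(flat, 1.0, sd)
        X = X / sd[:, None]
    return dataset.with_values(X)


def preprocess(dataset: ExpressionDataset, unit_sd: bool = True) -> ExpressionDataset:
    """Standard normalisation route used ahead of clustering.

    One-channel datasets are quantile normalised; two-channel datasets are
    taken as already log-ratio normalised upstream and skip that step.
    All datasets are then gene-standardised (zero mean, unit sd rows).
    """
    if dataset.channel == "one_channel":
        dataset = quantile_normalise(dataset)
    return standardise_genes(dataset, unit_sd=unit_sd)
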