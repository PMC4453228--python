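"""Synthetic multi-dataset expression collections with planted structure.

The generator emulates a six-dataset validation collection: three positive
datasets (P1, P2, P3 with 18, 18 and 6 samples) and three negative
datasets (N1, N2, N3 with 16, 12 and 12 samples) over a shared artificial
genome g1..gGS.  Cluster C1 (g1..g75 by default) is co-expressed in all
six datasets; cluster C2 (g76..g160) is co-expressed only in the
positives; the remaining background C0 is poorly co-expressed everywhere.
For realism, each dataset additionally contains a handful of *confounder*
genes drawn from C0 that are co-expressed with C1 (or C2, in positives) in
that one dataset only.

Co-expression is modelled as a shared smooth base profile (a standardised
random walk over the samples) plus independent Gaussian per-gene
deviations.  Background genes emulate non-differentially-expressed genes:
after the row standardisation every profile ends up on the same scale, so
a gene with no expression signal is an independent white-noise profile,
and that is how C0 is drawn.
A separate noise model estimates, per dataset and sample, the spread of
the planted clusters and injects zero-mean Gaussian noise of that
magnitude, for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .expression_io import ExpressionDataset, read_expression, write_expression

__all__ = [
    "SyntheticConfig",
    "SyntheticCollection",
    "NoiseModel",
    "generate",
    "estimate_noise_sigma",
    "add_noise",
    "write_collection",
    "load_collection",
]

DATASET_IDS = ("P1", "P2", "P3", "N1", "N2", "N3")
ROLES = ("positive", "positive", "positive", "negative", "negative", "negative")
#: P1, P2, P3 and N1 emulate one-channel platforms; N2 and N3 two-channel.
CHANNELS = ("one_channel", "one_channel", "one_channel", "one_channel",
            "two_channel", "two_channel")
DEFAULT_SAMPLES = (18, 18, 6, 16, 12, 12)
GS_SWEEP = (1200, 2000, 3000, 5000, 7000)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    ``within_cluster_sd`` is the standard deviation of the per-gene
    Gaussian deviation around a cluster's base profile, on the scale of the
    standardised base profiles (sd 1); 0.3 keeps planted clusters tight
    enough that the noiseless pipeline recovers them near-perfectly while
    remaining visibly noisy.  ``confounders_per_dataset`` is the inclusive
    range the per-dataset, per-cluster confounder count is drawn from.
    """

    gs: int = 1200
    samples_per_dataset: tuple[int, ...] = DEFAULT_SAMPLES
    c1_size: int = 75
    c2_size: int = 85
    confounders_per_dataset: tuple[int, int] = (5, 30)
    within_cluster_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples_per_dataset",
                           tuple(int(s) for s in self.samples_per_dataset))
        if self.c1_size < 2 or self.c2_size < 2:
            raise ValueError("planted clusters need at least 2 genes")
        if self.c1_size + self.c2_size >= self.gs:
            raise ValueError("c1_size + c2_size must be smaller than the "
                             "genome size")
        if any(s < 2 for s in self.samples_per_dataset):
            raise ValueError("every dataset needs at least 2 samples")
        lo, hi = self.confounders_per_dataset
        if not 0 <= lo <= hi:
            raise ValueError("invalid confounder count range")
        if self.within_cluster_sd < 0:
            raise ValueError("within_cluster_sd must be non-negative")


@dataclass(eq=False)
class SyntheticCollection:
    """Generated datasets plus their ground truth."""

    datasets: list[ExpressionDataset]
    truth_c1: frozenset[str]
    truth_c2: frozenset[str]
    confounder_log: dict[str, frozenset[str]]
    config: SyntheticConfig

    @property
    def gene_ids(self) -> list[str]:
        return self.datasets[0].gene_ids

    def truth_indices(self, which: str) -> frozenset[int]:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        truth = self.truth_c1 if which == "C1" else self.truth_c2
        return frozenset(index[g] for g in truth)


@dataclass(eq=False)
class NoiseModel:
    """Per-(dataset, sample) Gaussian noise standard deviations."""

    sigma: dict[str, np.ndarray]


def _standardise_rows(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1)
    sd[sd <= 0] = 1.0
    return X / sd[:, None]


def _random_walk_profiles(rng: np.random.Generator, n: int, D: int
                          ) -> np.ndarray:
    """n independent standardised random-walk profiles over D samples;
    used for the smooth base curves planted clusters share."""
    return _standardise_rows(rng.standard_normal((n, D)).cumsum(axis=1))


def _noise_profiles(rng: np.random.Generator, n: int, D: int) -> np.ndarray:
    """n independent standardised white-noise profiles; the background
    model for genes with no co-expression signal anywhere."""
    return _standardise_rows(rng.standard_normal((n, D)))


def generate(config: SyntheticConfig | None = None) -> SyntheticCollection:
    """Build a six-dataset collection with the planted C0/C1/C2 structure.

    Deterministic for a fixed seed.  With ``within_cluster_sd = 0`` every
    member of a planted cluster is identical to the cluster's base profile
    in each dataset where the cluster is active.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    GS = config.gs
    gene_ids = [f"g{i + 1}" for i in range(GS)]
    c1 = np.arange(config.c1_size)
    c2 = np.arange(config.c1_size, config.c1_size + config.c2_size)
    c0 = np.arange(config.c1_size + config.c2_size, GS)
    lo, hi = config.confounders_per_dataset
    wsd = config.within_cluster_sd

    datasets: list[ExpressionDataset] = []
    confounder_log: dict[str, frozenset[str]] = {}
    for ds_id, role, channel, D in zip(DATASET_IDS, ROLES, CHANNELS,
                                       config.samples_per_dataset):
        values = _noise_profiles(rng, GS, D)  # background for everyone
        active = [c1, c2] if role == "positive" else [c1]
        confounders: set[int] = set()
        free_background = set(c0.tolist())
        for members in active:
            base = _random_walk_profiles(rng, 1, D)[0]
            values[members] = base + rng.normal(0.0, wsd, (members.size, D))
            n_conf = int(rng.integers(lo, hi + 1))
            n_conf = min(n_conf, len(free_background))
            picked = rng.choice(sorted(free_background), size=n_conf,
                                replace=False)
            free_background -= set(picked.tolist())
            confounders.update(picked.tolist())
            if n_conf:
                values[picked] = base + rng.normal(0.0, wsd, (n_conf, D))
        confounder_log[ds_id] = frozenset(gene_ids[i] for i in confounders)
        datasets.append(ExpressionDataset(
            dataset_id=ds_id, gene_ids=list(gene_ids), values=values,
            role=role, channel=channel,
            missing_mask=np.zeros((GS, D), dtype=bool)))
    return SyntheticCollection(
        datasets=datasets,
        truth_c1=frozenset(gene_ids[i] for i in c1),
        truth_c2=frozenset(gene_ids[i] for i in c2),
        confounder_log=confounder_log,
        config=config)


def estimate_noise_sigma(collection: SyntheticCollection) -> NoiseModel:
    """Per-sample noise magnitudes estimated from the planted clusters.

    In positive datasets the noise sd at sample i is the mean of the C1
    and C2 spreads at that sample (each a sample standard deviation with
    denominator cluster size minus one); in negative datasets only C1 is
    co-expressed, so its spread alone is used.
    """
    idx_c1 = sorted(collection.truth_indices("C1"))
    idx_c2 = sorted(collection.truth_indices("C2"))
    if len(idx_c1) < 2 or len(idx_c2) < 2:
        raise ValueError("planted clusters need at least 2 genes to "
                         "estimate a spread")
    sigma: dict[str, np.ndarray] = {}
    for ds in collection.datasets:
        sd_c1 = ds.values[idx_c1].std(axis=0, ddof=1)
        if ds.role == "positive":
            sd_c2 = ds.values[idx_c2].std(axis=0, ddof=1)
            sigma[ds.dataset_id] = (sd_c1 + sd_c2) / 2.0
        else:
            sigma[ds.dataset_id] = sd_c1
    return NoiseModel(sigma=sigma)


def add_noise(collection: SyntheticCollection, noise: NoiseModel,
              seed: int) -> SyntheticCollection:
    """Perturb every value by independent zero-mean Gaussian noise.

    The standard deviation is the noise model's per-(dataset, sample)
    sigma; the ground truth is unchanged.  Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    datasets = []
    for ds in collection.datasets:
        if ds.dataset_id not in noise.sigma:
            raise ValueError(f"noise model has no sigmas for {ds.dataset_id}")
        sig = np.asarray(noise.sigma[ds.dataset_id], dtype=float)
        if sig.shape != (ds.n_samples,):
            raise ValueError(f"noise model for {ds.dataset_id} has "
                             f"{sig.shape} sigmas, expected ({ds.n_samples},)")
        perturbed = ds.values + rng.standard_normal(ds.values.shape) * sig
        datasets.append(ds.with_values(perturbed))
    return replace(collection, datasets=datasets)


def write_collection(collection: SyntheticCollection, outdir: str | Path
                     ) -> None:
    """Write the six TSVs, a truth file and a confounder log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in collection.datasets:
        write_expression(ds, outdir / f"{ds.dataset_id}.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene_id\tlabel\n")
        for g in collection.gene_ids:
            if g in collection.truth_c1:
                label = "C1"
            elif g in collection.truth_c2:
                label = "C2"
            else:
                label = "C0"
            fh.write(f"{g}\t{label}\n")
    with open(outdir / "confounders.tsv", "w") as fh:
        fh.write("dataset_id\tgenes\n")
        for ds_id in DATASET_IDS:
            genes = ";".join(sorted(collection.confounder_log.get(ds_id, ()),
                                    key=lambda g: int(g[1:])))
            fh.write(f"{ds_id}\t{genes}\n")


def load_collection(directory: str | Path,
                    config: SyntheticConfig | None = None
                    ) -> SyntheticCollection:
    """Read a collection laid out as by :func:`write_collection`
    (six matrices plus a gene-membership file)."""
    directory = Path(directory)
    datasets = [read_expression(directory / f"{ds_id}.tsv", dataset_id=ds_id,
                                role=role, channel=channel)
                for ds_id, role, channel in zip(DATASET_IDS, ROLES, CHANNELS)]
    c1, c2 = set(), set()
    with open(directory / "truth.tsv") as fh:
        next(fh)
        for line in fh:
            gene, label = line.split()
            if label == "C1":
                c1.add(gene)
            elif label == "C2":
                c2.add(gene)
    log: dict[str, frozenset[str]] = {}
    conf_path = directory / "confounders.tsv"
    if conf_path.exists():
        with open(conf_path) as fh:
            next(fh)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                genes = parts[1].split(";") if len(parts) > 1 and parts[1] else []
                log[parts[0]] = frozenset(genes)
    cfg = config or SyntheticConfig(
        gs=datasets[0].n_genes, c1_size=len(c1), c2_size=len(c2),
        samples_per_dataset=tuple(d.n_samples for d in datasets))
    return SyntheticCollection(datasets=datasets, truth_c1=frozenset(c1),
                               truth_c2=frozenset(c2), confounder_log=log,
                               config=cfg)
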