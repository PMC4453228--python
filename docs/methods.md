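# Methods

## Model and assumptions

The package treats a *collection* as L expression matrices over one shared,
ordered gene list; gene identity across datasets is purely positional.
Nothing about the samples is assumed beyond D ≥ 2 per dataset: time series,
tissue panels and condition series mix freely, because datasets are never
concatenated.  Instead, each dataset is clustered on its own and only the
resulting partitions are combined, projecting heterogeneous measurements
into the platform-invariant space of cluster memberships.

The consensus pipeline assumes (i) the base clusterers are diverse enough
that their agreement is informative — hence three methods from three
families (centroid-based k-means, competitive-learning SOM, agglomerative
Ward) — and (ii) a subset of genuinely co-regulated genes will co-cluster
in *every* dataset where the regulation is active, whereas spurious
within-study correlates will not repeat across studies.  The
difference-threshold binarisation (DTB) turns the fuzzy consensus into
gene sets at a chosen stringency δ: the gap between a gene's best and
second-best consensus membership must reach δ.  Type B differential runs
apply the same machinery to the positive and negative dataset subsets
separately and subtract the δ⁻-binarised negative assignments from the
δ⁺-binarised positive clusters.

No single (K, δ) is privileged.  All clusters over the grids are pooled
and ranked by the M-N scatter technique, which trades cluster dispersion
(M, a per-gene per-sample MSE; for type B the S⁺ mean MSE minus the S⁻
mean MSE so that dispersion in the negatives is rewarded) against cluster
size (log N), each min-max scaled, by distance to the ideal top-left
corner.  This removes K, δ, δ⁺ and δ⁻ as user-set parameters.

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| `k_list` | 4, 8, 12, 16, 20, 25 | cluster-count sweep; ΣK = 85 drives pool sizes (11·85 = 935 type A records, 11²·85 = 10,285 type B) |
| `delta_grid` | 0 … 1 step 0.1 | DTB stringencies; δ⁻ = 0 empties every type B record (all genes assigned in the negatives), so (0, 1) is the widest and (1, 0.1) the tightest useful pair |
| `methods` | kmeans, som, hc | partition order is datasets × (kmeans, som, hc) |
| `weight_by_samples` | off | CoPaM weights ∝ dataset sample counts instead of 1/R |
| `max_clusters` (selection) | user-set | the stopping point is study-specific; the tool reports the non-decreasing distance sequence so a quality gap can be read off, and deliberately implements no automatic gap test |
| `within_cluster_sd` (generator) | 0.3 | per-gene deviation around a planted base profile, on the standardised scale (base sd 1); calibrated once so the noiseless pipeline recovers the planted truth near-perfectly while members remain visibly dispersed |
| `confounders_per_dataset` (generator) | 5–30 | per planted cluster per dataset, drawn uniformly |

## Synthetic data: what it emulates and what it does not

The generator reproduces the six-dataset validation design: positives
P1, P2, P3 (18, 18, 6 samples), negatives N1, N2, N3 (16, 12, 12), a
75-gene cluster C1 planted in all six, an 85-gene cluster C2 planted in
the positives only, and per-dataset confounder genes co-expressed with an
active planted cluster in exactly one dataset.  Co-expression is a shared
smooth base curve — a standardised Gaussian random walk over the samples —
plus independent N(0, `within_cluster_sd`²) deviations per gene and
sample.  Background (C0) genes, and C2 rows inside negative datasets, are
independent standardised white-noise profiles: after row standardisation a
gene with no expression signal is indistinguishable from unit-variance
noise, which is the right null for "not differentially expressed"
background.  An early variant drew C0 as random walks too; that gives
every background gene a strong trend, and at K = 4 a few percent of them
then co-cluster with a planted cluster consistently across three datasets
by chance — background trendiness, not consensus, and unrepresentative of
non-differentially-expressed genes — so white noise is the deliberate
choice.

The noise model estimates, per dataset and sample, the spread of the
planted clusters themselves (mean of the C1 and C2 sample standard
deviations in positives, C1 alone in negatives, denominators cluster size
− 1) and injects independent zero-mean Gaussian noise of that magnitude —
a robustness stress on top of the generator's own dispersion.

What passing the planted-recovery tests does **not** show: the generator's
marginals are Gaussian constructions, not real microarray intensities; it
has no probe effects, batch structure, missing values, or correlated noise
across samples; and background genes are mutually independent, whereas
real transcriptomes contain many weakly correlated modules.  Recovery here
demonstrates the machinery end to end under the intended structure, not
performance on any particular real compendium.

## Numerical and convention choices

* **Relabelling** aligns every partition to the first (datasets in input
  order × methods in kmeans, som, hc order) via Hungarian assignment on
  shared-gene counts; optimal one-to-one matching avoids the collisions a
  greedy best-match pairing can produce.  Whether alignment should target
  a fixed reference or a running consensus was open; the fixed-reference
  convention is simpler and label-permutation invariant in the final gene
  sets, which the tests assert.
* **DTB ties**: an exact tie of the top two memberships has gap 0 — the
  gene is unassigned for any δ > 0 and joins the lowest-indexed tied
  cluster at δ = 0.  For K = 1 the runner-up membership is defined as 0.
  The gap comparison uses an absolute tolerance of 1e-9 because CoPaM
  entries are float sums of partition weights.
* **k-means** uses a deterministic maximin initialisation (first centre:
  largest-norm profile; then farthest-point) and a hand-run Lloyd loop so
  that an emptied cluster keeps its last centroid and yields an empty row
  — fixed K is required downstream, so empty clusters must be legal.
* **SOM** is a 1-D chain of K nodes (node count = cluster count exactly),
  trained in *batch* mode for 200 epochs with a Gaussian neighbourhood
  shrinking linearly from K/2 to 0.5; the seed randomises only the node
  initialisation.  Batch updates are order-independent, making runs exactly
  reproducible, and vectorise over all genes at once.
* **Quantile normalisation** averages tied values over the rank-means they
  span.  With ties, a second application is not an exact fixed point
  (columns with different tie patterns leave pass one with different
  multisets); on tie-free data — the generic case for measured intensities
  — the transform is exactly idempotent, and the property tests check it
  there.
* **Missing values**: a gene survives filtering iff its per-dataset
  missing counts are within the per-dataset allowances everywhere;
  survivors' residual gaps are imputed with the gene's observed mean in
  that dataset, which is neutral under the zero-mean standardisation that
  follows.
* **M-N scaling** is computed once on the full initial scatter and reused
  across selection iterations, so pick distances are comparable and
  non-decreasing; per-iteration rescaling would break that monotone
  profile.  A degenerate (constant) axis is set to its ideal coordinate.
  Natural log is used for N; the base is absorbed by min-max scaling.
  Distance ties break by larger N, then smaller K, then pool order.
* **Binomial tail** p-values are evaluated by log-sum-exp over the log
  pmf, keeping deep tails (≈ e⁻³⁴⁰ for the ideal 75-gene cluster in a
  7000-gene genome) exact in log space; the scaled p-value is computed
  from the log directly and clipped to [0, 1] with a logged warning.
* **FPR** is the in-cluster rate (N − n)/N, bounded [0, 1], rather than
  (N − n)/(M − m); empty clusters map to the worst corner (FPR 1, scaled
  p 0, distance √2) so they can never win a comparison.
* **Method comparison** keeps, per method, clusters with ≥ 1 true
  positive, retains the closest ⌈half⌉ by corner distance, rank-pairs the
  two retained lists after ascending sort (truncating to the shorter), and
  reports the mean, sample sd and paired-t p-value of the signed
  differences.  The pairing rule for unequal counts is a convention of
  this package.
* **Seeds**: one master seed; per-(dataset, method, K) sub-seeds derive
  deterministically from it via a CRC of the dataset id, so a type A run
  over all datasets and a type B run over the split reuse identical
  partitions (a shared `PartitionProvider` memoises them, and one Ward
  merge tree per dataset is re-cut for every K).

## Problem sizes in the checks

The bundled property and invariant tests run on small planted collections
(200–300 genes) where every structural claim is exact.  The end-to-end
recovery check and the reproduction script use full-size 1200-gene
six-dataset collections with the default grids — 935 type A and 10,285
type B records per run — over ten seeds, clean and noise-injected, plus
the three single-method comparator sweeps of 2,610 clusters each
(K ∈ {4, 8, 12, 16, 20, 25, 50, 75, 100, 125} × 6 datasets).  Larger
genomes (up to 7000) run with the same code paths and are exercised only
in the noise-magnitude law-of-large-numbers test.

## Known limitations

* Only the difference-threshold binarisation is implemented; other
  binarisation rules for the consensus matrix exist but are not used by
  any analysis here.
* Two-channel datasets are assumed already log-ratio normalised upstream;
  within-array (print-tip loess) normalisation needs array geometry a
  plain matrix does not carry, so the package only centres such data.
* No automatic stopping rule for iterative selection and no
  multiple-testing correction across pooled clusters' p-values — both are
  deliberate scope choices, not oversights.
* The paired comparison's rank-pairing is one of several defensible
  conventions for unequal pool sizes; μ is insensitive to it, the t-test
  p-value less so.
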