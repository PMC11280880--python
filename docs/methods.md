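# Methods

## Pipeline model and assumptions

`harssl` classifies fixed-length windows ("episodes") of tri-axial
accelerometer data by an iteratively retrained cluster model.  The working
assumptions are:

* activity regimes are separable in a low-dimensional feature space built
  from per-axis signal variability (coefficient of variation) and movement
  frequency (mean-crossing count);
* a very small fraction of episodes can be labelled reliably (because their
  feature values are extreme, or because an external oracle — e.g. a user
  prompt — supplies the label), and these sparse labels are sufficient to
  name clusters;
* the class set is fixed for a run and shared by pools, model and metrics.

The engine is an online loop: episodes arrive one at a time, are classified
with the model that existed at arrival, and are pooled; retraining replaces
the whole cluster model rather than updating it incrementally.

## Preprocessing

* **Normalisation** (default `per_sample_l2`): each 3-vector sample is
  divided by its Euclidean norm, which bounds every component in [−1, +1]
  exactly and makes the features scale-free.  Zero-norm samples map to the
  zero vector.  `per_axis_maxabs` (each axis divided by its max absolute
  value) is available because the two conventions give different feature
  and PCA geometry.
* **Windowing**: 40 samples at 20 Hz (2 s), non-overlapping by default;
  both window length and stride are configurable.  A window's ground-truth
  label is the majority of its per-sample labels; ties leave the episode
  unlabeled and it is then excluded from accuracy denominators.
* **Coefficient of variation** uses the population (n-denominator) standard
  deviation over |mean|; it is defined as 0 when |mean| < 1e−8 or
  sd < 1e−8.  The zero-mean guard matters in practice: ℓ₂-normalised
  oscillation axes can have means arbitrarily close to zero, where σ/μ
  would explode.
* **Mean crossings** counts strict sign changes of consecutive residuals
  about the axis mean; samples exactly at the mean never count as crossing
  endpoints, and an axis with sd < 1e−8 reports 0 ("no significant
  movement").  Both choices make the count deterministic and affine-
  invariant.
* **PCA**: top 3 components of the mean-centred 6-feature matrix, signs
  fixed so the largest-magnitude loading of each component is positive.
  Fitting requires ≥ 4 vectors spanning ≥ 3 directions.  By default PCA is
  refit on the current Spool at every training cycle (consistent with a
  fully on-device iterative system that owns no global statistics); a
  fit-once mode exists for comparison.

## The SSL engine

Key parameters (defaults in parentheses):

| parameter | meaning | default |
|---|---|---|
| `alpha` | pre-labelling budget, % of incoming episodes | 10 |
| `n_clusters` (Nc) | model size | 20 |
| `train_every` (Ne) | retraining interval, episodes | 100 |
| `clustering_method` | kmeans / gmm_spherical / gmm_diag / gmm_full | kmeans |
| `labelling_strategy` | population / distance | distance |
| `prelabel_mode` | threshold / oracle | oracle |
| `use_pca` | cluster in 3-D PCA space | on |

Ne = 100 is a deliberate default for desk-scale streams: frequent enough to
show the convergence curve, infrequent enough that k-means cost stays
negligible.

Design choices made where the design was genuinely open:

* **Pre-labelling**: the notion of "extreme feature values beyond a
  threshold" is detector-specific, so two modes are shipped.  Threshold
  mode takes per-class inclusive feature-bound predicates (defaults
  derivable from the quantiles of a calibration stream:
  all-below-10th-percentile → sedentary, all-above-90th → active, a narrow
  mid band → moderately active).  Oracle mode pre-labels a seeded random
  α-fraction with ground truth and is used for all quantitative
  experiments, because it controls the labelling budget exactly and
  decouples it from the detector.
* **Pre-labelled episodes are excluded from the clustering fit** — they
  live in LSpool and are used only to label clusters (assigned to clusters
  by nearest representative for the population count).  Training and
  prediction operate on the unlabeled pool.
* **Distances** are Euclidean in the active feature space (PCA space when
  enabled).  Cluster representatives are k-means centroids or GMM component
  means.  All ties (nearest cluster, nearest pre-labelled episode) break to
  the lowest index, so runs are exactly reproducible.
* **Prediction timing**: an arriving episode is classified with the
  pre-existing model, then pooled; any retraining it triggers happens
  after.  Per-cycle metrics, by contrast, re-classify the whole pool with
  the fresh model (pool-cumulative curves) — this is what makes the
  distance variant's classification rate exactly 100% from the first cycle
  onward.
* **Training guard**: retraining is skipped (not an error) until the
  unlabeled pool holds at least Nc points.
* **Numerics**: k-means uses 10 seeded restarts (best inertia); GMMs use
  seeded EM with covariance floor 1e−6.  A failed fit is retried up to 3
  times with fresh seeded initialisations.  All randomness (oracle
  pre-labelling, per-cycle training seeds) derives from one
  `random_seed` via a `SeedSequence`, so identical (data, config, seed)
  gives identical predictions.
* **Pool growth** is unbounded by default — memory accounting therefore
  grows linearly with the stream, which is the method's main practical
  limitation.  An optional `max_pool_size` cap (oldest-first eviction) is
  provided as an extension but is off by default.

## Metrics

Per cycle, over all ground-truth episodes seen so far: TP_c = recall of
class c among classified episodes; FP_c = fraction of classified
other-class episodes predicted c; Acc = correct / classified; λ =
classified / total (all ×100).  Unclassified episodes appear only in λ's
denominator; if nothing is classified, TP/FP/Acc are NaN sentinels and
λ = 0.  Acc is by construction the TP_c weighted by classified class
prevalence, and the k × (k+1) confusion table is emitted so alternative
denominator conventions can be recomputed.  Memory is reported as a
deterministic byte-accounting of pooled float64 features plus model arrays
— not OS-resident memory, which is hardware- and runtime-dependent (an
opt-in `os_memory_probe` exists but is never used in tests).

## Synthetic data

The generator emulates a wrist accelerometer at 20 Hz with three regimes:
sedentary (gravity baseline + 0.03 g postural drift at 0.3 Hz + 0.0015 g
noise), moderately active (walking-like 0.35 g oscillation at 1.7 Hz),
active (jogging-like 0.9 g oscillation at 2.8 Hz with a 0.3 g first
harmonic).  Episodes get independent random phases and arrive in blocked,
interleaved or randomly shuffled order (random by default, matching the
streaming setting).  The defaults were chosen so the per-class (cov, mcr)
distributions are separable but overlapping; `SignalSpec.interpolated(s)`
shrinks all class differences toward their mean, driving the problem to
chance level at s = 0.

What the generator does **not** emulate: subject-to-subject variability,
sensor drift/bias, transitions within an episode, gait irregularity, or
non-stationary class mixtures.  Passing tests on synthetic streams
therefore demonstrate the correctness and the structural properties of the
pipeline (labelling rules, classification-rate guarantees, parameter
trends), not field accuracy on real recordings — for those, feed WISDM-
format data through `harssl run --format wisdm`.

A feature-space blob generator (`generate_blobs`) exercises the engine in
isolation from preprocessing.

## Problem sizes

Default experiment sizes are desk-scale by design: synthetic streams of
200–1000 episodes per class, trend sweeps averaged over 10 engine seeds,
and 10 repetitions per sweep cell by default (`--runs` overrides).  All
reported numbers in the README were produced by the code as shown.

## Known limitations

* Unbounded pools make time/memory grow with the stream; no convergence
  detection or learning stop.
* No concept-drift handling; a changed activity profile requires the pool
  to dilute the old regime.
* No incremental PCA or incremental clustering; every cycle refits from
  scratch.
* The threshold pre-labeller is only as good as its predicates; episodes
  satisfying no predicate are never pre-labelled, so α is an upper bound
  realised exactly only in oracle mode.
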