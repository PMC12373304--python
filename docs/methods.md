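# Methods

## Problem setting

The unit of analysis is the *pre-AOM period*: the 365 days preceding the
start of an antiobesity-medication treatment session. The goal is an
unsupervised representation of each period — built from sparse, irregular
lab/vital measurements and binary CCS diagnosis categories — that clusters
into clinically coherent phenotypes. All dates are integer day offsets from
a fixed epoch; intervals are closed on both ends unless stated.

## Cohort construction

**Exposure filtering.** Off-label weight-management ingredients are often
prescribed briefly for unrelated indications. An off-label record shorter
than 30 days is removed unless another record of the same patient shares at
least one ingredient and its span comes within 30 days of the record's
span. Records of 30 days or longer always pass.

**Session building.** Records of a patient, sorted by start day, are merged
greedily into sessions. The open session's reference state is its
ingredient union, its start day, and the latest end among members. A
candidate joins iff

1. its ingredients equal the union and `start − session_end ≤ 40` d, or
2. its ingredients are a *proper subset* of the union, its length is ≤40 d,
   and the gap is ≤40 d, or
3. it adds at least one new ingredient, starts within 40 d of the session's
   start, and is ≤40 d long.

Overlapping or abutting records (gap ≤ 0) always satisfy the gap condition.
Two readings were genuinely open: whether a candidate is compared against
the previous *record* or the whole session state (we use session state —
the union and latest end — because a session is defined by its cumulative
regimen), and whether a subset record can extend the session's end (it
can; the end is the max of member ends). The exhaustive oracle test in the
suite pins the chosen semantics.

**Selection and periods.** Sessions with exposure length ≥112 days
(end − start + 1) are kept; a `strict_gt` flag switches to >112. Each kept
session yields one period `[start−365, start)` with index day `start−4`.

**Control matching.** Greedy 1:1 matching of case periods to normal-BMI
candidates: identical gender, age within 1 year, anchor dates within 365
days. Cases are visited in seeded random order and take the eligible unused
candidate minimizing (|age diff|, |date diff|). Greedy matching (not
optimal bipartite) is deliberate: it is reproducible, fast, and the
matched count is the only quantity consumed downstream.

## Featurization

The sampling grid has 13 points `t_k = start − 5 − 30k`, k = 0…12, each
with a half-open look-back window `(t_k−30, t_k]`, so adjacent windows
never double-count a day and the newest window spans days 35→5 before
initiation.

- **Measurements** are z-scored with statistics fitted on the training fold
  only, over window-aggregated cells (multiple observations in one window
  are averaged — a symmetric, outlier-robust choice). Zero-variance
  features are dropped with a warning.
- **CCS channels** are binary any-diagnosis-in-window indicators, treated
  as always observed (absence is an observed 0), so decay imputation acts
  only on measurement channels.
- **Delta** is the time since the feature was last observed, scaled by the
  30-day spacing: 0 at an observed step and at the cold start, otherwise
  the previous delta plus 30 days. The carry-forward value starts at 0 (the
  normalized training mean) at the window edge; events before the window do
  not seed it — the window is the unit of analysis and the cold start makes
  periods comparable.
- **Data quality** of a period is the mean over the 13 points of the
  fraction of measurement channels observed; quartiles are computed on the
  current run's case population, never frozen constants.
- An optional age channel (0–1 scaled, always observed) is supported but
  off by default; the default feature set is measurements + CCS.

## The autoencoder

Missing inputs are imputed as

    x̂ = m·x + (1−m)·(γ·x_last + (1−γ)·x̄),   γ = exp(−max(0, w_γ δ + b_γ))

with per-feature (diagonal) input-decay weights; as δ grows, γ → 0 and the
imputed value decays from the last observation toward the training mean x̄.
Hidden-state decay `h′ = exp(−max(0, W_γh δ + b_γh))·h` is included and on
by default, toggleable. The encoder is a GRU over `[x̂, m, h′]`; the final
hidden state `h_T` is the embedding. The decoder is a plain GRU initialized
with `h_T` and driven by zero inputs (the minimal reading of "passed to a
native GRU"), with a linear per-step readout.

The loss is the squared difference between the reconstruction and the
post-imputation inputs, summed over samples, steps and features. The
targets are **gradient-detached by default**: back-propagating through the
target side lets the model move the imputed targets toward the
reconstruction — a shortcut rather than representation learning. The
non-detached variant is available for studying that instability.

The implementation is pure NumPy with hand-derived reverse-mode gradients
through the unrolled recurrence; the test suite checks every parameter
block against central finite differences (both detach modes, hidden decay
on/off). Input-decay weights initialize small and positive (0.05) so the
rectifier inside γ starts active and receives gradient; gate weights use
uniform ±1/√H. Optimization is Adam (lr 1e-3, batch 64) with early
stopping on a training-loss plateau (patience 10, relative min-delta 1e-4).
Training normalizes the loss by batch size; the reported loss equation is
the plain sum, and the two differ only by a constant factor per batch.

**Cross-validation.** 5 folds, grouped by patient by default so a patient's
multiple periods never straddle a fold's train/test split (period-level
folding is available). Normalizers are refitted per fold on that fold's
training periods; each fold's model embeds every period, flagged
train/test. Seeds for fold assignment, initialization and batch order all
derive from the configured seed; runs are deterministic single-threaded.

**Static baseline.** Each period is collapsed to the last observed value
of each feature in the window (0 + mask where never observed); a dense
tanh-bottleneck autoencoder is trained with squared error summed over
observed cells only, using the temporal model's fold assignments.

## Clustering and profiling

PCA is an eigendecomposition of the training-split embedding covariance;
eigenvectors are applied to train and test embeddings alike. The top 40
PCs are used (all of them when the bottleneck is smaller). Periods below
the median data quality are removed before clustering; ties at the median
are retained. Gaussian mixtures are fitted over K = 1…15 and
{full, diagonal} covariance families with 3 seeded restarts each and
selected by BIC; the full selection trace is always emitted because a
"number of clusters" claim is only as good as its selection curve.
Responsibilities are hardened by max responsibility, ties to the lowest
index. t-SNE (perplexity 30, seeded) is visualization-only and excluded
from all quantitative checks. Cluster profiles — CCS prevalence in the 365
days before the index day, mean z-scored most-recent measurements,
temporal presence rates — are pure functions of (labels, events); heatmap
row/column orders use complete-linkage hierarchical clustering with
Euclidean distance.

## Synthetic data: what it emulates, and what it does not

Each synthetic patient carries a latent phenotype defining per-feature
measurement means (±`separation` z units on a seed-fixed random sign
pattern; default separation 2), optional linear drift per 30-day step
(default 0), and per-CCS prevalences (baseline 0.05 with two marker
categories at 0.70 per phenotype). Observed values add Gaussian noise
(default SD 1 z unit). Measurement presence is Bernoulli per 30-day window
(default 0.5 per feature) with a ×2 presence spike (capped at probability
1) in the window nearest treatment start, mimicking the care-
intensification bump real pre-treatment data show in days −35 to −5.
Exposure records exercise every session rule at configurable rates; break
records that open a second session are kept under the 112-day threshold so
the default benchmark yields exactly one qualifying period per patient.
Latent labels are returned separately and never written into feature
tables.

The generator does *not* emulate: informative missingness beyond the
pre-index spike (the true mechanism in clinical data is unknown), visit
structure, unit heterogeneity, coding drift over calendar time, or
correlated measurement panels. Passing the planted-recovery benchmark
therefore shows the pipeline recovers cluster structure under realistic
sparsity and noise — not that real pre-treatment data contain such
structure.

**Benchmark sizes.** The standard benchmark uses 600 patients, 15
measurement + 10 CCS channels, K=4 phenotypes, bottleneck 16, 30 epochs,
5 folds — sizes chosen so the full pipeline runs in about a minute on one
CPU while leaving every stage non-trivial (≈480 training periods per fold,
≈325 periods after the quality filter). Recovery was verified at three
independent seeds during development; the shipped suite runs one fixed
seed.

## Numerical choices and degenerate inputs

- Sigmoid computed in the numerically stable two-branch form.
- GMM covariance regularization 1e-6; singular fits are thereby handled
  and recorded in the selection trace.
- Zero-variance features: dropped at normalization (threshold 1e-12).
- Fully masked static vectors: excluded from SAE training with a warning.
- Empty clusters: excluded from profiles with a warning.
- `n_patients = 0`: population generation errors unless explicitly allowed
  to return an empty table.
- Tie at quality median: retained. Tie in responsibilities: lowest index.

## Known limitations

- The NumPy trainer is single-threaded and sized for desk-scale data;
  cohorts of 10⁴–10⁵ periods would need a GPU-backed reimplementation of
  the (small, well-specified) model module.
- Greedy matching does not maximize the matched count; a case visited late
  may find its only candidate taken.
- BIC-based K selection on mixtures is consistent but conservative at
  small n; the selection trace, not the single selected K, is the primary
  output.
- ICD→CCS mapping, ingredient concept-ID resolution, and live OMOP
  connectivity are out of scope; inputs are expected as flat tables
  already using CCS categories and ingredient names.
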