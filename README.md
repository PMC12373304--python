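# aomphen

Deep phenotyping of the year *before* antiobesity-medication (AOM)
treatment, from longitudinal EHR data.

Patients who start weight-management drugs are clinically heterogeneous:
diabetic, hypertensive, psychiatric, healthy-but-overweight, and many mixed
presentations. `aomphen` implements an unsupervised pipeline that turns raw
OMOP-style exposure, measurement and diagnosis tables into data-driven
patient phenotypes:

1. **Treatment sessions.** Raw drug-exposure records are merged into
   continuous treatment sessions by a greedy chronological rule set: a
   record joins the open session if it resumes the identical ingredient set
   within a 40-day gap, is a short (≤40 d) continuation with a dropped
   component, or is a short add-on started within 40 days of session onset.
   Short (<30 d) isolated off-label records are removed first, and only
   sessions with medium-to-long exposure (≥112 d) are kept.
2. **Pre-AOM periods.** Each session contributes the 365-day window before
   its start, sampled at 13 points spaced 30 days apart with a 30-day
   look-back (the newest interval covers days −35 to −5; the index date is
   4 days before initiation).
3. **Temporal tensors.** Every period becomes a 13×D array of z-scored
   values `x`, missingness mask `m`, and time-since-last-observation `δ`.
4. **GRU-D autoencoder.** A recurrent encoder imputes each missing input as
   `x̂ = m·x + (1−m)·(γ·x_last + (1−γ)·x̄)` with learned decay
   `γ = exp(−max(0, W_γ δ + b_γ))` — carrying recent observations forward
   and decaying stale ones toward the population mean. The final hidden
   state `h_T` is the period's embedding; a plain GRU decoder reconstructs
   the inputs, trained with squared error under 5-fold, patient-grouped
   cross-validation. A static autoencoder over last-observation vectors
   serves as the atemporal baseline.
5. **Clustering.** Embeddings are projected on train-fold principal
   components; periods in the lower half of data quality (the average
   fraction of observed measurement channels over the 13 points) are
   dropped; a Gaussian mixture model selected by BIC clusters the top PCs,
   and clusters are profiled by CCS diagnosis prevalence, mean z-scored
   most-recent measurements, and temporal presence rates.

A bundled synthetic-EHR generator plants phenotype clusters (cluster-
specific measurement means and diagnosis prevalences, realistic sparsity, a
pre-treatment presence spike) so the entire pipeline is testable end to end
without access to any clinical database.

## Worked example

Run the standard synthetic benchmark — 600 patients, 15 measurement + 10
CCS channels, 4 planted phenotypes at ±2 z-unit separation, 50% per-window
measurement presence, bottleneck 16, 30 epochs:

```bash
aomphen run --out results/demo --seed 1
```

prints

```
periods=600 retained=325 mean planted-label ARI=1.000 cross-fold ARI=1.000
```

meaning: 600 pre-treatment periods were derived (one qualifying session per
patient), 325 survived the median data-quality filter, clustering the
GRU-D embeddings recovered the planted phenotype labels perfectly in every
fold (adjusted Rand index 1.0 against labels the pipeline never saw), and
the five fold-models produced mutually identical clusterings. The written
`report.json` additionally records per-fold training curves, the BIC
selection trace (K=4 chosen in each fold), and silhouette scores showing
the temporal embedding separates the planted labels more cleanly than the
static baseline.

The same stages are available piecewise (`aomphen simulate`, `sessions`,
`periods`, `match`) and as library functions (`aomphen.synth`,
`aomphen.cohort`, `aomphen.featurize`, `aomphen.models`,
`aomphen.cluster`, `aomphen.pipeline`).

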