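# Methods

## The phenotype and its model

The package quantifies cellular DNA-repair capacity from the kinetics of
the gamma-H2AX signal — phosphorylated histone H2AX, which accumulates at
DNA double-strand breaks — after a radiation challenge. Peripheral-blood
mononuclear cells (PBMCs) from each donor are immunophenotyped into seven
subtypes (CD3+, CD4+, CD8a+ and TCRγδ+ T cells, CD19+ B cells, CD56+ NK
cells, CD14+ monocytes), exposed to a fixed gamma-ray dose, and the mean
fluorescence per subtype is read at 1, 2, 3, 6 and 20 hr, with
unirradiated (0-Gy) control tubes read at 2 and 20 hr.

For one donor and subtype the signal is modelled as

    Y(T) = Kprod · D · T · exp(−Kdec · T) + Fres · D · Ω

with dose `D` (Gy), time `T` (hr) and irradiation indicator `Ω`. The three
parameters have direct biological readings:

| parameter | units          | meaning                                        |
|-----------|----------------|------------------------------------------------|
| `Kprod`   | signal/Gy/hr   | initial rate of damage-signal production       |
| `Kdec`    | 1/hr           | initial exponential decay (repair) rate        |
| `Fres`    | signal/Gy      | residual (unrepaired/misrepaired) signal level |

The production term rises linearly and decays exponentially, peaking at
`T* = 1/Kdec`; as `T → ∞` the signal tends to `Fres · D`. Because the
challenge dose is fixed, the dose-scaled residual `Fres·D` is carried as a
single quantity (`fres_scaled`).

### Normalization and fitting

Challenge series are background-corrected against the 0-Gy controls: the
2-hr 0-Gy read is subtracted from the 1, 2, 3 and 6-hr challenge points
and the 20-hr 0-Gy read from the 20-hr point, correcting for drift in the
unirradiated background.

The fit follows a two-step constrained procedure. `Fres·D` is pinned to
the normalized 20-hr value — the assay's design treats the overnight
point as pure residual. `(Kprod, Kdec)` are then fitted by least squares
on a natural-log scale over all five time points, with the pinned
residual term included in the model. Numerical choices:

- **Log clipping.** Model and data are clipped at `ε = 1e−6` before
  taking logs, so noise-driven non-positive normalized values cannot
  break the objective; the number of clipped points is reported in the
  fit diagnostics. A series that is non-positive everywhere is a
  degenerate-fit error.
- **Optimizer.** Deterministic bounded L-BFGS-B from a fixed multi-start
  grid: nine decay rates log-spaced over 0.05–2 /hr, with the production
  rate at each start matched to the 1-hr point. Best objective wins; ties
  go to the smaller `Kdec`. Tight tolerances (`ftol=1e−15`) make refits
  reproducible to ~1e−7.
- **Duplicates.** Two measurements at one (dose, time) are rejected as an
  error — the design has exactly one tube per time point.
- **Negative residuals.** A negative pinned `Fres·D` is retained as a
  data-driven feature value and only flagged.

A self-consistency caveat worth stating explicitly: the model's own 20-hr
mean is `Fres·D` *plus* a production tail `Kprod·D·20·e^(−20·Kdec)`, so
pinning the residual to the 20-hr observation is exact only where repair
is essentially complete overnight (`Kdec·20 ≫ 1`). At the default decay
rates (~0.4 /hr) the tail is a 2–4% effect, far below measurement noise;
parameter-recovery tests that demand exactness draw their decay rates
from the repair-complete regime (`Kdec ∈ [1, 2] /hr`), where recovery is
accurate to ~1e−7.

## The synthetic cohort

No per-donor dataset ships with the package; a seeded generator emulates
the study conditions so every downstream stage is testable:

- 46 age-matched case/control pairs by default (92 donors); ages drawn
  from a bounded normal (mean 55, sd 10, range 30–80 yr), the control's
  age jittered uniformly within the 2-yr matching tolerance.
- Per-subtype baseline kinetics (`Kprod` ≈ 1 signal/Gy/hr, `Kdec` ≈
  0.35–0.45 /hr, `Fres` ≈ 0.45–0.6 signal/Gy) with lognormal
  between-pair dispersion (σ = 0.3). The two members of a pair share
  their latent kinetic parameters, so the planted effect is the only
  systematic case/control difference and noiseless invariants hold
  member-for-member.
- The planted case effect: cases' CD19+ (B-cell) `Fres` is multiplied by
  `1 − case_effect` (default 0.4), matching the direction of interest —
  lower residual damage in cases.
- Measurement noise is multiplicative lognormal on the model mean
  (σ = 0.1), mean-preserving (`exp(N(−σ²/2, σ²))`), reflecting positive,
  right-skewed fluorescence intensities; an additive 0-Gy background
  level (0.2 signal units) is present in every tube and removed by the
  normalization.

What the generator does *not* emulate: the single-cell layer (each
summary value stands for ~10³ cell images; the per-sample summary
statistic is unstated in the assay description), fluorescence spillover
between channels, instrument batch effects, or any age–status
association (pairs are matched, so age carries no signal in synthetic
cohorts — unlike in real case/control data, where age is usually the
strongest demographic predictor). Passing tests therefore demonstrate
the pipeline's statistical machinery, not the biology of any real
cohort.

## Feature screening

Candidate predictors are `Fres·D` and `Kdec` per subtype (14 kinetic
features) plus optional age at blood draw. The screen is a shadow-feature
(Boruta-style) filter: each iteration appends one freshly shuffled
"shadow" copy of every feature, fits a random forest on the augmented
table, and scores a hit for every real feature whose importance exceeds
the best shadow's. Hits over `n_iter = 100` iterations are tested against
the 50:50 null by a two-sided exact binomial test, Bonferroni-corrected
over the real features at α = 0.05: significantly above → confirmed,
below → rejected, else tentative. Tentative features are reported but not
passed downstream.

Importance is permutation importance on each tree's out-of-bag samples
(mean accuracy drop over trees when one feature column is shuffled),
with 100 trees per iteration. Every per-feature random stream is keyed
by the feature's *name*, so decisions are invariant to column order.

**Known limitation (by construction).** The binomial hit test controls
the consistency of hits, not a population-level false-discovery rate. In
a finite sample, a population-null feature that is chance-correlated with
the labels (at n = 200, |r| ≈ 0.15 arises regularly among a handful of
features) is genuinely informative *in that sample* and will beat its
shadows consistently — the screen confirms it, whatever the importance
measure. Label-permutation experiments show a per-dataset false-
confirmation rate of roughly 10–15% under these conditions, well above
the nominal α. Confirmed features from small cohorts warrant external
validation.

## Classification and inference

A random forest (500 trees, √p features per split) predicts case status
from the selected features. Because a 92-donor cohort is small,
the default evaluation is **out-of-bag**: each donor's predicted case
probability averages only the trees whose bootstrap sample excluded that
donor. Resubstitution (`insample`) and stratified k-fold (`kfold`) modes
exist for comparison; resubstitution is optimistic and never the default.
Note one OOB side effect: a feature with no signal yields OOB AUC
slightly *below* 0.5 (the forest memorizes in-bag noise), which is honest
behaviour, not a bug.

Evaluation statistics:

- **ROC/AUC** — threshold sweep; AUC equals the all-pairs concordance
  probability with ties counted ½.
- **Accuracy** — at a fixed 0.5 probability threshold (score ≥ 0.5 →
  case).
- **Bootstrap CIs** — percentile intervals from 10,000 donor resamples;
  resamples that lose a class are redrawn. Matched pairs can be resampled
  as units via `pair_ids` (the matched design enters only the sampling
  scheme, never the forest).
- **DeLong's test** — paired, two-sided, asymptotic-normal comparison of
  correlated AUCs via the structural-components covariance estimator.
  Calibration is verified by simulation (type-I error within [0.03,
  0.07] at α = 0.05, n = 200).
- **Fisher's exact test** — for accuracy contrasts, on the 2×2 table of
  models × (correct, incorrect) counts; a McNemar-style discordant-pair
  table is a reasonable alternative but not the default.
- **Spearman correlation** and the **Mann–Whitney U test** summarize
  single-feature case/control separation; the U test enumerates exactly
  for pooled samples ≤ 12 without ties and otherwise uses the
  tie-corrected normal approximation.

## Pipeline determinism

The pipeline (`simulate → fit → select → classify`) derives one seed per
stage from the global seed by hashing the stage name, so inserting a
stage never perturbs the randomness of the others. Every run writes a
manifest (config echo, stage seeds, SHA-256 checksum per artifact);
re-running a manifest's config reproduces every artifact byte-for-byte.

## Problem sizes used in the test suite

Property tests run at sizes chosen to make their statistical assertions
stable: 50 noiseless triples (vs a refined grid-search oracle), 200 noisy
donors for recovery error, 500 replicates for DeLong calibration and for
bootstrap-CI coverage (binormal scores, n = 100 per cohort, 1,000
resamples per CI), 20 seeded runs for screen behaviour and for the
end-to-end 46-pair cohort comparison. The full suite completes in about
a quarter hour on one CPU.
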