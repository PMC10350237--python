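# drckit

Phenotypic DNA-repair-capacity (DRC) profiling from gamma-H2AX
time-course data, for biostatisticians and radiation biologists working
with challenge-assay case/control studies.

After a fixed gamma-ray challenge (3 Gy by default), the gamma-H2AX
fluorescence signal in each PBMC subtype rises as double-strand breaks
are marked and falls as they are repaired. `drckit` fits, per donor and
per subtype, the kinetic model

    Y(T) = Kprod · D · T · e^(−Kdec·T) + Fres · D · Ω

(`D` dose in Gy, `T` hours post-challenge, `Ω` irradiation indicator),
yielding a production rate `Kprod`, a repair rate `Kdec` and a residual
damage level `Fres·D` pinned to the background-corrected 20-hr signal.
The per-subtype `Fres·D` and `Kdec` values then feed a shadow-feature
(Boruta-style) relevance screen and an out-of-bag-evaluated random
forest that classifies case/control status, with ROC/AUC, bootstrap
confidence intervals, DeLong's paired AUC test and Fisher's exact
accuracy comparison. A seeded generator produces matched case/control
cohorts with a planted reduction of B-cell (CD19+) residual damage, so
the whole chain runs and is tested without any external data; measured
cohorts in the same CSV schema drop in unchanged.

## Worked example

```python
from drckit import (
    CohortConfig, generate_cohort, fit_cohort,
    build_feature_table, boruta_select, CaseControlForest, ForestConfig,
)
from drckit.selection import split_features

# 1. a 46-pair matched cohort with reduced case B-cell residual damage
donors, points = generate_cohort(CohortConfig(n_pairs=46, seed=3))

# 2. kinetics per donor x subtype: 92 donors x 7 subtypes = 644 fits
params, skipped = fit_cohort(donors, points)

# 3. screen the 14 kinetic candidates against their shuffled shadows
table, _ = build_feature_table(params, donors)
X, y = split_features(table)
screen = boruta_select(X.drop(columns=["age_at_draw"]), y, n_iter=100, seed=3)
print(screen.confirmed)

# 4. classify case status from the confirmed feature, evaluated out-of-bag
res = CaseControlForest(X[screen.confirmed], y, ForestConfig(seed=3)).fit()
print(res.summary())
print("95% CI for AUC:", res.auc_ci(seed=3))
```

Output:

```
['fres_scaled CD19+']
Case/control random forest
==========================
features:  fres_scaled CD19+
donors:    92 (46 cases)
evaluation: oob
AUC:       0.851
accuracy:  0.761 (threshold 0.5)
95% CI for AUC: (0.7607194435547964, 0.930504023060014)
```

The screen singles out the planted predictor — residual B-cell damage
(`Fres·D` in CD19+ cells) — out of the 14 kinetic candidates, and a
forest using it alone separates cases from controls with an
out-of-bag AUC of 0.85 [0.76–0.93]: cases carry systematically *lower*
residual damage, so a single subtype-specific repair parameter carries
most of the case/control signal in this cohort.

The same analysis runs from the shell:

```sh
drckit all --outdir run1 --seed 3          # simulate -> fit -> select -> classify
drckit report --run-dir run1 --plot        # summary table + ROC curves
```

Each run directory contains the cohort CSVs, `repair_params.csv`,
`feature_table.csv`, `selection_report.json`, `classifier_report.json`,
`roc_points.csv` and a `manifest.json` with stage seeds and artifact
checksums; the same config and seed reproduce every artifact
byte-for-byte.

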