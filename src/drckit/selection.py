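"""Shadow-feature (Boruta-style) all-relevant predictor screening.

Candidate predictors of case/control status are the per-subtype repair
parameters Fres*D and Kdec (14 kinetic features over seven PBMC
subtypes), optionally joined by age at blood draw.  Each iteration
re-creates one shuffled "shadow" copy of every feature, fits a random
forest on the augmented table, and scores a hit for every real feature
whose importance beats the best shadow.  Hit counts are then tested
against the 50:50 null with an exact binomial test, Bonferroni-corrected
over the real features: significantly above chance -> confirmed,
significantly below -> rejected, otherwise tentative.

Importance is permutation importance evaluated on each tree's
out-of-bag samples (mean accuracy drop when one feature is shuffled).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "build_feature_table",
    "make_shadow",
    "oob_permutation_importance",
    "boruta_select",
    "SelectionReport",
]

SHADOW_PREFIX = "shadow_"

#: Kinetic parameters carried into the feature table, per subtype.
FEATURE_PARAMS = ("fres_scaled", "kdec")


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary labelled parts.

    Keyed by content (not position in some global stream) so that, e.g.,
    each feature's shadow shuffle is reproducible regardless of column
    order.
    """
    text = "\x1f".join(str(p) for p in parts)
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF


def build_feature_table(
    params: pd.DataFrame,
    donors: Sequence,
    include_age: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Pivot a fitted-parameter table into donors x predictors.

    Columns are ``fres_scaled <subtype>`` and ``kdec <subtype>`` (14
    kinetic features for the full panel), plus ``age_at_draw`` when
    requested, plus the ``status`` label.  Donors missing any fitted
    value are excluded and returned in the second element — feature
    tables downstream must be complete.
    """
    meta = {
        d.donor_id: (float(d.age_at_draw), int(d.status)) for d in donors
    }
    wide = params.pivot_table(
        index="donor_id",
        columns="subtype",
        values=list(FEATURE_PARAMS),
        aggfunc="first",
    )
    wide.columns = [f"{param} {sub}" for param, sub in wide.columns]
    wide = wide[sorted(wide.columns)]

    excluded = sorted(
        set(meta) - set(wide.dropna().index)
    )
    wide = wide.dropna()
    wide = wide.loc[[d for d in meta if d in wide.index]]
    if include_age:
        wide["age_at_draw"] = [meta[d][0] for d in wide.index]
    wide["status"] = [meta[d][1] for d in wide.index]
    return wide, excluded


def split_features(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split a feature table into (X, y) on the ``status`` column."""
    if "status" not in table.columns:
        raise ValueError("feature table must carry a 'status' column")
    X = table.drop(columns=["status"])
    if X.isna().any().any():
        raise ValueError("feature table must have no missing values")
    return X, table["status"].astype(int)


def make_shadow(X: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Append one shuffled shadow copy of every feature column.

    Each shadow is a label-independent permutation of its source column;
    a fresh permutation is drawn on every call.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    out = X.copy()
    for col in X.columns:
        out[SHADOW_PREFIX + col] = rng.permutation(X[col].to_numpy())
    return out


def oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-feature permutation importance on each tree's out-of-bag samples.

    For every tree, the accuracy on its out-of-bag rows is compared with
    the accuracy after shuffling one feature among those rows; the
    importance of the feature is the mean accuracy drop over trees.
    """
    n, p = X.shape
    drops = np.zeros(p)
    n_trees_used = 0
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        if not oob.any():
            continue
        n_trees_used += 1
        X_oob = X[oob]
        y_oob = y[oob]
        k = X_oob.shape[0]
        # one batched predict per tree: base block + one permuted block per feature
        stacked = np.tile(X_oob, (p + 1, 1))
        for j in range(p):
            block = slice((j + 1) * k, (j + 2) * k)
            stacked[block, j] = rng.permutation(X_oob[:, j])
        correct = (tree.predict(stacked) == np.tile(y_oob, p + 1)).reshape(p + 1, k)
        accs = correct.mean(axis=1)
        drops += accs[0] - accs[1:]
    if n_trees_used == 0:
        raise RuntimeError("no tree had out-of-bag samples; increase n_trees")
    return drops / n_trees_used


@dataclass
class SelectionReport:
    """Outcome of the shadow-feature screen."""

    decisions: dict[str, str]  # feature -> confirmed | rejected | tentative
    hits: dict[str, int]
    n_iter: int
    pvalues_adjusted: dict[str, float]
    alpha: float
    seed: int

    @property
    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "confirmed"]

    @property
    def rejected(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "rejected"]

    @property
    def tentative(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "tentative"]

    def to_dict(self) -> dict:
        return {
            "decisions": self.decisions,
            "hits": self.hits,
            "n_iter": self.n_iter,
            "pvalues_adjusted": self.pvalues_adjusted,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = ["Shadow-feature selection", "========================"]
        lines.append(f"iterations: {self.n_iter}, alpha: {self.alpha} (Bonferroni)")
        width = max(len(f) for f in self.decisions)
        for f in sorted(
            self.decisions, key=lambda f: (-self.hits[f], f)
        ):
            lines.append(
                f"{f:<{width}}  {self.decisions[f]:<9}  "
                f"hits {self.hits[f]:>4}/{self.n_iter}  "
                f"p_adj={self.pvalues_adjusted[f]:.3g}"
            )
        return "\n".join(lines)


def boruta_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_trees: int = 100,
) -> SelectionReport:
    """Screen features against their shuffled shadows.

    Deterministic given ``seed``; decisions do not depend on the column
    order of ``X`` (columns are canonicalized by name, and every
    per-feature random stream is keyed by the feature's name).
    """
    if n_iter < 10:
        raise ValueError(f"n_iter must be >= 10, got {n_iter}")
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels must contain both classes")
    features = sorted(X.columns)
    X = X[features]

    hits = {f: 0 for f in features}
    for it in range(n_iter):
        aug = X.copy()
        for f in features:
            aug[SHADOW_PREFIX + f] = np.random.default_rng(
                stable_seed(seed, "shadow", it, f)
            ).permutation(X[f].to_numpy())
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=stable_seed(seed, "forest", it),
            n_jobs=1,
        )
        aug_values = aug.to_numpy(dtype=float)
        forest.fit(aug_values, y)
        imp_rng = np.random.default_rng(stable_seed(seed, "importance", it))
        imp = oob_permutation_importance(forest, aug_values, y, imp_rng)
        named = dict(zip(aug.columns, imp))
        shadow_max = max(named[SHADOW_PREFIX + f] for f in features)
        for f in features:
            if named[f] > shadow_max:
                hits[f] += 1

    decisions: dict[str, str] = {}
    p_adj: dict[str, float] = {}
    n_features = len(features)
    for f in features:
        p = binomtest(hits[f], n_iter, 0.5, alternative="two-sided").pvalue
        p_adj[f] = min(1.0, p * n_features)
        if p_adj[f] < alpha and hits[f] > n_iter / 2:
            decisions[f] = "confirmed"
        elif p_adj[f] < alpha and hits[f] < n_iter / 2:
            decisions[f] = "rejected"
        else:
            decisions[f] = "tentative"
    return SelectionReport(
        decisions=decisions,
        hits=hits,
        n_iter=n_iter,
        pvalues_adjusted=p_adj,
        alpha=alpha,
        seed=seed,
    )
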