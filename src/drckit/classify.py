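"""Case/control classification and its evaluation statistics.

A random forest predicts case status from the selected repair-kinetic
features (plus, optionally, age at blood draw).  By default each donor's
predicted case probability is evaluated out-of-bag: it averages only the
trees whose bootstrap sample excluded that donor, which keeps the
reported discrimination honest at small cohort sizes without a held-out
set.  Evaluation statistics follow standard case/control practice:
ROC/AUC, percentile-bootstrap confidence intervals, DeLong's paired test
for correlated AUCs, Fisher's exact test for accuracy contrasts, plus
Spearman correlation and the Mann-Whitney U test for single-feature
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict

__all__ = [
    "ForestConfig",
    "rf_fit_predict",
    "roc_auc",
    "accuracy",
    "bootstrap_ci",
    "delong_test",
    "fisher_exact_2x2",
    "spearman",
    "mann_whitney_u",
    "compare_models",
    "ComparisonReport",
    "CaseControlForest",
    "CaseControlForestResults",
]

VALID_MODES = ("oob", "kfold", "insample")


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest settings and evaluation mode.

    ``mode='oob'`` (default) scores every donor with the trees that did
    not see them; ``'kfold'`` uses stratified cross-validated
    probabilities; ``'insample'`` is the resubstitution estimate and is
    optimistic — available for comparison only.
    """

    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    bootstrap_fraction: float = 1.0
    seed: int = 0
    mode: str = "oob"
    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_trees < 50:
            raise ValueError(f"n_trees must be >= 50, got {self.n_trees}")
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")

    def with_(self, **kwargs) -> "ForestConfig":
        return replace(self, **kwargs)


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    yv = np.asarray(y).astype(int)
    if np.unique(yv).size < 2:
        raise ValueError("labels must contain both classes")
    counts = np.bincount(yv)
    if counts.min() < 2:
        raise ValueError("need at least 2 donors per class")
    return Xv, yv


def _make_forest(config: ForestConfig) -> RandomForestClassifier:
    max_samples = (
        None if config.bootstrap_fraction == 1.0 else config.bootstrap_fraction
    )
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        bootstrap=True,
        max_samples=max_samples,
        oob_score=config.mode == "oob",
        random_state=config.seed,
        n_jobs=1,
    )


def rf_fit_predict(X, y, config: ForestConfig | None = None) -> np.ndarray:
    """Per-donor predicted case probability under the configured evaluation.

    Deterministic given the config seed.  In ``oob`` mode a donor that
    was in-bag for every tree has no honest prediction; this raises with
    advice to grow more trees rather than silently falling back.
    """
    config = config or ForestConfig()
    Xv, yv = _as_xy(X, y)
    if config.mode == "oob":
        forest = _make_forest(config).fit(Xv, yv)
        probs = forest.oob_decision_function_[:, list(forest.classes_).index(1)]
        if np.isnan(probs).any():
            n_bad = int(np.isnan(probs).sum())
            raise RuntimeError(
                f"{n_bad} donor(s) were never out-of-bag; "
                f"increase n_trees (currently {config.n_trees})"
            )
        return probs
    if config.mode == "kfold":
        cv = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        forest = _make_forest(config)
        probs = cross_val_predict(forest, Xv, yv, cv=cv, method="predict_proba")
        return probs[:, 1]
    forest = _make_forest(config).fit(Xv, yv)
    return forest.predict_proba(Xv)[:, list(forest.classes_).index(1)]


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    l = np.asarray(labels).astype(int)
    if s.shape != l.shape:
        raise ValueError("scores and labels must have the same length")
    if np.unique(l).size < 2:
        raise ValueError("labels must contain both classes")
    return s, l


def auc_score(scores, labels) -> float:
    """All-pairs concordance AUC (ties count 1/2), via midranks."""
    s, l = _check_scores_labels(scores, labels)
    n1 = int(l.sum())
    n0 = l.size - n1
    ranks = stats.rankdata(s)
    return float((ranks[l == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve by threshold sweep plus the concordance AUC.

    The returned frame has columns fpr, tpr, threshold; the curve starts
    at (0, 0) and ends at (1, 1) with both coordinates non-decreasing.
    """
    s, l = _check_scores_labels(scores, labels)
    fpr, tpr, thresholds = roc_curve(l, s)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return roc, auc_score(s, l)


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Fraction of donors whose thresholded score (>= threshold) matches the label."""
    s, l = _check_scores_labels(scores, labels)
    return float(np.mean((s >= threshold).astype(int) == l))


def bootstrap_ci(
    scores,
    labels,
    metric: Callable[[np.ndarray, np.ndarray], float] = auc_score,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    pair_ids: Sequence | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for a score/label metric.

    Donors are resampled with replacement; resamples that lose a class
    are redrawn.  With ``pair_ids`` given, matched pairs are resampled
    as units instead of individual donors.
    """
    if n_boot < 1000:
        raise ValueError(f"n_boot must be >= 1000, got {n_boot}")
    s, l = _check_scores_labels(scores, labels)
    rng = np.random.default_rng(seed)
    n = s.size
    values = np.empty(n_boot)

    if pair_ids is not None:
        pair_ids = np.asarray(pair_ids)
        unique_pairs = np.unique(pair_ids)
        members = {p: np.flatnonzero(pair_ids == p) for p in unique_pairs}

    for b in range(n_boot):
        for _attempt in range(1000):
            if pair_ids is None:
                idx = rng.integers(0, n, size=n)
            else:
                chosen = rng.choice(unique_pairs, size=unique_pairs.size, replace=True)
                idx = np.concatenate([members[p] for p in chosen])
            lb = l[idx]
            if lb.min() != lb.max():
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        values[b] = metric(s[idx], lb)
    if not np.isfinite(values).all():
        raise RuntimeError("metric was undefined on some bootstrap resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (cases) and V01 (controls) and the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01, float(v10.mean())


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong's paired two-sided test for the difference of correlated AUCs.

    Both score vectors must be on the same donors.  Returns
    (auc_a, auc_b, p); the variance of the AUC difference comes from the
    structural-components covariance estimator and the p-value from the
    asymptotic normal reference.
    """
    sa, l = _check_scores_labels(scores_a, labels)
    sb, _ = _check_scores_labels(scores_b, labels)
    v10a, v01a, auc_a = _delong_placements(sa, l)
    v10b, v01b, auc_b = _delong_placements(sb, l)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return auc_a, auc_b, 1.0
        raise RuntimeError(
            "zero variance of the AUC difference with unequal AUCs"
        )
    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, p


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums the hypergeometric probabilities (margins fixed) of all tables
    at most as probable as the observed one.
    """
    cells = (a, b, c, d)
    if any(x < 0 or int(x) != x for x in cells):
        raise ValueError(f"cell counts must be non-negative integers, got {cells}")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    r = stats.spearmanr(x, y).statistic
    return float(r)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (statistic for x) with a two-sided p-value.

    Exact enumeration when the pooled sample is small (<= 12) with no
    ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonReport:
    """Head-to-head comparison of two classifiers on the same donors."""

    label_a: str
    label_b: str
    auc_a: float
    auc_b: float
    delong_p: float
    acc_a: float
    acc_b: float
    fisher_p: float

    def to_dict(self) -> dict:
        return {
            "model_a": self.label_a,
            "model_b": self.label_b,
            "auc_a": self.auc_a,
            "auc_b": self.auc_b,
            "delong_p": self.delong_p,
            "accuracy_a": self.acc_a,
            "accuracy_b": self.acc_b,
            "fisher_p": self.fisher_p,
        }

    def summary(self) -> str:
        return (
            f"{self.label_a} vs {self.label_b}\n"
            f"  AUC:      {self.auc_a:.3f} vs {self.auc_b:.3f} "
            f"(DeLong p = {self.delong_p:.3g})\n"
            f"  accuracy: {self.acc_a:.3f} vs {self.acc_b:.3f} "
            f"(Fisher p = {self.fisher_p:.3g})"
        )


def compare_models(
    features_a,
    features_b,
    labels,
    config: ForestConfig | None = None,
    label_a: str = "model_a",
    label_b: str = "model_b",
    threshold: float = 0.5,
) -> ComparisonReport:
    """Fit two forests with the same seed stream and compare them.

    AUCs are compared with DeLong's paired test on the per-donor scores;
    accuracies at the probability threshold with Fisher's exact test on
    the models x (correct, incorrect) 2x2 table.
    """
    config = config or ForestConfig()
    scores_a = rf_fit_predict(features_a, labels, config)
    scores_b = rf_fit_predict(features_b, labels, config)
    l = np.asarray(labels).astype(int)
    auc_a, auc_b, delong_p = delong_test(scores_a, scores_b, l)
    acc_a = accuracy(scores_a, l, threshold)
    acc_b = accuracy(scores_b, l, threshold)
    n = l.size
    ca, cb = round(acc_a * n), round(acc_b * n)
    fisher_p = fisher_exact_2x2(ca, n - ca, cb, n - cb)
    return ComparisonReport(
        label_a=label_a,
        label_b=label_b,
        auc_a=auc_a,
        auc_b=auc_b,
        delong_p=delong_p,
        acc_a=acc_a,
        acc_b=acc_b,
        fisher_p=fisher_p,
    )


class CaseControlForest:
    """Random-forest case/control model over a feature table.

    Thin modelling wrapper: construct from features and labels (or a
    feature table with a ``status`` column via :meth:`from_table`),
    call :meth:`fit`, and read discrimination statistics off the
    results object.
    """

    def __init__(self, X, y, config: ForestConfig | None = None):
        self.X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        self.y = np.asarray(y).astype(int)
        self.config = config or ForestConfig()

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        features: Sequence[str] | None = None,
        config: ForestConfig | None = None,
    ) -> "CaseControlForest":
        y = table["status"].astype(int)
        X = table.drop(columns=["status"])
        if features is not None:
            X = X[list(features)]
        return cls(X, y, config)

    def fit(self) -> "CaseControlForestResults":
        scores = rf_fit_predict(self.X, self.y, self.config)
        return CaseControlForestResults(self, scores)


@dataclass
class CaseControlForestResults:
    """Per-donor case probabilities plus discrimination statistics."""

    model: CaseControlForest
    scores: np.ndarray
    auc: float = field(init=False)
    acc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc = auc_score(self.scores, self.model.y)
        self.acc = accuracy(self.scores, self.model.y)

    def roc(self) -> pd.DataFrame:
        roc, _ = roc_auc(self.scores, self.model.y)
        return roc

    def auc_ci(self, n_boot: int = 10_000, seed: int = 0) -> tuple[float, float]:
        return bootstrap_ci(
            self.scores, self.model.y, auc_score, n_boot=n_boot, seed=seed
        )

    def accuracy_ci(self, n_boot: int = 10_000, seed: int = 0) -> tuple[float, float]:
        return bootstrap_ci(
            self.scores, self.model.y, accuracy, n_boot=n_boot, seed=seed
        )

    def to_dict(self, n_boot: int = 10_000, seed: int = 0) -> dict:
        auc_lo, auc_hi = self.auc_ci(n_boot=n_boot, seed=seed)
        acc_lo, acc_hi = self.accuracy_ci(n_boot=n_boot, seed=seed)
        roc = self.roc()
        return {
            "features": list(self.model.X.columns),
            "mode": self.model.config.mode,
            "n_donors": int(self.model.y.size),
            "scores": {"donor_index": list(range(self.model.y.size)),
                       "probability": [float(s) for s in self.scores]},
            "auc": self.auc,
            "auc_ci95": [auc_lo, auc_hi],
            "accuracy": self.acc,
            "accuracy_ci95": [acc_lo, acc_hi],
            "n_bootstrap": n_boot,
            "seed": seed,
            "roc": {
                "fpr": [float(v) for v in roc["fpr"]],
                "tpr": [float(v) for v in roc["tpr"]],
            },
        }

    def plot_roc(self, ax=None, label: str | None = None):
        """Plot the ROC curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        roc = self.roc()
        ax.plot(roc["fpr"], roc["tpr"], label=label or f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax

    def summary(self) -> str:
        lines = [
            "Case/control random forest",
            "==========================",
            f"features:  {', '.join(map(str, self.model.X.columns))}",
            f"donors:    {self.model.y.size} "
            f"({int(self.model.y.sum())} cases)",
            f"evaluation: {self.model.config.mode}",
            f"AUC:       {self.auc:.3f}",
            f"accuracy:  {self.acc:.3f} (threshold 0.5)",
        ]
        return "\n".join(lines)
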