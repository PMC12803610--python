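"""Supervised case-control classification harness.

Nested, stratified two-level cross-validation around a gradient-boosted tree
learner (missing values passed through natively — no imputation), recursive
feature elimination inside training folds, threshold-based operating metrics
(ROC AUC by the rank identity, sensitivity/specificity at the Youden point,
accuracy, Brier score), paired DeLong AUC comparison against reference
scores (an age/BMI/atrial-fibrillation logistic score and raw NT-proBNP),
tree-path SHAP feature attributions, symptom lead-time reporting, and the
baseline-table group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

import lightgbm as lgb

MODALITY_CODES = ("LAB", "PHE", "MET", "PRO", "HxQ", "GEN")

# small default hyperparameter grid for the inner tuning loop (desk scale)
DEFAULT_GRID: tuple[dict, ...] = (
    {"num_leaves": 15, "learning_rate": 0.1, "n_estimators": 100},
    {"num_leaves": 31, "learning_rate": 0.05, "n_estimators": 200},
)


@dataclass
class CvConfig:
    outer_folds: int = 10
    inner_folds: int = 10
    stratify: bool = True
    n_seeds: int = 10
    modalities: tuple[str, ...] = ("LAB", "PHE", "MET", "PRO")
    rfe_target: int | None = 125
    max_missing_frac: float = 0.05
    grid: tuple[dict, ...] = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 <= self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac outside [0,1]")


@dataclass
class EvalReport:
    fold_metrics: pd.DataFrame          # one row per (seed, fold)
    aggregate: dict[str, tuple[float, float, float]]  # metric -> (mean, lo, hi)
    oof_scores: pd.Series               # out-of-fold scores, sample-indexed
    threshold: float
    models: list = field(default_factory=list)   # fitted outer-fold models

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Average predicted case probability over the outer-fold models."""
        X = features.to_numpy(dtype=float)
        probs = np.mean([m.predict_proba(X)[:, 1] for m in self.models], axis=0)
        return pd.Series(probs, index=features.index)


@dataclass
class ShapSummary:
    table: pd.DataFrame                 # feature, mean_abs_shap, rank, direction


def _make_model(params: dict, seed: int) -> lgb.LGBMClassifier:
    return lgb.LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                              **params)


def _check_folds(y: np.ndarray, splits) -> None:
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 1:
            raise ValueError("a class is absent from some fold")


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """ROC AUC via the Mann-Whitney rank identity (ties get half credit)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc_bruteforce(scores, labels) -> float:
    """All-pairs counting oracle for the AUC (cross-check only)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (pos.size * neg.size))


def youden_threshold(scores, labels) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    cand = np.unique(s)
    best_t, best_j = 0.5, -np.inf
    for t in cand:
        pred = s >= t
        sens = (pred & y).sum() / max(y.sum(), 1)
        spec = (~pred & ~y).sum() / max((~y).sum(), 1)
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def evaluate(scores, labels, threshold: float | None = None) -> dict[str, float]:
    """AUC, Brier, and threshold metrics for probabilistic scores in [0,1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if threshold is None:
        threshold = youden_threshold(s, y)
    pred = s >= threshold
    sens = float((pred & y).sum() / max(y.sum(), 1))
    spec = float((~pred & ~y).sum() / max((~y).sum(), 1))
    return {
        "auc": roc_auc(s, y),
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": float((pred == y).mean()),
        "brier": float(np.mean((s - y.astype(float)) ** 2)),
        "threshold": float(threshold),
    }


def delong_compare(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong test of two correlated ROC AUCs on the same samples.

    Placement-value construction: V10[i] = mean over controls of the win
    indicator for case i (ties half), V01[j] analogous for controls; the AUC
    difference divided by its paired variance is referred to the normal.
    Identical score vectors return p = 1 by convention.
    """
    y = np.asarray(labels).astype(bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValueError("score vectors and labels must share samples")

    def placements(s):
        pos, neg = s[y], s[~y]
        m, n = pos.size, neg.size
        diff = pos[:, None] - neg[None, :]
        win = (diff > 0).astype(float) + 0.5 * (diff == 0)
        return win.mean(axis=1), win.mean(axis=0), win.mean()

    v10_a, v01_a, auc_a = placements(a)
    v10_b, v01_b, auc_b = placements(b)
    m, n = int(y.sum()), int((~y).sum())
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return float(auc_a), float(auc_b), 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(p)


# --------------------------------------------------------------------------
# Nested cross-validation
# --------------------------------------------------------------------------

def _tune(X: np.ndarray, y: np.ndarray, config: CvConfig, seed: int) -> dict:
    """Inner-loop hyperparameter selection by mean inner-fold AUC."""
    if len(config.grid) == 1:
        return dict(config.grid[0])
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                            random_state=seed)
    best, best_auc = dict(config.grid[0]), -np.inf
    for params in config.grid:
        aucs = []
        for tr, te in inner.split(X, y):
            model = _make_model(params, seed)
            model.fit(X[tr], y[tr])
            aucs.append(roc_auc(model.predict_proba(X[te])[:, 1], y[te]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best = mean_auc, dict(params)
    return best


def _held_out_threshold(X: np.ndarray, y: np.ndarray, params: dict,
                        seed: int) -> float:
    """Youden threshold from 2-fold held-out predictions within a training
    split."""
    inner = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    scores = np.empty_like(y, dtype=float)
    for tr, te in inner.split(X, y):
        model = _make_model(params, seed)
        model.fit(X[tr], y[tr])
        scores[te] = model.predict_proba(X[te])[:, 1]
    return youden_threshold(scores, y)


def nested_cv(features: pd.DataFrame, labels: pd.Series,
              config: CvConfig | None = None) -> EvalReport:
    """Stratified nested cross-validation with native missing-value handling.

    Outer folds give the unbiased metric estimates; inner folds tune the
    hyperparameter grid; the Youden operating threshold is chosen on training
    -fold predictions.  Stratification keeps the per-fold case fraction within
    one case of the overall fraction.
    """
    config = config or CvConfig()
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes")
    fold_rows = []
    oof = pd.Series(np.nan, index=features.index, dtype=float)
    outer = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                            random_state=config.seed)
    splits = list(outer.split(X, y))
    _check_folds(y, splits)
    thresholds = []
    models = []
    for fold, (tr, te) in enumerate(splits):
        params = _tune(X[tr], y[tr], config, config.seed + fold)
        model = _make_model(params, config.seed + fold)
        model.fit(X[tr], y[tr])
        models.append(model)
        # operating threshold from held-out inner predictions (a threshold
        # chosen on training-set scores of a boosted model is degenerate)
        thr = _held_out_threshold(X[tr], y[tr], params, config.seed + fold)
        thresholds.append(thr)
        te_scores = model.predict_proba(X[te])[:, 1]
        oof.iloc[te] = te_scores
        metrics = evaluate(te_scores, y[te], threshold=thr)
        metrics.update({"fold": fold, "seed": config.seed})
        fold_rows.append(metrics)
    frame = pd.DataFrame(fold_rows)
    aggregate = {}
    for metric in ("auc", "sensitivity", "specificity", "accuracy", "brier"):
        vals = frame[metric].to_numpy()
        aggregate[metric] = (float(vals.mean()),
                             float(np.percentile(vals, 2.5)),
                             float(np.percentile(vals, 97.5)))
    return EvalReport(fold_metrics=frame, aggregate=aggregate,
                      oof_scores=oof, threshold=float(np.mean(thresholds)),
                      models=models)


def drop_high_missing(features: pd.DataFrame, max_missing_frac: float
                      ) -> pd.DataFrame:
    """Exclude samples with more than the allowed fraction of missing values."""
    frac = features.isna().mean(axis=1)
    return features.loc[frac <= max_missing_frac]


# --------------------------------------------------------------------------
# Recursive feature elimination
# --------------------------------------------------------------------------

def rfe_select(features: pd.DataFrame, labels: pd.Series, target_n: int,
               config: CvConfig | None = None, step_frac: float = 0.5
               ) -> list[str]:
    """Iteratively drop the lowest-importance features until ``target_n``
    remain (gain importance from the gradient-boosted learner); call inside
    training folds only."""
    config = config or CvConfig()
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    if target_n >= features.shape[1]:
        return list(features.columns)
    cols = list(features.columns)
    y = labels.to_numpy().astype(int)
    while len(cols) > target_n:
        model = _make_model(dict(config.grid[0]), config.seed)
        model.fit(features[cols].to_numpy(dtype=float), y)
        imp = pd.Series(model.feature_importances_, index=cols)
        n_next = max(target_n, int(len(cols) * step_frac))
        cols = list(imp.sort_values(ascending=False).index[:n_next])
    return cols


# --------------------------------------------------------------------------
# Reference scores
# --------------------------------------------------------------------------

# Representative logistic coefficients for the age/BMI/atrial-fibrillation
# screening score; placeholders on the published model's scale, overridable.
DEFAULT_ABA_COEFS = {"intercept": -9.2, "age": 0.05, "bmi": 0.14, "af": 1.75}


def reference_scores(table: pd.DataFrame,
                     coefs: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-participant reference scores.

    ``table`` needs columns age_years, bmi, af (0/1) and nt_probnp.  Returns
    ``hfpef_aba`` (logistic over age, BMI, AF) and ``ntprobnp_only`` (the raw
    biomarker as a ranking score); missing inputs yield missing scores.
    """
    coefs = coefs or DEFAULT_ABA_COEFS
    lin = (coefs["intercept"] + coefs["age"] * table["age_years"]
           + coefs["bmi"] * table["bmi"] + coefs["af"] * table["af"])
    aba = 1.0 / (1.0 + np.exp(-lin))
    return pd.DataFrame({"hfpef_aba": aba, "ntprobnp_only": table["nt_probnp"]},
                        index=table.index)


# --------------------------------------------------------------------------
# SHAP summary
# --------------------------------------------------------------------------

def shap_top(model: lgb.LGBMClassifier, features: pd.DataFrame, k: int = 30
             ) -> ShapSummary:
    """Top-k features by mean |SHAP| using the tree-path attribution built
    into the boosted-tree library; per-sample contributions sum to the raw
    prediction minus the base value."""
    contrib = model.predict(features.to_numpy(dtype=float),
                            pred_contrib=True)
    shap_vals = contrib[:, :-1]          # last column is the base value
    mean_abs = np.abs(shap_vals).mean(axis=0)
    direction = []
    X = features.to_numpy(dtype=float)
    for j in range(X.shape[1]):
        x, s = X[:, j], shap_vals[:, j]
        ok = np.isfinite(x)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(s[ok]) == 0:
            direction.append(0)
        else:
            direction.append(int(np.sign(np.corrcoef(x[ok], s[ok])[0, 1])))
    table = pd.DataFrame({
        "feature": features.columns,
        "mean_abs_shap": mean_abs,
        "direction": direction,
    }).sort_values("mean_abs_shap", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return ShapSummary(table=table.head(min(k, len(table))).reset_index(drop=True))


def shap_values(model: lgb.LGBMClassifier, features: pd.DataFrame) -> np.ndarray:
    contrib = model.predict(features.to_numpy(dtype=float), pred_contrib=True)
    return contrib


# --------------------------------------------------------------------------
# Lead-time report
# --------------------------------------------------------------------------

def lead_time_report(is_case: pd.Series, onset_years: pd.Series,
                     scores: pd.Series, threshold: float) -> dict:
    """Pre-symptomatic detection summary.

    Asymptomatic at recruitment = onset strictly after recruitment
    (onset > 0); lead time is reported only for true cases scored above the
    operating threshold.
    """
    cases = is_case[is_case].index
    onset = onset_years.loc[cases]
    asym = onset > 0
    flagged = scores.loc[cases] > threshold
    lead = onset[asym & flagged]
    report = {
        "n_cases": int(len(cases)),
        "fraction_asymptomatic": float(asym.mean()) if len(cases) else np.nan,
        "n_flagged_asymptomatic": int((asym & flagged).sum()),
        "lead_time_mean_years": float(lead.mean()) if len(lead) else np.nan,
        "lead_time_sd_years": float(lead.std(ddof=0)) if len(lead) else np.nan,
    }
    if not len(lead):
        warnings.warn("no flagged asymptomatic cases; lead time empty")
    return report


# --------------------------------------------------------------------------
# Baseline-table statistics
# --------------------------------------------------------------------------

def percent(count: int, group_size: int) -> float:
    """Group percentage rounded to one decimal, half away from zero."""
    if group_size <= 0:
        raise ValueError("zero group size")
    raw = 100.0 * count / group_size
    return float(np.floor(raw * 10 + 0.5) / 10) if raw >= 0 else \
        float(-np.floor(-raw * 10 + 0.5) / 10)


def table_stats(counts: dict[str, int], sizes: dict[str, int]) -> dict:
    """Binary-variable row of a baseline table: per-group n (%) plus a
    chi-square (or Fisher for 2x2 with small cells) group-comparison p."""
    groups = list(counts)
    if any(sizes[g] <= 0 for g in groups):
        raise ValueError("zero group size")
    pct = {g: percent(counts[g], sizes[g]) for g in groups}
    table = np.array([[counts[g], sizes[g] - counts[g]] for g in groups])
    if table.shape == (2, 2) and (table < 5).any():
        _, p = stats.fisher_exact(table)
    else:
        with np.errstate(all="ignore"):
            _, p, _, _ = stats.chi2_contingency(table)
    return {"percent": pct, "p": float(p)}


def continuous_stats(values_by_group: dict[str, np.ndarray]) -> dict:
    """Continuous-variable row: mean (SD) per group plus Kruskal-Wallis p."""
    out = {g: (float(np.nanmean(v)), float(np.nanstd(v, ddof=1)))
           for g, v in values_by_group.items()}
    groups = [np.asarray(v)[np.isfinite(v)] for v in values_by_group.values()]
    _, p = stats.kruskal(*groups)
    return {"mean_sd": out, "p": float(p)}
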