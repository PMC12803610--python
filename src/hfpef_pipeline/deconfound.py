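"""Confounder-aware association analysis.

A naive non-parametric screen (Mann-Whitney U for binary group contrasts,
Spearman for continuous covariates) with Benjamini-Hochberg adjustment and
standardized effect sizes (Cliff's delta / Spearman's rho) is followed, for
naively significant features, by per-covariate nested linear model
comparisons on rank-transformed feature values.  Likelihood-ratio tests
decide whether disease status explains the feature beyond each covariate
(deconfounded), whether a covariate explains it instead (confounded, with the
covariate recorded), or whether neither model resolves the direction
(ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class Status(str, Enum):
    DECONFOUNDED = "DECONFOUNDED"
    AMBIGUOUS = "AMBIGUOUS"
    CONFOUNDED = "CONFOUNDED"
    NO_ASSOCIATION = "NO_ASSOCIATION"


@dataclass
class DeconfoundParams:
    naive_fdr_cut: float = 0.1
    lrt_alpha: float = 0.05
    min_group_size: int = 5
    rank_transform: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.naive_fdr_cut < 1:
            raise ValueError("naive_fdr_cut must be in (0,1)")
        if not 0 < self.lrt_alpha < 1:
            raise ValueError("lrt_alpha must be in (0,1)")


@dataclass
class AssociationRecord:
    feature: str
    contrast: str
    p: float
    q: float
    effect: float                         # Cliff's delta for group contrasts
    lrt: dict[str, tuple[float, float]] = field(default_factory=dict)
    status: Status = Status.NO_ASSOCIATION
    confounders: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Effect sizes
# --------------------------------------------------------------------------

def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all pairs; ties contribute 0.

    Computed via the Mann-Whitney U statistic (rank method), which equals the
    brute-force pair count: delta = 2U/(n1*n2) - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta: empty sample")
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(2.0 * u / (x.size * y.size) - 1.0)


def cliffs_delta_bruteforce(x, y) -> float:
    """O(n*m) pair-count oracle, kept for cross-checks."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float((np.sign(x - y)).mean())


# --------------------------------------------------------------------------
# Naive screen
# --------------------------------------------------------------------------

def naive_screen(features: pd.DataFrame, contrast: pd.Series,
                 params: DeconfoundParams | None = None,
                 contrast_name: str = "case_vs_control") -> list[AssociationRecord]:
    """Per-feature naive association against a binary contrast.

    ``contrast`` is a boolean/0-1 series aligned to ``features`` rows; missing
    feature values are dropped pairwise.  Binary contrast -> two-sided
    Mann-Whitney U p-value plus Cliff's delta; q-values by Benjamini-Hochberg
    within the feature family.  Zero-variance features get p=1, effect 0.
    """
    params = params or DeconfoundParams()
    mask = contrast.notna()
    y = contrast[mask].astype(bool)
    if y.sum() < params.min_group_size or (~y).sum() < params.min_group_size:
        raise ValueError("each group needs at least min_group_size members")
    recs: list[AssociationRecord] = []
    for feat in features.columns:
        v = features.loc[mask, feat].to_numpy(dtype=float)
        ok = np.isfinite(v)
        vc = v[ok & y.to_numpy()]
        vn = v[ok & ~y.to_numpy()]
        if (vc.size < params.min_group_size or vn.size < params.min_group_size
                or np.nanstd(np.concatenate([vc, vn])) == 0):
            recs.append(AssociationRecord(feat, contrast_name, 1.0, np.nan, 0.0))
            continue
        res = stats.mannwhitneyu(vc, vn, alternative="two-sided")
        delta = 2.0 * res.statistic / (vc.size * vn.size) - 1.0
        recs.append(AssociationRecord(feat, contrast_name,
                                      float(res.pvalue), np.nan, float(delta)))
    ps = np.array([r.p for r in recs])
    qs = multipletests(ps, method="fdr_bh")[1]
    for r, q in zip(recs, qs):
        r.q = float(q)
    return recs


def spearman_screen(features: pd.DataFrame, covariate: pd.Series
                    ) -> pd.DataFrame:
    """Spearman rho and p per feature against a continuous covariate, with BH
    q-values (continuous-covariate arm of the naive screen)."""
    rows = []
    for feat in features.columns:
        v = features[feat]
        ok = v.notna() & covariate.notna()
        if ok.sum() < 3 or v[ok].std() == 0 or covariate[ok].std() == 0:
            rows.append((feat, 0.0, 1.0))
            continue
        rho, p = stats.spearmanr(v[ok], covariate[ok])
        rows.append((feat, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["feature", "rho", "p"]).set_index("feature")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# --------------------------------------------------------------------------
# Nested likelihood-ratio tests
# --------------------------------------------------------------------------

def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _lrt_p(rss0: float, rss1: float, n: int) -> float:
    """Chi-square LRT with 1 df between nested Gaussian linear models."""
    rss1 = max(rss1, 1e-300)
    stat = n * np.log(max(rss0, 1e-300) / rss1)
    return float(stats.chi2.sf(max(stat, 0.0), df=1))


def lrt_nested(feature: np.ndarray, disease: np.ndarray, covariate: np.ndarray,
               params: DeconfoundParams | None = None
               ) -> tuple[float, float]:
    """Per-covariate nested-model likelihood ratio tests.

    Returns ``(lrt_disease_p, lrt_covariate_p)``: the first compares
    feature ~ covariate against feature ~ covariate + disease (does disease
    add predictive power beyond the covariate?); the second compares
    feature ~ disease against feature ~ disease + covariate.  Gaussian linear
    models on rank-transformed feature values, chi-square with 1 df.
    Collinear disease/covariate columns return (nan, nan).
    """
    params = params or DeconfoundParams()
    y = np.asarray(feature, dtype=float)
    d = np.asarray(disease, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = np.isfinite(y) & np.isfinite(d) & np.isfinite(c)
    y, d, c = y[ok], d[ok], c[ok]
    n = y.size
    if n < max(params.min_group_size * 2, 8):
        return (np.nan, np.nan)
    if params.rank_transform:
        y = stats.rankdata(y)
    d_c = d - d.mean()
    c_c = c - c.mean()
    if (np.allclose(d_c, 0) or np.allclose(c_c, 0)
            or abs(np.corrcoef(d, c)[0, 1]) > 1 - 1e-10):
        return (np.nan, np.nan)
    ones = np.ones(n)
    X_cov = np.column_stack([ones, c])
    X_dis = np.column_stack([ones, d])
    X_both = np.column_stack([ones, c, d])
    rss_cov = _ols_rss(y, X_cov)
    rss_dis = _ols_rss(y, X_dis)
    rss_both = _ols_rss(y, X_both)
    return (_lrt_p(rss_cov, rss_both, n), _lrt_p(rss_dis, rss_both, n))


def classify_status(q: float, lrt_results: dict[str, tuple[float, float]],
                    params: DeconfoundParams | None = None
                    ) -> tuple[Status, list[str]]:
    """Combine the naive FDR and the per-covariate LRTs into a status.

    NO_ASSOCIATION when the naive q fails the FDR cut; DECONFOUNDED when
    disease adds signal beyond every covariate; CONFOUNDED when some covariate
    both blocks the disease term and carries signal itself (those covariates
    are returned); AMBIGUOUS otherwise.
    """
    params = params or DeconfoundParams()
    if not np.isfinite(q) or q >= params.naive_fdr_cut:
        return Status.NO_ASSOCIATION, []
    if not lrt_results:
        return Status.DECONFOUNDED, []
    confounders = []
    all_pass = True
    any_nan = False
    for cov, (p_dis, p_cov) in lrt_results.items():
        if not np.isfinite(p_dis):
            any_nan = True
            all_pass = False
            continue
        if p_dis >= params.lrt_alpha:
            all_pass = False
            if np.isfinite(p_cov) and p_cov < params.lrt_alpha:
                confounders.append(cov)
    if all_pass:
        return Status.DECONFOUNDED, []
    if confounders:
        return Status.CONFOUNDED, confounders
    return Status.AMBIGUOUS, []


def deconfound(features: pd.DataFrame, contrast: pd.Series,
               covariates: pd.DataFrame,
               params: DeconfoundParams | None = None,
               contrast_name: str = "case_vs_control"
               ) -> list[AssociationRecord]:
    """Full pipeline: naive screen, then nested LRTs per covariate for the
    naively significant features, then status classification.

    Binary covariates with fewer than ``min_group_size`` positives among
    complete cases are skipped for that feature.
    """
    params = params or DeconfoundParams()
    recs = naive_screen(features, contrast, params, contrast_name)
    d = contrast.astype(float).to_numpy()
    for rec in recs:
        if not np.isfinite(rec.q) or rec.q >= params.naive_fdr_cut:
            rec.status = Status.NO_ASSOCIATION
            continue
        y = features[rec.feature].to_numpy(dtype=float)
        for cov_name in covariates.columns:
            c = covariates[cov_name].to_numpy(dtype=float)
            uniq = np.unique(c[np.isfinite(c)])
            if len(uniq) <= 2:   # binary covariate: require enough positives
                ok = np.isfinite(y) & np.isfinite(c)
                if (c[ok] == uniq.max()).sum() < params.min_group_size:
                    continue
            rec.lrt[cov_name] = lrt_nested(y, d, c, params)
        rec.status, rec.confounders = classify_status(rec.q, rec.lrt, params)
    return recs


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------

def significance_stars(q: float) -> str:
    """Star encoding of the FDR: *<0.1, **<0.01, ***<0.001, else empty."""
    if not np.isfinite(q) or q >= 0.1:
        return ""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    return "*"


_STATUS_MARKER = {Status.DECONFOUNDED: "*", Status.CONFOUNDED: "o",
                  Status.AMBIGUOUS: "~", Status.NO_ASSOCIATION: ""}


def heatmap_table(records_by_group: dict[str, list[AssociationRecord]],
                  reference_group: str, k: int = 25) -> pd.DataFrame:
    """Long-format heatmap table: top-k highest- and lowest-effect features of
    the reference group across all groups, with star bins and a status marker
    (o = confounded, * = deconfounded); empty significance = FDR >= 0.1."""
    ref = {r.feature: r for r in records_by_group[reference_group]}
    ranked = sorted(ref.values(), key=lambda r: r.effect)
    lowest = [r.feature for r in ranked[:k]]
    highest = [r.feature for r in ranked[-k:]]
    chosen = list(dict.fromkeys(highest[::-1] + lowest))
    rows = []
    for grp, recs in records_by_group.items():
        by_feat = {r.feature: r for r in recs}
        for feat in chosen:
            r = by_feat.get(feat)
            if r is None:
                continue
            rows.append({
                "feature": feat, "group": grp, "effect": r.effect,
                "stars": significance_stars(r.q),
                "status": _STATUS_MARKER[r.status],
            })
    return pd.DataFrame(rows, columns=["feature", "group", "effect",
                                       "stars", "status"])


def associations_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.lrt:
            for cov, (pd_, pc) in r.lrt.items():
                rows.append({"feature": r.feature, "contrast": r.contrast,
                             "p": r.p, "q": r.q, "effect": r.effect,
                             "covariate": cov, "lrt_disease_p": pd_,
                             "lrt_covariate_p": pc, "status": r.status.value})
        else:
            rows.append({"feature": r.feature, "contrast": r.contrast,
                         "p": r.p, "q": r.q, "effect": r.effect,
                         "covariate": "", "lrt_disease_p": np.nan,
                         "lrt_covariate_p": np.nan, "status": r.status.value})
    return pd.DataFrame(rows)
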