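"""Five-stage feature-selection cascade producing a per-region radiomics signature.

Stage order: univariate filter (Welch t / Mann-Whitney U at p < 0.05, routed
by Shapiro-Wilk normality in both classes) → Pearson correlation prune at
|r| > 0.9 → greedy recursive elimination on mean absolute correlation →
mRMR (FCQ variant, top 15) → L1-penalized logistic regression with 10-fold
cross-validated λ. Every statistic is computed on the training cohort only;
the resulting :class:`Signature` is a frozen linear predictor applicable to
any cohort carrying the same feature names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Signature",
    "univariate_filter",
    "correlation_prune",
    "greedy_recursive_elimination",
    "mrmr_select",
    "lasso_signature",
    "run_cascade",
]


@dataclass
class Signature:
    region: str
    selected_features: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_star: float = float("nan")
    stage_log: dict = field(default_factory=dict)

    def linear_score(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.selected_features].to_numpy(dtype=float)
        return self.intercept + x @ self.coefficients

    def probability(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_score(table)))


def _univariate_p(x: np.ndarray, y: np.ndarray) -> float:
    """Welch t if both classes pass Shapiro-Wilk at α=0.05, else Mann-Whitney U."""
    a, b = x[y == 0], x[y == 1]
    if np.ptp(x) <= 1e-300:  # constant feature: no information
        return 1.0
    normal = True
    for grp in (a, b):
        if np.ptp(grp) <= 0:
            normal = False
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(grp).pvalue < 0.05:
                normal = False
                break
    if normal:
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def univariate_p_values(table: pd.DataFrame, labels) -> pd.Series:
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly two classes")
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need at least 3 patients per class")
    return pd.Series(
        {c: _univariate_p(table[c].to_numpy(dtype=float), y) for c in table.columns}
    )


def univariate_filter(table: pd.DataFrame, labels, alpha: float = 0.05) -> list[str]:
    """Features significantly associated with the binary label (no multiplicity
    correction)."""
    p = univariate_p_values(table, labels)
    return p.index[p < alpha].tolist()


def correlation_prune(table: pd.DataFrame, surviving: list[str],
                      labels=None, threshold: float = 0.9,
                      p_values: pd.Series | None = None) -> list[str]:
    """Drop one member of every feature pair with |Pearson r| > threshold.

    Pairs are visited in descending |r|; the member with the larger univariate
    p-value is dropped (ties break lexicographically by name). The surviving
    set has max pairwise |r| ≤ threshold.
    """
    if not surviving:
        raise ValueError("no surviving features to prune")
    if p_values is None:
        p_values = (univariate_p_values(table[surviving], labels)
                    if labels is not None
                    else pd.Series(0.0, index=surviving))
    cols = list(surviving)
    corr = table[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    alive = {c: i for i, c in enumerate(cols)}
    pairs = [(corr[i, j], cols[i], cols[j])
             for i in range(len(cols)) for j in range(i + 1, len(cols))
             if corr[i, j] > threshold]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    for r, a, b in pairs:
        if a not in alive or b not in alive:
            continue
        pa, pb = p_values.get(a, 0.0), p_values.get(b, 0.0)
        drop = max((pa, a), (pb, b))[1]  # larger p, then later name
        del alive[drop]
    return [c for c in cols if c in alive]


def greedy_recursive_elimination(table: pd.DataFrame, features: list[str],
                                 target_redundancy: float = 0.75,
                                 min_features: int = 20,
                                 p_values: pd.Series | None = None) -> list[str]:
    """Iteratively remove the feature with the highest mean |r| to the rest.

    Stops when that maximum mean correlation drops below
    ``target_redundancy`` or ≤ ``min_features`` remain. Ties break by larger
    univariate p then name. Idempotent on its own output.
    """
    feats = list(features)
    if p_values is None:
        p_values = pd.Series(0.0, index=feats)
    while len(feats) > min_features:
        corr = table[feats].corr().abs().to_numpy()
        np.fill_diagonal(corr, np.nan)
        mean_r = np.nanmean(corr, axis=1)
        worst = float(np.nanmax(mean_r))
        if worst < target_redundancy:
            break
        cand = [(mean_r[i], p_values.get(f, 0.0), f) for i, f in enumerate(feats)
                if mean_r[i] >= worst - 1e-12]
        cand.sort(key=lambda t: (-t[0], -t[1], t[2]))
        feats.remove(cand[0][2])
    return feats


def mrmr_select(table: pd.DataFrame, features: list[str], labels,
                m: int = 15) -> list[str]:
    """mRMR greedy forward selection (FCQ: F-statistic / mean |r| quotient).

    The first pick maximizes the ANOVA F-statistic alone; later picks
    maximize F(f) divided by the mean absolute Pearson correlation with the
    already-selected set. Returns min(m, |features|) names in pick order.
    """
    if not features:
        return []
    y = np.asarray(labels)
    x = table[features].to_numpy(dtype=float)
    a, b = x[y == 0], x[y == 1]
    # one-way ANOVA F per feature (two classes)
    n0, n1 = len(a), len(b)
    grand = x.mean(axis=0)
    ssb = n0 * (a.mean(0) - grand) ** 2 + n1 * (b.mean(0) - grand) ** 2
    ssw = ((a - a.mean(0)) ** 2).sum(0) + ((b - b.mean(0)) ** 2).sum(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(ssw > 1e-30, ssb / (ssw / (n0 + n1 - 2)), np.inf)

    corr = np.abs(np.corrcoef(x, rowvar=False))
    if corr.ndim == 0:
        corr = np.array([[1.0]])
    corr = np.nan_to_num(corr, nan=0.0)

    remaining = list(range(len(features)))
    picked: list[int] = []
    while remaining and len(picked) < m:
        if not picked:
            scores = [(f_stat[i], features[i]) for i in remaining]
            best = max(scores, key=lambda t: (t[0], t[1]))[1]
        else:
            best_score, best = -np.inf, None
            for i in remaining:
                red = corr[i, picked].mean()
                score = f_stat[i] / max(red, 1e-12)
                if score > best_score:
                    best_score, best = score, features[i]
        bi = features.index(best)
        picked.append(bi)
        remaining.remove(bi)
    return [features[i] for i in picked]


def lasso_signature(table: pd.DataFrame, features: list[str], labels,
                    seed: int = 0, region: str = "region", n_folds: int = 10,
                    rule: str = "1se",
                    stage_log: dict | None = None) -> Signature:
    """ℓ1-penalized logistic signature with 10-fold CV choice of λ.

    λ grid: 100 log-spaced values from λ_max (the smallest penalty zeroing
    every coefficient) down four decades. ``rule="min"`` takes the minimizer
    of mean held-out binomial deviance; the default ``rule="1se"`` takes the
    largest λ within one standard error of that minimum, which curbs the
    well-known overselection of the plain minimizer while keeping the true
    support. If λ* yields an all-zero solution, falls back to the largest λ
    with ≥ 1 nonzero coefficient.
    """
    y = np.asarray(labels).astype(int)
    x = table[features].to_numpy(dtype=float)
    n = len(y)
    n_min = min((y == 0).sum(), (y == 1).sum())
    if n_min < n_folds:
        n_folds = max(2, int(n_min))
        warnings.warn(f"reduced CV folds to {n_folds} (minority class size)")

    ybar = y.mean()
    lam_max = np.abs(x.T @ (y - ybar)).max()
    if lam_max <= 0:
        lam_max = 1.0
    lams = np.logspace(np.log10(lam_max), np.log10(lam_max) - 4, 100)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    deviance = np.zeros((len(folds), len(lams)))
    for fi, (tr, va) in enumerate(folds):
        for i, lam in enumerate(lams):
            clf = LogisticRegression(l1_ratio=1.0, C=1.0 / lam,
                                     solver="liblinear", max_iter=1000,
                                     random_state=seed)
            clf.fit(x[tr], y[tr])
            p = clf.predict_proba(x[va])[:, 1].clip(1e-12, 1 - 1e-12)
            deviance[fi, i] = -2.0 * (y[va] * np.log(p)
                                      + (1 - y[va]) * np.log(1 - p)).mean()
    mean_dev = deviance.mean(axis=0)
    imin = int(np.argmin(mean_dev))
    if rule == "min":
        lam_star = lams[imin]
    elif rule == "1se":
        se = deviance.std(axis=0, ddof=1) / np.sqrt(len(folds))
        # grid descends from lam_max: the first index within 1 SE of the
        # minimum is the largest admissible penalty
        i1se = int(np.flatnonzero(mean_dev <= mean_dev[imin] + se[imin])[0])
        lam_star = lams[i1se]
    else:
        raise ValueError(f"rule must be 'min' or '1se', got {rule!r}")

    def fit(lam):
        clf = LogisticRegression(l1_ratio=1.0, C=1.0 / lam, solver="liblinear",
                                 max_iter=1000, random_state=seed)
        clf.fit(x, y)
        return clf

    clf = fit(lam_star)
    nonzero = np.flatnonzero(np.abs(clf.coef_[0]) > 1e-12)
    if len(nonzero) == 0:
        warnings.warn("all-zero LASSO solution at λ*; falling back to the "
                      "largest λ with an active feature")
        for lam in lams:
            clf = fit(lam)
            nonzero = np.flatnonzero(np.abs(clf.coef_[0]) > 1e-12)
            if len(nonzero):
                lam_star = lam
                break
    selected = [features[i] for i in nonzero]
    log = dict(stage_log or {})
    log["lasso"] = selected
    return Signature(region=region, selected_features=selected,
                     coefficients=clf.coef_[0][nonzero].copy(),
                     intercept=float(clf.intercept_[0]),
                     lambda_star=float(lam_star), stage_log=log)


def run_cascade(table: pd.DataFrame, labels, region: str, seed: int = 0,
                correlation_threshold: float = 0.9,
                target_redundancy: float = 0.75, mrmr_m: int = 15) -> Signature:
    """Full training-cohort cascade; records survivors of every stage."""
    y = np.asarray(labels)
    p_values = univariate_p_values(table, y)
    s1 = p_values.index[p_values < 0.05].tolist()
    if not s1:
        # degenerate cohort with no univariate signal: keep the 30 smallest p
        warnings.warn(f"{region}: no feature passed the univariate filter; "
                      "falling back to the 30 smallest p-values")
        s1 = p_values.nsmallest(min(30, len(p_values))).index.tolist()
    s2 = correlation_prune(table, s1, threshold=correlation_threshold,
                           p_values=p_values)
    s3 = greedy_recursive_elimination(table, s2,
                                      target_redundancy=target_redundancy,
                                      p_values=p_values)
    s4 = mrmr_select(table, s3, y, m=mrmr_m)
    log = {"univariate": s1, "correlation_prune": s2,
           "greedy_elimination": s3, "mrmr": s4}
    return lasso_signature(table, s4, y, seed=seed, region=region, stage_log=log)
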