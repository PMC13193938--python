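"""Evaluation statistics for response models and survival stratification.

Includes: mRECIST response classification, ROC/AUC with DeLong variance and
paired DeLong test, confusion metrics at a frozen Youden threshold,
continuous NRI and IDI, calibration curves with logistic recalibration,
decision-curve net benefit, exact Shapley attributions (background-marginal
expectation over all coalitions), Kaplan-Meier curves with log-rank test
(via lifelines; median convention: first time with S ≤ 0.5), and
baseline-table tests (t / Mann-Whitney for continuous, chi-square / Fisher
for categorical). All tests are two-sided at α = 0.05.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "ResponseAssessment",
    "mrecist_classify",
    "roc_auc",
    "delong_test",
    "confusion_metrics",
    "nri_idi",
    "calibration_curve",
    "decision_curve",
    "shapley_attributions",
    "youden_cutoff",
    "km_logrank",
    "baseline_table_tests",
    "roc_points",
]

UNDEFINED = float("nan")  # sentinel for zero-denominator ratios


# --------------------------------------------------------------------------
# mRECIST

@dataclass
class ResponseAssessment:
    baseline_sum_mm: float
    followup_sum_mm: float
    enhancement_present: bool
    new_lesions: bool
    category: str = ""

    @property
    def orr_positive(self) -> bool:
        return self.category in ("CR", "PR")


def mrecist_classify(baseline_sum_mm: float, followup_sum_mm: float,
                     enhancement_present: bool,
                     new_lesions: bool) -> ResponseAssessment:
    """Categorize treatment response per mRECIST.

    CR: no residual intratumoral arterial enhancement. PD: new lesions or a
    ≥ 20% increase in the sum of target-lesion diameters. PR: ≥ 30% decrease.
    SD: otherwise. ORR+ ⇔ CR or PR.
    """
    if baseline_sum_mm <= 0:
        raise ValueError("baseline diameter sum must be positive")
    if followup_sum_mm < 0:
        raise ValueError("follow-up diameter sum must be non-negative")
    change = (followup_sum_mm - baseline_sum_mm) / baseline_sum_mm
    if not enhancement_present:
        cat = "CR"
    elif new_lesions or change >= 0.20:
        cat = "PD"
    elif change <= -0.30:
        cat = "PR"
    else:
        cat = "SD"
    return ResponseAssessment(baseline_sum_mm, followup_sum_mm,
                              enhancement_present, new_lesions, cat)


# --------------------------------------------------------------------------
# ROC / DeLong

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong structural components V10 (cases), V01 (controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    allr = _midrank(np.concatenate([pos, neg]))
    rp = _midrank(pos)
    rn = _midrank(neg)
    auc = (allr[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (allr[:m] - rp) / n
    v01 = 1.0 - (allr[m:] - rn) / m
    return auc, v10, v01


def roc_auc(scores, labels) -> dict:
    """Mann-Whitney AUC (tie-corrected) with DeLong variance and Wald 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_components(scores, labels)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    se = math.sqrt(max(var, 0.0))
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)
    return {"auc": float(auc), "variance": float(var), "ci95": (float(lo), float(hi))}


def delong_test(scores_a, scores_b, labels) -> dict:
    """Paired DeLong test comparing two correlated AUCs on the same patients."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(a) != len(b) or len(a) != len(y):
        raise ValueError("paired score vectors must align with labels")
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-24:
        return {"z": 0.0, "p": 1.0, "auc_a": float(auc_a), "auc_b": float(auc_b)}
    z = (auc_a - auc_b) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p), "auc_a": float(auc_a), "auc_b": float(auc_b)}


def roc_points(scores, labels) -> pd.DataFrame:
    """Monotone ROC staircase from (0,0) to (1,1) over observed thresholds."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    tps = np.concatenate([[0], np.cumsum(ys)])
    fps = np.concatenate([[0], np.cumsum(1 - ys)])
    # collapse ties on score
    ss = scores[order]
    keep = np.concatenate([np.flatnonzero(np.diff(ss)) + 1, [len(ss)]])
    keep = np.concatenate([[0], keep])
    tpr = tps[keep] / max(ys.sum(), 1)
    fpr = fps[keep] / max((1 - ys).sum(), 1)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def confusion_metrics(scores, labels, threshold: float) -> dict:
    """Accuracy / sensitivity / specificity / PPV / NPV at a frozen threshold.

    Predicted positive ⇔ score ≥ threshold; zero-denominator ratios return a
    NaN sentinel.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    def ratio(num, den):
        return num / den if den > 0 else UNDEFINED

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "threshold": float(threshold),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


# --------------------------------------------------------------------------
# reclassification

def nri_idi(p_old, p_new, labels) -> dict:
    """Continuous (category-free) NRI and IDI of model ``new`` over ``old``."""
    po = np.asarray(p_old, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    y = np.asarray(labels).astype(int)
    ev, non = y == 1, y == 0
    up, down = pn > po, pn < po
    nri = ((up[ev].mean() - down[ev].mean()) if ev.any() else 0.0) \
        + ((down[non].mean() - up[non].mean()) if non.any() else 0.0)
    idi = (pn[ev].mean() - po[ev].mean()) - (pn[non].mean() - po[non].mean())
    return {"nri": float(nri), "idi": float(idi)}


# --------------------------------------------------------------------------
# calibration / decision curves

def calibration_curve(probabilities, labels, n_bins: int = 10) -> dict:
    """Equal-width probability bins + logistic recalibration slope/intercept."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(p) < n_bins:
        raise ValueError("need at least n_bins observations")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    skipped = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            skipped.append(b)
            continue
        rows.append({"bin": b, "mean_predicted": float(p[sel].mean()),
                     "observed_rate": float(y[sel].mean()),
                     "count": int(sel.sum())})
    logit = np.log(np.clip(p, 1e-9, 1 - 1e-9) / np.clip(1 - p, 1e-9, 1 - 1e-9))
    if len(np.unique(y)) == 2 and np.ptp(logit) > 0:
        import statsmodels.api as sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, sm.add_constant(logit),
                         family=sm.families.Binomial()).fit()
        slope, intercept = float(res.params[1]), float(res.params[0])
    else:
        slope, intercept = UNDEFINED, UNDEFINED
    return {"bins": pd.DataFrame(rows), "slope": slope, "intercept": intercept,
            "skipped_bins": skipped}


def decision_curve(probabilities, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/N − FP/N · pt/(1−pt), with treat-all/none refs."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        pos = p >= pt
        tp = float((pos & (y == 1)).sum())
        fp = float((pos & (y == 0)).sum())
        nb = tp / n - fp / n * pt / (1 - pt)
        nb_all = prev - (1 - prev) * pt / (1 - pt)
        rows.append({"threshold": pt, "net_benefit": nb,
                     "treat_all": nb_all, "treat_none": 0.0})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Shapley

def shapley_attributions(predict, background: np.ndarray,
                         instances: np.ndarray) -> dict:
    """Exact Shapley values with background-marginal coalition expectations.

    ``predict(X) -> array`` is the model output (e.g. probability of the
    positive class). For each instance and coalition S, the value is the mean
    prediction over the background set with instance values substituted on S.
    Refuses M > 15 features (2^M coalition enumeration). Satisfies local
    accuracy: base value + Σ attributions = prediction.
    """
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    xs = np.atleast_2d(np.asarray(instances, dtype=float))
    m = bg.shape[1]
    if m > 15:
        raise ValueError(f"{m} features: exact enumeration refused above 15; "
                         "use a sampling estimator")
    n_bg = len(bg)
    subsets = list(itertools.product([0, 1], repeat=m))
    fact = [math.factorial(i) for i in range(m + 1)]

    attributions = np.zeros((len(xs), m))
    base_value = float(np.mean(predict(bg)))
    values = np.zeros((len(xs), len(subsets)))
    for si, s in enumerate(subsets):
        mask = np.array(s, dtype=bool)
        if not mask.any():
            values[:, si] = base_value
            continue
        hybrid = np.repeat(bg[None, :, :], len(xs), axis=0)
        hybrid[:, :, mask] = xs[:, None, mask]
        preds = predict(hybrid.reshape(-1, m)).reshape(len(xs), n_bg)
        values[:, si] = preds.mean(axis=1)

    index = {s: i for i, s in enumerate(subsets)}
    for s in subsets:
        size = sum(s)
        if size == m:
            continue
        w = fact[size] * fact[m - size - 1] / fact[m]
        for j in range(m):
            if s[j]:
                continue
            s_with = tuple(1 if i == j else v for i, v in enumerate(s))
            attributions[:, j] += w * (values[:, index[s_with]] - values[:, index[s]])
    return {"attributions": attributions, "base_value": base_value,
            "prediction": values[:, index[tuple([1] * m)]]}


# --------------------------------------------------------------------------
# thresholds / survival

def youden_cutoff(scores_train, labels_train) -> float:
    """argmax of (sensitivity + specificity − 1) over observed score midpoints.

    Ties resolve to the lower threshold. A degenerate single-value score
    vector returns that value with a warning (J = 0 there).
    """
    s = np.asarray(scores_train, dtype=float)
    y = np.asarray(labels_train).astype(int)
    uniq = np.unique(s)
    if len(uniq) == 1:
        warnings.warn("all scores identical; Youden index is 0 at the only midpoint")
        return float(uniq[0])
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    npos = max((y == 1).sum(), 1)
    nneg = max((y == 0).sum(), 1)
    best_t, best_j = mids[0], -np.inf
    for t in mids:
        pred = s >= t
        j = (pred & (y == 1)).sum() / npos + (~pred & (y == 0)).sum() / nneg - 1.0
        if j > best_j + 1e-15:
            best_j, best_t = j, t
    return float(best_t)


def km_logrank(times, events, groups) -> dict:
    """Kaplan-Meier curves per group + two-group log-rank test.

    Median survival is the first observed time with S(t) ≤ 0.5 (NaN sentinel
    if the curve never reaches 0.5).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    g = np.asarray(groups)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"expected two groups, got {len(labels)}")
    curves = {}
    medians = {}
    for lab in labels:
        sel = g == lab
        if not sel.any():
            raise ValueError(f"empty group {lab}")
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        sf = kmf.survival_function_.iloc[:, 0]
        curves[lab] = pd.DataFrame({"time": sf.index.to_numpy(),
                                    "survival": sf.to_numpy()})
        below = sf[sf <= 0.5]
        medians[lab] = float(below.index[0]) if len(below) else UNDEFINED
    res = _ll_logrank(t[g == labels[0]], t[g == labels[1]],
                      e[g == labels[0]], e[g == labels[1]])
    return {"curves": curves, "medians": medians,
            "chi2": float(res.test_statistic), "p": float(res.p_value)}


# --------------------------------------------------------------------------
# baseline table

def baseline_table_tests(cohort: pd.DataFrame, grouping,
                         continuous: list[str], categorical: list[str]) -> pd.DataFrame:
    """Per-variable between-group p-values, Table-1 style.

    Continuous: Welch t when both groups pass Shapiro-Wilk (α = 0.05), else
    Mann-Whitney U. Categorical: chi-square, switching to Fisher's exact test
    when any expected cell count is < 5 (2×2 tables only — larger sparse
    tables stay on chi-square, flagged in the ``note`` column).
    """
    y = np.asarray(grouping)
    glabels = np.unique(y)
    if len(glabels) != 2:
        raise ValueError("grouping must have two levels")
    rows = []
    for var in continuous:
        x = cohort[var].to_numpy(dtype=float)
        a, b = x[y == glabels[0]], x[y == glabels[1]]
        normal = True
        for grp in (a, b):
            if len(grp) < 3 or np.ptp(grp) <= 0:
                normal = False
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if stats.shapiro(grp).pvalue < 0.05:
                    normal = False
                    break
        if normal:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            test = "t"
        else:
            if np.ptp(x) <= 0:
                p, test = 1.0, "mwu"
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                test = "mwu"
        rows.append({"variable": var, "test": test, "p": p, "note": ""})
    for var in categorical:
        tab = pd.crosstab(cohort[var], y).to_numpy()
        if tab.shape[0] < 2:
            rows.append({"variable": var, "test": "none", "p": 1.0,
                         "note": "single level"})
            continue
        expected = stats.contingency.expected_freq(tab)
        note = ""
        if (expected < 5).any() and tab.shape == (2, 2):
            p = float(stats.fisher_exact(tab)[1])
            test = "fisher"
        else:
            if (expected < 5).any():
                note = "sparse cells; chi-square retained (no RxC exact test)"
            p = float(stats.chi2_contingency(tab)[1])
            test = "chi2"
        rows.append({"variable": var, "test": test, "p": p, "note": note})
    return pd.DataFrame(rows)
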