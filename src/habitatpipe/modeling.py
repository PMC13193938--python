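"""Classifier training: SMOTE, per-region candidate models, clinical model, stacking.

The modeled positive class throughout is non-response (ORR−), matching the
interpretation of the per-patient force attributions as "predicted
probability of non-response"; AUC is symmetric to this choice. Candidate
algorithms per region are Random Forest, XGBoost, multilayer perceptron and
Extra Trees, each tuned by stratified five-fold grid search (AUC objective)
with SMOTE applied inside training folds only, then refit on the full
SMOTE-augmented training cohort. The winner per region is the candidate with
the highest internal-validation AUC (ties: higher accuracy, then a fixed
algorithm order). The combined model is a logistic stacker over out-of-fold
training probabilities of the two best radiomics models plus the clinical
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

__all__ = [
    "ModelBundle",
    "smote_oversample",
    "train_candidates",
    "select_best",
    "clinical_model",
    "stack_combined",
    "oof_probabilities",
    "repeated_cv_stability",
    "DEFAULT_GRIDS",
]

ALGORITHM_ORDER = ["rf", "xgb", "mlp", "extratrees", "logistic"]

DEFAULT_GRIDS = {
    "rf": [{"n_estimators": n, "max_depth": d}
           for n in (100, 300) for d in (3, 5, None)],
    "xgb": [{"n_estimators": n, "max_depth": d, "learning_rate": lr}
            for n in (100, 300) for d in (3, 5) for lr in (0.05, 0.1)],
    "mlp": [{"hidden_layer_sizes": h} for h in ((32,), (64, 32))],
    "extratrees": [{"n_estimators": n, "max_depth": d}
                   for n in (100, 300) for d in (3, 5, None)],
}


@dataclass
class ModelBundle:
    region: str
    algorithm: str
    hyperparameters: dict
    fitted_state: object
    training_seed: int
    cv_auc: float = float("nan")
    probabilities: dict = field(default_factory=dict)  # cohort -> array
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.fitted_state.predict_proba(x)[:, 1]
        return np.clip(p, 1e-6, 1 - 1e-6)


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "xgb":
        return XGBClassifier(random_state=seed, n_jobs=1, tree_method="hist",
                             eval_metric="logloss", verbosity=0, **params)
    if algorithm == "mlp":
        return MLPClassifier(random_state=seed, max_iter=500, **params)
    if algorithm == "extratrees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "logistic":
        return LogisticRegression(random_state=seed, max_iter=1000, **params)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def smote_oversample(features: np.ndarray, labels: np.ndarray, k: int = 5,
                     seed: int = 0):
    """SMOTE: upsample the minority class to parity by convex interpolation.

    Each synthetic sample is x + u·(x_nn − x) with u ~ U(0, 1) and x_nn one
    of the k nearest minority neighbours of x. Already-balanced input is
    returned unchanged.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE requires both classes present")
    if counts[0] == counts[1]:
        return x, y
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    xm = x[y == minority]
    if len(xm) < 2:
        raise ValueError("minority class too small for SMOTE (need >= 2)")
    k_eff = min(k, len(xm) - 1)
    if k_eff < k:
        warnings.warn(f"SMOTE neighbours reduced to {k_eff}")
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(xm)
    _, idx = nn.kneighbors(xm)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(xm), size=need)
    pick = rng.integers(1, k_eff + 1, size=need)
    u = rng.uniform(size=need)[:, None]
    neigh = xm[idx[base, pick]]
    synth = xm[base] + u * (neigh - xm[base])
    x_out = np.vstack([x, synth])
    y_out = np.concatenate([y, np.full(need, minority)])
    return x_out, y_out


def _grid_search(algorithm: str, grid: list[dict], x, y, seed: int,
                 n_folds: int = 5):
    """Stratified CV grid search with SMOTE inside training folds (AUC objective)."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    best = None
    for params in grid:
        aucs = []
        for tr, va in folds:
            xs, ys = smote_oversample(x[tr], y[tr], seed=seed)
            est = _make_estimator(algorithm, params, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(xs, ys)
            if len(np.unique(y[va])) < 2:
                continue
            aucs.append(roc_auc_score(y[va], est.predict_proba(x[va])[:, 1]))
        mean_auc = float(np.mean(aucs)) if aucs else 0.5
        key = (mean_auc, -grid.index(params))
        if best is None or key > best[0]:
            best = (key, params, mean_auc)
    return best[1], best[2]


def train_candidates(features, labels, region: str = "region",
                     algorithms=("rf", "xgb", "mlp", "extratrees"),
                     grids: dict | None = None, seed: int = 0) -> list[ModelBundle]:
    """Grid-search, then refit each candidate algorithm on the full training set."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    grids = grids or DEFAULT_GRIDS
    bundles = []
    for algo in algorithms:
        grid = grids.get(algo, [{}])
        if not grid:
            raise ValueError(f"degenerate (empty) grid for {algo}")
        params, cv_auc = _grid_search(algo, grid, x, y, seed)
        xs, ys = smote_oversample(x, y, seed=seed)
        est = _make_estimator(algo, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(xs, ys)
        bundles.append(ModelBundle(region=region, algorithm=algo,
                                   hyperparameters=dict(params),
                                   fitted_state=est, training_seed=seed,
                                   cv_auc=cv_auc))
    return bundles


def select_best(bundles: list[ModelBundle], features_val, labels_val) -> ModelBundle:
    """Highest internal-validation AUC; ties by accuracy, then algorithm order."""
    if not bundles:
        raise ValueError("no candidate bundles")
    y = np.asarray(labels_val).astype(int)
    scored = []
    for b in bundles:
        p = b.predict_proba(features_val)
        auc = roc_auc_score(y, p) if len(np.unique(y)) == 2 else 0.5
        acc = float(((p >= 0.5).astype(int) == y).mean())
        order = -ALGORITHM_ORDER.index(b.algorithm) if b.algorithm in ALGORITHM_ORDER else -99
        scored.append(((auc, acc, order), b))
        b.metadata["internal_auc"] = float(auc)
        b.metadata["internal_accuracy"] = acc
    return max(scored, key=lambda t: t[0])[1]


def clinical_model(cohort: pd.DataFrame, covariates: list[str], labels,
                   alpha: float = 0.05, seed: int = 0) -> ModelBundle:
    """Univariable → multivariable logistic screen, final unpenalized logistic fit.

    Covariates with univariable p < α enter a multivariable fit; those with
    multivariable p < α form the final model. With no survivor an
    intercept-only model is returned with a warning. Odds ratios with 95% CIs
    for the final fit are stored in ``metadata["odds_ratios"]``.
    """
    y = np.asarray(labels).astype(int)
    x = cohort[covariates].astype(float)
    uni_p = {}
    for c in covariates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, sm.add_constant(x[[c]])).fit(disp=0)
            uni_p[c] = float(res.pvalues[c])
        except Exception:
            uni_p[c] = 1.0
    survivors = [c for c in covariates if uni_p[c] < alpha]

    final = survivors
    multi_p = {}
    if len(survivors) > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(x[survivors])).fit(disp=0)
        multi_p = {c: float(res.pvalues[c]) for c in survivors}
        final = [c for c in survivors if multi_p[c] < alpha]
        if not final:  # keep the strongest multivariable predictor
            final = [min(multi_p, key=multi_p.get)]
    if not final:
        warnings.warn("no clinical covariate survived; intercept-only model")
        est = LogisticRegression(max_iter=1000)
        est.fit(np.zeros((len(y), 1)), y)
        bundle = ModelBundle(region="clinical", algorithm="logistic",
                             hyperparameters={}, fitted_state=est,
                             training_seed=seed,
                             metadata={"covariates": [], "univariable_p": uni_p})
        return bundle

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, sm.add_constant(x[final])).fit(disp=0)
    ors = {}
    ci = res.conf_int()
    for c in final:
        ors[c] = {"or": float(np.exp(res.params[c])),
                  "ci95": [float(np.exp(ci.loc[c, 0])), float(np.exp(ci.loc[c, 1]))],
                  "p": float(res.pvalues[c])}

    class _SMWrapper:
        def __init__(self, result, cols):
            self._res = result
            self._cols = cols

        def predict_proba(self, xx):
            xx = np.asarray(xx, dtype=float)
            lin = self._res.params.iloc[0] + xx @ self._res.params.iloc[1:].to_numpy()
            p = 1.0 / (1.0 + np.exp(-lin))
            return np.column_stack([1 - p, p])

    bundle = ModelBundle(region="clinical", algorithm="logistic",
                         hyperparameters={}, fitted_state=_SMWrapper(res, final),
                         training_seed=seed,
                         metadata={"covariates": final, "univariable_p": uni_p,
                                   "multivariable_p": multi_p, "odds_ratios": ors})
    return bundle


def oof_probabilities(algorithm: str, params: dict, features, labels,
                      seed: int = 0, n_folds: int = 5) -> np.ndarray:
    """Cross-fitted (out-of-fold) training probabilities for a frozen candidate."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    out = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, va in skf.split(x, y):
        xs, ys = smote_oversample(x[tr], y[tr], seed=seed)
        est = _make_estimator(algorithm, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(xs, ys)
        out[va] = est.predict_proba(x[va])[:, 1]
    return np.clip(out, 1e-6, 1 - 1e-6)


def stack_combined(p_a: np.ndarray, p_b: np.ndarray, p_clinical: np.ndarray,
                   labels_train, seed: int = 0,
                   input_names=("radiomics_a", "radiomics_b", "clinical")) -> ModelBundle:
    """Logistic stacker over three base probability vectors.

    Inputs should be out-of-fold training probabilities so the stacker does
    not learn resubstitution optimism. Coefficients are exported in
    ``metadata`` (nomogram data).
    """
    arrs = [np.asarray(p, dtype=float) for p in (p_a, p_b, p_clinical)]
    n = {len(a) for a in arrs} | {len(np.asarray(labels_train))}
    if len(n) != 1:
        raise ValueError("misaligned probability vectors / labels")
    x = np.column_stack(arrs)
    y = np.asarray(labels_train).astype(int)
    # near-unpenalized; the tiny ridge keeps non-informative (constant or
    # collinear) base probabilities identifiable with coefficient ~0
    est = LogisticRegression(C=1e3, max_iter=20000, tol=1e-10, random_state=seed)
    est.fit(x, y)
    meta = {"coefficients": dict(zip(input_names, est.coef_[0].tolist())),
            "intercept": float(est.intercept_[0]), "inputs": list(input_names)}
    return ModelBundle(region="combined", algorithm="logistic",
                       hyperparameters={"C": 1e3}, fitted_state=est,
                       training_seed=seed, metadata=meta)


def repeated_cv_stability(fit_predict, features, labels, folds: int = 5,
                          repeats: int = 10, seed: int = 0) -> np.ndarray:
    """AUC distribution of the frozen pipeline under repeated stratified CV.

    ``fit_predict(x_train, y_train, x_val) -> probabilities`` must refit the
    whole pipeline (selection included) on each training split.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    aucs = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for tr, va in skf.split(x, y):
            if len(np.unique(y[va])) < 2:
                continue
            p = fit_predict(x[tr], y[tr], x[va])
            aucs.append(roc_auc_score(y[va], p))
    return np.array(aucs)
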