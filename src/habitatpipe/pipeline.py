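"""End-to-end orchestration: simulate → preprocess → habitats → shells →
features → select → model → evaluate → survival, with a reproducible manifest.

Cohort design mirrors a two-center study: center 1 is split 7:3 into training
and internal-validation cohorts (stratified by ORR); center 2 is the external
test cohort. Re-running with the same config reproduces the manifest
bit-for-bit (wall time is logged separately, never in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import modeling as mo
from . import selection as se
from .habitat import assign_habitats, compute_local_features, fit_habitats
from .imaging import apply_window, peritumoral_shell, resample_isotropic, resample_mask
from .radiomics import RadiomicsConfig, extract_features
from .synthetic import SyntheticCohortSpec, cohort_table, generate_cohort

__all__ = ["RunConfig", "split_cohorts", "run_pipeline"]

CLINICAL_COVARIATES = ["Age", "BMI", "ECOG", "Child_Pugh", "BCLC",
                       "Tumor_size_cm", "AFP", "ALB", "PLT"]

# desk-scale hyperparameter grids for full cohort runs
PIPELINE_GRIDS = {
    "rf": [{"n_estimators": 100, "max_depth": d} for d in (3, None)],
    "xgb": [{"n_estimators": 100, "max_depth": 3, "learning_rate": lr}
            for lr in (0.05, 0.1)],
    "mlp": [{"hidden_layer_sizes": (32,)}],
    "extratrees": [{"n_estimators": 100, "max_depth": d} for d in (3, None)],
}


@dataclass
class RunConfig:
    seed: int = 0
    n_center1: int = 143
    n_center2: int = 70
    train_fraction: float = 0.7
    image_shape_mm: tuple = (48.0, 48.0, 48.0)
    tumor_radius_range_mm: tuple = (8.0, 12.0)
    shell_mm: tuple = (3.0, 9.0)
    k_range: tuple = (2, 10)
    radiomics_preset: str = "light"   # "light": original image; "full": +wavelet/log
    mrmr_m: int = 15
    algorithms: tuple = ("rf", "xgb", "mlp", "extratrees")
    rim_effect_size: float = 1.5
    habitat_effect_size: float = 1.0
    afp_effect: float = -0.8
    orr_prevalence: float = 0.52

    def radiomics_config(self) -> RadiomicsConfig:
        if self.radiomics_preset == "full":
            return RadiomicsConfig()
        return RadiomicsConfig(use_wavelet=False, use_logarithm=False)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("image_shape_mm", "tumor_radius_range_mm", "shell_mm",
                    "k_range", "algorithms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _child_seed(seed: int, k: int) -> int:
    return (seed * 1000003 + k) % (2 ** 31 - 1)


def split_cohorts(labels, ratio: float, seed: int):
    """Stratified train/internal split indices at the given training ratio.

    Per-class training counts follow largest-remainder rounding of
    ``round(n·ratio)`` total. If a split misses a class, the draw is repeated
    with stepped seeds (up to 100) before erroring.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < 10 and ratio < 1.0:
        raise ValueError("need at least 10 patients to split")
    if ratio >= 1.0:
        return np.arange(n), np.array([], dtype=int)
    n_train = int(round(n * ratio))
    for attempt in range(100):
        rng = np.random.default_rng(_child_seed(seed, attempt))
        train_idx = []
        # proportional per-class allocation, largest remainder
        classes = np.unique(y)
        quotas = {c: (y == c).sum() * n_train / n for c in classes}
        base = {c: int(np.floor(q)) for c, q in quotas.items()}
        leftover = n_train - sum(base.values())
        for c in sorted(classes, key=lambda c: -(quotas[c] - base[c])):
            if leftover <= 0:
                break
            base[c] += 1
            leftover -= 1
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            train_idx.extend(idx[: base[c]])
        train_idx = np.sort(np.array(train_idx))
        val_idx = np.setdiff1d(np.arange(n), train_idx)
        if (len(np.unique(y[train_idx])) == len(np.unique(y))
                and (len(val_idx) == 0 or len(np.unique(y[val_idx])) == len(np.unique(y)))):
            return train_idx, val_idx
    raise ValueError("could not produce a stratified split with both classes")


def _preprocess(patient, shell_mm):
    """Window the (already isotropic) volume and build peritumoral shells."""
    v = resample_isotropic(patient.volume, 1.0)
    tumor = resample_mask(patient.tumor_mask, 1.0)
    liver = resample_mask(patient.liver_mask, 1.0)
    excl = resample_mask(patient.exclusion_mask, 1.0)
    wv = apply_window(v)
    shells = {}
    for mm in shell_mm:
        shells[mm] = peritumoral_shell(tumor, liver, mm, exclusion=excl)
    return wv, tumor, shells


def _region_tables(patients, prepped, habitat_maps, k_star, shell_mm, rconfig):
    """Per-region radiomics feature tables (rows: patients)."""
    ids = [p.patient_id for p in patients]
    intra, hab, peri = {}, {}, {mm: {} for mm in shell_mm}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in patients:
            wv, tumor, shells = prepped[p.patient_id]
            intra[p.patient_id] = extract_features(wv, tumor, rconfig)
            hrow = {}
            hmap = habitat_maps[p.patient_id]
            for h in range(1, k_star + 1):
                mask = hmap.habitat_mask(h, wv.spacing)
                feats = extract_features(wv, mask, rconfig)
                hrow.update({f"{k}_h{h}": v for k, v in feats.items()})
            hab[p.patient_id] = hrow
            for mm in shell_mm:
                feats = extract_features(wv, shells[mm], rconfig)
                peri[mm][p.patient_id] = {f"{k}_peri{mm:g}mm": v
                                          for k, v in feats.items()}
    tables = {"intra": pd.DataFrame([intra[i] for i in ids], index=ids),
              "habitat": pd.DataFrame([hab[i] for i in ids], index=ids)}
    for mm in shell_mm:
        tables[f"peri{mm:g}"] = pd.DataFrame([peri[mm][i] for i in ids], index=ids)
    return tables


def _impute_with_train_means(table: pd.DataFrame, train_ids) -> tuple[pd.DataFrame, int]:
    """Replace NaN sentinels (too-small ROIs) with training-cohort means."""
    n_missing = int(table.isna().to_numpy().sum())
    if n_missing:
        means = table.loc[train_ids].mean(axis=0)
        table = table.fillna(means).fillna(0.0)
    return table, n_missing


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute all stages; returns a result dict and writes the manifest.

    The result carries the manifest (reproducible metadata + metrics), the
    per-cohort probabilities per model, signatures and evaluation tables.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate two centers -------------------------------------------
    spec1 = SyntheticCohortSpec(
        n_patients=config.n_center1, seed=_child_seed(config.seed, 1),
        image_shape_mm=config.image_shape_mm,
        tumor_radius_range_mm=config.tumor_radius_range_mm,
        rim_effect_size=config.rim_effect_size,
        habitat_effect_size=config.habitat_effect_size,
        afp_effect=config.afp_effect, orr_prevalence=config.orr_prevalence,
        center=1)
    spec2 = replace(spec1, n_patients=config.n_center2,
                    seed=_child_seed(config.seed, 2), center=2)
    center1 = generate_cohort(spec1)
    center2 = generate_cohort(spec2)

    y1 = np.array([p.orr_label for p in center1])
    tr_idx, iv_idx = split_cohorts(y1, config.train_fraction,
                                   _child_seed(config.seed, 3))
    cohorts = {
        "train": [center1[i] for i in tr_idx],
        "internal": [center1[i] for i in iv_idx],
        "external": center2,
    }
    all_patients = cohorts["train"] + cohorts["internal"] + cohorts["external"]
    ids = {name: [p.patient_id for p in ps] for name, ps in cohorts.items()}

    # --- preprocess ------------------------------------------------------
    prepped = {}
    for p in all_patients:
        try:
            prepped[p.patient_id] = _preprocess(p, config.shell_mm)
        except Exception as exc:
            raise RuntimeError(f"stage=preprocess patient={p.patient_id}: {exc}") from exc

    # --- habitats --------------------------------------------------------
    blocks = {}
    for p in all_patients:
        wv, tumor, _ = prepped[p.patient_id]
        try:
            blocks[p.patient_id] = compute_local_features(wv, tumor)
        except Exception as exc:
            raise RuntimeError(f"stage=local_features patient={p.patient_id}: {exc}") from exc
    k_star, hmodel = fit_habitats([blocks[i] for i in ids["train"]],
                                  k_range=range(config.k_range[0], config.k_range[1] + 1),
                                  seed=_child_seed(config.seed, 4))
    habitat_maps = {p.patient_id: assign_habitats(hmodel, blocks[p.patient_id],
                                                  prepped[p.patient_id][1])
                    for p in all_patients}

    # --- radiomics -------------------------------------------------------
    rconfig = config.radiomics_config()
    tables = _region_tables(all_patients, prepped, habitat_maps, k_star,
                            config.shell_mm, rconfig)

    clin = cohort_table(all_patients).set_index("patient_id")
    # modeled positive class is non-response (ORR−)
    y = {name: (1 - clin.loc[ids[name], "ORR"].to_numpy()).astype(int)
         for name in cohorts}

    # --- selection + candidate models per region -------------------------
    region_names = list(tables)
    signatures, best_bundles, candidates = {}, {}, {}
    imputed_counts, stage_counts = {}, {}
    norm_tables = {}
    for region in region_names:
        table, n_missing = _impute_with_train_means(tables[region], ids["train"])
        imputed_counts[region] = n_missing
        train_z, (internal_z, external_z), stats = se_zscore(
            table, ids["train"], ids["internal"], ids["external"])
        norm_tables[region] = {"train": train_z, "internal": internal_z,
                               "external": external_z}
        sig = se.run_cascade(train_z, y["train"], region=region,
                             seed=_child_seed(config.seed, 5),
                             mrmr_m=config.mrmr_m)
        signatures[region] = sig
        stage_counts[region] = {k: len(v) for k, v in sig.stage_log.items()}
        feats = sig.selected_features
        bundles = mo.train_candidates(
            train_z[feats].to_numpy(), y["train"], region=region,
            algorithms=config.algorithms, grids=PIPELINE_GRIDS,
            seed=_child_seed(config.seed, 6))
        candidates[region] = bundles
        best_bundles[region] = mo.select_best(
            bundles, internal_z[feats].to_numpy(), y["internal"])

    # --- clinical model ---------------------------------------------------
    clin_bundle = mo.clinical_model(clin.loc[ids["train"]], CLINICAL_COVARIATES,
                                    y["train"], seed=_child_seed(config.seed, 7))
    clin_covs = clin_bundle.metadata["covariates"]

    def clinical_probs(which):
        x = (clin.loc[ids[which], clin_covs].to_numpy(dtype=float)
             if clin_covs else np.zeros((len(ids[which]), 1)))
        return clin_bundle.predict_proba(x)

    # --- probabilities per cohort ----------------------------------------
    probs: dict[str, dict[str, np.ndarray]] = {}
    for region in region_names:
        feats = signatures[region].selected_features
        b = best_bundles[region]
        probs[region] = {name: b.predict_proba(norm_tables[region][name][feats].to_numpy())
                         for name in cohorts}
    probs["clinical"] = {name: clinical_probs(name) for name in cohorts}

    # --- stacking ---------------------------------------------------------
    peri_regions = [r for r in region_names if r.startswith("peri")]
    intra_family = [r for r in region_names if not r.startswith("peri")]
    best_intra = max(intra_family,
                     key=lambda r: best_bundles[r].metadata["internal_auc"])
    best_peri = max(peri_regions,
                    key=lambda r: best_bundles[r].metadata["internal_auc"])

    oof = {}
    for region in (best_intra, best_peri):
        b = best_bundles[region]
        feats = signatures[region].selected_features
        oof[region] = mo.oof_probabilities(
            b.algorithm, b.hyperparameters,
            norm_tables[region]["train"][feats].to_numpy(), y["train"],
            seed=_child_seed(config.seed, 8))
    oof["clinical"] = mo.oof_probabilities(
        "logistic", {},
        clin.loc[ids["train"], clin_covs].to_numpy(dtype=float)
        if clin_covs else np.zeros((len(ids["train"]), 1)),
        y["train"], seed=_child_seed(config.seed, 8))

    combined = mo.stack_combined(oof[best_intra], oof[best_peri],
                                 oof["clinical"], y["train"],
                                 seed=_child_seed(config.seed, 9),
                                 input_names=(best_intra, best_peri, "clinical"))
    probs["combined"] = {
        name: combined.predict_proba(np.column_stack([
            probs[best_intra][name], probs[best_peri][name],
            probs["clinical"][name]]))
        for name in cohorts
    }

    # --- evaluation -------------------------------------------------------
    model_names = region_names + ["clinical", "combined"]
    metrics = {}
    thresholds = {}
    for model in model_names:
        thresholds[model] = ev.youden_cutoff(probs[model]["train"], y["train"])
        metrics[model] = {}
        for name in cohorts:
            r = ev.roc_auc(probs[model][name], y[name])
            cm = ev.confusion_metrics(probs[model][name], y[name], thresholds[model])
            metrics[model][name] = {
                "auc": round(r["auc"], 10), "auc_ci95": [round(v, 10) for v in r["ci95"]],
                "accuracy": cm["accuracy"], "sensitivity": cm["sensitivity"],
                "specificity": cm["specificity"], "ppv": cm["ppv"], "npv": cm["npv"],
            }
    delong = {name: {m: round(ev.delong_test(probs["combined"][name], probs[m][name],
                                             y[name])["p"], 10)
                     for m in model_names if m != "combined"}
              for name in ("internal", "external")}
    nri_idi = {name: {m: {k: round(v, 10) for k, v in
                          ev.nri_idi(probs[m][name], probs["combined"][name],
                                     y[name]).items()}
                      for m in model_names if m != "combined"}
               for name in ("internal", "external")}

    # --- survival ---------------------------------------------------------
    cutoff = thresholds["combined"]
    survival = {}
    for name in cohorts:
        sub = clin.loc[ids[name]]
        high = probs["combined"][name] >= cutoff  # high predicted non-response risk
        if len(np.unique(high)) == 2:
            km = ev.km_logrank(sub["PFS_months"].to_numpy(),
                               sub["PFS_event"].to_numpy(),
                               np.where(high, "high", "low"))
            survival[name] = {"medians": {k: round(v, 6) if np.isfinite(v) else None
                                          for k, v in km["medians"].items()},
                              "logrank_chi2": round(km["chi2"], 10),
                              "logrank_p": round(km["p"], 10)}
        else:
            survival[name] = {"medians": None, "logrank_chi2": None,
                              "logrank_p": None, "note": "single risk group"}

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "cohort_sizes": {k: len(v) for k, v in cohorts.items()},
        "orr_rates": {k: round(float(clin.loc[ids[k], "ORR"].mean()), 10)
                      for k in cohorts},
        "k_star": int(k_star),
        "ch_scores": {int(k): round(float(v), 10)
                      for k, v in hmodel.ch_scores.items()},
        "stage_feature_counts": stage_counts,
        "imputed_feature_values": imputed_counts,
        "best_algorithms": {r: best_bundles[r].algorithm for r in region_names},
        "stacked_inputs": [best_intra, best_peri, "clinical"],
        "clinical_covariates": clin_covs,
        "youden_thresholds": {m: round(t, 10) for m, t in thresholds.items()},
        "metrics": metrics,
        "delong_p_combined_vs": delong,
        "nri_idi_combined_vs": nri_idi,
        "survival": survival,
    }
    if out is not None:
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1))
        cohort_col = pd.Series({pid: name for name in cohorts for pid in ids[name]},
                               name="cohort")
        clin.join(cohort_col).to_csv(out / "clinical.csv")
        rows = []
        for model in model_names:
            for name in cohorts:
                for pid, p in zip(ids[name], probs[model][name]):
                    rows.append({"patient_id": pid, "cohort": name,
                                 "model": model, "probability": p})
        pd.DataFrame(rows).to_csv(out / "probabilities.csv", index=False)
        sig_blob = {r: {"features": s.selected_features,
                        "coefficients": s.coefficients.tolist(),
                        "intercept": s.intercept, "lambda": s.lambda_star,
                        "stage_log": {k: len(v) for k, v in s.stage_log.items()}}
                    for r, s in signatures.items()}
        (out / "signatures.json").write_text(json.dumps(sig_blob, sort_keys=True,
                                                        indent=1))

    return {"manifest": manifest, "probabilities": probs, "labels": y,
            "cohort_ids": ids, "signatures": signatures,
            "best_bundles": best_bundles, "candidates": candidates,
            "clinical_bundle": clin_bundle, "combined_bundle": combined,
            "habitat_model": hmodel, "tables": tables, "clinical_table": clin}


def se_zscore(table: pd.DataFrame, train_ids, internal_ids, external_ids):
    """Region-table z-scoring with training statistics only."""
    from .radiomics import zscore_fit_apply

    train = table.loc[train_ids]
    internal = table.loc[internal_ids]
    external = table.loc[external_ids]
    train_z, (internal_z, external_z), stats = zscore_fit_apply(
        train, internal, external)
    return train_z, (internal_z, external_z), stats
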