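"""Evaluate the fitted models from the pipeline artifacts and stratify survival.

Reads results/pipeline/ (probabilities + clinical table), recomputes ROC/
DeLong comparisons, NRI/IDI of the combined model over each base model,
calibration and decision curves, then applies the training-cohort Youden
cutoff of the combined model to split each cohort into high/low risk and
runs Kaplan-Meier / log-rank. Tidy CSVs land in results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from habitatpipe.evaluation import (
    calibration_curve,
    decision_curve,
    delong_test,
    km_logrank,
    nri_idi,
    roc_auc,
    roc_points,
    youden_cutoff,
)

BASE = Path(__file__).resolve().parents[1] / "results"
RUN = BASE / "pipeline"


def main() -> None:
    probs = pd.read_csv(RUN / "probabilities.csv")
    clin = pd.read_csv(RUN / "clinical.csv", index_col=0)
    # modeled positive class is non-response
    clin["y"] = 1 - clin["ORR"]

    wide = probs.pivot_table(index="patient_id", columns="model",
                             values="probability")
    wide = wide.join(clin[["cohort", "y", "PFS_months", "PFS_event"]])
    models = [m for m in probs["model"].unique()]

    rows = []
    for cohort, sub in wide.groupby("cohort"):
        for model in models:
            r = roc_auc(sub[model], sub["y"])
            rows.append({"cohort": cohort, "model": model, "auc": r["auc"],
                         "ci_lo": r["ci95"][0], "ci_hi": r["ci95"][1]})
    auc_table = pd.DataFrame(rows)
    auc_table.to_csv(BASE / "auc_table.csv", index=False)
    print("AUC (95% CI) by cohort:")
    for _, r in auc_table.iterrows():
        print(f"  {r['cohort']:9s} {r['model']:10s} "
              f"{r['auc']:.3f} ({r['ci_lo']:.3f}-{r['ci_hi']:.3f})")

    # combined vs each base model on the held-out cohorts
    rows = []
    for cohort in ("internal", "external"):
        sub = wide[wide.cohort == cohort]
        for model in models:
            if model == "combined":
                continue
            d = delong_test(sub["combined"], sub[model], sub["y"])
            ni = nri_idi(sub[model], sub["combined"], sub["y"])
            rows.append({"cohort": cohort, "vs": model, "delong_p": d["p"],
                         "nri": ni["nri"], "idi": ni["idi"]})
    pd.DataFrame(rows).to_csv(BASE / "combined_vs_bases.csv", index=False)

    train = wide[wide.cohort == "train"]
    roc_points(train["combined"], train["y"]).to_csv(
        BASE / "roc_combined_train.csv", index=False)
    cal = calibration_curve(train["combined"], train["y"])
    cal["bins"].to_csv(BASE / "calibration_combined_train.csv", index=False)
    decision_curve(train["combined"], train["y"]).to_csv(
        BASE / "dca_combined_train.csv", index=False)
    print(f"calibration slope (train, combined): {cal['slope']:.2f}")

    # survival stratification at the training Youden cutoff
    cutoff = youden_cutoff(train["combined"], train["y"])
    print(f"Youden cutoff (combined, training cohort): {cutoff:.3f}")
    km_rows = []
    for cohort, sub in wide.groupby("cohort"):
        groups = np.where(sub["combined"] >= cutoff, "high", "low")
        if len(np.unique(groups)) < 2:
            continue
        km = km_logrank(sub["PFS_months"], sub["PFS_event"], groups)
        km_rows.append({"cohort": cohort,
                        "median_high": km["medians"].get("high"),
                        "median_low": km["medians"].get("low"),
                        "logrank_p": km["p"]})
        print(f"  {cohort:9s} median PFS high-risk "
              f"{km['medians'].get('high'):.1f} vs low-risk "
              f"{km['medians'].get('low'):.1f} months (log-rank p={km['p']:.4f})")
    pd.DataFrame(km_rows).to_csv(BASE / "km_stratification.csv", index=False)
    print(f"wrote evaluation tables to {BASE}")


if __name__ == "__main__":
    main()
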