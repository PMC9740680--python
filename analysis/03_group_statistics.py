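#!/usr/bin/env python
"""Group comparisons and ROC analysis of the sensor features.

For each tube type, compares the inflammatory and infectious classes
(Mann-Whitney U on per-sample means) and evaluates each feature as a
predictor of infectious fluid (AUC with Hanley-McNeil SE and 95% CI,
infectious positive, higher value more positive -- the viscosity feature
therefore lands below 0.5).  Writes summary tables, ROC curve coordinates
and a curve figure under results/.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from qcrvisc.cohort import default_config, generate_cohort
from qcrvisc.seeding import stage_seed
from qcrvisc.stats import roc_auc, summary_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--mode", choices=["per_sample", "per_point"], default="per_sample")
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "figures").mkdir(exist_ok=True)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5), sharey=True)
    for ax, tube in zip(axes, ("edta", "heparin")):
        rows = generate_cohort(default_config(tube, seed=stage_seed(args.seed, f"cohort:{tube}")))
        table = summary_table(rows, mode=args.mode)
        table.to_csv(args.out / f"summary_{tube}.csv", index=False)
        print(f"\n=== {tube} ({args.mode}) ===")
        print(table[["feature", "mean_inflammatory", "mean_infectious",
                     "p_value", "auc", "auc_ci_low", "auc_ci_high"]].to_string(index=False))

        curves = []
        agg = rows.groupby(["sample_id", "label"], as_index=False)[
            ["delta_f_hz", "delta_gamma_hz", "eta_mpas"]
        ].mean() if args.mode == "per_sample" else rows
        for feat in ("delta_f_hz", "delta_gamma_hz", "eta_mpas"):
            res = roc_auc(agg[feat], agg["label"], positive="infectious")
            ax.plot(res.fpr, res.tpr, label=f"{feat} (AUC {res.auc:.2f})")
            curves.append(pd.DataFrame({"feature": feat, "fpr": res.fpr, "tpr": res.tpr}))
        pd.concat(curves, ignore_index=True).to_csv(args.out / f"roc_{tube}.csv", index=False)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_title(tube)
        ax.set_xlabel("false positive rate")
        ax.legend(fontsize=8)
    axes[0].set_ylabel("true positive rate")
    fig.tight_layout()
    fig.savefig(args.out / "figures" / "roc_curves.png", dpi=150)
    print(f"\nROC curves written to {args.out / 'figures' / 'roc_curves.png'}")


if __name__ == "__main__":
    main()
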