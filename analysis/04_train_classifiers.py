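#!/usr/bin/env python
"""Train and evaluate the classifier grid on the synthetic cohorts.

For each tube type and for unbalanced/balanced input, trains the six
network configurations (1-2 hidden layers x 100/200/300 epochs), the linear
squared-hinge SVM and the 2171-tree random forest, and writes the accuracy
grid, per-scenario confusion matrices, training histories and a
training-curve figure (2 hidden layers, 200 epochs) under results/.

The full grid is 24 network fits and takes on the order of 15 minutes on a
single CPU; ``--quick`` restricts it to one configuration per tube.
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from qcrvisc.classify import MlpSpec, SplitSpec, run_experiment
from qcrvisc.cohort import default_config, generate_cohort
from qcrvisc.seeding import stage_seed


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--split", choices=["point", "grouped"], default="point")
    parser.add_argument("--quick", action="store_true")
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "figures").mkdir(exist_ok=True)

    mlp_grid = [(2, 200)] if args.quick else [(hl, ep) for hl in (1, 2) for ep in (100, 200, 300)]
    records = []
    for tube in ("edta", "heparin"):
        rows = generate_cohort(default_config(tube, seed=stage_seed(args.seed, f"cohort:{tube}")))
        for balance_name, balance in [("unbalanced", "none"), ("balanced", "before_split")]:
            for hl, ep in mlp_grid:
                rs = stage_seed(args.seed, f"mlp:{tube}:{balance_name}:{hl}:{ep}")
                res = run_experiment(
                    rows, "mlp",
                    mlp_spec=MlpSpec(hidden_layers=hl, epochs=ep, seed=rs),
                    split=SplitSpec(mode=args.split, seed=rs),
                    balance=balance, seed=rs,
                )
                _record(records, args.out, tube, balance_name, f"mlp_hl{hl}_e{ep}", res)
                if (hl, ep) == (2, 200):
                    _plot_history(res, args.out, tube, balance_name)
            for model in ("rf", "svm"):
                rs = stage_seed(args.seed, f"{model}:{tube}:{balance_name}")
                res = run_experiment(
                    rows, model,
                    split=SplitSpec(fractions=(0.85, 0.0, 0.15), mode=args.split, seed=rs),
                    balance=balance, seed=rs,
                )
                _record(records, args.out, tube, balance_name, model, res)

    grid = pd.DataFrame.from_records(records)
    grid.to_csv(args.out / "accuracy_table.csv", index=False)
    print(grid.pivot_table(index="model", columns=["tube", "balance"],
                           values="accuracy").round(3).to_string())
    print(f"\naccuracy grid written to {args.out / 'accuracy_table.csv'}")


def _record(records, out, tube, balance_name, name, res) -> None:
    tag = f"{name}_{tube}_{balance_name}"
    payload = {
        **res["confusion"].as_dict(),
        "accuracy": res["accuracy"],
        "accuracy_reported": res["accuracy_reported"],
        "n_test": res["n_test"],
    }
    (out / f"confusion_{tag}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    if res["history"] is not None:
        res["history"].to_frame().to_csv(out / f"history_{tag}.csv", index=False)
    records.append({"tube": tube, "balance": balance_name, "model": name,
                    "accuracy": res["accuracy"],
                    "accuracy_reported": res["accuracy_reported"]})
    print(f"{tag}: accuracy {res['accuracy']:.4f}")


def _plot_history(res, out, tube, balance_name) -> None:
    frame = res["history"].to_frame()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(frame["epoch"], frame["train_accuracy"], label="training")
    ax1.plot(frame["epoch"], frame["val_accuracy"], label="validation")
    ax1.set_xlabel("epoch"); ax1.set_ylabel("accuracy"); ax1.legend()
    ax2.plot(frame["epoch"], frame["train_loss"], label="training")
    ax2.plot(frame["epoch"], frame["val_loss"], label="validation")
    ax2.set_xlabel("epoch"); ax2.set_ylabel("cross-entropy loss"); ax2.legend()
    fig.suptitle(f"{tube}, {balance_name}, 2 hidden layers, 200 epochs")
    fig.tight_layout()
    fig.savefig(out / "figures" / f"training_curves_{tube}_{balance_name}.png", dpi=150)
    plt.close(fig)


if __name__ == "__main__":
    main()
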