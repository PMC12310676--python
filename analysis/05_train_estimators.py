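"""Train SVM and BPNN nitrogen estimators on all VNIR bands.

Splits each 100-sample stage 60/40 (one shared split per stage across
sensors and models), trains an RBF-kernel SVR with cross-validated
hyperparameters and a single-hidden-layer backpropagation network, and
writes the full sensor × model × stage × split accuracy report plus
measured-vs-predicted scatter data.
"""

import argparse
from pathlib import Path

import pandas as pd

from canopy2sat import SplitSpec, evaluate_all
from canopy2sat.sensors import SimulatedBandTable

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    tables: dict[str, dict[str, SimulatedBandTable]] = {}
    for path in sorted((RESULTS / "tables").glob("*_*.csv")):
        sensor, stage = path.stem.rsplit("_", 1)
        tables.setdefault(sensor, {})[stage] = SimulatedBandTable.from_csv(
            path, sensor=sensor
        )
    report = evaluate_all(tables, SplitSpec(seed=args.seed))
    out = RESULTS / "evaluation.csv"
    report.table.to_csv(out, index=False)
    print(f"wrote {out} ({len(report.table)} rows)\n")

    scatter_rows = []
    for (sensor, model, stage, split), (y, y_hat) in report.predictions.items():
        for yi, yh in zip(y, y_hat):
            scatter_rows.append(
                {"sensor": sensor, "model": model, "stage": stage,
                 "split": split, "measured": yi, "predicted": yh}
            )
    pd.DataFrame(scatter_rows).to_csv(RESULTS / "scatter.csv", index=False)

    pivot = report.table.pivot_table(
        index=["sensor", "model"], columns=["stage", "split"], values="r2"
    ).round(2)
    print("R² by sensor × model:")
    print(pivot.to_string())


if __name__ == "__main__":
    main()
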