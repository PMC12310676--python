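"""Aggregate the accuracy report: per-sensor means across stages.

Averages the SVM training/validation R² and RMSE over the three
phenological stages per sensor, the aggregation used to rank the sensors;
on the synthetic libraries the red-edge sensors (Sentinel-2, GF-6) come
out ahead of Landsat-8.
"""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "evaluation.csv")
    svm = table[table["model"] == "SVM"]
    rows = []
    for sensor, group in svm.groupby("sensor", sort=False):
        tr = group[group["split"] == "training"]
        va = group[group["split"] == "validation"]
        rows.append(
            {"sensor": sensor,
             "mean_r2_training": tr["r2"].mean(),
             "mean_rmse_training": tr["rmse"].mean(),
             "mean_r2_validation": va["r2"].mean(),
             "mean_rmse_validation": va["rmse"].mean()}
        )
    summary = pd.DataFrame(rows).sort_values("mean_r2_validation", ascending=False)
    out = RESULTS / "summary.csv"
    summary.to_csv(out, index=False)
    print("SVM accuracy averaged over stages (sorted by validation R²):")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
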