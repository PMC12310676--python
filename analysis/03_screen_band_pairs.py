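"""Screen every normalized-difference band pair against nitrogen.

For each sensor × stage band table, computes the Pearson correlation of
every unordered band pair's normalized difference with nitrogen, writes the
full |r|-sorted matrices, and prints the winning pair per sensor × stage —
on the synthetic libraries the winners concentrate in the red-edge/NIR
region, mirroring the planted signal.
"""

from pathlib import Path

import pandas as pd

from canopy2sat import screen_band_pairs
from canopy2sat.screening import screening_matrix_export
from canopy2sat.sensors import SimulatedBandTable

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for path in sorted((RESULTS / "tables").glob("*_*.csv")):
        sensor, stage = path.stem.rsplit("_", 1)
        table = SimulatedBandTable.from_csv(path, sensor=sensor)
        result = screen_band_pairs(table)
        screening_matrix_export(result, RESULTS / "screening" / path.name, sort=True)
        rows.append(
            {"sensor": sensor, "stage": stage, "band_i": result.best.band_i,
             "band_j": result.best.band_j, "r": result.best.r}
        )
        print(
            f"{sensor:9s} {stage}: best pair ({result.best.band_i}, "
            f"{result.best.band_j})  r = {result.best.r:+.3f}"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "screening" / "best_pairs.csv", index=False)


if __name__ == "__main__":
    main()
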