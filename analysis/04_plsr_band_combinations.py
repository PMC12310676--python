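"""PLSR band-combination ablations: what does removing a band cost?

For each sensor × stage table, fits NIPALS PLSR on all VNIR bands and on
every single-band-removal subset, reporting training R² and ΔR².  Prints
the red-edge removals for Sentinel-2, which carry the largest accuracy cost
on the synthetic libraries.
"""

from pathlib import Path

from canopy2sat import ablation_table
from canopy2sat.plsr import combination_reports_frame
from canopy2sat.sensors import SimulatedBandTable

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    reports = []
    for path in sorted((RESULTS / "tables").glob("*_*.csv")):
        sensor, _ = path.stem.rsplit("_", 1)
        table = SimulatedBandTable.from_csv(path, sensor=sensor)
        reports.extend(
            ablation_table(table, table.band_names, table.band_names)
        )
    frame = combination_reports_frame(reports)
    out = RESULTS / "plsr_combinations.csv"
    frame.to_csv(out, index=False)
    print(f"wrote {out} ({len(frame)} rows)\n")

    s2 = frame[frame["sensor"] == "sentinel2"]
    base = s2[s2["delta_r2"].isna()]
    print("Sentinel-2, all-band PLSR training R² per stage:")
    for row in base.itertuples():
        print(f"  {row.stage}: R² = {row.r2:.3f}")
    dropped_re = s2[
        s2["delta_r2"].notna()
        & ~s2["band_combination"].str.contains("RE1")
    ]
    print("cost of removing RE1 (ΔR²):")
    for row in dropped_re.itertuples():
        print(f"  {row.stage}: ΔR² = {row.delta_r2:+.3f}")


if __name__ == "__main__":
    main()
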