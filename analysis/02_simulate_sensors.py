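"""Convolve the smoothed libraries into satellite VNIR band tables.

Reads the smoothed stage libraries written by 01_simulate_libraries.py,
resamples each through the Landsat-8, Sentinel-2 and GF-6 spectral response
functions, and writes one band-table CSV per sensor × stage.  Prints the
retained band count per sensor (5 / 10 / 8).
"""

from pathlib import Path

from canopy2sat import load_sensor, read_library, simulate_sensor_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for sensor_key in ("landsat8", "sentinel2", "gf6"):
        sensor = load_sensor(sensor_key)
        for stage in ("NGS", "NSS", "ASS"):
            lib_dir = RESULTS / "smoothed" / stage
            lib = read_library(lib_dir / "spectra.csv", lib_dir / "metadata.csv")
            table = simulate_sensor_table(lib, sensor)
            table.to_csv(RESULTS / "tables" / f"{sensor_key}_{stage}.csv")
        print(f"{sensor.name}: {len(table.band_names)} VNIR bands -> {table.band_names}")
    print(f"band tables written under {RESULTS}/tables")


if __name__ == "__main__":
    main()
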