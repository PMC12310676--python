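"""Generate the three stage libraries and smooth them.

Creates a seeded 100-sample canopy spectral library per phenological stage
(NGS, NSS, ASS), applies Savitzky–Golay smoothing, writes both raw and
smoothed libraries under results/, and prints the per-stage nitrogen
statistics (mean / min / max, mg·g⁻¹).
"""

import argparse
from pathlib import Path

from canopy2sat import SmoothingConfig, generate_dataset, smooth_library, write_library

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n", type=int, default=100)
    args = parser.parse_args()

    for stage in ("NGS", "NSS", "ASS"):
        lib = generate_dataset(stage, args.n, args.seed)
        write_library(lib, RESULTS / "libraries" / stage)
        smoothed = smooth_library(lib, SmoothingConfig())
        write_library(smoothed, RESULTS / "smoothed" / stage)
        n = lib.nitrogen
        print(
            f"{stage}: n={len(lib)}  nitrogen mean={n.mean():.2f} "
            f"min={n.min():.2f} max={n.max():.2f} mg/g"
        )
    print(f"libraries written under {RESULTS}/libraries and {RESULTS}/smoothed")


if __name__ == "__main__":
    main()
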