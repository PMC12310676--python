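"""End-to-end orchestration: generate → smooth → resample → screen → PLSR → train.

One JSON config and one integer seed drive the whole analysis; every
intermediate artifact (library CSVs, band tables, screening CSVs,
combination-R² and accuracy reports, prediction scatter data) is written
under the output directory, and a manifest records the config hash, the
seed, and a SHA-256 checksum per file so reruns can be verified
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import Canopy2SatError, ConfigurationError
from .library import write_library
from .models import SplitSpec, evaluate_all
from .plsr import ablation_table, combination_reports_frame
from .preprocess import SmoothingConfig, smooth_library
from .screening import screen_band_pairs, screening_matrix_export
from .sensors import load_sensor, simulate_sensor_table
from .synth import Stage, generate_dataset

log = logging.getLogger(__name__)

DEFAULT_STAGES = ("NGS", "NSS", "ASS")
DEFAULT_SENSORS = ("landsat8", "sentinel2", "gf6")


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_per_stage: int = 100
    sensors: tuple[str, ...] = DEFAULT_SENSORS
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    out_dir: Path = Path("runs/default")
    r2_mode: str = "std"
    n_components: int | None = None  # PLSR latent variables; None → min(3, #bands)

    def __post_init__(self) -> None:
        self.stages = tuple(Stage.coerce(s).value for s in self.stages)
        self.out_dir = Path(self.out_dir)
        if self.n_per_stage != self.split.n_train + self.split.n_validation:
            raise ConfigurationError(
                "n_per_stage must equal split.n_train + split.n_validation"
            )
        for sensor in self.sensors:
            load_sensor(sensor)  # raises ConfigurationError naming the sensor

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = json.loads(path.read_text())
        smoothing = SmoothingConfig(**raw.get("smoothing", {}))
        split = SplitSpec(
            **{**raw.get("split", {}), "seed": int(raw.get("seed", 0))}
        )
        out_dir = path.parent / raw.get("out_dir", "run")
        return cls(
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", DEFAULT_STAGES)),
            n_per_stage=int(raw.get("n_per_stage", 100)),
            sensors=tuple(raw.get("sensors", DEFAULT_SENSORS)),
            smoothing=smoothing,
            split=split,
            out_dir=out_dir,
            r2_mode=raw.get("r2_mode", "std"),
            n_components=raw.get("n_components"),
        )

    def canonical(self) -> str:
        payload = {
            "seed": self.seed,
            "stages": list(self.stages),
            "n_per_stage": self.n_per_stage,
            "sensors": list(self.sensors),
            "smoothing": {"window": self.smoothing.window, "polyorder": self.smoothing.polyorder},
            "split": {"n_train": self.split.n_train, "n_validation": self.split.n_validation},
            "r2_mode": self.r2_mode,
            "n_components": self.n_components,
        }
        return json.dumps(payload, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# Bands counted as red edge for the default ablation, by bundled band name.
RED_EDGE_BANDS = ("RE1", "RE2", "RE3")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage of the analysis; returns the run manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def record(path: Path) -> None:
        artifacts.append(Path(path))

    try:
        # 1. synthetic libraries, then smoothing
        smoothed = {}
        for stage in config.stages:
            log.info("generate: stage %s, n=%d", stage, config.n_per_stage)
            lib = generate_dataset(stage, config.n_per_stage, config.seed)
            for p in write_library(lib, out / "libraries" / stage):
                record(p)
            sm = smooth_library(lib, config.smoothing)
            for p in write_library(sm, out / "smoothed" / stage):
                record(p)
            smoothed[stage] = sm

        # 2. sensor simulation
        tables: dict[str, dict[str, object]] = {}
        for sensor_key in config.sensors:
            sensor = load_sensor(sensor_key)
            tables[sensor_key] = {}
            for stage in config.stages:
                log.info("resample: %s × %s", sensor.name, stage)
                table = simulate_sensor_table(smoothed[stage], sensor)
                record(table.to_csv(out / "tables" / f"{sensor_key}_{stage}.csv"))
                tables[sensor_key][stage] = table

        # 3. band-pair screening
        best_rows = []
        for sensor_key in config.sensors:
            for stage in config.stages:
                result = screen_band_pairs(tables[sensor_key][stage])
                record(
                    screening_matrix_export(
                        result, out / "screening" / f"{sensor_key}_{stage}.csv", sort=True
                    )
                )
                best_rows.append(
                    {
                        "sensor": sensor_key,
                        "stage": stage,
                        "band_i": result.best.band_i,
                        "band_j": result.best.band_j,
                        "r": result.best.r,
                        "abs_r": result.best.abs_r,
                    }
                )
        best_path = out / "screening" / "best_pairs.csv"
        pd.DataFrame(best_rows).to_csv(best_path, index=False)
        record(best_path)

        # 4. PLSR combination/ablation reports (all bands, one removal per band)
        combo_reports = []
        for sensor_key in config.sensors:
            for stage in config.stages:
                table = tables[sensor_key][stage]
                combo_reports.extend(
                    ablation_table(
                        table,
                        base_bands=table.band_names,
                        removable=table.band_names,
                        n_components=config.n_components,
                    )
                )
        combos_path = out / "plsr_combinations.csv"
        combination_reports_frame(combo_reports).to_csv(combos_path, index=False)
        record(combos_path)

        # 5. SVM / BPNN accuracy over all VNIR bands
        log.info("train: %d sensors × 2 models × %d stages", len(config.sensors), len(config.stages))
        report = evaluate_all(tables, config.split, r2_mode=config.r2_mode)
        eval_path = out / "evaluation.csv"
        report.table.to_csv(eval_path, index=False)
        record(eval_path)
        for stage in config.stages:
            rows = []
            for (sensor, model, st, split), (y, y_hat) in report.predictions.items():
                if st != stage:
                    continue
                for yi, yh in zip(y, y_hat):
                    rows.append(
                        {"sensor": sensor, "model": model, "split": split,
                         "measured": yi, "predicted": yh}
                    )
            scatter_path = out / "scatter" / f"{stage}.csv"
            scatter_path.parent.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(rows).to_csv(scatter_path, index=False)
            record(scatter_path)
    except Canopy2SatError:
        raise
    except Exception as exc:  # surface the stage context, then abort
        raise Canopy2SatError(f"pipeline aborted: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "config": json.loads(config.canonical()),
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def report_summary(run_dir: str | Path) -> pd.DataFrame:
    """Per-sensor mean training/validation R² and RMSE across stages.

    The aggregate is the arithmetic mean over the phenological stages of the
    per-stage accuracy rows.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    eval_path = run_dir / "evaluation.csv"
    missing = [str(p) for p in (manifest_path, eval_path) if not p.exists()]
    if missing:
        raise Canopy2SatError(f"incomplete run, missing artifacts: {missing}")
    manifest = json.loads(manifest_path.read_text())
    absent = [
        rel for rel in manifest["files"] if not (run_dir / rel).exists()
    ]
    if absent:
        raise Canopy2SatError(f"incomplete run, missing artifacts: {absent}")

    table = pd.read_csv(eval_path)
    rows = []
    for sensor, group in table[table["model"] == "SVM"].groupby("sensor", sort=False):
        tr = group[group["split"] == "training"]
        va = group[group["split"] == "validation"]
        rows.append(
            {
                "sensor": sensor,
                "mean_r2_training": tr["r2"].mean(),
                "mean_rmse_training": tr["rmse"].mean(),
                "mean_r2_validation": va["r2"].mean(),
                "mean_rmse_validation": va["rmse"].mean(),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(run_dir / "summary.csv", index=False)
    return summary
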