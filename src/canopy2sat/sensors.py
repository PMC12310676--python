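"""Spectral response functions and hyperspectral → multispectral resampling.

Each simulated satellite band reflectance is the SRF-weighted mean of the
canopy spectrum,

    ρ_band = ∫ s(λ) ρ(λ) dλ / ∫ s(λ) dλ,

evaluated by the trapezoidal rule on the native 1-nm grid.  Range-defined
sensors (Landsat-8, GF-6) use boxcar responses over their published band
limits; Sentinel-2 publishes only band centers here, so its responses are
synthesized as gaussians, ``exp(−4 ln2 (λ−c)² / fwhm²)``, with editable
FWHM defaults in the bundled JSON config (15 nm for the red-edge bands).
Only the visible–near-infrared subset of bands is simulated: boxcar bands
fully inside 400–1000 nm (plus the 433–453 nm coastal band) and
center-defined bands with centers inside 400–1000 nm, which retains
5 Landsat-8, 10 Sentinel-2 and 8 GF-6 bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateBandError, FormatError
from .library import SpectralLibrary, Spectrum

#: VNIR retention window, nm.
VNIR_RANGE = (400.0, 1000.0)
#: Gaussian SRFs are truncated where the weight falls below this value.
GAUSSIAN_TRUNCATION = 1e-4

_BUNDLED = {"landsat8": "landsat8.json", "sentinel2": "sentinel2.json", "gf6": "gf6.json"}


@dataclass(frozen=True)
class BandDefinition:
    """One satellite band: a boxcar range or a gaussian center/FWHM."""

    name: str
    shape: str  # "boxcar" | "gaussian"
    lower: float | None = None
    upper: float | None = None
    center: float | None = None
    fwhm: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "boxcar":
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ConfigurationError(f"boxcar band {self.name!r} needs lower < upper")
            lo, hi = self.lower, self.upper
        elif self.shape == "gaussian":
            if self.center is None or self.fwhm is None or self.fwhm <= 0:
                raise ConfigurationError(f"gaussian band {self.name!r} needs center and fwhm > 0")
            lo = hi = self.center
        else:
            raise ConfigurationError(f"unknown band shape {self.shape!r}")
        if not (350.0 <= lo and hi <= 2500.0):
            raise ConfigurationError(f"band {self.name!r} outside 350–2500 nm")


@dataclass(frozen=True)
class SensorDefinition:
    name: str
    bands: tuple[BandDefinition, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate band names in sensor {self.name!r}")

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]


@dataclass(frozen=True)
class SRF:
    """A band's response sampled on the spectrum grid over its support."""

    band: BandDefinition
    grid: np.ndarray      # wavelengths (nm) over the band support
    weights: np.ndarray   # s(λ) ≥ 0, at least one strictly positive
    indices: slice = field(repr=False, default_factory=lambda: slice(None))  # position in the full grid


def load_sensor(source: str | Path) -> SensorDefinition:
    """Load a sensor definition from a bundled name or a JSON file path.

    Bundled names: ``landsat8``, ``sentinel2``, ``gf6``.
    """
    key = str(source).lower()
    if key in _BUNDLED:
        text = (
            resources.files("canopy2sat").joinpath(f"data/sensors/{_BUNDLED[key]}").read_text()
        )
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"unknown sensor {source!r}")
        text = path.read_text()
    try:
        payload = json.loads(text)
        bands = tuple(
            BandDefinition(
                name=b["name"],
                shape=b["shape"],
                lower=b.get("lower"),
                upper=b.get("upper"),
                center=b.get("center"),
                fwhm=b.get("fwhm"),
            )
            for b in payload["bands"]
        )
        return SensorDefinition(name=payload["name"], bands=bands)
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed sensor definition {source!r}: {exc}") from exc


def bundled_sensor_names() -> list[str]:
    return list(_BUNDLED)


def build_srf(band: BandDefinition, grid: np.ndarray) -> SRF:
    """Sample a band's response function on a uniform 1-nm grid."""
    grid = np.asarray(grid, dtype=float)
    steps = np.diff(grid)
    if grid.size < 2 or not np.allclose(steps, 1.0):
        raise ValueError("grid must be uniform at 1 nm")
    if band.shape == "boxcar":
        if band.lower < grid[0] or band.upper > grid[-1]:
            raise ValueError(f"band {band.name!r} support outside the spectrum grid")
        mask = (grid >= band.lower) & (grid <= band.upper)
        idx = np.flatnonzero(mask)
        weights = np.ones(idx.size)
    else:
        # half-width where exp(−4 ln2 d²/fwhm²) = truncation level
        half = band.fwhm * np.sqrt(np.log(1.0 / GAUSSIAN_TRUNCATION) / (4.0 * np.log(2.0)))
        if band.center - half < grid[0] or band.center + half > grid[-1]:
            raise ValueError(f"band {band.name!r} support outside the spectrum grid")
        w = np.exp(-4.0 * np.log(2.0) * ((grid - band.center) / band.fwhm) ** 2)
        idx = np.flatnonzero(w >= GAUSSIAN_TRUNCATION)
        weights = w[idx]
    if idx.size == 0 or not np.any(weights > 0):
        raise DegenerateBandError(f"band {band.name!r} has no positive weight on the grid")
    sl = slice(int(idx[0]), int(idx[-1]) + 1)
    return SRF(band=band, grid=grid[sl], weights=weights, indices=sl)


def resample_band(spectrum: Spectrum, srf: SRF) -> float:
    """SRF-weighted mean reflectance of one spectrum over one band."""
    denom = np.trapezoid(srf.weights, srf.grid)
    if denom <= 0:
        raise DegenerateBandError(f"band {srf.band.name!r} has zero total SRF weight")
    rho = spectrum.reflectance[srf.indices]
    if rho.shape != srf.grid.shape:
        raise ValueError("spectrum and SRF must share the grid over the band support")
    return float(np.trapezoid(srf.weights * rho, srf.grid) / denom)


def filter_vnir_bands(sensor: SensorDefinition) -> SensorDefinition:
    """Retain the visible–near-infrared band subset, preserving order.

    Boxcar bands are kept when their full range lies inside 400–1000 nm or
    when they are the 433–453 nm coastal band; gaussian bands are kept when
    their center lies inside 400–1000 nm.
    """
    lo, hi = VNIR_RANGE
    kept = []
    for band in sensor.bands:
        if band.shape == "boxcar":
            if (lo <= band.lower and band.upper <= hi) or (
                band.lower == 433 and band.upper == 453
            ):
                kept.append(band)
        else:
            if lo <= band.center <= hi:
                kept.append(band)
    return SensorDefinition(name=sensor.name, bands=tuple(kept))


@dataclass
class SimulatedBandTable:
    """Samples × simulated band reflectances for one sensor and stage."""

    sensor: str
    stage: str
    sample_ids: list[str]
    band_names: list[str]
    values: np.ndarray  # (n_samples, n_bands), each in [0, 1]
    nitrogen: np.ndarray  # mg·g⁻¹, aligned with sample_ids

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nitrogen = np.asarray(self.nitrogen, dtype=float)
        n, b = len(self.sample_ids), len(self.band_names)
        if self.values.shape != (n, b):
            raise ValueError("values must be (n_samples, n_bands)")
        if self.nitrogen.shape != (n,):
            raise ValueError("nitrogen must align with sample_ids")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("band reflectances must lie in [0, 1]")

    def select(self, bands: list[str]) -> np.ndarray:
        missing = [b for b in bands if b not in self.band_names]
        if missing:
            raise ValueError(f"unknown band name(s): {missing}")
        cols = [self.band_names.index(b) for b in bands]
        return self.values[:, cols]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.band_names)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "stage", self.stage)
        df.insert(2, "nitrogen_mg_per_g", self.nitrogen)
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, sensor: str = "") -> "SimulatedBandTable":
        df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
        fixed = ["sample_id", "stage", "nitrogen_mg_per_g"]
        if list(df.columns[:3]) != fixed:
            raise FormatError(f"band table must start with columns {fixed}")
        band_names = [str(c) for c in df.columns[3:]]
        stages = df["stage"].unique().tolist()
        return cls(
            sensor=sensor,
            stage=stages[0] if len(stages) == 1 else "mixed",
            sample_ids=df["sample_id"].tolist(),
            band_names=band_names,
            values=df[band_names].to_numpy(dtype=float),
            nitrogen=df["nitrogen_mg_per_g"].to_numpy(dtype=float),
        )


def simulate_sensor_table(
    library: SpectralLibrary, sensor: SensorDefinition
) -> SimulatedBandTable:
    """Convolve every spectrum in a library into a sensor's VNIR bands."""
    if len(library) == 0:
        raise ValueError("library is empty")
    vnir = filter_vnir_bands(sensor)
    srfs = [build_srf(band, library.wavelengths) for band in vnir.bands]
    values = np.empty((len(library), len(srfs)))
    for j, srf in enumerate(srfs):
        rho = library.reflectance[:, srf.indices]
        denom = np.trapezoid(srf.weights, srf.grid)
        values[:, j] = np.trapezoid(srf.weights * rho, srf.grid, axis=1) / denom
    stages = set(library.stages)
    return SimulatedBandTable(
        sensor=sensor.name,
        stage=library.stages[0] if len(stages) == 1 else "mixed",
        sample_ids=list(library.sample_ids),
        band_names=vnir.band_names,
        values=values,
        nitrogen=library.nitrogen.copy(),
    )
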