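"""Spectral containers and the CSV dialect for canopy spectral libraries.

A library is stored as two plain CSV files:

* ``spectra.csv`` — first column ``wavelength_nm`` (integer 1-nm grid,
  350–2500), one float column per sample named by ``sample_id``;
* ``metadata.csv`` — columns ``sample_id, stage, nitrogen_mg_per_g``, one
  row per sample, in the same order as the spectra columns.

The round trip through :func:`write_library` / :func:`read_library` is
lossless at full float precision (``repr`` formatting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError

#: Native acquisition grid: 350..2500 nm inclusive at 1 nm, 2151 points.
WAVELENGTH_GRID = np.arange(350, 2501, dtype=float)
N_WAVELENGTHS = WAVELENGTH_GRID.size


@dataclass(frozen=True)
class Spectrum:
    """One canopy reflectance curve on the 1-nm 350–2500 nm grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or refl.shape != wl.shape:
            raise ValueError("wavelengths and reflectance must be equal-length 1-D arrays")
        steps = np.diff(wl)
        if wl.size < 2 or not np.all(steps > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("wavelength grid must be uniform")
        if np.any(refl < 0) or np.any(refl > 1) or not np.all(np.isfinite(refl)):
            raise ValueError("reflectance must lie in [0, 1]")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def at(self, wavelength_nm: float) -> float:
        """Reflectance at the grid point nearest ``wavelength_nm``."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        return float(self.reflectance[idx])


@dataclass
class SpectralLibrary:
    """A set of canopy spectra with per-sample stage and nitrogen labels.

    ``reflectance`` is an ``(n_samples, n_wavelengths)`` array sharing the
    single ``wavelengths`` grid; ``nitrogen`` is mg·g⁻¹.
    """

    sample_ids: list[str]
    stages: list[str]
    nitrogen: np.ndarray
    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nitrogen = np.asarray(self.nitrogen, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise FormatError("sample_ids must be unique")
        if len(self.stages) != n or self.nitrogen.shape != (n,):
            raise ValueError("stage and nitrogen labels must match sample count")
        if self.reflectance.shape != (n, self.wavelengths.size):
            raise ValueError("reflectance must be (n_samples, n_wavelengths)")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.reflectance[i])

    def spectra(self) -> list[Spectrum]:
        return [self.spectrum(i) for i in range(len(self))]


def write_library(library: SpectralLibrary, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a library as ``spectra.csv`` + ``metadata.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spectra_path = out_dir / "spectra.csv"
    meta_path = out_dir / "metadata.csv"

    spectra = pd.DataFrame(
        library.reflectance.T, columns=library.sample_ids, copy=True
    )
    spectra.insert(0, "wavelength_nm", library.wavelengths)
    # %.17g round-trips float64 exactly
    spectra.to_csv(spectra_path, index=False, float_format="%.17g")

    meta = pd.DataFrame(
        {
            "sample_id": library.sample_ids,
            "stage": library.stages,
            "nitrogen_mg_per_g": library.nitrogen,
        }
    )
    meta.to_csv(meta_path, index=False, float_format="%.17g")
    return spectra_path, meta_path


def read_library(path_spectra: str | Path, path_metadata: str | Path) -> SpectralLibrary:
    """Read a library, validating grid uniformity and metadata completeness."""
    spectra = pd.read_csv(path_spectra, float_precision="round_trip")
    if spectra.columns[0] != "wavelength_nm":
        raise FormatError("first spectra column must be 'wavelength_nm'")
    wavelengths = spectra["wavelength_nm"].to_numpy(dtype=float)
    steps = np.diff(wavelengths)
    if wavelengths.size < 2 or not np.all(steps > 0) or not np.allclose(steps, steps[0]):
        raise FormatError("wavelength grid must be uniform and strictly increasing")

    sample_ids = [str(c) for c in spectra.columns[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"duplicate sample_id in spectra file: {dupes[0]}")

    meta = pd.read_csv(path_metadata, dtype={"sample_id": str}, float_precision="round_trip")
    required = {"sample_id", "stage", "nitrogen_mg_per_g"}
    if not required.issubset(meta.columns):
        raise FormatError(f"metadata must have columns {sorted(required)}")
    meta_ids = meta["sample_id"].tolist()
    if len(set(meta_ids)) != len(meta_ids):
        raise FormatError("duplicate sample_id in metadata")
    meta_by_id = meta.set_index("sample_id")
    missing = [s for s in sample_ids if s not in meta_by_id.index]
    if missing:
        raise FormatError(f"metadata missing sample_id: {missing[0]}")

    reflectance = spectra[sample_ids].to_numpy(dtype=float).T
    stages = [str(meta_by_id.loc[s, "stage"]) for s in sample_ids]
    nitrogen = np.array(
        [float(meta_by_id.loc[s, "nitrogen_mg_per_g"]) for s in sample_ids]
    )
    return SpectralLibrary(
        sample_ids=sample_ids,
        stages=stages,
        nitrogen=nitrogen,
        wavelengths=wavelengths,
        reflectance=reflectance,
    )


def library_from_spectra(
    sample_ids: Sequence[str],
    stages: Sequence[str],
    nitrogen: Sequence[float],
    spectra: Sequence[Spectrum],
) -> SpectralLibrary:
    """Assemble a library from per-sample :class:`Spectrum` objects."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, grid):
            raise FormatError("all spectra must share one wavelength grid")
    return SpectralLibrary(
        sample_ids=list(sample_ids),
        stages=list(stages),
        nitrogen=np.asarray(nitrogen, dtype=float),
        wavelengths=grid,
        reflectance=np.vstack([s.reflectance for s in spectra]),
    )
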