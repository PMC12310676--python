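"""Savitzky–Golay smoothing of canopy spectra.

Field ASD spectra are conventionally denoised before resampling; the
Savitzky–Golay filter (default 15-point window, cubic polynomial) is the
community default because it suppresses high-frequency noise while passing
polynomials up to the configured order through unchanged — the property the
tests assert.  Output is clipped to [0, 1] to keep the reflectance
invariant intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .library import SpectralLibrary, Spectrum


@dataclass(frozen=True)
class SmoothingConfig:
    window: int = 15
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if not (0 <= self.polyorder < self.window):
            raise ValueError("polyorder must be non-negative and < window")


def smooth_spectrum(spectrum: Spectrum, config: SmoothingConfig = SmoothingConfig()) -> Spectrum:
    """Savitzky–Golay filter one spectrum on its native grid."""
    if config.window > len(spectrum):
        raise ValueError(
            f"window ({config.window}) exceeds spectrum length ({len(spectrum)})"
        )
    smoothed = savgol_filter(spectrum.reflectance, config.window, config.polyorder)
    return Spectrum(spectrum.wavelengths, np.clip(smoothed, 0.0, 1.0))


def smooth_library(
    library: SpectralLibrary, config: SmoothingConfig = SmoothingConfig()
) -> SpectralLibrary:
    """Smooth every spectrum in a library, preserving ids and labels."""
    if config.window > library.wavelengths.size:
        raise ValueError("window exceeds spectrum length")
    smoothed = savgol_filter(library.reflectance, config.window, config.polyorder, axis=1)
    return SpectralLibrary(
        sample_ids=list(library.sample_ids),
        stages=list(library.stages),
        nitrogen=library.nitrogen.copy(),
        wavelengths=library.wavelengths.copy(),
        reflectance=np.clip(smoothed, 0.0, 1.0),
        meta={**library.meta, "smoothed": f"savgol({config.window},{config.polyorder})"},
    )
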