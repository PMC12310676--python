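"""Normalized-difference band-pair screening against nitrogen.

For every unordered pair of simulated bands (i before j in sensor order) the
index ``ND = (ρ_i − ρ_j)/(ρ_i + ρ_j)`` is computed per sample and correlated
with nitrogen by the Pearson product-moment coefficient.  The pair with the
largest |r| is the screening winner; signed r is retained so orientation can
be recovered, and ties on |r| break to the first pair in band order.

Samples whose denominator ρ_i + ρ_j is zero have an undefined index; those
samples are dropped pairwise from that pair's correlation and counted in
``n_missing``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ScreeningError,
    UndefinedCorrelationError,
    UndefinedIndexError,
)
from .sensors import SimulatedBandTable

log = logging.getLogger(__name__)


def nd_index(r_i: float | np.ndarray, r_j: float | np.ndarray) -> float | np.ndarray:
    """Normalized difference (ρ_i − ρ_j)/(ρ_i + ρ_j), in [−1, 1].

    Antisymmetric under argument swap; undefined when the sum is zero.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    if np.any(r_i < 0) or np.any(r_j < 0):
        raise ValueError("reflectances must be non-negative")
    total = r_i + r_j
    if np.any(total == 0):
        raise UndefinedIndexError("zero-sum denominator in normalized difference")
    out = (r_i - r_j) / total
    return float(out) if out.ndim == 0 else out


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient.

    Implemented from the definition with the square-rooted denominator
    √(Σ(x−x̄)² Σ(y−ȳ)²), so the result lies in [−1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0 or ssy == 0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    r = float(dx @ dy) / np.sqrt(ssx * ssy)
    return float(np.clip(r, -1.0, 1.0))


@dataclass(frozen=True)
class PairEntry:
    band_i: str
    band_j: str
    r: float
    n_samples: int
    n_missing: int = 0

    @property
    def abs_r(self) -> float:
        return abs(self.r)


@dataclass
class ScreenResult:
    """All band-pair correlations for one sensor × stage, plus the winner."""

    sensor: str
    stage: str
    entries: list[PairEntry]
    best: PairEntry

    def to_dataframe(self, sort: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "band_i": [e.band_i for e in self.entries],
                "band_j": [e.band_j for e in self.entries],
                "r": [e.r for e in self.entries],
                "abs_r": [e.abs_r for e in self.entries],
                "n_samples": [e.n_samples for e in self.entries],
                "n_missing": [e.n_missing for e in self.entries],
            }
        )
        if sort:
            df = df.sort_values("abs_r", ascending=False, kind="mergesort").reset_index(
                drop=True
            )
        return df


def screen_band_pairs(
    table: SimulatedBandTable, nitrogen: np.ndarray | None = None
) -> ScreenResult:
    """Correlate every unordered band pair's normalized difference with nitrogen.

    ``nitrogen`` defaults to the table's own labels and must align with its
    rows.  Produces B·(B−1)/2 entries for B bands; pairs whose index is
    undefined for every sample are skipped (all-skipped raises).
    """
    y = table.nitrogen if nitrogen is None else np.asarray(nitrogen, dtype=float)
    if y.shape != (len(table.sample_ids),):
        raise ValueError("nitrogen vector must align with table rows")
    entries: list[PairEntry] = []
    for i, j in combinations(range(len(table.band_names)), 2):
        ri, rj = table.values[:, i], table.values[:, j]
        total = ri + rj
        defined = total > 0
        n_missing = int(np.count_nonzero(~defined))
        if n_missing:
            log.warning(
                "pair (%s, %s): %d sample(s) with zero-sum denominator excluded",
                table.band_names[i],
                table.band_names[j],
                n_missing,
            )
        if np.count_nonzero(defined) < 3:
            continue
        nd = (ri[defined] - rj[defined]) / total[defined]
        try:
            r = pearson_r(nd, y[defined])
        except UndefinedCorrelationError:
            continue
        entries.append(
            PairEntry(
                band_i=table.band_names[i],
                band_j=table.band_names[j],
                r=r,
                n_samples=int(np.count_nonzero(defined)),
                n_missing=n_missing,
            )
        )
    if not entries:
        raise ScreeningError("no band pair produced a defined correlation")
    best = max(entries, key=lambda e: e.abs_r)  # max is stable: first pair wins ties
    return ScreenResult(sensor=table.sensor, stage=table.stage, entries=entries, best=best)


def screening_matrix_export(
    result: ScreenResult, path: str | Path, sort: bool = False
) -> Path:
    """Write a long-format CSV (band_i, band_j, r, abs_r, ...); lossless."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_dataframe(sort=sort).to_csv(path, index=False)
    return path


def read_screening(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
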