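"""Frequency grids, spectrum records and their CSV representation.

A sweep covers 10–30 kHz in 150 Hz steps, which yields 134 points (the last
one at 29.95 kHz, since the span is not an integer multiple of the step).
Each :class:`SpectrumRecord` holds one sweep plus the metadata needed to
place it in the three-day study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyGrid",
    "make_frequency_grid",
    "ScanMeta",
    "SpectrumRecord",
    "NormalizedSpectrum",
    "band_slice",
    "records_to_frame",
    "frame_to_records",
    "save_records_csv",
    "load_records_csv",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform frequency grid ``f_min + k*step`` for ``k = 0 .. n-1``."""

    f_min: float
    f_max: float
    step: float
    points: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("frequency step must be positive")
        if self.f_min >= self.f_max:
            raise ValueError("f_min must be below f_max")
        n = math.floor((self.f_max - self.f_min) / self.step) + 1
        pts = self.f_min + self.step * np.arange(n, dtype=float)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def index_of(self, f: float) -> int:
        """Index of the grid point nearest to ``f`` (must lie on the grid span)."""
        if not self.f_min <= f <= self.points[-1] + self.step / 2:
            raise ValueError(f"{f!r} Hz outside the grid span")
        return int(round((f - self.f_min) / self.step))


def make_frequency_grid(
    f_min: float = 10_000.0, f_max: float = 30_000.0, step: float = 150.0
) -> FrequencyGrid:
    """Build the sweep grid; the default reproduces the 134-point layout."""
    return FrequencyGrid(f_min=f_min, f_max=f_max, step=step)


@dataclass(frozen=True)
class ScanMeta:
    """Provenance of one sweep: phantom identity and acquisition context."""

    concentration: float
    day: int = 1
    round_index: int = 1
    sample_id: int = 1
    pressure: float = 6.0  # N/cm² applied to the sample


@dataclass(frozen=True)
class SpectrumRecord:
    """One frequency sweep of lock-in amplitudes (arbitrary units, >= 0)."""

    grid: FrequencyGrid
    amplitudes: np.ndarray
    meta: ScanMeta

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.shape != (len(self.grid),):
            raise ValueError(
                f"amplitudes length {amps.shape} does not match grid ({len(self.grid)})"
            )
        if np.any(amps < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "amplitudes", amps)

    def with_amplitudes(self, amplitudes: np.ndarray) -> "SpectrumRecord":
        return replace(self, amplitudes=np.asarray(amplitudes, dtype=float))


@dataclass(frozen=True)
class NormalizedSpectrum:
    """Carbon-normalized (dimensionless) spectrum; produced after rectification."""

    grid: FrequencyGrid
    amplitudes: np.ndarray
    meta: ScanMeta

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.shape != (len(self.grid),):
            raise ValueError("amplitudes length does not match grid")
        object.__setattr__(self, "amplitudes", amps)


def band_slice(grid: FrequencyGrid, f_lo: float, f_hi: float) -> slice:
    """Slice selecting grid points with ``f_lo <= f <= f_hi``."""
    if f_lo >= f_hi:
        raise ValueError("f_lo must be below f_hi")
    pts = grid.points
    if f_lo < pts[0] or f_hi > pts[-1]:
        raise ValueError("band outside the frequency grid")
    lo = int(np.searchsorted(pts, f_lo, side="left"))
    hi = int(np.searchsorted(pts, f_hi, side="right"))
    return slice(lo, hi)


_META_COLUMNS = ["day", "sample_id", "round", "concentration", "pressure"]


def records_to_frame(records: list[SpectrumRecord]) -> pd.DataFrame:
    """Tabulate records: metadata columns then one column per frequency (Hz)."""
    if not records:
        raise ValueError("no records to tabulate")
    grid = records[0].grid
    for rec in records:
        if not np.array_equal(rec.grid.points, grid.points):
            raise ValueError("records do not share a common frequency grid")
    meta = pd.DataFrame(
        {
            "day": [r.meta.day for r in records],
            "sample_id": [r.meta.sample_id for r in records],
            "round": [r.meta.round_index for r in records],
            "concentration": [r.meta.concentration for r in records],
            "pressure": [r.meta.pressure for r in records],
        }
    )
    amps = pd.DataFrame(
        np.vstack([r.amplitudes for r in records]),
        columns=[f"{f:.6g}" for f in grid.points],
    )
    return pd.concat([meta, amps], axis=1)


def frame_to_records(frame: pd.DataFrame) -> list[SpectrumRecord]:
    """Inverse of :func:`records_to_frame`."""
    freq_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    freqs = np.array([float(c) for c in freq_cols])
    step = float(np.median(np.diff(freqs))) if len(freqs) > 1 else 1.0
    grid = FrequencyGrid(
        f_min=float(freqs[0]), f_max=float(freqs[-1]) + step / 2, step=step
    )
    records = []
    for _, row in frame.iterrows():
        meta = ScanMeta(
            concentration=float(row["concentration"]),
            day=int(row["day"]),
            round_index=int(row["round"]),
            sample_id=int(row["sample_id"]),
            pressure=float(row["pressure"]),
        )
        records.append(
            SpectrumRecord(grid=grid, amplitudes=row[freq_cols].to_numpy(float), meta=meta)
        )
    return records


def save_records_csv(records: list[SpectrumRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def load_records_csv(path) -> list[SpectrumRecord]:
    return frame_to_records(pd.read_csv(path))
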