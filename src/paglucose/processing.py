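"""Classical signal chain: rectify, normalize, integrate, summarize.

The measurement suffers contact-induced frequency shifts, so before any
quantitative comparison all spectra are *rectified* — shifted by whole bins
so their in-band maxima coincide.  Each spectrum is then divided pointwise
by a glucose-independent carbon reference (system-response calibration) and
the 19–23 kHz band is integrated to a single mean amplitude per scan.  The
summary statistics are the mean adjacent-concentration resolution (percent
per 25 mg/dL step) and an ordinary least-squares calibration line with its
Pearson correlation.

A moving-median outlier filter (asymmetric window, scaled-MAD threshold) and
the background-suppression metric complete the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import NormalizedSpectrum, SpectrumRecord, band_slice

__all__ = [
    "CalibrationResult",
    "rectify",
    "normalize_by_reference",
    "integrate_band",
    "adjacent_resolution",
    "linear_calibration",
    "remove_outliers_moving_median",
    "suppression_percent",
]

#: Consistency factor making the median absolute deviation estimate the
#: standard deviation of a Gaussian.
MAD_SCALE = 1.4826


def rectify(
    records: list[SpectrumRecord], band: tuple[float, float] = (19_000.0, 23_000.0)
) -> list[SpectrumRecord]:
    """Align spectra so every in-band maximum sits at the same bin.

    The reference bin is the median of the in-band argmax positions across
    the record set (ties in a record's argmax break toward the lower
    frequency).  Each spectrum is shifted by whole bins; bins shifted in
    from outside the grid are padded with the edge value and never wrap
    into the analysis band.
    """
    if not records:
        raise ValueError("cannot rectify an empty record list")
    grid = records[0].grid
    sl = band_slice(grid, *band)
    argmaxes = np.array(
        [sl.start + int(np.argmax(r.amplitudes[sl])) for r in records]
    )
    ref_bin = int(np.floor(np.median(argmaxes)))
    out = []
    for rec, am in zip(records, argmaxes):
        shift = ref_bin - int(am)
        if shift == 0:
            out.append(rec)
            continue
        shifted = np.roll(rec.amplitudes, shift)
        if shift > 0:
            shifted[:shift] = rec.amplitudes[0]
        else:
            shifted[shift:] = rec.amplitudes[-1]
        out.append(rec.with_amplitudes(shifted))
    return out


def normalize_by_reference(
    record: SpectrumRecord, reference: SpectrumRecord
) -> NormalizedSpectrum:
    """Pointwise ratio of a spectrum to the carbon reference."""
    if not np.array_equal(record.grid.points, reference.grid.points):
        raise ValueError("record and reference are on different grids")
    if np.any(reference.amplitudes <= 0):
        raise ValueError("reference spectrum must be strictly positive")
    return NormalizedSpectrum(
        grid=record.grid,
        amplitudes=record.amplitudes / reference.amplitudes,
        meta=record.meta,
    )


def integrate_band(
    spectrum: NormalizedSpectrum | SpectrumRecord,
    f_lo: float = 19_000.0,
    f_hi: float = 23_000.0,
) -> float:
    """Trapezoidal band integral normalized by band width (a mean amplitude).

    The width normalization makes the value independent of the grid step, so
    resolution statistics computed from it are grid-free.
    """
    sl = band_slice(spectrum.grid, f_lo, f_hi)
    f = spectrum.grid.points[sl]
    if len(f) < 2:
        raise ValueError("band must contain at least two grid points")
    return float(np.trapezoid(spectrum.amplitudes[sl], f) / (f[-1] - f[0]))


def adjacent_resolution(areas_by_concentration: dict[float, float]) -> float:
    """Mean percent step between band integrals of adjacent concentrations.

    ``mean over adjacent pairs of 100·(area_{i+1} − area_i) / area_i`` with
    concentrations taken in increasing order.
    """
    items = sorted(areas_by_concentration.items())
    if len(items) < 2:
        raise ValueError("need at least two concentrations")
    concs = [c for c, _ in items]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("concentrations must be strictly increasing")
    areas = [a for _, a in items]
    if any(a == 0 for a in areas):
        raise ValueError("zero band integral: resolution undefined")
    steps = [100.0 * (b - a) / a for a, b in zip(areas, areas[1:])]
    return float(np.mean(steps))


@dataclass(frozen=True)
class CalibrationResult:
    """OLS calibration line of band integral versus concentration."""

    concentrations: np.ndarray
    integrals: np.ndarray
    slope: float
    intercept: float
    correlation_R: float

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.integrals):
            raise ValueError("length mismatch")
        if not -1.0 <= self.correlation_R <= 1.0 + 1e-12:
            raise ValueError("invalid correlation")


def linear_calibration(concentrations, areas) -> CalibrationResult:
    """Ordinary least-squares fit of band integrals against concentration."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(areas, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least three points for a calibration line")
    if np.ptp(c) == 0 or np.ptp(a) == 0:
        raise ValueError("zero variance in calibration inputs")
    fit = stats.linregress(c, a)
    return CalibrationResult(
        concentrations=c,
        integrals=a,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        correlation_R=float(fit.rvalue),
    )


def remove_outliers_moving_median(
    series,
    window_before: int = 10,
    window_after: int = 2,
    threshold: float = 2.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Flag and replace outliers against an asymmetric moving median.

    Point ``i`` is compared with the window running from ``window_before``
    points before it through ``window_after`` points after it (the point
    itself included; the window truncates at the series edges).  It is an
    outlier when it deviates from the window median by more than
    ``threshold`` times the scaled MAD (MAD × 1.4826) of the window.
    Flagged points are replaced by their window median.

    Returns ``(cleaned, mask)`` where ``mask[i]`` is True for outliers.
    """
    x = np.asarray(series, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if window_before < 0 or window_after < 0:
        raise ValueError("window sizes must be non-negative")
    n = len(x)
    if n <= window_before + window_after:
        raise ValueError("series shorter than the moving window")
    cleaned = x.copy()
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - window_before)
        hi = min(n, i + window_after + 1)
        window = x[lo:hi]
        med = np.median(window)
        sigma = MAD_SCALE * np.median(np.abs(window - med))
        if np.abs(x[i] - med) > threshold * sigma:
            mask[i] = True
            cleaned[i] = med
    return cleaned, mask


def suppression_percent(noisy: SpectrumRecord, damped: SpectrumRecord) -> float:
    """Mean-amplitude background suppression: ``100·(1 − mean(damped)/mean(noisy))``."""
    if not np.array_equal(noisy.grid.points, damped.grid.points):
        raise ValueError("spectra are on different grids")
    mean_noisy = float(np.mean(noisy.amplitudes))
    if mean_noisy == 0:
        raise ValueError("noisy spectrum has zero mean amplitude")
    return 100.0 * (1.0 - float(np.mean(damped.amplitudes)) / mean_noisy)
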