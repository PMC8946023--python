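"""Seeded generator for the three-day phantom glucose study.

The generator emulates the statistical structure of a frequency-swept
photoacoustic measurement of oil-in-gelatin skin phantoms:

* two resonant modes of the acoustic cell (16.50 and 21.80 kHz), modelled as
  power-Lorentzian lines on a small instrumental baseline;
* a glucose-dependent second line whose height grows affinely with
  concentration — 2.3 % of the base per 25 mg/dL step — driven through the
  physics amplitude law (absorption coefficient α scales with glucose);
* per-scan multiplicative coupling-gain jitter plus a per-(day, sample)
  offset, calibrated so the standard deviation of the carbon-normalized
  19–23 kHz band integral per concentration equals the study's measured
  values (``MEASURED_INTEGRAL_SD``);
* whole-spectrum contact-induced frequency shifts, iid per-bin microphone
  noise, and occasional short positive noise bursts (the outliers the
  moving-median preprocessing stage removes);
* amplitude saturation at the cell's amplification limit, and a pressure
  gain that doubles the signal between 0 and 9 N/cm².

All stochastic features switch off cleanly (``StudyPlan.noise_free``), in
which case the generated study is an exact, seed-independent function of the
plan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .physics import CellGeometry, LaserConfig, SampleOptics, pa_amplitude
from .spectra import (
    FrequencyGrid,
    NormalizedSpectrum,
    ScanMeta,
    SpectrumRecord,
    band_slice,
    make_frequency_grid,
)

__all__ = [
    "MEASURED_INTEGRAL_SD",
    "GLUCOSE_LEVELS",
    "PhantomSpec",
    "StudyPlan",
    "generate_spectrum",
    "generate_study",
    "generate_carbon_reference",
    "generate_background_pair",
    "noise_free_band_integral",
]

#: Glucose classes of the study: 75–300 mg/dL in 25 mg/dL steps.
GLUCOSE_LEVELS: tuple[float, ...] = tuple(float(c) for c in range(75, 301, 25))

#: Measured standard deviation of the carbon-normalized band integral per
#: concentration over the three-day study (dimensionless).
MEASURED_INTEGRAL_SD: dict[float, float] = {
    75.0: 2.55e-2,
    100.0: 2.71e-2,
    125.0: 3.10e-2,
    150.0: 2.69e-2,
    175.0: 2.76e-2,
    200.0: 3.11e-2,
    225.0: 2.64e-2,
    250.0: 2.54e-2,
    275.0: 2.17e-2,
    300.0: 1.94e-2,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Identity of one phantom scan: concentration, day and replicate."""

    concentration: float
    day: int = 1
    sample_id: int = 1

    def __post_init__(self) -> None:
        if self.concentration not in GLUCOSE_LEVELS:
            raise ValueError(
                f"concentration {self.concentration!r} not on the 75-300 mg/dL "
                "ladder (25 mg/dL steps)"
            )
        if self.day < 1:
            raise ValueError("day index starts at 1")


def _power_lorentzian(f: np.ndarray, f0: float, gamma: float) -> np.ndarray:
    """Power response of a resonant mode: 1 / (1 + u²)² with u=(f-f0)/γ."""
    u = (f - f0) / gamma
    return 1.0 / (1.0 + u * u) ** 2


@dataclass(frozen=True)
class StudyPlan:
    """Generative parameters of the full three-day experiment.

    The defaults reproduce the study design: 3 days × 10 rounds × 10
    concentrations at 6 N/cm² applied pressure, with per-concentration noise
    at the measured standard deviations.
    """

    days: int = 3
    rounds_per_day: int = 10
    concentrations: tuple[float, ...] = GLUCOSE_LEVELS
    pressure: float = 6.0
    noise_sd_by_concentration: dict[float, float] = field(
        default_factory=lambda: dict(MEASURED_INTEGRAL_SD)
    )
    #: fractional increase of the glucose line per 25 mg/dL step
    resolution_step: float = 0.023
    #: sd of the contact-induced whole-spectrum frequency shift (Hz)
    shift_sd: float = 15.0
    #: instrumental baseline of the cell response (arbitrary units)
    background_floor: float = 0.005
    #: day-effect sd as a fraction of the per-concentration noise sd
    day_effect_fraction: float = 1.0 / 3.0
    #: iid per-bin microphone/lock-in noise sd (arbitrary units)
    bin_noise_sd: float = 0.002
    #: probability that a scan carries a short environmental noise burst
    burst_rate: float = 0.06
    burst_width_bins: tuple[int, int] = (2, 3)
    burst_amplitude: tuple[float, float] = (0.5, 1.0)
    #: frequency range in which bursts occur (below the analysis band, where
    #: the first resonance amplifies ambient transients)
    burst_band: tuple[float, float] = (10_000.0, 19_000.0)
    #: heights of the 16.5 and 21.8 kHz lines at the lowest concentration
    line_heights: tuple[float, float] = (2.0, 3.0)
    #: carbon reference spectrum: baseline, line heights and width scale
    carbon_floor: float = 0.05
    carbon_heights: tuple[float, float] = (4.0, 0.8)
    carbon_width_scale: float = 2.2
    #: pressure at which the acoustic gain doubles (N/cm²)
    pressure_doubling: float = 9.0
    #: acoustic absorption panels installed (ambient background suppressed)
    panels_on: bool = True
    ambient_level: float = 0.05
    #: analysis band used for noise calibration (Hz)
    band: tuple[float, float] = (19_000.0, 23_000.0)
    grid: FrequencyGrid = field(default_factory=make_frequency_grid)
    laser: LaserConfig = field(default_factory=LaserConfig)
    #: sample optics at the lowest concentration; α scales affinely above it
    sample: SampleOptics = field(default_factory=SampleOptics)

    def __post_init__(self) -> None:
        if self.days < 1 or self.rounds_per_day < 1:
            raise ValueError("days and rounds_per_day must be at least 1")
        if not self.concentrations:
            raise ValueError("at least one concentration is required")
        for c in self.concentrations:
            if c not in self.noise_sd_by_concentration:
                raise ValueError(f"no noise sd configured for {c} mg/dL")
        if self.resolution_step < 0:
            raise ValueError("resolution_step must be non-negative")
        if self.pressure < 0:
            raise ValueError("pressure must be non-negative")

    # -- derived quantities -------------------------------------------------

    def pressure_gain(self) -> float:
        """Acoustic gain from contact pressure: 1 + p / p_double."""
        return 1.0 + self.pressure / self.pressure_doubling

    def glucose_gain(self, concentration: float) -> float:
        """Affine concentration → amplitude factor via the PA amplitude law.

        α(c) = α0·(1 + step·(c-75)/25); the amplitude law is linear in α, so
        the ratio to the base amplitude is exactly 1 + step·(c-75)/25.
        """
        k = (concentration - GLUCOSE_LEVELS[0]) / 25.0
        alpha_c = self.sample.alpha * (1.0 + self.resolution_step * k)
        cell = CellGeometry()
        sample_c = dc_replace(self.sample, alpha=alpha_c, mu_a=None)
        base = pa_amplitude(self.laser, self.sample, cell)
        return pa_amplitude(self.laser, sample_c, cell) / base

    def noise_free(self) -> "StudyPlan":
        """Copy of the plan with every stochastic component switched off."""
        return dc_replace(
            self,
            noise_sd_by_concentration={c: 0.0 for c in self.concentrations},
            shift_sd=0.0,
            bin_noise_sd=0.0,
            burst_rate=0.0,
            day_effect_fraction=0.0,
        )


def _cell_response(
    grid: FrequencyGrid,
    cell: CellGeometry,
    heights: tuple[float, ...],
    shift: float = 0.0,
    width_scale: float = 1.0,
) -> np.ndarray:
    resp = np.zeros(len(grid))
    for (f0, _q), gamma, h in zip(cell.resonances, cell.half_widths(), heights):
        resp += h * _power_lorentzian(grid.points, f0 + shift, gamma * width_scale)
    return resp


def _noise_free_amplitudes(
    plan: StudyPlan, cell: CellGeometry, concentration: float, shift: float = 0.0
) -> np.ndarray:
    """Deterministic part of a scan: baseline + lines, pressure-amplified."""
    h1, h2 = plan.line_heights
    gc = plan.glucose_gain(concentration)
    heights = (h1, gc * h2)
    signal = plan.background_floor + _cell_response(plan.grid, cell, heights, shift)
    return plan.pressure_gain() * signal


def generate_carbon_reference(
    grid: FrequencyGrid,
    cell: CellGeometry,
    floor: float = 0.05,
    heights: tuple[float, float] = (4.0, 0.8),
    width_scale: float = 2.2,
) -> SpectrumRecord:
    """Noise-free, glucose-independent carbon calibration spectrum.

    Shares the cell's resonance structure (slightly broadened) and is
    strictly positive everywhere, as required for pointwise normalization.
    """
    if floor <= 0:
        raise ValueError("carbon floor must be positive for division")
    amps = floor + _cell_response(grid, cell, heights, width_scale=width_scale)
    meta = ScanMeta(concentration=GLUCOSE_LEVELS[0], day=0, round_index=0, sample_id=0)
    return SpectrumRecord(grid=grid, amplitudes=amps, meta=meta)


def _carbon_for_plan(plan: StudyPlan, cell: CellGeometry) -> SpectrumRecord:
    return generate_carbon_reference(
        plan.grid,
        cell,
        floor=plan.carbon_floor,
        heights=plan.carbon_heights,
        width_scale=plan.carbon_width_scale,
    )


def noise_free_band_integral(
    plan: StudyPlan, cell: CellGeometry, concentration: float
) -> float:
    """Band-mean of the noise-free carbon-normalized spectrum.

    This is the deterministic operating point the noise calibration is
    anchored to: the per-scan gain jitter is scaled so the realized integral
    standard deviation equals the configured per-concentration value.
    """
    amps = _noise_free_amplitudes(plan, cell, concentration)
    carbon = _carbon_for_plan(plan, cell)
    ratio = amps / carbon.amplitudes
    sl = band_slice(plan.grid, *plan.band)
    f = plan.grid.points[sl]
    return float(np.trapezoid(ratio[sl], f) / (f[-1] - f[0]))


def generate_spectrum(
    spec: PhantomSpec,
    plan: StudyPlan,
    cell: CellGeometry,
    rng: np.random.Generator,
    gain_offset: float = 0.0,
    round_index: int = 1,
) -> SpectrumRecord:
    """Generate one scan of the given phantom.

    ``gain_offset`` carries the per-(day, concentration) effect drawn by
    :func:`generate_study`; record-level draws (frequency shift, gain
    jitter, bin noise, bursts) happen here in a fixed order so that a seeded
    generator reproduces the study byte for byte.
    """
    if spec.concentration not in plan.concentrations:
        raise ValueError(
            f"concentration {spec.concentration} mg/dL is not part of the plan"
        )
    sd_int = plan.noise_sd_by_concentration[spec.concentration]
    a0 = noise_free_band_integral(plan, cell, spec.concentration)
    # decompose the configured integral sd: day offset (handled upstream)
    # carries day_effect_fraction of it, the per-scan gain the remainder.
    frac = plan.day_effect_fraction
    sd_record = sd_int * math.sqrt(max(0.0, 1.0 - frac * frac)) / a0

    shift = rng.normal(0.0, plan.shift_sd) if plan.shift_sd > 0 else 0.0
    eps = rng.normal(0.0, sd_record) if sd_record > 0 else 0.0
    gain = 1.0 + gain_offset + eps

    amps = gain * _noise_free_amplitudes(plan, cell, spec.concentration, shift)

    if plan.bin_noise_sd > 0:
        amps = amps + rng.normal(0.0, plan.bin_noise_sd, size=len(plan.grid))
    if not plan.panels_on:
        amps = amps + plan.ambient_level * rng.gamma(25.0, 1.0 / 25.0, len(plan.grid))
    if plan.burst_rate > 0 and rng.random() < plan.burst_rate:
        w = int(rng.integers(plan.burst_width_bins[0], plan.burst_width_bins[1] + 1))
        bsl = band_slice(plan.grid, *plan.burst_band)
        start = int(rng.integers(bsl.start, max(bsl.start + 1, bsl.stop - w)))
        height = rng.uniform(*plan.burst_amplitude)
        amps[start : start + w] += height * plan.pressure_gain()

    amps = np.clip(amps, 0.0, cell.amplification_limit)
    meta = ScanMeta(
        concentration=spec.concentration,
        day=spec.day,
        round_index=round_index,
        sample_id=spec.sample_id,
        pressure=plan.pressure,
    )
    return SpectrumRecord(grid=plan.grid, amplitudes=amps, meta=meta)


def generate_study(
    plan: StudyPlan,
    seed: int,
    cell: CellGeometry | None = None,
) -> list[SpectrumRecord]:
    """Generate the full study: days × rounds × concentrations records.

    Row order is (day, concentration, round) lexicographic, matching the
    layout the feature table expects.  A per-(day, concentration) gain
    offset models the day-to-day phantom degradation; its sd is
    ``day_effect_fraction`` of the configured integral sd.
    """
    cell = cell or CellGeometry()
    rng = np.random.default_rng(seed)
    day_offsets: dict[tuple[int, float], float] = {}
    for day in range(1, plan.days + 1):
        for c in plan.concentrations:
            sd_int = plan.noise_sd_by_concentration[c]
            if sd_int > 0 and plan.day_effect_fraction > 0:
                a0 = noise_free_band_integral(plan, cell, c)
                sd_day = plan.day_effect_fraction * sd_int / a0
                day_offsets[(day, c)] = rng.normal(0.0, sd_day)
            else:
                day_offsets[(day, c)] = 0.0

    records: list[SpectrumRecord] = []
    for day in range(1, plan.days + 1):
        for c in plan.concentrations:
            spec = PhantomSpec(concentration=c, day=day, sample_id=day)
            for rnd in range(1, plan.rounds_per_day + 1):
                records.append(
                    generate_spectrum(
                        spec,
                        plan,
                        cell,
                        rng,
                        gain_offset=day_offsets[(day, c)],
                        round_index=rnd,
                    )
                )
    return records


def generate_background_pair(
    grid: FrequencyGrid,
    suppression: float,
    rng: np.random.Generator | None = None,
    level: float = 0.05,
) -> tuple[SpectrumRecord, SpectrumRecord]:
    """Ambient background spectra without and with acoustic absorption panels.

    The damped spectrum's mean amplitude is ``(1 - suppression)`` times the
    noisy one's, within sampling error.
    """
    if not 0.0 <= suppression <= 1.0:
        raise ValueError("suppression must lie in [0, 1]")
    rng = rng or np.random.default_rng(0)
    n = len(grid)
    noisy = level * rng.gamma(25.0, 1.0 / 25.0, n)
    damped = (1.0 - suppression) * level * rng.gamma(25.0, 1.0 / 25.0, n)
    meta = ScanMeta(concentration=GLUCOSE_LEVELS[0], day=0, round_index=0)
    return (
        SpectrumRecord(grid=grid, amplitudes=noisy, meta=meta),
        SpectrumRecord(grid=grid, amplitudes=damped, meta=meta),
    )
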