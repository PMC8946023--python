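"""Closed-form photoacoustic signal model.

The photoacoustic (PA) effect converts modulated optical absorption into a
periodic pressure wave.  For an optically thin solid sample coupled to a gas
column (the Rosencwaig–Gersho picture), the signal amplitude seen by a
microphone factorises into

* a gas-coupling factor ``F`` — linear in laser intensity and fibre
  transmission, inversely proportional to the gas column length and ambient
  temperature, and proportional to the thermal diffusion length of the
  coupling gas at the modulation frequency;
* an amplitude law ``A_PA ∝ I0·α / (V0·f^{3/2})`` — the mechanism by which a
  higher optical absorption coefficient α (more glucose in the sample)
  produces a stronger acoustic signal.

Amplitudes are in arbitrary (lock-in) units; all other quantities are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GasCoupling",
    "LaserConfig",
    "SampleOptics",
    "CellGeometry",
    "thermal_diffusion_length",
    "coupling_factor",
    "pa_amplitude",
    "DEFAULT_DENOMINATOR_CONSTANT",
]

#: Denominator constant of the coupling-factor formula.  The conventional
#: derivation gives 4*sqrt(2); it is exposed as a parameter of
#: :func:`coupling_factor` because printed variants of the formula disagree.
DEFAULT_DENOMINATOR_CONSTANT: float = 4.0 * math.sqrt(2.0)


def thermal_diffusion_length(D: float, f: float) -> float:
    """Thermal diffusion length ``μ = sqrt(D / (π f))`` in metres.

    Parameters
    ----------
    D : float
        Thermal diffusivity in m²/s (gas or sample).
    f : float
        Modulation frequency in Hz.
    """
    if D <= 0:
        raise ValueError(f"thermal diffusivity must be positive, got {D!r}")
    if f <= 0:
        raise ValueError(f"modulation frequency must be positive, got {f!r}")
    return math.sqrt(D / (math.pi * f))


@dataclass(frozen=True)
class GasCoupling:
    """Thermodynamic properties of the coupling gas column.

    gamma
        Specific-heat ratio Cp/Cv (dimensionless, > 1).
    P0, T0
        Ambient pressure (Pa) and temperature (K).
    Dg
        Gas thermal diffusivity (m²/s).
    lg
        Length of the coupling-gas column (m).
    """

    gamma: float = 1.40
    P0: float = 101_325.0
    T0: float = 295.0
    Dg: float = 2.2e-5
    lg: float = 5.0e-3

    def __post_init__(self) -> None:
        if self.gamma <= 1.0:
            raise ValueError("specific-heat ratio gamma must exceed 1")
        for name in ("P0", "T0", "Dg", "lg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LaserConfig:
    """Modulated laser source.

    I0
        Laser intensity (W/m²).
    t_lambda
        Wavelength-dependent fibre/optics transmission in (0, 1].
    f_mod
        Modulation frequency (Hz).
    duty_cycle
        Square-wave duty fraction.
    wavenumber
        Emission wavenumber (cm⁻¹); 1080 cm⁻¹ is the glucose fingerprint.
    """

    I0: float = 1.9e7
    t_lambda: float = 0.95
    f_mod: float = 21_800.0
    duty_cycle: float = 0.40
    wavenumber: float = 1080.0

    def __post_init__(self) -> None:
        if self.I0 <= 0:
            raise ValueError("laser intensity I0 must be positive")
        if not 0.0 < self.t_lambda <= 1.0:
            raise ValueError("transmission t_lambda must lie in (0, 1]")
        if self.f_mod <= 0:
            raise ValueError("modulation frequency must be positive")
        if not 0.0 < self.duty_cycle <= 1.0:
            raise ValueError("duty cycle must lie in (0, 1]")


@dataclass(frozen=True)
class SampleOptics:
    """Optical/thermal properties of the irradiated sample.

    alpha
        Optical absorption coefficient (1/m); grows with glucose content.
    Ds
        Sample thermal diffusivity (m²/s).
    length
        Sample thickness (m).
    mu_a
        Optical absorption depth 1/alpha (m); derived if not given.
    mu_s
        Sample thermal diffusion length (m) at the configured modulation
        frequency; derived if not given, validated against ``Ds`` otherwise.
    """

    alpha: float = 1.0e4
    Ds: float = 1.0e-7
    length: float = 1.0e-2
    mu_a: float | None = None
    mu_s: float | None = None
    f_mod: float = 21_800.0

    def __post_init__(self) -> None:
        for name in ("alpha", "Ds", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_a is None:
            object.__setattr__(self, "mu_a", 1.0 / self.alpha)
        expected = thermal_diffusion_length(self.Ds, self.f_mod)
        if self.mu_s is None:
            object.__setattr__(self, "mu_s", expected)
        elif not math.isclose(self.mu_s, expected, rel_tol=1e-6):
            raise ValueError(
                f"mu_s={self.mu_s!r} inconsistent with sqrt(Ds/(pi*f))={expected!r}"
            )


@dataclass(frozen=True)
class CellGeometry:
    """Acoustic cell: volume, resonant modes and saturation limit.

    resonances
        Sequence of ``(centre frequency Hz, quality factor)`` pairs.  The
        default cell resonates at 16.50 and 21.80 kHz with quality factors
        giving each mode an underlying half-width of ~1 kHz.
    amplification_limit
        Amplitude (arbitrary units) at which the cell saturates; recorded
        amplitudes are clipped here.
    """

    V0: float = 5.0e-8
    resonances: tuple[tuple[float, float], ...] = (
        (16_500.0, 8.25),
        (21_800.0, 10.90),
    )
    amplification_limit: float = 50.0

    def __post_init__(self) -> None:
        if self.V0 <= 0:
            raise ValueError("cell volume V0 must be positive")
        if self.amplification_limit <= 0:
            raise ValueError("amplification_limit must be positive")
        for f0, q in self.resonances:
            if not 10_000.0 <= f0 <= 30_000.0:
                raise ValueError(
                    f"resonance centre {f0!r} Hz outside the 10-30 kHz scan range"
                )
            if q <= 0:
                raise ValueError("quality factor must be positive")

    def half_widths(self) -> tuple[float, ...]:
        """Half-width at half-maximum γ = f0 / (2Q) of each mode, in Hz."""
        return tuple(f0 / (2.0 * q) for f0, q in self.resonances)


def coupling_factor(
    gas: GasCoupling,
    laser: LaserConfig,
    c0: float = DEFAULT_DENOMINATOR_CONSTANT,
) -> float:
    """Gas-coupling factor ``F = γ·P0·t(λ)·I0·μg / (c0·lg·T0)``.

    ``μg`` is evaluated at the laser modulation frequency.  ``F`` is linear
    in ``I0`` and ``t(λ)`` and inversely proportional to ``lg`` and ``T0``.
    The output is in arbitrary units (it carries the lock-in scale).
    """
    if c0 <= 0:
        raise ValueError("denominator constant c0 must be positive")
    mu_g = thermal_diffusion_length(gas.Dg, laser.f_mod)
    return (gas.gamma * gas.P0 * laser.t_lambda * laser.I0 * mu_g) / (
        c0 * gas.lg * gas.T0
    )


def pa_amplitude(
    laser: LaserConfig,
    sample: SampleOptics,
    cell: CellGeometry,
    scale: float = 1.0,
) -> float:
    """Photoacoustic amplitude law ``scale · I0·α / (V0·f^{3/2})``.

    Monotone increasing in the absorption coefficient α: raising the glucose
    concentration raises α and hence the acoustic amplitude.  Output in
    arbitrary units.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    return scale * laser.I0 * sample.alpha / (cell.V0 * laser.f_mod**1.5)
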