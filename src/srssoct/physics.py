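"""Units, spectral axes, and the complex Raman susceptibility model.

Conventions used throughout the package:

* wavelengths in nm, Raman shifts / wavenumbers in cm^-1,
* depths in um, attenuation (decay) coefficients in mm^-1,
* the Raman shift is ``Omega = nu_pump - nu_stokes`` in wavenumbers, so
  ``Omega > 0`` when the pump is bluer than the Stokes beam (the
  high-wavenumber C-H stretch region, ~2700-3200 cm^-1).

The third-order susceptibility ``chi3`` of an ensemble of isolated Raman
lines is modelled as a sum of complex Lorentzians,

    chi3(Omega) = sum_j  A_j * Gamma_j / (Omega_j - Omega - i*Gamma_j),

whose real and imaginary parts form a Kramers-Kronig-consistent pair by
construction.  ``Im{chi3} >= 0`` (stimulated Raman gain) for non-negative
line amplitudes; ``Re{chi3}`` is the dispersive part that drives the
nonlinear phase shift of the pump field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralAxis",
    "RamanLine",
    "ChiSpectrum",
    "PhysicalConstants",
    "LaserConfig",
    "raman_shift",
    "pump_wavelength_for_shift",
    "band_to_pump_window",
    "chi3_eval",
]

#: speed of light [m/s]
C_LIGHT = 299_792_458.0
#: vacuum permittivity [F/m]
EPSILON_0 = 8.8541878128e-12


def raman_shift(pump_wavelength_nm, stokes_wavelength_nm):
    """Raman shift Omega = nu_pump - nu_stokes in cm^-1.

    Accepts scalars or arrays.  Raises ``ValueError`` on non-positive
    wavelengths.
    """
    pump = np.asarray(pump_wavelength_nm, dtype=float)
    stokes = np.asarray(stokes_wavelength_nm, dtype=float)
    if np.any(pump <= 0) or np.any(stokes <= 0):
        raise ValueError("wavelengths must be positive")
    out = 1e7 / pump - 1e7 / stokes
    return out if out.ndim else float(out)


def pump_wavelength_for_shift(shift_cm, stokes_wavelength_nm):
    """Pump wavelength (nm) whose Raman shift against the Stokes line is
    ``shift_cm`` (cm^-1)."""
    stokes = np.asarray(stokes_wavelength_nm, dtype=float)
    if np.any(stokes <= 0):
        raise ValueError("wavelengths must be positive")
    nu = np.asarray(shift_cm, dtype=float) + 1e7 / stokes
    if np.any(nu <= 0):
        raise ValueError("requested shift maps to a non-positive frequency")
    out = 1e7 / nu
    return out if out.ndim else float(out)


def band_to_pump_window(band_center_cm, band_width_cm, stokes_wavelength_nm):
    """Pump-wavelength interval covering a Raman band.

    Returns ``(lambda_lo_nm, lambda_hi_nm)`` such that the Raman shifts of
    the interval edges are ``band_center +/- band_width/2``.  The interval
    width is approximately ``lambda**2 * d_nu * 1e-7`` (nm).
    """
    if band_width_cm < 0:
        raise ValueError("band_width_cm must be >= 0")
    hi_shift = band_center_cm + band_width_cm / 2.0
    lo_shift = band_center_cm - band_width_cm / 2.0
    # higher Raman shift -> bluer (shorter) pump wavelength
    lam_short = pump_wavelength_for_shift(hi_shift, stokes_wavelength_nm)
    lam_long = pump_wavelength_for_shift(lo_shift, stokes_wavelength_nm)
    return (lam_short, lam_long)


@dataclass
class SpectralAxis:
    """Strictly monotonic wavelength axis of a spectrometer."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("wavelength axis must be a 1D array of >= 2 samples")
        if np.any(lam <= 0):
            raise ValueError("wavelengths must be positive")
        d = np.diff(lam)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength axis must be strictly monotonic")
        self.wavelengths_nm = lam

    @property
    def n_pixels(self) -> int:
        return self.wavelengths_nm.size

    @property
    def wavenumbers_cm(self) -> np.ndarray:
        """Optical frequency in wavenumbers, 1e7/lambda (cm^-1); strictly
        monotonic in the opposite sense of the wavelengths."""
        return 1e7 / self.wavelengths_nm

    def raman_shifts_cm(self, stokes_wavelength_nm: float) -> np.ndarray:
        return raman_shift(self.wavelengths_nm, stokes_wavelength_nm)


@dataclass(frozen=True)
class RamanLine:
    """Single Raman resonance: center (cm^-1), HWHM width (cm^-1),
    dimensionless amplitude."""

    center_cm: float
    width_cm: float
    amplitude: float

    def __post_init__(self):
        if self.center_cm <= 0:
            raise ValueError("line center must be > 0")
        if self.width_cm <= 0:
            raise ValueError("line width must be > 0")
        if self.amplitude < 0:
            raise ValueError("line amplitude must be >= 0")


def chi3_eval(lines, omega_cm):
    """Complex chi3(Omega) of a set of Lorentzian Raman lines.

    ``chi3(Omega) = sum_j A_j Gamma_j / (Omega_j - Omega - i Gamma_j)``.
    Linear in the amplitudes; on resonance a single unit-amplitude line
    contributes exactly ``+1i``.
    """
    lines = list(lines)
    if not lines:
        raise ValueError("at least one Raman line is required")
    omega = np.asarray(omega_cm, dtype=float)
    chi = np.zeros(omega.shape, dtype=complex)
    for ln in lines:
        chi = chi + ln.amplitude * ln.width_cm / (ln.center_cm - omega - 1j * ln.width_cm)
    return chi if chi.ndim else complex(chi)


@dataclass
class ChiSpectrum:
    """chi3 sampled on a Raman-shift grid."""

    lines: list
    raman_axis_cm: np.ndarray
    values: np.ndarray = None

    def __post_init__(self):
        self.raman_axis_cm = np.asarray(self.raman_axis_cm, dtype=float)
        if self.values is None:
            self.values = chi3_eval(self.lines, self.raman_axis_cm)


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and the composite SRS coupling constant
    ``beta = 3 / (2 n0^2 c eps0)``."""

    c: float = C_LIGHT
    epsilon_0: float = EPSILON_0
    n0: float = 1.0

    @property
    def beta(self) -> float:
        return 3.0 / (2.0 * self.n0**2 * self.c * self.epsilon_0)


@dataclass
class LaserConfig:
    """Pump/Stokes source configuration.

    Defaults mirror the imaging system emulated by the simulator: a
    broadband pump centered at 790 nm with ~40 nm FWHM bandwidth (shared
    OCT source), a fixed 1040 nm Stokes beam amplitude-modulated at 15 kHz.
    Powers are in arbitrary units; only ratios and signal-to-background
    matter downstream.
    """

    pump_center_nm: float = 790.0
    pump_bandwidth_fwhm_nm: float = 40.0
    pump_power_scale: float = 1.0
    stokes_wavelength_nm: float = 1040.0
    stokes_intensity: float = 1.0
    modulation_frequency_khz: float = 15.0

    def __post_init__(self):
        for name in (
            "pump_center_nm",
            "pump_bandwidth_fwhm_nm",
            "pump_power_scale",
            "stokes_wavelength_nm",
            "stokes_intensity",
            "modulation_frequency_khz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def pump_spectrum(self, wavelengths_nm) -> np.ndarray:
        """Gaussian pump/reference spectral intensity I0(lambda)."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        sigma = self.pump_bandwidth_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.pump_power_scale * np.exp(
            -0.5 * ((lam - self.pump_center_nm) / sigma) ** 2
        )

    def raman_coverage_cm(self, axis: SpectralAxis) -> tuple:
        """(min, max) Raman shift covered by a spectrometer axis against the
        Stokes line.  Exposed as a computed property; the usable band in
        practice is narrower (set by the pump spectral support)."""
        shifts = axis.raman_shifts_cm(self.stokes_wavelength_nm)
        return (float(np.min(shifts)), float(np.max(shifts)))
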