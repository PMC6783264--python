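"""Photoreceptor photometry: power spectra → photoisomerisation rates.

The calibration chain converts an LED's electrical power spectrum measured
at the sample plane into the photoisomerisation rate R_Iso it evokes in
each photoreceptor type:

    P_el (nW)  →  energy flux (eV/s)  →  photon flux (photons/s)
    →  photon flux density (photons/s/µm², over the stimulus area)
    →  R_Iso = Σ_λ P_E(λ)·A_Collect·S_Act(λ)   (P*/photoreceptor/s)

with S_Act(λ) = S_Opsin(λ)·S_LED(λ) the effective activation spectrum
(peak-normalised opsin sensitivity × peak-normalised LED spectrum).

The sum over λ is a plain sum over the wavelength grid, so the grid step is
part of the convention; the 1-nm default grid must be kept when comparing
rates across calibrations.

Note on weighting: applying S_Act to the spectrally resolved photon flux
weights the measured LED spectrum by its own normalised shape a second
time.  Both conventions are available through ``weighting``:
``"as_printed"`` (the default, S_Opsin·S_LED) and ``"opsin_only"``
(S_Opsin alone, the radiometrically conventional choice).
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import warnings

import numpy as np
import pandas as pd

from .opsins import SensitivityCurve
from .spectra import SpectralMeasurement, Stage

__all__ = [
    "SPEED_OF_LIGHT_M_PER_S",
    "PLANCK_EV_S",
    "JOULE_TO_EV",
    "StimulusGeometry",
    "ReceptorOptics",
    "ActivationMatrix",
    "CrossActivation",
    "power_to_energy_flux",
    "photon_energy",
    "energy_to_photon_flux",
    "flux_density",
    "effective_activation",
    "photoisomerisation_rate",
    "build_activation_matrix",
    "cross_activation",
]

# physical constants, in the units the calibration chain uses
SPEED_OF_LIGHT_M_PER_S = 299_792_458.0
PLANCK_EV_S = 4.135667e-15
JOULE_TO_EV = 6.242e18


@dataclass(frozen=True)
class StimulusGeometry:
    """Area of the light stimulus at the sample plane, µm²."""

    a_stim: float

    def __post_init__(self) -> None:
        if self.a_stim <= 0:
            raise ValueError("stimulus area must be positive (µm²)")

    @classmethod
    def from_spot_diameter(cls, diameter_um: float) -> "StimulusGeometry":
        if diameter_um <= 0:
            raise ValueError("spot diameter must be positive (µm)")
        return cls(a_stim=math.pi * (diameter_um / 2.0) ** 2)


@dataclass(frozen=True)
class ReceptorOptics:
    """Light collection area of the photoreceptor outer segment, µm².

    The 0.2 µm² default is the standard value for cone outer segments.
    """

    a_collect: float = 0.2

    def __post_init__(self) -> None:
        if self.a_collect <= 0:
            raise ValueError("collection area must be positive (µm²)")


def power_to_energy_flux(m: SpectralMeasurement) -> SpectralMeasurement:
    """Electrical power (nW) → energy flux (eV/s): P·a·10⁻⁹, a = 6.242e18 eV/J."""
    m.require_stage(Stage.POWER_NW)
    return m.with_values(m.values * JOULE_TO_EV * 1e-9, Stage.ENERGY_FLUX)


def photon_energy(wavelength_nm) -> np.ndarray | float:
    """Photon energy in eV: c·h/(λ·10⁻⁹)."""
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive (nm)")
    q = SPEED_OF_LIGHT_M_PER_S * PLANCK_EV_S / (lam * 1e-9)
    return float(q) if np.isscalar(wavelength_nm) else q


def energy_to_photon_flux(m: SpectralMeasurement) -> SpectralMeasurement:
    """Energy flux (eV/s) → photon flux (photons/s) via the photon energy."""
    m.require_stage(Stage.ENERGY_FLUX)
    return m.with_values(m.values / photon_energy(m.wavelengths), Stage.PHOTON_FLUX)


def flux_density(m: SpectralMeasurement, geom: StimulusGeometry) -> SpectralMeasurement:
    """Photon flux (photons/s) → flux density (photons/s/µm²) over the stimulus area."""
    m.require_stage(Stage.PHOTON_FLUX)
    return m.with_values(m.values / geom.a_stim, Stage.FLUX_DENSITY)


def _common_grid(opsin: SensitivityCurve, led: SpectralMeasurement):
    if not np.array_equal(opsin.wavelengths, led.wavelengths):
        opsin = opsin.resample(led.wavelengths)
    return opsin


def effective_activation(
    opsin: SensitivityCurve, led: SpectralMeasurement
) -> tuple[np.ndarray, float]:
    """Effective activation spectrum S_Act and its scalar summary.

    S_Act(λ) = S_Opsin(λ)·S_LED(λ) with the LED spectrum peak-normalised.
    The scalar is Σ S_Act / Σ S_LED — the LED-shape-weighted mean opsin
    sensitivity, which reduces to S_Opsin(λ₀) for a narrow LED at λ₀.
    Returned as a fraction in [0, 1].
    """
    opsin = _common_grid(opsin, led)
    if led.values.max() <= 0:
        warnings.warn("LED spectrum is all-zero; effective activation undefined, returning 0")
        return np.zeros_like(led.values), 0.0
    s_led = led.values / led.values.max()
    s_act = opsin.sensitivity * s_led
    denom = s_led.sum()
    fraction = float(s_act.sum() / denom) if denom > 0 else 0.0
    if s_act.sum() == 0:
        warnings.warn(
            f"LED {led.name!r} and opsin {opsin.name!r} have disjoint spectral support"
        )
    return s_act, fraction


def photoisomerisation_rate(
    flux: SpectralMeasurement,
    opsin: SensitivityCurve,
    optics: ReceptorOptics = ReceptorOptics(),
    weighting: str = "as_printed",
) -> float:
    """Photoisomerisation rate R_Iso in P*/photoreceptor/s.

    R_Ph(λ) = P_E(λ)·A_Collect is the photon flux collected by one outer
    segment; R_Iso = Σ_λ R_Ph(λ)·S_Act(λ) sums its effective absorption
    over the wavelength grid.

    ``weighting`` selects the activation spectrum: ``"as_printed"`` uses
    S_Act = S_Opsin·S_LED(normalised); ``"opsin_only"`` uses S_Opsin alone.
    """
    flux.require_stage(Stage.FLUX_DENSITY)
    opsin_rs = _common_grid(opsin, flux)
    if weighting == "as_printed":
        s_act, _ = effective_activation(
            opsin_rs, flux.with_values(flux.values, Stage.FLUX_DENSITY)
        )
    elif weighting == "opsin_only":
        s_act = opsin_rs.sensitivity
    else:
        raise ValueError("weighting must be 'as_printed' or 'opsin_only'")
    r_ph = flux.values * optics.a_collect
    return float(np.sum(r_ph * s_act))


@dataclass(frozen=True)
class ActivationMatrix:
    """R_Iso and effective-activation fractions for every LED × opsin pair."""

    led_names: tuple[str, ...]
    opsin_names: tuple[str, ...]
    r_iso: np.ndarray                 # P*/photoreceptor/s, LEDs × opsins
    effective_activation: np.ndarray  # unitless fraction in [0, 1]
    weighting: str = "as_printed"

    def __post_init__(self) -> None:
        r = np.asarray(self.r_iso, dtype=float)
        e = np.asarray(self.effective_activation, dtype=float)
        shape = (len(self.led_names), len(self.opsin_names))
        if r.shape != shape or e.shape != shape:
            raise ValueError(f"matrices must have shape {shape} (LEDs × opsins)")
        if np.any(r < 0):
            raise ValueError("photoisomerisation rates must be non-negative")
        if np.any((e < 0) | (e > 1)):
            raise ValueError("effective activation fractions must lie in [0, 1]")
        object.__setattr__(self, "r_iso", r)
        object.__setattr__(self, "effective_activation", e)

    def rate(self, led: str, opsin: str) -> float:
        return float(self.r_iso[self.led_names.index(led), self.opsin_names.index(opsin)])

    def to_frame(self, kilo: bool = False) -> pd.DataFrame:
        """Rates as a DataFrame (LED rows × opsin columns); kilo=True → 10³ P*/s."""
        scale = 1e-3 if kilo else 1.0
        return pd.DataFrame(self.r_iso * scale, index=list(self.led_names),
                            columns=list(self.opsin_names))

    def activation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effective_activation, index=list(self.led_names),
                            columns=list(self.opsin_names))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, weighting: str = "as_printed"):
        r = frame.to_numpy(dtype=float)
        eff = np.zeros_like(r)
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)),
                   r, eff, weighting)


@dataclass(frozen=True)
class CrossActivation:
    """Activation of one opsin by an off-band LED, relative to its main LED."""

    target_opsin: str
    reference_led: str
    cross_led: str
    s_cross_act: float

    def __post_init__(self) -> None:
        if self.s_cross_act < 0:
            raise ValueError("cross-activation ratio must be non-negative")


def build_activation_matrix(
    leds: list[SpectralMeasurement],
    opsins: list[SensitivityCurve],
    geom: StimulusGeometry,
    optics: ReceptorOptics = ReceptorOptics(),
    weighting: str = "as_printed",
) -> ActivationMatrix:
    """Run the full chain for every LED × opsin pair.

    Each LED measurement must be at the electrical-power stage (nW); the
    chain power → energy flux → photon flux → flux density → R_Iso is
    applied per LED, then summed against each opsin's activation spectrum.
    """
    if not leds or not opsins:
        raise ValueError("need at least one LED and one opsin")
    r = np.zeros((len(leds), len(opsins)))
    eff = np.zeros_like(r)
    for i, led in enumerate(leds):
        dens = flux_density(energy_to_photon_flux(power_to_energy_flux(led)), geom)
        for j, opsin in enumerate(opsins):
            r[i, j] = photoisomerisation_rate(dens, opsin, optics, weighting)
            _, eff[i, j] = effective_activation(opsin, led)
    return ActivationMatrix(
        tuple(m.name or f"LED{i}" for i, m in enumerate(leds)),
        tuple(o.name or f"opsin{j}" for j, o in enumerate(opsins)),
        r, eff, weighting,
    )


def cross_activation(
    matrix: ActivationMatrix, opsin: str, reference_led: str, cross_led: str
) -> CrossActivation:
    """Ratio of an opsin's activation by the cross LED vs its reference LED.

    s_cross_act = R_Iso(cross_led, opsin) / R_Iso(reference_led, opsin);
    this is the factor by which a counterphase stimulus must be scaled to
    silence the opsin (see :func:`stimcal.stimulus.silent_substitution_dichromatic`).
    """
    ref = matrix.rate(reference_led, opsin)
    if ref <= 0:
        raise ZeroDivisionError(
            f"reference activation R_Iso({reference_led}, {opsin}) is zero; "
            "cross-activation undefined"
        )
    return CrossActivation(opsin, reference_led, cross_led,
                           matrix.rate(cross_led, opsin) / ref)
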