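"""Spectrometer measurement handling: reading, denoising, unit conversion.

A :class:`SpectralMeasurement` carries a wavelength-resolved quantity plus a
``stage`` tag recording where it sits in the calibration chain
(counts → counts/s → electrical power → energy flux → photon flux → photon
flux density).  Conversions only move forward through that chain, so a
mis-ordered pipeline fails loudly instead of silently producing numbers in
the wrong unit.

Also provides a band-pass LED spectrum generator used throughout the test
fixtures: a Gaussian emission profile hard-clipped by an ideal band-pass
filter, emulating LED/interference-filter combinations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Stage",
    "SpectralMeasurement",
    "SpectrometerCalibration",
    "LedModel",
    "SpectrumFormatError",
    "GaussianFitError",
    "read_spectrum",
    "read_calibration",
    "write_spectrum",
    "average_reads",
    "denoise_gaussian",
    "counts_to_power",
    "synth_led_spectrum",
]


class Stage(str, Enum):
    """Position of a measurement in the calibration chain."""

    COUNTS = "counts"
    COUNTS_PER_S = "counts_per_s"
    POWER_NW = "power_nW"
    ENERGY_FLUX = "energy_flux_eV_per_s"
    PHOTON_FLUX = "photon_flux_per_s"
    FLUX_DENSITY = "flux_density_per_s_per_um2"


class SpectrumFormatError(ValueError):
    """Malformed spectral table (carries the offending line number)."""


class GaussianFitError(RuntimeError):
    """Gaussian denoising failed; ``diagnostics`` holds fit context."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class SpectralMeasurement:
    wavelengths: np.ndarray
    values: np.ndarray
    stage: Stage
    integration_time: float = 1.0
    n_reads: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.shape != v.shape or w.ndim != 1:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if w.size >= 2 and np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.integration_time <= 0:
            raise ValueError("integration_time must be positive (seconds)")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "stage", Stage(self.stage))

    def require_stage(self, *stages: Stage) -> None:
        if self.stage not in stages:
            wanted = ", ".join(s.value for s in stages)
            raise ValueError(
                f"measurement is at stage {self.stage.value!r}; expected {wanted}"
            )

    def with_values(self, values: np.ndarray, stage: Stage) -> "SpectralMeasurement":
        return replace(self, values=np.asarray(values, float), stage=stage)

    def peak_normalised(self) -> np.ndarray:
        m = self.values.max()
        if m <= 0:
            raise ValueError("cannot peak-normalise an all-zero spectrum")
        return self.values / m


@dataclass(frozen=True)
class SpectrometerCalibration:
    """Per-wavelength conversion factor, µJ/count, from the vendor."""

    wavelengths: np.ndarray
    factor: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        f = np.asarray(self.factor, dtype=float)
        if w.shape != f.shape or w.ndim != 1:
            raise ValueError("wavelengths and factor must be equal-length 1-D arrays")
        if np.any(np.diff(w) <= 0):
            raise ValueError("calibration wavelengths must be strictly increasing")
        if np.any(f <= 0):
            raise ValueError("calibration factors must be positive")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "factor", f)

    def at(self, wavelengths: np.ndarray) -> np.ndarray:
        """Linearly interpolate the factor; extrapolation is refused."""
        wavelengths = np.asarray(wavelengths, float)
        if wavelengths.min() < self.wavelengths[0] or wavelengths.max() > self.wavelengths[-1]:
            raise ValueError(
                "measurement grid "
                f"[{wavelengths.min():g}, {wavelengths.max():g}] nm exceeds calibrated "
                f"range [{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm; "
                "extrapolating a calibration factor is not meaningful"
            )
        return np.interp(wavelengths, self.wavelengths, self.factor)


@dataclass(frozen=True)
class LedModel:
    """Synthetic LED/band-pass-filter combination."""

    name: str
    peak: float
    fwhm: float
    passband: tuple[float, float]
    peak_power: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.passband
        if not lo < self.peak < hi:
            raise ValueError(f"passband {self.passband} must bracket the peak {self.peak}")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


_NUMERIC = re.compile(r"^[\s]*[-+0-9.eE]")


def _parse_table(path, expect_cols: int = 2) -> np.ndarray:
    """Two-column numeric table; '#' comments; one optional textual header."""
    rows = []
    header_allowed = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\t;]+|\s+", line)
            try:
                vals = [float(p) for p in parts if p]
            except ValueError:
                if header_allowed:
                    header_allowed = False
                    continue
                raise SpectrumFormatError(
                    f"{path}: non-numeric data at line {lineno}: {line!r}"
                )
            header_allowed = False
            if len(vals) < expect_cols:
                raise SpectrumFormatError(
                    f"{path}: expected {expect_cols} columns at line {lineno}"
                )
            rows.append(vals[:expect_cols])
    if not rows:
        raise SpectrumFormatError(f"{path}: no numeric data rows found")
    return np.asarray(rows, dtype=float)


def read_spectrum(path, integration_time: float = 1.0, n_reads: int = 1,
                  name: str = "") -> SpectralMeasurement:
    """Read a two-column (wavelength, counts) table as a raw-counts measurement."""
    data = _parse_table(path)
    w = data[:, 0]
    if np.any(np.diff(w) <= 0):
        bad = int(np.flatnonzero(np.diff(w) <= 0)[0]) + 2
        raise SpectrumFormatError(
            f"{path}: wavelengths not strictly increasing near data row {bad}"
        )
    return SpectralMeasurement(
        w, data[:, 1], Stage.COUNTS,
        integration_time=integration_time, n_reads=n_reads, name=name,
    )


def read_calibration(path) -> SpectrometerCalibration:
    """Read a two-column (wavelength, µJ/count) calibration table."""
    data = _parse_table(path)
    return SpectrometerCalibration(data[:, 0], data[:, 1])


def write_spectrum(m: SpectralMeasurement, path) -> None:
    header = (
        f"stimcal spectrum: {m.name}\n"
        f"stage: {m.stage.value}  integration_time_s: {m.integration_time:g}  "
        f"n_reads: {m.n_reads}\n"
        "wavelength_nm\tvalue"
    )
    np.savetxt(path, np.column_stack([m.wavelengths, m.values]),
               fmt="%.8g", delimiter="\t", header=header)


def average_reads(reads: list[SpectralMeasurement]) -> SpectralMeasurement:
    """Average repeated reads of the same spectrum (done before denoising)."""
    if not reads:
        raise ValueError("no reads to average")
    first = reads[0]
    for r in reads[1:]:
        if not np.array_equal(r.wavelengths, first.wavelengths):
            raise ValueError("reads must share one wavelength grid")
        r.require_stage(first.stage)
    mean = np.mean([r.values for r in reads], axis=0)
    return replace(first, values=mean, n_reads=sum(r.n_reads for r in reads))


def _gauss(w, amp, centre, sigma, baseline):
    return baseline + amp * np.exp(-0.5 * ((w - centre) / sigma) ** 2)


def denoise_gaussian(m: SpectralMeasurement) -> SpectralMeasurement:
    """Replace a noisy single-peaked spectrum by its least-squares Gaussian.

    Models the measurement as Gaussian peak + constant baseline, suppressing
    shot noise in low-intensity reads.  The fitted curve (negative values
    clipped to 0) replaces the data; fit parameters are attached as
    ``.fit_params``.
    """
    m.require_stage(Stage.COUNTS, Stage.COUNTS_PER_S)
    w, v = m.wavelengths, m.values
    rng = v.max() - v.min()
    if v.max() <= 0 or rng <= 0:
        raise GaussianFitError(
            "spectrum has no peak to fit (flat or all-zero input)",
            {"max": float(v.max()), "range": float(rng)},
        )
    # moment-based initial guess around the dominant peak
    peak_idx = int(np.argmax(v))
    centre0 = w[peak_idx]
    above = v - v.min() > 0.5 * rng
    sigma0 = max((w[above].max() - w[above].min()) / 2.355, np.diff(w).min())
    p0 = [rng, centre0, sigma0, max(v.min(), 0.0)]
    bounds = ([0.0, w[0], 0.0, 0.0], [np.inf, w[-1], w[-1] - w[0], np.inf])
    try:
        popt, _ = curve_fit(_gauss, w, v, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise GaussianFitError(
            f"Gaussian fit did not converge: {exc}",
            {"p0": p0, "n_points": int(w.size)},
        ) from exc
    fitted = np.clip(_gauss(w, *popt), 0.0, None)
    resid = float(np.sqrt(np.mean((fitted - v) ** 2)))
    out = m.with_values(fitted, m.stage)
    object.__setattr__(out, "fit_params", {
        "amplitude": float(popt[0]), "centre": float(popt[1]),
        "sigma": float(popt[2]), "baseline": float(popt[3]),
        "rms_residual": resid,
    })
    return out


def counts_to_power(m: SpectralMeasurement,
                    cal: SpectrometerCalibration) -> SpectralMeasurement:
    """Convert raw counts to electrical power in nW.

    P_el(λ) = counts(λ)/Δt · S_Cal(λ) · 10³, with Δt the integration time in
    seconds and S_Cal in µJ/count (µJ/s = µW; ×10³ gives nW).
    """
    m.require_stage(Stage.COUNTS)
    factor = cal.at(m.wavelengths)
    power = m.values / m.integration_time * factor * 1e3
    return m.with_values(power, Stage.POWER_NW)


def synth_led_spectrum(led: LedModel, grid: np.ndarray) -> SpectralMeasurement:
    """Model spectrum of an LED behind an ideal band-pass filter.

    Gaussian emission of the given peak/FWHM, zero outside the filter
    passband, scaled so the maximum equals ``peak_power`` (nW).
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = led.passband
    if lo < grid[0] or hi > grid[-1]:
        raise ValueError(
            f"passband ({lo}, {hi}) nm not covered by grid "
            f"[{grid[0]}, {grid[-1]}] nm"
        )
    sigma = led.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    s = np.exp(-0.5 * ((grid - led.peak) / sigma) ** 2)
    s[(grid < lo) | (grid > hi)] = 0.0
    if led.peak_power > 0 and s.max() > 0:
        s = s / s.max() * led.peak_power
    else:
        s = np.zeros_like(s)
    return SpectralMeasurement(grid, s, Stage.POWER_NW, name=led.name)
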