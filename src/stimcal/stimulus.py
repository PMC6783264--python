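"""Stimulus design: display linearisation (gamma LUTs) and silent substitution.

Gamma correction: an LED's photoisomerisation output is a sigmoidal, not
linear, function of the 8-bit pixel value driving it.  From a measured
intensity series (pixel value vs R_Iso) we fit

    y = K0 + K1 / (1 + exp(-(x - K2)/K3))

and build a 256-entry lookup table mapping each requested linear level to
the drive value that produces it, so that requested and emitted intensity
become proportional.

Silent substitution: to stimulate one opsin in isolation, every other opsin
must see constant excitation.  For a dichromat this reduces to scaling the
counterphase primary by the cross-activation ratio (I_G = I − I_UV·S_CrossAct);
for more primaries/opsins the per-LED weights solve the linear system
R_Isoᵀ·w = target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .photometry import ActivationMatrix

__all__ = [
    "IntensitySeries",
    "GammaFit",
    "Lut",
    "SubstitutionResult",
    "GammaFitError",
    "GamutError",
    "fit_intensity_curve",
    "build_lut",
    "silent_substitution_dichromatic",
    "substitution_solve",
    "read_intensity_series",
    "write_lut",
    "read_lut",
]


class GammaFitError(RuntimeError):
    """Sigmoid fit to the intensity series failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class GamutError(ValueError):
    """A requested stimulus needs drive values outside the displayable range."""


@dataclass(frozen=True)
class IntensitySeries:
    """Measured intensity response of one LED across display pixel values."""

    led_name: str
    pixel_values: np.ndarray   # 0–255 display levels, strictly increasing
    r_iso: np.ndarray          # measured rate per level, P*/photoreceptor/s

    def __post_init__(self) -> None:
        x = np.asarray(self.pixel_values, dtype=float)
        y = np.asarray(self.r_iso, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("pixel_values and r_iso must be equal-length 1-D arrays")
        if np.any(np.diff(x) <= 0):
            raise ValueError("pixel_values must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("measured rates must be non-negative")
        object.__setattr__(self, "pixel_values", x)
        object.__setattr__(self, "r_iso", y)


def _sigmoid(x, k0, k1, k2, k3):
    return k0 + k1 / (1.0 + np.exp(-(x - k2) / k3))


@dataclass(frozen=True)
class GammaFit:
    """Fitted sigmoid parameters of an LED intensity curve."""

    k0: float
    k1: float
    k2: float
    k3: float
    rms_residual: float
    led_name: str = ""

    def __call__(self, x) -> np.ndarray:
        return _sigmoid(np.asarray(x, dtype=float), self.k0, self.k1, self.k2, self.k3)

    def inverse(self, y) -> np.ndarray:
        """Analytic inverse of the sigmoid, clipped to its open range."""
        y = np.asarray(y, dtype=float)
        # keep the argument of the log inside the sigmoid's open interval
        frac = np.clip((y - self.k0) / self.k1, 1e-12, 1.0 - 1e-12)
        return self.k2 - self.k3 * np.log(1.0 / frac - 1.0)


def fit_intensity_curve(series: IntensitySeries) -> GammaFit:
    """Least-squares sigmoid through (pixel value, measured intensity).

    Initialisation: K0 = min(y), K1 = range(y), K2 = x at half range,
    K3 = range(x)/10, with K1, K3 bounded positive so only rising curves
    are accepted.
    """
    x, y = series.pixel_values, series.r_iso
    if x.size < 8:
        raise ValueError("need at least 8 points spanning the dynamic range")
    if y[-1] <= y[0]:
        raise GammaFitError(
            "intensity series is not rising; cannot fit an increasing sigmoid",
            {"first": float(y[0]), "last": float(y[-1])},
        )
    y_rng = float(y.max() - y.min())
    half = y.min() + 0.5 * y_rng
    k2_0 = float(x[np.argmin(np.abs(y - half))])
    p0 = [float(y.min()), y_rng, k2_0, float((x[-1] - x[0]) / 10.0)]
    bounds = (
        [-np.inf, 1e-12, x[0] - (x[-1] - x[0]), 1e-12],
        [np.inf, np.inf, x[-1] + (x[-1] - x[0]), np.inf],
    )
    try:
        popt, _ = curve_fit(_sigmoid, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise GammaFitError(
            f"sigmoid fit did not converge: {exc}", {"p0": p0}
        ) from exc
    resid = float(np.sqrt(np.mean((_sigmoid(x, *popt) - y) ** 2)))
    if popt[3] > 10.0 * (x[-1] - x[0]):
        warnings.warn(
            "fitted K3 is much larger than the pixel range; the intensity "
            "curve is nearly linear and the sigmoid is degenerate"
        )
    return GammaFit(*map(float, popt), rms_residual=resid, led_name=series.led_name)


@dataclass(frozen=True)
class Lut:
    """256-entry gamma-correction table: requested linear level → drive value."""

    entries: np.ndarray
    led_name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=int)
        if e.shape != (256,):
            raise ValueError("LUT must have exactly 256 entries")
        if np.any(np.diff(e) < 0):
            raise ValueError("LUT entries must be non-decreasing")
        if e[0] < 0 or e[-1] > 255:
            raise ValueError("LUT entries must lie in [0, 255]")
        object.__setattr__(self, "entries", e)

    def __call__(self, requested) -> np.ndarray:
        return self.entries[np.asarray(requested, dtype=int)]


def build_lut(source: GammaFit | IntensitySeries, mode: str = "fit") -> Lut:
    """Build the linearising LUT from a fitted or measured intensity curve.

    entry[v] is the drive level whose (fitted or interpolated) intensity
    equals ymin + (v/255)·(ymax − ymin); endpoints map to 0 and 255.

    ``mode="fit"`` inverts the fitted sigmoid analytically (fits first if
    given a series), suppressing measurement noise; ``mode="interp"``
    inverts the measured points by monotone piecewise-linear interpolation
    and requires a non-decreasing series.
    """
    levels = np.arange(256)
    if mode == "fit":
        fit = source if isinstance(source, GammaFit) else fit_intensity_curve(source)
        if fit.k1 <= 0 or fit.k3 <= 0:
            raise ValueError("fitted curve is not rising; refit or use mode='interp'")
        y0, y1 = fit(0.0), fit(255.0)
        targets = y0 + levels / 255.0 * (y1 - y0)
        drive = fit.inverse(targets)
        meta = {"mode": "fit", "k0": fit.k0, "k1": fit.k1, "k2": fit.k2, "k3": fit.k3}
        name = fit.led_name
    elif mode == "interp":
        if not isinstance(source, IntensitySeries):
            raise TypeError("mode='interp' requires an IntensitySeries")
        x, y = source.pixel_values, source.r_iso
        if np.any(np.diff(y) < 0):
            raise ValueError(
                "measured intensity curve is not monotone non-decreasing; "
                "refit with mode='fit' or smooth the series"
            )
        if y[-1] <= y[0]:
            raise ValueError("constant intensity curve cannot be inverted")
        targets = y[0] + levels / 255.0 * (y[-1] - y[0])
        drive = np.interp(targets, y, x)
        meta = {"mode": "interp", "n_points": int(x.size)}
        name = source.led_name
    else:
        raise ValueError("mode must be 'fit' or 'interp'")
    drive = np.clip(np.rint(drive), 0, 255).astype(int)
    drive[0], drive[-1] = 0, 255
    drive = np.maximum.accumulate(drive)
    return Lut(drive, led_name=name, metadata=meta)


def silent_substitution_dichromatic(i: float, i_uv: float, s_cross_act: float) -> float:
    """Counterphase green amplitude silencing the M-opsin in a dichromat.

    I_G = I − I_UV·S_CrossAct: the UV primary's leak into M-opsin
    (scaled by the cross-activation ratio) is subtracted from the green
    amplitude so M-opsin sees only the intended modulation I.
    """
    if s_cross_act < 0:
        raise ValueError("cross-activation ratio must be non-negative")
    return i - i_uv * s_cross_act


@dataclass(frozen=True)
class SubstitutionResult:
    """Per-LED weights realising a per-opsin target modulation."""

    led_names: tuple[str, ...]
    opsin_names: tuple[str, ...]
    weights: np.ndarray            # signed, linearised (post-LUT) units
    residual: np.ndarray           # achieved − target, per opsin
    target: np.ndarray
    in_gamut: bool                 # weights within the supplied bounds

    def achieved(self, matrix: ActivationMatrix) -> np.ndarray:
        return matrix.r_iso.T @ self.weights


def substitution_solve(
    matrix: ActivationMatrix,
    target: dict[str, float] | np.ndarray,
    bounds: tuple[float, float] | None = None,
    rtol: float = 1e-9,
) -> SubstitutionResult:
    """Solve R_Isoᵀ·w = target for per-LED modulation weights.

    ``target`` gives the desired differential photoisomerisation rate per
    opsin (dict by opsin name, missing opsins silenced at 0).  Square
    full-rank systems are solved exactly; overdetermined ones by least
    squares with the per-opsin residual reported.  ``bounds`` (lo, hi) in
    linearised units flags out-of-gamut weights via ``in_gamut`` without
    clipping them.
    """
    n_led, n_ops = matrix.r_iso.shape
    if n_led < n_ops:
        raise ValueError(
            f"{n_led} LEDs cannot independently control {n_ops} opsins"
        )
    if isinstance(target, dict):
        unknown = set(target) - set(matrix.opsin_names)
        if unknown:
            raise KeyError(f"target names {sorted(unknown)} not in matrix opsins "
                           f"{list(matrix.opsin_names)}")
        t = np.array([float(target.get(o, 0.0)) for o in matrix.opsin_names])
    else:
        t = np.asarray(target, dtype=float)
        if t.shape != (n_ops,):
            raise ValueError(f"target must have one entry per opsin ({n_ops})")
    a = matrix.r_iso.T  # opsins × LEDs
    rank = np.linalg.matrix_rank(a)
    if rank < n_ops:
        warnings.warn(
            f"activation matrix is rank-deficient (rank {rank} < {n_ops}); "
            "solving in the least-squares sense"
        )
    w, *_ = np.linalg.lstsq(a, t, rcond=None)
    residual = a @ w - t
    scale = max(np.abs(t).max(), np.abs(a @ w).max(), 1e-300)
    if rank < n_ops and np.abs(residual).max() > rtol * scale:
        raise ValueError(
            "target is unsatisfiable with this activation matrix; per-opsin "
            f"residuals: {dict(zip(matrix.opsin_names, residual.round(6)))}"
        )
    in_gamut = True
    if bounds is not None:
        lo, hi = bounds
        in_gamut = bool(np.all((w >= lo) & (w <= hi)))
        if not in_gamut:
            warnings.warn(
                f"solution weights {w.round(4)} exceed the displayable range "
                f"[{lo}, {hi}]; stimulus amplitude must be reduced"
            )
    return SubstitutionResult(matrix.led_names, matrix.opsin_names,
                              w, residual, t, in_gamut)


def read_intensity_series(path, led_name: str = "") -> IntensitySeries:
    """Read a two-column (pixel value, intensity) table."""
    from .spectra import _parse_table

    data = _parse_table(path)
    return IntensitySeries(led_name, data[:, 0], data[:, 1])


def write_lut(lut: Lut, path) -> None:
    """Write a LUT as `index,drive_value` lines with a '#' metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# stimcal gamma LUT  led: {lut.led_name}\n")
        for key, val in lut.metadata.items():
            fh.write(f"# {key}: {val}\n")
        for i, v in enumerate(lut.entries):
            fh.write(f"{i},{int(v)}\n")


def read_lut(path) -> Lut:
    entries = np.full(256, -1, dtype=int)
    name = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "led:" in line:
                    name = line.split("led:", 1)[1].strip()
                continue
            if not line:
                continue
            idx, val = line.split(",")
            entries[int(idx)] = int(val)
    if np.any(entries < 0):
        raise ValueError(f"{path}: LUT file does not define all 256 entries")
    return Lut(entries, led_name=name)
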