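"""Visual pigment spectral sensitivity templates.

Peak-normalised sensitivity curves S(λ) for photoreceptor opsins are
generated from the pigment's peak wavelength λmax using the A1-retinal
nomogram of Govardovskii et al. (2000): a main alpha band plus an optional
short-wavelength beta band.  The template coefficients are stored as plain
data (:data:`GOVARDOVSKII_A1`) so an alternative template family can be
swapped in without touching the code.

Species presets bundle the opsin complement of common model organisms
(dichromatic mouse, tetrachromatic zebrafish) with literature default
λmax values; every value is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "GOVARDOVSKII_A1",
    "DEFAULT_GRID",
    "OpsinTemplate",
    "SpeciesPreset",
    "SensitivityCurve",
    "template_sensitivity",
    "species_preset",
    "default_grid",
    "load_preset",
    "save_curve",
]

# A1-pigment nomogram coefficients (Govardovskii et al. 2000).
# alpha band: S(x) = 1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D),
# x = λmax/λ, with a depending weakly on λmax;
# beta band: Gaussian of fixed relative amplitude riding on the UV limb.
GOVARDOVSKII_A1: dict[str, float] = {
    "A": 69.7,
    "B": 28.0,
    "b": 0.922,
    "C": -14.9,
    "c": 1.104,
    "D": 0.674,
    "a0": 0.8795,
    "a1": 0.0459,
    "a2": 300.0,
    "a3": 11940.0,
    "beta_amplitude": 0.26,
    "beta_centre0": 189.0,
    "beta_centre1": 0.315,
    "beta_width0": -40.5,
    "beta_width1": 0.195,
}

LAMBDA_MAX_RANGE = (300.0, 650.0)
GRID_RANGE = (300.0, 800.0)


def default_grid(start: float = 300.0, stop: float = 720.0, step: float = 1.0) -> np.ndarray:
    """Default wavelength grid: 300–720 nm at 1-nm steps."""
    return np.arange(start, stop + 0.5 * step, step, dtype=float)


DEFAULT_GRID = default_grid()


@dataclass(frozen=True)
class OpsinTemplate:
    """A pigment defined by its name, λmax and template settings."""

    name: str
    lambda_max: float
    include_beta_band: bool = True
    template_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(GOVARDOVSKII_A1)
    )

    def __post_init__(self) -> None:
        lo, hi = LAMBDA_MAX_RANGE
        if not lo <= self.lambda_max <= hi:
            raise ValueError(
                f"lambda_max={self.lambda_max} nm outside supported range "
                f"[{lo}, {hi}] nm"
            )

    def sensitivity(self, grid: np.ndarray | None = None) -> "SensitivityCurve":
        return template_sensitivity(
            self.lambda_max,
            DEFAULT_GRID if grid is None else grid,
            include_beta_band=self.include_beta_band,
            coefficients=self.template_coefficients,
            name=self.name,
        )


@dataclass(frozen=True)
class SensitivityCurve:
    """Relative spectral sensitivity of one opsin on a wavelength grid.

    ``sensitivity`` is unitless, non-negative, with maximum 1.
    """

    wavelengths: np.ndarray
    sensitivity: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        s = np.asarray(self.sensitivity, dtype=float)
        if w.shape != s.shape or w.ndim != 1:
            raise ValueError("wavelengths and sensitivity must be equal-length 1-D arrays")
        if w.size and np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(s)) or np.any(s < 0):
            raise ValueError("sensitivity must be finite and non-negative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "sensitivity", s)

    def at(self, wavelength: float) -> float:
        """Sensitivity linearly interpolated at a wavelength (0 outside grid)."""
        return float(
            np.interp(wavelength, self.wavelengths, self.sensitivity, left=0.0, right=0.0)
        )

    def resample(self, grid: np.ndarray) -> "SensitivityCurve":
        s = np.interp(grid, self.wavelengths, self.sensitivity, left=0.0, right=0.0)
        return SensitivityCurve(np.asarray(grid, float), s, name=self.name)


@dataclass(frozen=True)
class SpeciesPreset:
    """Opsin complement of one species: cone opsins plus the rod pigment."""

    species: str
    cone_opsins: tuple[OpsinTemplate, ...]
    rod_opsin: OpsinTemplate

    @property
    def all_opsins(self) -> tuple[OpsinTemplate, ...]:
        return self.cone_opsins + (self.rod_opsin,)

    def curves(self, grid: np.ndarray | None = None, include_rod: bool = False):
        """Sensitivity curves for all cone opsins (optionally the rod too)."""
        opsins = self.all_opsins if include_rod else self.cone_opsins
        return [o.sensitivity(grid) for o in opsins]


def _alpha_band(lam: np.ndarray, lambda_max: float, c: dict[str, float]) -> np.ndarray:
    x = lambda_max / lam
    a = c["a0"] + c["a1"] * np.exp(-((lambda_max - c["a2"]) ** 2) / c["a3"])
    return 1.0 / (
        np.exp(c["A"] * (a - x))
        + np.exp(c["B"] * (c["b"] - x))
        + np.exp(c["C"] * (c["c"] - x))
        + c["D"]
    )


def _beta_band(lam: np.ndarray, lambda_max: float, c: dict[str, float]) -> np.ndarray:
    centre = c["beta_centre0"] + c["beta_centre1"] * lambda_max
    width = c["beta_width0"] + c["beta_width1"] * lambda_max
    return c["beta_amplitude"] * np.exp(-(((lam - centre) / width) ** 2))


def template_sensitivity(
    lambda_max: float,
    grid: np.ndarray,
    include_beta_band: bool = True,
    coefficients: dict[str, float] | None = None,
    name: str = "",
) -> SensitivityCurve:
    """Evaluate the pigment template on a wavelength grid.

    Parameters
    ----------
    lambda_max
        Peak wavelength of the alpha band, nm; must lie in [300, 650].
    grid
        Strictly increasing wavelengths, nm, within [300, 800].
    include_beta_band
        Add the short-wavelength beta band (on by default; its long UV tail
        is what produces cross-activation of mid-wavelength opsins by UV
        primaries).
    coefficients
        Template coefficient set; defaults to :data:`GOVARDOVSKII_A1`.

    Returns
    -------
    SensitivityCurve
        Peak-normalised so the maximum over the grid equals 1 (attained at
        the grid wavelength nearest λmax).
    """
    lo, hi = LAMBDA_MAX_RANGE
    if not lo <= lambda_max <= hi:
        raise ValueError(f"lambda_max={lambda_max} nm outside [{lo}, {hi}] nm")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    glo, ghi = GRID_RANGE
    if grid[0] < glo or grid[-1] > ghi:
        raise ValueError(f"grid must lie within [{glo}, {ghi}] nm")
    c = dict(GOVARDOVSKII_A1 if coefficients is None else coefficients)

    s = _alpha_band(grid, lambda_max, c)
    if include_beta_band:
        s = s + _beta_band(grid, lambda_max, c)
    # normalise at the grid point nearest λmax; the beta band can push the
    # true maximum a grid step short of λmax, by well under 1%
    s = s / s[int(np.argmin(np.abs(grid - lambda_max)))]
    return SensitivityCurve(grid, s, name=name)


_PRESETS: dict[str, dict] = {
    "mouse": {
        "cones": [("S", 360.0), ("M", 508.0)],
        "rod": ("rod", 498.0),
    },
    "zebrafish": {
        "cones": [("UV", 365.0), ("S", 416.0), ("M", 480.0), ("L", 570.0)],
        "rod": ("rod", 501.0),
    },
}


def species_preset(
    species: str, lambda_max_overrides: dict[str, float] | None = None
) -> SpeciesPreset:
    """Built-in opsin complement for a supported species.

    ``lambda_max_overrides`` maps opsin name (e.g. ``"M"``) to a replacement
    λmax in nm; the built-in values are literature defaults, not
    measurements, and experiments with shifted pigments should override
    them.
    """
    key = species.lower()
    if key not in _PRESETS:
        raise KeyError(
            f"unknown species {species!r}; supported: {sorted(_PRESETS)}"
        )
    overrides = lambda_max_overrides or {}
    spec = _PRESETS[key]
    cones = tuple(
        OpsinTemplate(name, overrides.get(name, lmax)) for name, lmax in spec["cones"]
    )
    rod_name, rod_lmax = spec["rod"]
    rod = OpsinTemplate(rod_name, overrides.get(rod_name, rod_lmax))
    return SpeciesPreset(key, cones, rod)


def load_preset(path) -> SpeciesPreset:
    """Read a species preset from a key/value (YAML) file.

    Expected layout::

        species: mouse
        opsins:
          - {name: S, lambda_max: 360, beta_band: true}
          - {name: M, lambda_max: 508}
        rod: {name: rod, lambda_max: 498}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cones = tuple(
        OpsinTemplate(
            str(o["name"]), float(o["lambda_max"]), bool(o.get("beta_band", True))
        )
        for o in doc["opsins"]
    )
    r = doc["rod"]
    rod = OpsinTemplate(str(r["name"]), float(r["lambda_max"]), bool(r.get("beta_band", True)))
    return SpeciesPreset(str(doc["species"]), cones, rod)


def save_curve(curve: SensitivityCurve, path) -> None:
    """Write a curve as a two-column text table (wavelength_nm, sensitivity)."""
    header = f"opsin sensitivity {curve.name}".strip() + "\nwavelength_nm\tsensitivity"
    np.savetxt(
        path,
        np.column_stack([curve.wavelengths, curve.sensitivity]),
        fmt="%.6g",
        delimiter="\t",
        header=header,
    )
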