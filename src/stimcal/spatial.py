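"""Spatial resolution of projected stimuli, from checkerboard images.

A projected checkerboard imaged at the sample plane degrades in two
measurable ways as the checker size approaches the projector's resolution
limit: the bright/dark contrast (I_max − I_min of an intensity profile)
collapses, and the dark→bright edge transitions blur.  Edge blur is
quantified by fitting a sigmoid

    y = K0 + K1 / (1 + exp(-(x - K2)/K3))

to the rising phase of the peak-normalised, half-width-normalised profile
and reporting 1/K3 as the edge sharpness.

The synthetic checkerboard generator (binary board convolved with a
Gaussian of configurable σ per colour channel) emulates defocus and
chromatic blur for fixture-based testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

__all__ = [
    "CheckerImage",
    "IntensityProfile",
    "EdgeFit",
    "EdgeDetectionError",
    "synth_checkerboard",
    "extract_profile",
    "contrast",
    "edge_sharpness",
    "pixel_footprint",
]


class EdgeDetectionError(ValueError):
    """No usable dark→bright transition found in the profile."""


@dataclass(frozen=True)
class CheckerImage:
    """A (possibly blurred) checkerboard image at the sample plane."""

    pixels: np.ndarray       # 2-D intensity array, arbitrary units ≥ 0
    pixel_pitch: float       # µm per image pixel
    checker_size: float      # µm
    channel: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(p < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive (µm/pixel)")
        object.__setattr__(self, "pixels", p)


@dataclass(frozen=True)
class IntensityProfile:
    """1-D intensity cut through an image, positions in µm."""

    position: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.position, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("position and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(x) <= 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "position", x)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class EdgeFit:
    """Sigmoid fit of one dark→bright edge.

    ``sharpness`` is 1/K3 on the half-width-normalised position axis (the
    primary, size-independent readout); ``sharpness_um`` is 1/K3 on the raw
    µm axis.  ``capped`` marks step-like edges whose true K3 is below the
    grid resolution.
    """

    k0: float
    k1: float
    k2: float
    k3: float
    sharpness: float
    sharpness_um: float
    capped: bool = False

    def __post_init__(self) -> None:
        if self.k3 <= 0:
            raise ValueError("K3 must be positive")
        if not np.isfinite(self.sharpness):
            raise ValueError("sharpness must be finite")


def synth_checkerboard(
    checker_size: float,
    pitch: float,
    blur_sigma: float = 0.0,
    size: tuple[int, int] = (256, 256),
    phase: tuple[float, float] = (0.0, 0.0),
    channel: str = "",
) -> CheckerImage:
    """Generate a blurred checkerboard image.

    Parameters
    ----------
    checker_size
        Edge length of one checker, µm; must be at least one image pixel.
    pitch
        µm per image pixel.
    blur_sigma
        Gaussian blur σ in µm (0 = ideal binary board).  Per-channel blur
        emulates chromatic defocus.
    size
        Image shape (rows, cols).
    phase
        Offset of the checker pattern in µm per axis.
    """
    if checker_size < pitch:
        raise ValueError(
            f"checker_size {checker_size} µm below the image pitch {pitch} µm "
            "would alias; render at finer pitch"
        )
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be non-negative")
    rows, cols = size
    y = (np.arange(rows) * pitch + phase[0])[:, None]
    x = (np.arange(cols) * pitch + phase[1])[None, :]
    board = ((np.floor(y / checker_size) + np.floor(x / checker_size)) % 2).astype(float)
    if blur_sigma > 0:
        board = gaussian_filter(board, sigma=blur_sigma / pitch, mode="reflect")
    return CheckerImage(np.clip(board, 0.0, 1.0), pitch, checker_size, channel)


def extract_profile(img: CheckerImage, index: int, axis: int = 0) -> IntensityProfile:
    """Extract a 1-D profile: ``axis=0`` cuts along a row, 1 along a column."""
    if axis not in (0, 1):
        raise ValueError("axis must be 0 (row cut) or 1 (column cut)")
    n = img.pixels.shape[axis]
    if not 0 <= index < n:
        raise IndexError(f"index {index} out of bounds for axis {axis} of length {n}")
    line = img.pixels[index, :] if axis == 0 else img.pixels[:, index]
    pos = np.arange(line.size) * img.pixel_pitch
    return IntensityProfile(pos, line)


def contrast(profile: IntensityProfile) -> float:
    """Profile contrast I_max − I_min."""
    if profile.intensity.size < 2:
        raise ValueError("need at least 2 samples to compute a contrast")
    return float(profile.intensity.max() - profile.intensity.min())


def _sigmoid(x, k0, k1, k2, k3):
    return k0 + k1 / (1.0 + np.exp(-(x - k2) / k3))


def _rising_segment(y: np.ndarray) -> tuple[int, int, int]:
    """Locate the first dark→bright transition: (trough, crossing, peak) indices.

    The crossing is where the normalised profile first rises through 50% of
    its range; the window spans the preceding local trough to the following
    local peak.
    """
    rng = y.max() - y.min()
    if rng <= 0:
        raise EdgeDetectionError("profile is constant; no transition to fit")
    yn = (y - y.min()) / rng
    above = yn >= 0.5
    crossings = np.flatnonzero(~above[:-1] & above[1:])
    if crossings.size == 0:
        raise EdgeDetectionError("no dark→bright transition found in profile")
    c = int(crossings[0]) + 1
    lo = c
    while lo > 0 and yn[lo - 1] <= yn[lo]:
        lo -= 1
    hi = c
    while hi < y.size - 1 and yn[hi + 1] >= yn[hi]:
        hi += 1
    if hi - lo < 3:
        # widen minimal windows so the fit has enough points
        lo, hi = max(0, lo - 2), min(y.size - 1, hi + 2)
    return lo, c, hi


def _half_max_width(pos: np.ndarray, yn: np.ndarray, c: int) -> float:
    """Width of the bright region at 50%: rising crossing → next falling crossing."""
    x_rise = np.interp(0.5, [yn[c - 1], yn[c]], [pos[c - 1], pos[c]])
    below = yn < 0.5
    falls = np.flatnonzero(~below[:-1] & below[1:])
    falls = falls[falls >= c]
    if falls.size:
        f = int(falls[0]) + 1
        x_fall = np.interp(0.5, [yn[f], yn[f - 1]], [pos[f], pos[f - 1]])
        return float(x_fall - x_rise)
    # profile ends bright: fall back to the extent of the bright plateau
    return float(pos[-1] - x_rise)


def edge_sharpness(profile: IntensityProfile) -> EdgeFit:
    """Fit a sigmoid to the first rising edge of a profile and report 1/K3.

    The profile is peak-normalised and its position axis rescaled so the
    half-maximum width of the bright region equals 1, making sharpness
    values comparable across checker sizes; the fit runs on the segment
    from the trough preceding the 50% crossing to the following peak.
    Step-like edges whose K3 collapses below the sample spacing are capped
    there and flagged.
    """
    pos, y = profile.position, profile.intensity
    if y.size < 5:
        raise EdgeDetectionError("profile too short to fit an edge")
    rng = y.max() - y.min()
    if rng <= 0:
        raise EdgeDetectionError("profile is constant; no transition to fit")
    yn = (y - y.min()) / rng
    lo, c, hi = _rising_segment(y)
    width = _half_max_width(pos, yn, c)
    if width <= 0:
        raise EdgeDetectionError("degenerate half-maximum width")
    xs = (pos - pos[c]) / width     # normalised axis: half-max width = 1
    seg = slice(lo, hi + 1)
    x_fit, y_fit = xs[seg], yn[seg]
    dx = float(np.min(np.diff(x_fit)))
    k3_floor = dx / 4.0             # below this the grid cannot resolve the edge
    p0 = [0.0, 1.0, 0.0, max(0.25 * (x_fit[-1] - x_fit[0]), k3_floor)]
    try:
        popt, _ = curve_fit(
            _sigmoid, x_fit, y_fit, p0=p0,
            bounds=([-0.5, 0.1, x_fit[0], k3_floor], [0.5, 2.0, x_fit[-1], np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise EdgeDetectionError(f"sigmoid fit to rising edge failed: {exc}") from exc
    k0, k1, k2, k3 = map(float, popt)
    capped = k3 <= k3_floor * (1.0 + 1e-6)
    if capped:
        warnings.warn(
            "edge is steeper than the sampling grid resolves; 1/K3 capped"
        )
    return EdgeFit(k0, k1, k2, k3, sharpness=1.0 / k3,
                   sharpness_um=1.0 / (k3 * width), capped=capped)


def pixel_footprint(feature_size: float, scale) -> tuple[float, ...] | float:
    """Extent of a feature in device pixels: feature_size × scale per axis.

    ``scale`` is in pixels per µm (scalar or one value per axis).  Note that
    device documentation often quotes the reciprocal (µm/pixel); invert
    before calling.
    """
    if feature_size <= 0:
        raise ValueError("feature size must be positive (µm)")
    s = np.atleast_1d(np.asarray(scale, dtype=float))
    if np.any(s <= 0):
        raise ValueError("scale must be positive (pixels/µm)")
    out = feature_size * s
    return float(out[0]) if out.size == 1 else tuple(float(v) for v in out)
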