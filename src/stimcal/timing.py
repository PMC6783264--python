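"""LED blanking vs display frame rate: aliasing of perceived brightness.

During two-photon imaging the stimulator LEDs are gated so they are on only
during the scan-line retrace (typically the last 20% of a 1–2 ms line).
The display refreshes at its own 60 Hz frame clock, unsynchronised with the
line clock, so the number of LED-on windows falling inside a photoreceptor's
integration time drifts slowly — a beat that appears as a slow brightness
modulation.  This module simulates the ideal gating and quantifies the
residual modulation after box-filter smoothing at the cone integration time
(100 ms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "BlankingConfig",
    "LedTrace",
    "ModulationResult",
    "simulate_gated_led",
    "perceived_modulation",
]


@dataclass(frozen=True)
class BlankingConfig:
    """Timing of the scan-line gate and the display frame clock."""

    line_period: float = 1e-3        # s; 1–2 ms scan lines are typical
    retrace_fraction: float = 0.2    # LED-on fraction at the end of each line
    frame_rate: float = 60.0         # Hz; display refresh (sample-and-hold)
    duration: float = 5.0            # s
    sample_rate: float = 100e3       # Hz

    def __post_init__(self) -> None:
        if not 0.0 < self.retrace_fraction < 1.0:
            raise ValueError("retrace_fraction must lie in (0, 1)")
        if self.line_period <= 0 or self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("line_period, frame_rate and duration must be positive")
        if self.sample_rate < 20.0 / self.line_period:
            raise ValueError(
                f"sample_rate {self.sample_rate:g} Hz under-samples the "
                f"{1.0 / self.line_period:g} Hz line clock (need ≥ 20 samples/line)"
            )


@dataclass(frozen=True)
class LedTrace:
    """Instantaneous gated LED output over time."""

    time: np.ndarray
    intensity: np.ndarray
    config: BlankingConfig

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.intensity, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and intensity must be equal-length 1-D arrays")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", v)


@dataclass(frozen=True)
class ModulationResult:
    """Smoothed trace and its residual modulation depth."""

    time: np.ndarray
    smoothed: np.ndarray
    modulation_depth: float   # (max − min)/mean over the edge-free region
    mean_level: float

    def __post_init__(self) -> None:
        if self.modulation_depth < 0:
            raise ValueError("modulation depth cannot be negative")


def simulate_gated_led(
    cfg: BlankingConfig,
    stimulus_level: Callable[[np.ndarray], np.ndarray] | float = 1.0,
) -> LedTrace:
    """Simulate the instantaneous LED output under retrace gating.

    The LED is on during the final ``retrace_fraction`` of every scan line
    and off otherwise (ideal gate, zero rise/fall time).  The stimulus level
    is sampled-and-held at display frame boundaries, reproducing the
    unsynchronised frame/line beat; ``stimulus_level`` may be a constant or
    a function of time evaluated at each frame start.
    """
    n = int(round(cfg.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    frame_start = np.floor(t * cfg.frame_rate) / cfg.frame_rate
    if callable(stimulus_level):
        level = np.asarray(stimulus_level(frame_start), dtype=float)
        level = np.broadcast_to(level, t.shape).copy()
    else:
        level = np.full_like(t, float(stimulus_level))
    u = t / cfg.line_period
    line_phase = u - np.floor(u)
    # absorb float representation error at phase boundaries (≲1e-12 for
    # seconds-long traces, far below one sample in phase units): phases a
    # hair under 1 are the start of the next line, not the end of this one
    line_phase = np.where(line_phase >= 1.0 - 1e-9, 0.0, line_phase)
    gate = line_phase >= 1.0 - cfg.retrace_fraction - 1e-9
    return LedTrace(t, np.where(gate, level, 0.0), cfg)


def _moving_mean_valid(x: np.ndarray, width: int) -> np.ndarray:
    """Moving average over complete windows only, via cumulative sums (O(n))."""
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return (csum[width:] - csum[:-width]) / width


def perceived_modulation(trace: LedTrace, box_width: float = 0.1) -> ModulationResult:
    """Brightness modulation seen through a photoreceptor's integration time.

    The gated trace is smoothed with a box filter of ``box_width`` seconds
    (default 100 ms, about the integration time of mouse cones); only
    complete (untruncated) windows enter the modulation depth
    (max − min)/mean, so edge transients cannot inflate it.
    """
    fs = trace.config.sample_rate
    if trace.time.size / fs <= 3.0 * box_width:
        raise ValueError(
            f"trace duration {trace.time.size / fs:g} s must exceed 3× the "
            f"box width {box_width:g} s"
        )
    w = int(round(box_width * fs))
    seg = _moving_mean_valid(trace.intensity, w)
    t = trace.time[w // 2 : w // 2 + seg.size]
    mean = float(seg.mean())
    depth = 0.0 if mean == 0 else float((seg.max() - seg.min()) / mean)
    return ModulationResult(t, seg, depth, mean)
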