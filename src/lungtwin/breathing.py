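"""Parametric hysteresis-loop model of lung-tumor motion during breathing.

A lung tumor does not retrace the same path during inhalation and
exhalation: over one breath it sweeps a closed, planar hysteresis loop.
This module implements the two-parabola loop family used by the phantom.
With the loop width ``2r`` (mm) and height ``h`` (mm), the two branches are

    y_inhale(x) = h / (2r)^2 * x^2
    y_exhale(x) = [ -(x - 2r)^2 + (2r)^2 ] * h / (2r)^2

for x in [0, 2r]; they meet at (0, 0) and (2r, h).  The height follows from
the phantom's lever geometry, ``h = 2 * d1 * l / d2``, where ``d1`` and
``d2`` are the lever offsets and ``l`` the rod length.

Time parameterization uses the horizontal crank of the mechanism,
``x(t) = r * (1 - cos(2*pi*t/T))`` with ``T`` the breath period, so that
the ideal loop and the simulated machine motion share a common clock:
inhalation occupies t in [0, T/2], exhalation t in (T/2, T].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BreathingSpec",
    "GeometryConfig",
    "HysteresisLoop",
    "period_from_bpm",
    "bpm_from_period",
    "amplitude_from_lever",
    "y_inhale",
    "y_exhale",
    "x_of_time",
    "y_of_time",
    "sample_loop",
    "loop_area",
    "sweep_family",
]


# --------------------------------------------------------------------------
# breathing timing
# --------------------------------------------------------------------------

def period_from_bpm(bpm: float) -> float:
    """Breath period in seconds from a respiratory rate in breaths/minute.

    Resting adults breathe roughly 16-20 times per minute, i.e. one full
    inhale+exhale every 3-3.75 s.
    """
    if not bpm > 0:
        raise ValueError(f"breaths per minute must be positive, got {bpm}")
    return 60.0 / bpm


def bpm_from_period(period_s: float) -> float:
    """Respiratory rate in breaths/minute from the breath period in seconds."""
    if not period_s > 0:
        raise ValueError(f"period must be positive, got {period_s}")
    return 60.0 / period_s


@dataclass(frozen=True)
class BreathingSpec:
    """Breathing timing: one crank revolution per breath of period ``period_s``.

    ``breaths_per_min`` is a redundant encoding kept for config readability;
    the two must agree (product equals 60).
    """

    period_s: float
    breaths_per_min: float | None = None

    def __post_init__(self) -> None:
        if not self.period_s > 0:
            raise ValueError(f"period_s must be positive, got {self.period_s}")
        if self.breaths_per_min is None:
            object.__setattr__(self, "breaths_per_min", 60.0 / self.period_s)
        elif abs(self.breaths_per_min * self.period_s - 60.0) > 1e-9 * 60.0:
            raise ValueError(
                f"inconsistent breathing spec: {self.breaths_per_min} bpm x "
                f"{self.period_s} s != 60"
            )

    @classmethod
    def from_bpm(cls, bpm: float) -> "BreathingSpec":
        return cls(period_s=period_from_bpm(bpm))


# --------------------------------------------------------------------------
# mechanism geometry and loop amplitude
# --------------------------------------------------------------------------

def amplitude_from_lever(d1: float, d2: float, l: float) -> float:
    """Loop height h = 2*d1*l/d2 (mm) from the vertical lever geometry.

    Sliding the rod joint changes ``d1``/``d2`` and thereby the vertical
    amplitude of the Tip; ``h = 0`` (flat loop) is a legal degenerate case.
    """
    if d2 == 0:
        raise ValueError("lever pivot offset d2 must be nonzero")
    if d2 < 0 or d1 < 0 or l < 0:
        raise ValueError("lever dimensions must be nonnegative (d2 > 0)")
    return 2.0 * d1 * l / d2


@dataclass(frozen=True)
class GeometryConfig:
    """Mechanism dimensions in mm: crank radius ``r`` (half the loop width),
    lever offsets ``d1``/``d2`` and rod length ``l``.

    ``mirror`` flips which branch is the lower one (inhale lower by default;
    patients differ and the device does not fix the orientation).
    """

    r: float
    d1: float
    d2: float
    l: float
    mirror: bool = False

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"crank radius r must be positive, got {self.r}")
        # validates d1, d2, l
        h = amplitude_from_lever(self.d1, self.d2, self.l)
        if h == 0:
            logger.warning("degenerate flat loop: h = 0 (d1 or l is zero)")
        if self.r < 1e-3:
            logger.warning("very narrow loop: r = %g mm", self.r)

    @property
    def h(self) -> float:
        """Derived loop height, mm."""
        return amplitude_from_lever(self.d1, self.d2, self.l)

    @property
    def width(self) -> float:
        """Loop width 2r, mm."""
        return 2.0 * self.r


# --------------------------------------------------------------------------
# loop branches
# --------------------------------------------------------------------------

def _check_x(x: np.ndarray, r: float) -> None:
    if np.any(x < -1e-9) or np.any(x > 2.0 * r + 1e-9):
        raise ValueError(f"x must lie in [0, 2r] = [0, {2 * r}]")


def y_inhale(x, r: float, h: float):
    """Lower (inhalation) branch y = h*x^2/(4 r^2), mm."""
    if not r > 0:
        raise ValueError("r must be positive")
    x = np.asarray(x, dtype=float)
    _check_x(x, r)
    out = h * x**2 / (4.0 * r**2)
    return float(out) if out.ndim == 0 else out


def y_exhale(x, r: float, h: float):
    """Upper (exhalation) branch y = h*[4r^2 - (x-2r)^2]/(4 r^2), mm."""
    if not r > 0:
        raise ValueError("r must be positive")
    x = np.asarray(x, dtype=float)
    _check_x(x, r)
    out = h * (4.0 * r**2 - (x - 2.0 * r) ** 2) / (4.0 * r**2)
    return float(out) if out.ndim == 0 else out


def x_of_time(t, geometry: GeometryConfig, breathing: BreathingSpec):
    """Horizontal crank position x(t) = r*(1 - cos(2*pi*t/T)), mm."""
    t = np.asarray(t, dtype=float)
    out = geometry.r * (1.0 - np.cos(2.0 * np.pi * t / breathing.period_s))
    # clip the float roundoff that can push x a hair outside [0, 2r]
    out = np.clip(out, 0.0, 2.0 * geometry.r)
    return float(out) if out.ndim == 0 else out


def y_of_time(t, geometry: GeometryConfig, breathing: BreathingSpec):
    """Ideal vertical position at time t: inhale branch for t mod T <= T/2,
    exhale branch after, mm."""
    t = np.asarray(t, dtype=float)
    T = breathing.period_s
    x = x_of_time(t, geometry, breathing)
    tm = np.mod(t, T)
    inhale = tm <= T / 2.0
    y_in = y_inhale(x, geometry.r, geometry.h)
    y_ex = y_exhale(x, geometry.r, geometry.h)
    if geometry.mirror:
        inhale = ~inhale
    out = np.where(inhale, y_in, y_ex)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# sampled loop container
# --------------------------------------------------------------------------

@dataclass
class HysteresisLoop:
    """A time-sampled closed hysteresis loop.

    ``t`` (s), ``x``/``y`` (mm) are equal-length arrays; ``branch`` labels
    each sample ``"inhale"`` or ``"exhale"``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    branch: np.ndarray
    width_mm: float
    height_mm: float

    def __len__(self) -> int:
        return len(self.t)

    @property
    def vertices(self) -> np.ndarray:
        """(n, 2) array of (x, y) vertices."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "x_mm": self.x, "y_mm": self.y, "branch": self.branch}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HysteresisLoop":
        df = pd.read_csv(path)
        x = df["x_mm"].to_numpy(float)
        y = df["y_mm"].to_numpy(float)
        return cls(
            t=df["t_s"].to_numpy(float),
            x=x,
            y=y,
            branch=df["branch"].to_numpy(str),
            width_mm=float(x.max() - x.min()),
            height_mm=float(y.max() - y.min()),
        )


def sample_loop(
    geometry: GeometryConfig, breathing: BreathingSpec, n: int = 2000
) -> HysteresisLoop:
    """Sample one ideal loop at ``n`` uniformly spaced times on [0, T].

    The first and last samples coincide at the origin; the apex (2r, h) is
    reached at t = T/2.
    """
    if n < 8:
        raise ValueError(f"need at least 8 samples to represent a loop, got {n}")
    T = breathing.period_s
    t = np.linspace(0.0, T, n)
    x = x_of_time(t, geometry, breathing)
    y = y_of_time(t, geometry, breathing)
    inhale = t <= T / 2.0
    branch = np.where(inhale, "inhale", "exhale")
    return HysteresisLoop(
        t=t, x=x, y=y, branch=branch, width_mm=2.0 * geometry.r,
        height_mm=geometry.h,
    )


def loop_area(geometry: GeometryConfig) -> float:
    """Area enclosed by the loop, mm^2.

    The gap between the branches is h*(4rx - 2x^2)/(4r^2); integrating over
    [0, 2r] gives 2*h*r/3.  Useful as a one-number QA summary of a setup.
    """
    return 2.0 * geometry.h * geometry.r / 3.0


def sweep_family(
    base: GeometryConfig,
    param: str,
    values: Sequence[float],
    breathing: BreathingSpec | None = None,
    n: int = 2000,
) -> list[HysteresisLoop]:
    """Family of loops obtained by sweeping one geometric parameter.

    ``param`` is ``"r"`` (loop width sweep) or ``"d1"`` (loop height sweep);
    all other dimensions are held at the base geometry.  Loops are returned
    in the order of ``values``.
    """
    if param not in ("r", "d1"):
        raise ValueError(f"unknown sweep parameter {param!r}; expected 'r' or 'd1'")
    if any(v <= 0 for v in values):
        raise ValueError("sweep values must be positive")
    if breathing is None:
        breathing = BreathingSpec(period_s=3.75)
    loops = []
    for v in values:
        kwargs = dict(r=base.r, d1=base.d1, d2=base.d2, l=base.l, mirror=base.mirror)
        kwargs[param] = v
        loops.append(sample_loop(GeometryConfig(**kwargs), breathing, n))
    return loops
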