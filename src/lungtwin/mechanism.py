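"""Two-stepper mechanism model: kinematics, speed planning, step simulation.

The phantom moves its Tip (the simulated tumor) with two NEMA 17 stepper
motors.  The horizontal motor turns at constant speed, one revolution per
breath; through a Scotch-yoke slider it produces ``x = r (1 - cos th_h)``.
The vertical motor drives a crank-lever of amplitude ``h`` giving
``y = (h/2)(1 - cos th_v)``.  To trace the asymmetric hysteresis loop the
vertical motor cannot turn uniformly: its revolution is divided into six
sections of 60 degrees each, every section driven at its own constant
speed, with the six speeds averaging to the horizontal speed so both motors
complete a revolution per breath.

The planner inverts the ideal loop into the required vertical angle
``th_v*(t)`` and either collocates the six section boundaries on it
(default) or additionally least-squares-refines the section speeds against
the ideal path.  ``quantize`` turns a profile into the firmware-equivalent
stream of microstep pulses, and ``simulate_run`` replays that stream
through the forward kinematics to produce the achieved Tip trajectory,
including the homing/synchronization transient of the first two cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from ._geom import polyline_distances
from .breathing import (
    BreathingSpec,
    GeometryConfig,
    x_of_time,
    y_of_time,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MotorSpec",
    "SpeedProfile",
    "StepStream",
    "MachineState",
    "SimulatedTrajectory",
    "forward_kinematics",
    "required_vertical_angle",
    "solve_speed_profile",
    "quantize",
    "home",
    "simulate_run",
]

#: number of sections the vertical revolution is split into (60 deg each)
N_SECTIONS = 6
SECTION_DEG = 360.0 / N_SECTIONS
#: step-pulse timestamps are kept on a 1 microsecond tick
TIME_TICK_S = 1e-6
#: cycles during which the controller runs the vertical motor uniformly
#: while synchronizing (the startup transient seen on the physical device)
SYNC_CYCLES = 2

_ALLOWED_MICROSTEPS = (1, 2, 4, 8, 16, 32)


@dataclass(frozen=True)
class MotorSpec:
    """Stepper motor resolution: 1.8 deg full steps (200/rev) with one of
    the driver's microstep divisors (down to 1/32)."""

    full_step_deg: float = 1.8
    microstep_divisor: int = 32

    def __post_init__(self) -> None:
        spr = 360.0 / self.full_step_deg
        if abs(spr - round(spr)) > 1e-9:
            raise ValueError(
                f"full step angle {self.full_step_deg} deg does not divide 360"
            )
        if self.microstep_divisor not in _ALLOWED_MICROSTEPS:
            raise ValueError(
                f"microstep divisor must be one of {_ALLOWED_MICROSTEPS}"
            )

    @property
    def steps_per_rev(self) -> int:
        return round(360.0 / self.full_step_deg)

    @property
    def microstep_deg(self) -> float:
        """Angle of one (micro)step increment, degrees."""
        return self.full_step_deg / self.microstep_divisor

    @property
    def pulses_per_rev(self) -> int:
        return self.steps_per_rev * self.microstep_divisor


# --------------------------------------------------------------------------
# forward kinematics
# --------------------------------------------------------------------------

def forward_kinematics(theta_h, theta_v, geometry: GeometryConfig):
    """Tip position (x, y) in mm from the two motor angles in degrees.

    x = r (1 - cos th_h), y = (h/2)(1 - cos th_v); both maps are 2*pi
    periodic, so continuous forward rotation retraces the loop every turn.
    """
    th = np.radians(np.asarray(theta_h, dtype=float))
    tv = np.radians(np.asarray(theta_v, dtype=float))
    x = geometry.r * (1.0 - np.cos(th))
    y = (geometry.h / 2.0) * (1.0 - np.cos(tv))
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


# --------------------------------------------------------------------------
# inverse problem: required vertical angle and the six-section profile
# --------------------------------------------------------------------------

def required_vertical_angle(
    t,
    geometry: GeometryConfig,
    breathing: BreathingSpec,
    y_fn=None,
):
    """Vertical motor angle th_v*(t), degrees, that places the Tip on the
    ideal loop at time t.

    Inverts y = (h/2)(1 - cos th_v): the arccos branch is mapped to
    [0, 180] while y rises (t <= T/2) and to [180, 360] while it falls, so
    th_v* increases monotonically from 0 to 360 over one breath.

    ``y_fn(t)`` may override the ideal vertical trajectory (used for
    ablation; default is the hysteresis-loop ideal).
    """
    h = geometry.h
    if h == 0:
        raise ValueError("flat loop (h = 0): no vertical inversion exists")
    t = np.asarray(t, dtype=float)
    T = breathing.period_s
    if np.any(t < -1e-12) or np.any(t > T * (1 + 1e-12)):
        raise ValueError(f"t must lie within one cycle [0, {T}]")
    y = np.asarray(y_fn(t) if y_fn is not None else y_of_time(t, geometry, breathing))
    a = np.degrees(np.arccos(np.clip(1.0 - 2.0 * y / h, -1.0, 1.0)))
    out = np.where(t <= T / 2.0, a, 360.0 - a)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SpeedProfile:
    """Piecewise-constant vertical speed plan over one breath cycle.

    Six section speeds (deg/s) each covering exactly 60 degrees of vertical
    rotation; section boundary times run from 0 to the period T.  The
    horizontal motor turns at the constant 360/T throughout, which equals
    the cycle-average of the six vertical speeds.
    """

    horizontal_speed_dps: float
    section_speeds_dps: tuple[float, ...]
    section_boundaries_s: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.section_speeds_dps, dtype=float)
        tb = np.asarray(self.section_boundaries_s, dtype=float)
        if len(w) != N_SECTIONS or len(tb) != N_SECTIONS + 1:
            raise ValueError("profile needs 6 speeds and 7 boundary times")
        if np.any(w <= 0):
            raise ValueError("section speeds must be positive")
        turn = w * np.diff(tb)
        if np.any(np.abs(turn - SECTION_DEG) > 1e-6):
            raise ValueError("each section must cover exactly 60 degrees")
        T = tb[-1] - tb[0]
        if abs(self.horizontal_speed_dps - 360.0 / T) > 1e-6 * 360.0 / T:
            raise ValueError("mean vertical speed must equal horizontal speed")

    @property
    def period_s(self) -> float:
        return float(
            self.section_boundaries_s[-1] - self.section_boundaries_s[0]
        )

    @classmethod
    def uniform(cls, period_s: float) -> "SpeedProfile":
        """The unmodulated profile: both motors at 360/T."""
        w = 360.0 / period_s
        tb = tuple(period_s * k / N_SECTIONS for k in range(N_SECTIONS + 1))
        return cls(w, (w,) * N_SECTIONS, tb)

    def theta_v(self, t):
        """Accumulated vertical angle (deg) at time t within one cycle,
        the piecewise-linear integral of the section speeds."""
        tb = np.asarray(self.section_boundaries_s)
        ang = np.concatenate([[0.0], np.cumsum(
            np.asarray(self.section_speeds_dps) * np.diff(tb))])
        out = np.interp(np.asarray(t, dtype=float), tb, ang)
        return float(out) if np.ndim(t) == 0 else out


def _collocation_boundaries(
    geometry: GeometryConfig, breathing: BreathingSpec, y_fn=None
) -> np.ndarray:
    """Times t_k at which th_v*(t_k) = k*60 deg, k = 0..6, by bracketed
    root-finding on the monotone inverse trajectory."""
    T = breathing.period_s

    def g(t, target):
        return required_vertical_angle(t, geometry, breathing, y_fn) - target

    tk = [0.0]
    for k in range(1, N_SECTIONS):
        target = k * SECTION_DEG
        lo, hi = tk[-1], T
        if g(lo, target) > 0 or g(hi, target) < 0:  # pragma: no cover
            raise RuntimeError("vertical angle is not monotone; cannot bracket")
        tk.append(brentq(g, lo, hi, args=(target,), xtol=1e-12, rtol=1e-15))
    tk.append(T)
    return np.asarray(tk)


def solve_speed_profile(
    geometry: GeometryConfig,
    breathing: BreathingSpec,
    refine: bool = False,
    y_fn=None,
    refine_grid: int = 201,
    refine_polyline: int = 1201,
) -> SpeedProfile:
    """Solve the six vertical section speeds that trace the ideal loop.

    Collocation (default): place the section boundaries where the required
    angle crosses multiples of 60 deg, so the profile's accumulated angle is
    exact at every boundary; each speed is then 60 deg over the section
    duration.

    With ``refine`` the six speeds are additionally adjusted by least
    squares over a dense time grid, minimizing the Euclidean deviation of
    the resulting path from the ideal loop subject to the synchronization
    constraint (the six sections still cover 60 deg each and sum to one
    revolution per period).  Collocation interpolates the angle exactly at
    boundaries but overshoots in between; the refined profile trades the
    boundary exactness for a smaller path deviation overall.
    """
    if geometry.h == 0:
        raise ValueError("flat loop (h = 0) has no vertical speed profile")
    T = breathing.period_s
    tk = _collocation_boundaries(geometry, breathing, y_fn)
    w0 = SECTION_DEG / np.diff(tk)
    if not refine:
        return SpeedProfile(360.0 / T, tuple(w0), tuple(tk))

    # ideal path polyline and evaluation grid shared by all objective calls
    tl = np.linspace(0.0, T, refine_polyline)
    poly = np.column_stack([
        x_of_time(tl, geometry, breathing),
        y_fn(tl) if y_fn is not None else y_of_time(tl, geometry, breathing),
    ])
    tg = np.linspace(0.0, T, refine_grid)
    xg = x_of_time(tg, geometry, breathing)
    half_h = geometry.h / 2.0

    def path_rms(w):
        dt = SECTION_DEG / w
        tb = np.concatenate([[0.0], np.cumsum(dt)])
        ang = np.concatenate([[0.0], np.cumsum(w * dt)])
        th = np.interp(tg, tb, ang)
        pts = np.column_stack([xg, half_h * (1.0 - np.cos(np.radians(th)))])
        d = polyline_distances(pts, poly)
        return float(np.mean(d**2))

    res = minimize(
        path_rms,
        w0,
        method="SLSQP",
        bounds=[(0.05 * 360.0 / T, 50.0 * 360.0 / T)] * N_SECTIONS,
        constraints=[{"type": "eq",
                      "fun": lambda w: float(np.sum(SECTION_DEG / w) - T)}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    # accept any feasible iterate that improves on collocation (SLSQP may
    # stop at the iteration limit while already far below the start)
    feasible = abs(np.sum(SECTION_DEG / res.x) - T) < 1e-6 * T
    if feasible and path_rms(res.x) <= path_rms(w0):
        w = res.x
    else:  # pragma: no cover
        logger.warning("speed refinement rejected: %s", res.message)
        w = w0
    # renormalize so the durations sum to T exactly
    dt = SECTION_DEG / w
    dt *= T / dt.sum()
    w = SECTION_DEG / dt
    tb = np.concatenate([[0.0], np.cumsum(dt)])
    tb[-1] = T
    return SpeedProfile(360.0 / T, tuple(w), tuple(tb))


# --------------------------------------------------------------------------
# step quantization
# --------------------------------------------------------------------------

@dataclass
class StepStream:
    """Timestamped microstep pulses for both motors (firmware equivalent).

    All pulses are direction +1: the device runs by continuous forward
    rotation.  Timestamps are on a 1 microsecond tick, nondecreasing
    overall and strictly increasing per motor.
    """

    t: np.ndarray
    motor: np.ndarray  # "horizontal" | "vertical"
    direction: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def times(self, motor: str) -> np.ndarray:
        return self.t[self.motor == motor]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "motor": self.motor, "direction": self.direction}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _round_tick(t: np.ndarray) -> np.ndarray:
    """Round times to the nearest 1 us tick, halves up."""
    return np.floor(t / TIME_TICK_S + 0.5) * TIME_TICK_S


def _vertical_pulse_times(profile: SpeedProfile, motor: MotorSpec) -> np.ndarray:
    """Unrounded pulse times for one vertical revolution under ``profile``.

    Pulse m fires when the accumulated angle reaches m * microstep; the
    sub-step phase therefore carries across section boundaries and exactly
    ``pulses_per_rev`` pulses occur per cycle.
    """
    delta = motor.microstep_deg
    n = motor.pulses_per_rev
    angles = np.arange(1, n + 1) * delta
    tb = np.asarray(profile.section_boundaries_s)
    w = np.asarray(profile.section_speeds_dps)
    bounds = np.arange(N_SECTIONS + 1) * SECTION_DEG
    k = np.clip(np.searchsorted(bounds, angles, side="left") - 1, 0, N_SECTIONS - 1)
    return tb[k] + (angles - bounds[k]) / w[k]


def quantize(profile: SpeedProfile, motor: MotorSpec, n_cycles: int = 1) -> StepStream:
    """Expand a speed profile into ``n_cycles`` of microstep pulses.

    Within each section pulses are evenly spaced at microstep/speed; per
    cycle each motor accumulates exactly steps_per_rev * microstep_divisor
    pulses.
    """
    return _quantize_cycles([profile] * int(n_cycles), motor)


def _quantize_cycles(profiles: list[SpeedProfile], motor: MotorSpec) -> StepStream:
    """One StepStream from a per-cycle list of profiles (all same period)."""
    if len(profiles) < 1:
        raise ValueError("need at least one cycle")
    T = profiles[0].period_s
    n = motor.pulses_per_rev
    delta = motor.microstep_deg
    w_h = profiles[0].horizontal_speed_dps
    n_cycles = len(profiles)

    t_h = np.arange(1, n * n_cycles + 1) * (delta / w_h)
    t_v = np.concatenate(
        [c * T + _vertical_pulse_times(p, motor) for c, p in enumerate(profiles)]
    )
    t_h, t_v = _round_tick(t_h), _round_tick(t_v)

    t = np.concatenate([t_h, t_v])
    motor_id = np.concatenate([np.zeros(len(t_h), int), np.ones(len(t_v), int)])
    order = np.lexsort((motor_id, t))  # by time, horizontal first on ties
    labels = np.array(["horizontal", "vertical"])
    return StepStream(
        t=t[order],
        motor=labels[motor_id[order]],
        direction=np.ones(len(t), dtype=int),
    )


# --------------------------------------------------------------------------
# homing against the optical endstops
# --------------------------------------------------------------------------

@dataclass
class MachineState:
    """Motor angles (deg) plus the homing status of the machine.

    Each motor has an optical endstop triggered by a protuberance on its
    axis; the endstop reference defines angle zero.
    """

    angle_h_deg: float = 0.0
    angle_v_deg: float = 0.0
    homed: bool = False
    endstop_h_deg: float = 0.0
    endstop_v_deg: float = 0.0


def _home_axis(angle: float, endstop: float, motor: MotorSpec) -> float:
    """Forward-only rotation in microsteps until the endstop is crossed."""
    delta = motor.microstep_deg
    residual = (endstop - angle) % 360.0
    steps = int(np.ceil(residual / delta - 1e-9))
    if steps > 2 * motor.pulses_per_rev:  # pragma: no cover
        raise RuntimeError("endstop not triggered within 2 revolutions")
    return angle + steps * delta


def home(initial: MachineState, motor: MotorSpec) -> MachineState:
    """Rotate each motor forward until its optical endstop triggers.

    Rotation is forward-only (the device never reverses); the final angle
    overshoots the endstop reference by less than one microstep.  Homing an
    already-homed state is a no-op.
    """
    if initial.homed:
        return initial
    return MachineState(
        angle_h_deg=_home_axis(initial.angle_h_deg, initial.endstop_h_deg, motor),
        angle_v_deg=_home_axis(initial.angle_v_deg, initial.endstop_v_deg, motor),
        homed=True,
        endstop_h_deg=initial.endstop_h_deg,
        endstop_v_deg=initial.endstop_v_deg,
    )


# --------------------------------------------------------------------------
# full-run simulation
# --------------------------------------------------------------------------

@dataclass
class SimulatedTrajectory:
    """Achieved Tip path: one (t, x, y) sample per step-pulse event, with
    the breath-cycle index attributed from the horizontal motor angle."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cycle_index: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "x_mm": self.x, "y_mm": self.y,
             "cycle": self.cycle_index}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_run(
    geometry: GeometryConfig,
    breathing: BreathingSpec,
    motor: MotorSpec | None = None,
    n_cycles: int = 20,
    include_homing: bool = True,
    profile: SpeedProfile | None = None,
    seed: int | None = None,
) -> SimulatedTrajectory:
    """Simulate ``n_cycles`` breaths of the machine at step resolution.

    With ``include_homing`` the run models the device's startup: the motors
    home from (seeded) arbitrary angles before t = 0, and the controller
    runs the vertical motor unmodulated for the first two cycles while
    synchronizing — during these the Tip traces the degenerate straight
    segment instead of the loop, reproducing the transient observed before
    the profile engages at cycle 2.  Without it the solved profile is
    active from the first cycle.
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    if motor is None:
        motor = MotorSpec()
    if profile is None:
        profile = solve_speed_profile(geometry, breathing)

    if include_homing:
        rng = np.random.default_rng(seed)
        start = MachineState(
            angle_h_deg=float(rng.uniform(0.0, 360.0)),
            angle_v_deg=float(rng.uniform(0.0, 360.0)),
        )
        state = home(start, motor)
        logger.debug(
            "homed from (%.1f, %.1f) deg", start.angle_h_deg, start.angle_v_deg
        )
        n_sync = min(SYNC_CYCLES, n_cycles)
        profiles = [SpeedProfile.uniform(profile.period_s)] * n_sync + [
            profile
        ] * (n_cycles - n_sync)
    else:
        profiles = [profile] * n_cycles

    stream = _quantize_cycles(profiles, motor)
    delta = motor.microstep_deg
    is_h = stream.motor == "horizontal"
    count_h = np.cumsum(is_h)
    count_v = np.cumsum(~is_h)
    x, y = forward_kinematics(count_h * delta, count_v * delta, geometry)
    cycle = np.maximum(count_h - 1, 0) // motor.pulses_per_rev
    return SimulatedTrajectory(t=stream.t, x=x, y=y, cycle_index=cycle)
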