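"""Deviation scoring between measured and ideal Tip trajectories.

A run is scored by the nearest-point Euclidean distance from each measured
sample to the densely sampled ideal hysteresis loop, reported per breath
cycle and split into upper/lower loop regions (boundary y = h/2).  The
first cycles of a run are the synchronization transient and are excluded
from the headline maximum (two by default), mirroring how the physical
device settles after startup.

``run_verification`` chains the whole twin: speed-profile solve ->
microstep quantization -> kinematic simulation -> synthetic-camera render
-> sticker tracking -> deviation report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._geom import polyline_distances
from .breathing import BreathingSpec, GeometryConfig, HysteresisLoop, sample_loop
from .mechanism import MotorSpec, SimulatedTrajectory, simulate_run, solve_speed_profile
from .tracking import CameraConfig, TrackedTrajectory, render_frames, track

logger = logging.getLogger(__name__)

__all__ = [
    "DeviationReport",
    "SetupPreset",
    "PRESETS",
    "get_preset",
    "point_to_loop_distance",
    "deviation_report",
    "run_verification",
]


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SetupPreset:
    """A named device setup: 'wider' loops are wide and flat, 'higher'
    loops narrow and tall."""

    name: str
    geometry: GeometryConfig

    def __post_init__(self) -> None:
        w, h = self.geometry.width, self.geometry.h
        if self.name == "wider" and not w > h:
            raise ValueError("wider preset must have width > height")
        if self.name == "higher" and not h > w:
            raise ValueError("higher preset must have height > width")


#: Default setups: a wide-flat loop (40 x 10 mm) and a narrow-tall loop
#: (15 x 30 mm), both realizable with the stock lever (d2 = 20, l = 20 mm).
PRESETS: dict[str, SetupPreset] = {
    "wider": SetupPreset("wider", GeometryConfig(r=20.0, d1=5.0, d2=20.0, l=20.0)),
    "higher": SetupPreset("higher", GeometryConfig(r=7.5, d1=15.0, d2=20.0, l=20.0)),
}


def get_preset(name: str) -> SetupPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


# --------------------------------------------------------------------------
# deviation metric
# --------------------------------------------------------------------------

def point_to_loop_distance(p, loop: HysteresisLoop) -> float:
    """Minimum Euclidean distance (mm) from a point to the loop polyline.

    Distances are to the nearest point on a segment, not the nearest
    vertex, so a densely sampled loop (>= 2000 points) gives an essentially
    continuous metric.
    """
    if len(loop) < 2:
        raise ValueError("loop must have at least 2 samples")
    return float(polyline_distances(np.asarray(p, float)[None, :], loop.vertices)[0])


@dataclass
class DeviationReport:
    """Per-cycle and region-wise deviation summary of one run.

    ``per_cycle`` is a DataFrame (cycle, n_valid, max_dev_mm, mean_dev_mm);
    cycles with no valid samples carry NaN (missing, not zero).
    ``overall_max_mm`` is the maximum over cycles after excluding the first
    ``excluded_cycles`` as the synchronization transient, while the
    upper/lower region maxima are taken over the whole run.
    """

    per_cycle: pd.DataFrame
    overall_max_mm: float
    upper_max_mm: float
    lower_max_mm: float
    excluded_cycles: int

    def to_text(self) -> str:
        lines = [
            f"excluded_cycles: {self.excluded_cycles}",
            f"overall_max_mm: {self.overall_max_mm:.4f}",
            f"upper_max_mm: {self.upper_max_mm:.4f}",
            f"lower_max_mm: {self.lower_max_mm:.4f}",
            "per_cycle:",
            self.per_cycle.to_csv(index=False).rstrip(),
        ]
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())


def _measured_arrays(measured, period_s: float):
    """Common (t, x, y, valid, cycle) view of tracked or simulated data."""
    t = np.asarray(measured.t, dtype=float)
    x = np.asarray(measured.x, dtype=float)
    y = np.asarray(measured.y, dtype=float)
    if isinstance(measured, TrackedTrajectory) or hasattr(measured, "valid"):
        valid = np.asarray(measured.valid, dtype=bool)
    else:
        valid = np.ones(len(t), dtype=bool)
    if hasattr(measured, "cycle_index"):
        cycle = np.asarray(measured.cycle_index, dtype=int)
    else:
        # attribute cycles from the horizontal period
        cycle = np.floor(t / period_s - 1e-12).astype(int)
        cycle = np.maximum(cycle, 0)
    return t, x, y, valid, cycle


def deviation_report(
    measured,
    ideal: HysteresisLoop,
    n_sync: int = 2,
) -> DeviationReport:
    """Score a measured trajectory against the ideal loop.

    ``measured`` is a TrackedTrajectory or SimulatedTrajectory (anything
    with t/x/y and optionally valid/cycle_index).  The first ``n_sync``
    cycles are excluded from ``overall_max_mm``; the upper/lower region
    maxima (split at y = h/2 of the ideal loop) cover every cycle.
    """
    if n_sync < 0:
        raise ValueError("n_sync must be nonnegative")
    period = float(ideal.t[-1] - ideal.t[0])
    t, x, y, valid, cycle = _measured_arrays(measured, period)

    dev = np.full(len(t), np.nan)
    if valid.any():
        pts = np.column_stack([x[valid], y[valid]])
        dev[valid] = polyline_distances(pts, ideal.vertices)

    n_cycles = int(cycle.max()) + 1 if len(cycle) else 0
    rows = []
    for c in range(n_cycles):
        sel = valid & (cycle == c)
        if sel.any():
            rows.append((c, int(sel.sum()), float(np.max(dev[sel])),
                         float(np.mean(dev[sel]))))
        else:
            logger.warning("cycle %d has no valid samples", c)
            rows.append((c, 0, np.nan, np.nan))
    per_cycle = pd.DataFrame(
        rows, columns=["cycle", "n_valid", "max_dev_mm", "mean_dev_mm"]
    )

    included = per_cycle[per_cycle["cycle"] >= n_sync]["max_dev_mm"]
    overall = float(included.max()) if included.notna().any() else float("nan")

    half = ideal.height_mm / 2.0
    upper = valid & (y > half)
    lower = valid & ~(y > half)
    upper_max = float(np.max(dev[upper])) if upper.any() else float("nan")
    lower_max = float(np.max(dev[lower])) if lower.any() else float("nan")

    return DeviationReport(
        per_cycle=per_cycle,
        overall_max_mm=overall,
        upper_max_mm=upper_max,
        lower_max_mm=lower_max,
        excluded_cycles=n_sync,
    )


# --------------------------------------------------------------------------
# end-to-end verification
# --------------------------------------------------------------------------

def run_verification(
    preset: SetupPreset | str,
    breathing: BreathingSpec | None = None,
    motor: MotorSpec | None = None,
    camera: CameraConfig | None = None,
    n_cycles: int = 20,
    seed: int = 0,
    n_sync: int = 2,
    refine: bool = True,
    use_tracking: bool = True,
    loop_samples: int = 4000,
) -> DeviationReport:
    """Run the full digital-twin verification experiment.

    Solves the (by default least-squares refined) speed profile, simulates
    ``n_cycles`` breaths at microstep resolution with homing and the
    two-cycle synchronization transient, films and tracks the run with the
    synthetic camera, and scores the tracked path against the ideal loop.
    Deterministic given ``seed``.  ``use_tracking=False`` scores the
    simulated trajectory directly (ablation of the camera stage).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if breathing is None:
        breathing = BreathingSpec(period_s=3.75)
    if motor is None:
        motor = MotorSpec()
    geometry = preset.geometry

    profile = solve_speed_profile(geometry, breathing, refine=refine)
    sim = simulate_run(
        geometry, breathing, motor, n_cycles=n_cycles,
        include_homing=True, profile=profile, seed=seed,
    )
    ideal = sample_loop(geometry, breathing, loop_samples)

    if use_tracking:
        if camera is None:
            camera = CameraConfig()
        camera = CameraConfig(**{**camera.__dict__, "seed": seed})
        stack = render_frames(sim, camera, lazy=True)
        measured = track(stack)
        logger.info(
            "tracked %d frames (%.1f%% valid)", len(measured),
            100.0 * measured.valid.mean() if len(measured) else 0.0,
        )
    else:
        measured = sim
    return deviation_report(measured, ideal, n_sync=n_sync)
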