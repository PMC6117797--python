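"""Synthetic camera and sticker-tracking stage of the verification workflow.

The physical phantom is verified by filming the Tip, which carries a white
sticker, and tracking it frame by frame: the image is converted to HSV, a
threshold isolates the low-saturation/high-value sticker pixels, the
largest connected binary region is taken to be the sticker and its
centroid gives the Tip position.  This module reproduces that workflow on
synthetic frames rendered from a simulated (or ideal) trajectory, so the
whole verification loop can run without a camera.

Conventions: hue is expressed in degrees (0-360) and saturation/value on
[0, 1] regardless of the 8-bit storage of frames; the image v axis points
down, so the mm conversion flips it (larger y in mm = higher in the scene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import uniform_filter
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

__all__ = [
    "CameraConfig",
    "HsvBounds",
    "FrameStack",
    "TrackedTrajectory",
    "render_frames",
    "hsv_threshold",
    "largest_region",
    "centroid",
    "track",
]


@dataclass(frozen=True)
class CameraConfig:
    """Synthetic camera: frame size, mm-to-pixel scale and noise model.

    ``origin_px`` is the pixel (u0, v0) of the trajectory origin (x, y) =
    (0, 0); when None the renderer centers the trajectory in the frame and
    records the origin it used.  ``noise_sigma`` is the std of additive
    Gaussian intensity noise in 8-bit counts.
    """

    width_px: int = 640
    height_px: int = 480
    px_per_mm: float = 8.0
    fps: float = 30.0
    sticker_radius_mm: float = 2.5
    noise_sigma: float = 3.0
    seed: int = 0
    origin_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be positive")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if 2.0 * self.sticker_radius_mm * self.px_per_mm < 3.0:
            raise ValueError("sticker diameter must cover at least 3 px")

    @property
    def sticker_radius_px(self) -> float:
        return self.sticker_radius_mm * self.px_per_mm


@dataclass(frozen=True)
class HsvBounds:
    """HSV threshold window: hue in degrees, saturation/value on [0, 1].

    Hue may wrap (low > high means the window crosses 0/360); saturation
    and value windows must be ordered.
    """

    h_lo: float = 0.0
    h_hi: float = 360.0
    s_lo: float = 0.0
    s_hi: float = 1.0
    v_lo: float = 0.0
    v_hi: float = 1.0

    def __post_init__(self) -> None:
        for name, val, top in (("h_lo", self.h_lo, 360.0), ("h_hi", self.h_hi, 360.0),
                               ("s_lo", self.s_lo, 1.0), ("s_hi", self.s_hi, 1.0),
                               ("v_lo", self.v_lo, 1.0), ("v_hi", self.v_hi, 1.0)):
            if not 0.0 <= val <= top:
                raise ValueError(f"{name}={val} outside [0, {top}]")
        if self.s_lo > self.s_hi:
            raise ValueError("inverted saturation bounds")
        if self.v_lo > self.v_hi:
            raise ValueError("inverted value bounds")

    @classmethod
    def white_sticker(cls) -> "HsvBounds":
        """Default window for the white sticker: any hue, low saturation,
        high value."""
        return cls(s_hi=0.25, v_lo=0.8)


@dataclass
class FrameStack:
    """Ordered 8-bit RGB frames with uniform timestamps at 1/fps.

    ``frames`` may be a materialized list or a one-shot generator (used for
    long runs so the full video never sits in memory).
    """

    frames: Iterable[np.ndarray]
    timestamps: np.ndarray
    camera: CameraConfig

    def __len__(self) -> int:
        return len(self.timestamps)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def save(self, directory) -> None:
        """Write a numbered PNG sequence plus a key-value metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(self.frames):
            iio.imwrite(directory / f"frame_{i:05d}.png", frame)
        meta = {
            "fps": self.camera.fps,
            "px_per_mm": self.camera.px_per_mm,
            "width_px": self.camera.width_px,
            "height_px": self.camera.height_px,
            "sticker_radius_mm": self.camera.sticker_radius_mm,
            "noise_sigma": self.camera.noise_sigma,
            "seed": self.camera.seed,
            "origin_u_px": None if self.camera.origin_px is None
            else float(self.camera.origin_px[0]),
            "origin_v_px": None if self.camera.origin_px is None
            else float(self.camera.origin_px[1]),
        }
        with open(directory / "metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, directory) -> "FrameStack":
        directory = Path(directory)
        with open(directory / "metadata.yaml") as fh:
            meta = yaml.safe_load(fh)
        origin = None
        if meta.get("origin_u_px") is not None:
            origin = (meta["origin_u_px"], meta["origin_v_px"])
        camera = CameraConfig(
            width_px=meta["width_px"], height_px=meta["height_px"],
            px_per_mm=meta["px_per_mm"], fps=meta["fps"],
            sticker_radius_mm=meta["sticker_radius_mm"],
            noise_sigma=meta["noise_sigma"], seed=meta["seed"],
            origin_px=origin,
        )
        paths = sorted(directory.glob("frame_*.png"))
        frames = [iio.imread(p) for p in paths]
        ts = np.arange(len(frames)) / camera.fps
        return cls(frames=frames, timestamps=ts, camera=camera)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _background(camera: CameraConfig, rng: np.random.Generator) -> np.ndarray:
    """Static darker textured backdrop (gray, well below the sticker value)."""
    tex = rng.normal(0.0, 40.0, (camera.height_px, camera.width_px))
    return np.clip(55.0 + uniform_filter(tex, size=9), 0.0, 140.0).astype(
        np.float32
    )


def render_frames(traj, camera: CameraConfig, lazy: bool = False) -> FrameStack:
    """Render the white-sticker scene along a trajectory.

    ``traj`` is anything with ``t`` (s) and ``x``/``y`` (mm) arrays (a
    simulated trajectory or a sampled ideal loop); positions are resampled
    at the camera frame times by linear interpolation.  Rendering is
    deterministic given ``camera.seed``.  With ``lazy`` the frames are a
    one-shot generator (constant memory for long runs).
    """
    t = np.asarray(traj.t, dtype=float)
    x = np.asarray(traj.x, dtype=float)
    y = np.asarray(traj.y, dtype=float)
    if len(t) == 0:
        return FrameStack(frames=[], timestamps=np.empty(0), camera=camera)

    n_frames = int(np.floor(t[-1] * camera.fps + 1e-9)) + 1
    ts = np.arange(n_frames) / camera.fps
    xs = np.interp(ts, t, x)
    ys = np.interp(ts, t, y)

    if camera.origin_px is None:
        u0 = (camera.width_px - 1) / 2.0 - camera.px_per_mm * (x.min() + x.max()) / 2.0
        v0 = (camera.height_px - 1) / 2.0 + camera.px_per_mm * (y.min() + y.max()) / 2.0
        camera = replace(camera, origin_px=(float(u0), float(v0)))
    u0, v0 = camera.origin_px

    us = u0 + camera.px_per_mm * xs
    vs = v0 - camera.px_per_mm * ys
    pad = camera.sticker_radius_px + 1.0
    if (us.min() < pad or us.max() > camera.width_px - 1 - pad
            or vs.min() < pad or vs.max() > camera.height_px - 1 - pad):
        raise ValueError("trajectory exceeds frame bounds at this camera scale")

    rng = np.random.default_rng(camera.seed)
    background = _background(camera, rng)
    h_px, w_px = background.shape
    radius = camera.sticker_radius_px

    def generate() -> Iterator[np.ndarray]:
        for u, v in zip(us, vs):
            gray = background.copy()
            # anti-aliased disc composited inside its bounding box only
            r_int = int(np.ceil(radius)) + 2
            r0, r1 = max(0, int(v) - r_int), min(h_px, int(v) + r_int + 1)
            c0, c1 = max(0, int(u) - r_int), min(w_px, int(u) + r_int + 1)
            rows = np.arange(r0, r1, dtype=np.float32)[:, None]
            cols = np.arange(c0, c1, dtype=np.float32)[None, :]
            dist = np.hypot(rows - v, cols - u)
            cov = np.clip(radius + 0.5 - dist, 0.0, 1.0).astype(np.float32)
            gray[r0:r1, c0:c1] = gray[r0:r1, c0:c1] * (1.0 - cov) + 255.0 * cov
            if camera.noise_sigma > 0:
                # gray sensor noise, identical across the three channels
                gray = gray + camera.noise_sigma * rng.standard_normal(
                    gray.shape, dtype=np.float32
                )
            frame8 = np.clip(gray, 0.0, 255.0).astype(np.uint8)
            yield np.repeat(frame8[:, :, None], 3, axis=2)

    frames: Iterable[np.ndarray] = generate() if lazy else list(generate())
    return FrameStack(frames=frames, timestamps=ts, camera=camera)


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

def _hue_degrees(frame: np.ndarray, cmax: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Hue in degrees from an RGB frame (0 where the pixel is achromatic)."""
    r = frame[..., 0].astype(np.float64)
    g = frame[..., 1].astype(np.float64)
    b = frame[..., 2].astype(np.float64)
    d = np.where(delta == 0, 1.0, delta).astype(np.float64)
    h = np.where(
        cmax == frame[..., 0], (g - b) / d,
        np.where(cmax == frame[..., 1], 2.0 + (b - r) / d, 4.0 + (r - g) / d),
    )
    h = (h * 60.0) % 360.0
    return np.where(delta == 0, 0.0, h)


def hsv_threshold(frame: np.ndarray, bounds: HsvBounds) -> np.ndarray:
    """Binary mask of pixels whose HSV values fall inside ``bounds``.

    The conversion follows the usual hexcone formulas (V = max/255,
    S = (max - min)/max, H from the dominant channel); hue is only
    evaluated when the hue window actually constrains it.
    """
    cmax = frame.max(axis=2)
    cmin = frame.min(axis=2)
    v = cmax / 255.0
    s = np.where(cmax == 0, 0.0, (cmax - cmin) / np.maximum(cmax, 1))
    mask = (
        (s >= bounds.s_lo) & (s <= bounds.s_hi)
        & (v >= bounds.v_lo) & (v <= bounds.v_hi)
    )
    if (bounds.h_lo, bounds.h_hi) != (0.0, 360.0):
        h = _hue_degrees(frame, cmax, cmax - cmin)
        if bounds.h_lo <= bounds.h_hi:
            mask &= (h >= bounds.h_lo) & (h <= bounds.h_hi)
        else:  # hue window wraps through 0/360
            mask &= (h >= bounds.h_lo) | (h <= bounds.h_hi)
    return mask


def largest_region(mask: np.ndarray) -> np.ndarray | None:
    """Largest 8-connected component of a binary mask as (n, 2) pixel
    (row, col) coordinates, or None when the mask is empty (no detection).

    Size ties are broken by the component whose first pixel comes earliest
    in row-major order.
    """
    labels = cc_label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        return None
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    top = np.flatnonzero(counts == counts[best - 1]) + 1
    if len(top) > 1:
        flat = labels.ravel()
        best = min(top, key=lambda lab: int(np.argmax(flat == lab)))
    return np.argwhere(labels == best)


def centroid(region: np.ndarray) -> tuple[float, float]:
    """Unweighted centroid (u, v) in pixels of a pixel region (sub-pixel)."""
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("cannot take the centroid of an empty region")
    return float(region[:, 1].mean()), float(region[:, 0].mean())


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------

@dataclass
class TrackedTrajectory:
    """Per-frame tracked Tip positions in pixels and calibrated mm.

    Frames with no detection are flagged invalid and carry NaN coordinates
    (they are kept, not dropped, to preserve the time base).
    """

    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "u_px": self.u, "v_px": self.v,
             "x_mm": self.x, "y_mm": self.y, "valid": self.valid}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrackedTrajectory":
        """Read a tracked trajectory CSV; a minimal (t, x, y) file from an
        external tracker is accepted (pixel columns filled with NaN)."""
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        t = df[cols.get("t_s", cols.get("t"))].to_numpy(float)
        x = df[cols.get("x_mm", cols.get("x"))].to_numpy(float)
        y = df[cols.get("y_mm", cols.get("y"))].to_numpy(float)
        nan = np.full(len(t), np.nan)
        u = df[cols["u_px"]].to_numpy(float) if "u_px" in cols else nan.copy()
        v = df[cols["v_px"]].to_numpy(float) if "v_px" in cols else nan.copy()
        valid = (df[cols["valid"]].astype(bool).to_numpy()
                 if "valid" in cols else ~np.isnan(x))
        return cls(t=t, u=u, v=v, x=x, y=y, valid=valid)


def track(
    stack: FrameStack,
    bounds: HsvBounds | None = None,
    origin_px: tuple[float, float] | None = None,
) -> TrackedTrajectory:
    """Track the sticker through a frame stack.

    Per frame: HSV threshold -> largest binary region -> centroid -> mm
    conversion x = (u - u0)/scale, y = (v0 - v)/scale (image v axis points
    down).  The calibration origin defaults to the one recorded by the
    renderer.
    """
    if bounds is None:
        bounds = HsvBounds.white_sticker()
    if origin_px is None:
        origin_px = stack.camera.origin_px
    if origin_px is None and len(stack) > 0:
        raise ValueError("no calibration origin available for this stack")

    n = len(stack)
    u = np.full(n, np.nan)
    v = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, frame in enumerate(stack):
        region = largest_region(hsv_threshold(frame, bounds))
        if region is None:
            logger.debug("no detection in frame %d", i)
            continue
        u[i], v[i] = centroid(region)
        valid[i] = True

    ppm = stack.camera.px_per_mm
    if n > 0:
        u0, v0 = origin_px
        x = (u - u0) / ppm
        y = (v0 - v) / ppm
    else:
        x = np.empty(0)
        y = np.empty(0)
    return TrackedTrajectory(
        t=np.asarray(stack.timestamps, dtype=float), u=u, v=v, x=x, y=y,
        valid=valid,
    )
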