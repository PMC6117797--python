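# Methods

`lungtwin` is a digital twin of an open-source, 3D-printed lung-tumor
motion phantom used in radiotherapy quality assurance. The physical
device moves a "Tip" (a sphere standing in for the tumor, optionally
carrying a dosimeter) along the closed planar path a lung tumor traces
over one breath, driven by two stepper motors. The twin reproduces the
whole chain in software: the ideal trajectory family, the motor speed
planning, the step-resolution motion, and the camera-based verification
used to measure how accurately the mechanism follows the plan.

## Trajectory model

Lung-tumor motion during quiet breathing is largely two-dimensional and
hysteretic: inhalation and exhalation follow different branches of a
closed loop. The model is a two-parabola loop of width `2r` and height
`h` (both mm):

    y_in(x) = h x^2 / (2r)^2
    y_ex(x) = [ -(x - 2r)^2 + (2r)^2 ] h / (2r)^2,   x in [0, 2r]

The branches meet at the origin (end of exhale) and the apex `(2r, h)`
(end of inhale); the exhale branch lies above the inhale branch
everywhere in between, and the enclosed area is `2hr/3`. The printed
form of the exhale equation is typographically ambiguous; the grouping
above is the only dimensionally consistent one that closes the loop at
both endpoints, and is the one implemented. `h` follows from the
vertical lever of the mechanism, `h = 2 d1 l / d2`, with `d1`, `d2` the
lever offsets and `l` the rod length; `h = 0` (flat loop) and very small
`r` are accepted as degenerate cases with a logged warning, since the
physical device allows sliding `d1` to zero.

Time is attached to the loop through the horizontal crank:
`x(t) = r (1 - cos(2 pi t / T))`, with `T` the breath period (default
3.75 s = 16 breaths/min; resting adults breathe 16-20 times per minute).
Inhalation occupies `[0, T/2]`, exhalation `(T/2, T]`. Which branch is
"lower" varies between patients; a `mirror` flag flips the orientation.

## Mechanism model and speed planning

Transfer functions: horizontal Scotch-yoke `x = r (1 - cos th_h)` and
vertical crank-lever `y = (h/2)(1 - cos th_v)`. Both motors rotate
forward only, one revolution per breath. The horizontal motor turns
uniformly at `360/T` deg/s. The vertical motor must be modulated: its
revolution is divided into six sections of 60 degrees, each driven at a
constant speed, with the constraint that the six sections together take
exactly `T` (equivalently, the mean vertical speed equals the horizontal
speed). The cosine form of the vertical transfer was chosen because the
uniform-speed case is then analytically checkable: equal motor speeds
collapse the loop onto the straight segment `y = (h/2r) x`.

The required vertical angle is the inversion
`th_v*(t) = arccos(1 - 2 y_ideal(t)/h)`, mapped to `[0, 180]` degrees
while `y` rises and `[180, 360]` while it falls; it is monotone, so the
six section boundaries are found by bracketed root finding
(`th_v*(t_k) = 60 k`, Brent's method, `xtol = 1e-12`). Collocation fixes
each section speed to `60 deg / (t_{k+1} - t_k)`; the accumulated angle
is then exact at every boundary but overshoots in between.

An optional least-squares refinement (enabled by default in the
verification pipeline) adjusts the six speeds to minimize the mean
squared nearest-point distance between the resulting path and the ideal
loop, evaluated on a 201-point time grid against a 1201-vertex loop
polyline, under the equality constraint `sum(60/w_k) = T` (SLSQP,
collocation as the starting point; the optimizer's iterate is accepted
whenever it is feasible and improves on collocation). For the
narrow-tall default setup this lowers the maximum path deviation from
about 1.17 mm to about 0.93 mm; experiments with higher-order p-norm
objectives gave no further improvement, indicating ~0.93 mm is close to
the floor of the six-constant-speed family for that geometry.

## Step quantization and homing

Steppers are 1.8 degrees per full step (200 steps/revolution) with
microstepping down to 1/32 (0.05625 degrees). Pulse `m` of a revolution
fires when the accumulated profile angle reaches `m` microsteps; because
60 degrees is not an integer number of microsteps, the sub-step phase
carries across section boundaries and each cycle emits exactly
`200 x divisor` pulses per motor. Timestamps are rounded to the nearest
1 microsecond, halves up — three orders of magnitude below the shortest
inter-pulse interval, so ordering per motor is preserved.

Each axis has an optical endstop defining angle zero. Homing rotates
forward (never reversing, matching continuous-rotation operation) until
the endstop is crossed, overshooting by less than one microstep; a state
already at the endstop is considered triggered (zero rotation), and
homing an already-homed state is a no-op.

`simulate_run` merges both motors' pulse streams, advances the
corresponding angle one microstep per pulse, and evaluates the forward
kinematics at every pulse event, so adjacent samples differ by at most
one microstep's kinematic increment. Cycle indices are attributed from
the accumulated horizontal angle (one cycle per 360 degrees).

### Synchronization transient

The physical device deviates during its first two cycles until
synchronization completes. The twin models this startup as: homing from
seeded arbitrary initial angles before `t = 0`, then two cycles with the
vertical motor at uniform (unmodulated) speed while the controller
synchronizes, after which the solved profile engages exactly at the
cycle boundary (the uniform cycles end with the vertical angle at a
multiple of 360 degrees, so the hand-off is continuous). During the
transient the Tip traces the degenerate diagonal segment, which sits
between the two loop branches — a deviation of roughly `h/4` at worst,
about 2.4 mm for the wide-flat setup and 2.9 mm for the narrow-tall one.
Deviation reports exclude these two cycles from the headline maximum by
default (`n_sync = 2`).

## Synthetic camera and tracking

The verification camera is synthetic (the physical experiment's camera
was uncalibrated, and its pose is unknown): 640 x 480 px at 30 fps,
8 px/mm, chosen so one pixel (0.125 mm) sits an order of magnitude below
the 1 mm bound being tested. The white sticker on the Tip is rendered as
an anti-aliased disc of radius 2.5 mm over a static, darker textured
gray background, with additive gray Gaussian sensor noise (sigma = 3 of
255 intensity counts) drawn from a generator seeded per run; rendering
is bit-reproducible given the seed. For long runs frames are generated
lazily so the video never resides in memory.

Tracking mirrors the device's verification workflow: convert to HSV,
threshold, take the largest binary region, and report its unweighted
centroid. HSV is expressed as hue in degrees (0-360) and
saturation/value on [0, 1] regardless of 8-bit storage; the default
sticker window is S <= 0.25, V >= 0.8, hue unconstrained. Connected
components use 8-connectivity with size ties broken by the earliest
first pixel in row-major order. Frames with no detection are flagged
invalid but kept. Pixel coordinates convert to mm by
`x = (u - u0)/s`, `y = (v0 - v)/s` (image v axis points down), with the
origin recorded by the renderer.

What the synthetic scene does not emulate: perspective or lens
distortion, motion blur, illumination gradients, rolling shutter,
occlusions, and background clutter that could produce competing bright
regions. Passing the round-trip and deviation tests therefore
demonstrates the correctness of the planning/simulation/tracking chain
under a benign, calibrated camera, not robustness of the tracker to
hostile real footage.

## Deviation metric and verification experiment

Each measured sample is scored by its nearest-point Euclidean distance
to the ideal loop, computed against a densely sampled polyline (4000
vertices) with exact point-to-segment projection. Nearest-point distance
(rather than same-time deviation) was adopted because the device's
published figures describe how far the traced curve strays from the
desired shape; it is the weaker of the two metrics and is insensitive to
pure timing error. Reports give per-cycle maxima and means, the overall
maximum after excluding the transient cycles, and region-wise maxima
split at `y = h/2` (the "upper area" is otherwise undefined), computed
over all cycles without exclusion.

The verification experiment runs two stock setups for 20 cycles each at
`T = 3.75 s`, 1/32 microstepping, with homing and transient enabled and
least-squares refinement on:

- **wider** (wide-flat): `r = 20, d1 = 5, d2 = 20, l = 20` -> 40 x 10 mm
- **higher** (narrow-tall): `r = 7.5, d1 = 15, d2 = 20, l = 20` -> 15 x 30 mm

The published numeric dimensions of these setups are not stated; the
values above were chosen once to match the qualitative wide-flat vs
narrow-tall shapes within the lever formula, with `d2 = l = 20 mm` as a
plausible stock lever. 20 cycles at 30 fps is 2250 frames per setup,
about 80 s of computation per run.

## Numerical choices and limitations

- Root-finder tolerance 1e-12 s; profile invariants enforced to 1e-6
  degrees per section and 1e-9 s on the period.
- The refinement objective is smooth almost everywhere but evaluated on
  a finite grid; the grid (201 points) is dense relative to the six-knot
  profile, and results were checked against a 1501-point grid.
- Degenerate inputs: `h = 0` is legal for loop sampling (flat loop) but
  rejected by the inverse planner, which would need to divide by `h`.
- No torque, current, acceleration or resonance modeling: the simulation
  is purely kinematic, so it cannot reproduce missed steps or mechanical
  backlash — one reason a physical device can deviate more than its
  twin.
- The six-section piecewise-constant speed family fundamentally limits
  how closely the parabolic-branch loop can be traced (~0.93 mm for the
  15 x 30 mm setup); a firmware with more sections or continuous
  velocity control would lower this floor.
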