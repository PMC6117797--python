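# lungtwin

A digital twin of an open-source, 3D-printed lung-tumor motion phantom
for radiotherapy quality assurance.

Lung tumors move with breathing, so a treatment plan for a moving target
is ideally verified on a device that reproduces that motion before the
patient is irradiated. The phantom this package models drives a "Tip"
(a sphere standing in for the tumor, which can hold a dosimeter) along
the closed planar hysteresis loop a tumor traces over one breath —
inhalation and exhalation follow different branches — using two stepper
motors and a printed crank/lever mechanism. `lungtwin` reproduces the
whole chain in software, for medical physicists and phantom builders who
want to plan, predict and verify a setup without (or before) hardware:

- **breathing** — the parametric loop family: branches
  `y_in = h x²/(2r)²` and `y_ex = [-(x-2r)² + (2r)²] h/(2r)²` on
  `x ∈ [0, 2r]`, height `h = 2·d1·l/d2` from the lever geometry, timed
  by the crank `x(t) = r(1 − cos 2πt/T)`; loop sampling, areas
  (`2hr/3`), parameter sweeps.
- **mechanism** — forward kinematics (`x = r(1 − cos θ_h)`,
  `y = (h/2)(1 − cos θ_v)`), the six-section vertical speed-profile
  solver (each section exactly 60° of rotation, mean speed equal to the
  horizontal motor's `360/T`), microstep quantization into a
  firmware-equivalent pulse stream, optical-endstop homing, and
  step-resolution simulation of whole runs including the two-cycle
  synchronization transient.
- **tracking** — a synthetic calibrated camera that films the white
  sticker on the Tip, and the verification tracker: HSV threshold →
  largest binary region → centroid → mm.
- **qa** — nearest-point deviation of a tracked/simulated run from the
  ideal loop, per cycle and per loop region, plus the end-to-end
  `run_verification` pipeline and the `wider`/`higher` stock setups.

## Worked example

Solve the vertical speed plan for the default setup (loop 40 × 10 mm,
16 breaths/min):

```
$ lungtwin plan
horizontal speed: 96.0000 deg/s
section 0:   64.0000 deg/s over [0.0000, 0.9375] s
section 1:  122.4006 deg/s over [0.9375, 1.4277] s
section 2:  134.1116 deg/s over [1.4277, 1.8751] s
section 3:   64.0056 deg/s over [1.8751, 2.8125] s
section 4:  122.4006 deg/s over [2.8125, 3.3027] s
section 5:  134.1363 deg/s over [3.3027, 3.7500] s
```

The horizontal motor turns one revolution per 3.75 s breath (96 deg/s);
the vertical motor slows to 64 deg/s where the loop branches are shallow
and speeds up to ~134 deg/s where they are steep, averaging 96 deg/s so
both motors stay synchronized.

Run a short verification of the narrow-tall setup (simulate at 1/32
microstep, film at 30 fps, track, score):

```
$ lungtwin --seed 1 verify --preset higher --cycles 5
excluded_cycles: 2
overall_max_mm: 0.9347
upper_max_mm: 2.8843
lower_max_mm: 2.9116
per_cycle:
cycle,n_valid,max_dev_mm,mean_dev_mm
0,113,2.9116282328392207,1.1707452471656772
1,113,2.905975782058448,1.1701545140850105
2,112,0.9332060017824708,0.22944411486036728
3,113,0.9347436032574924,0.22736664112299615
4,112,0.9339763546063821,0.2294975248139017
```

Cycles 0–1 are the startup transient (homing plus unmodulated vertical
rotation while the controller synchronizes): the Tip runs the diagonal
between the branches, ~2.9 mm from the loop. From cycle 2 the solved
profile engages and the tracked path stays within 0.94 mm of the ideal
loop — under the 1 mm tolerance expected of the narrow-tall setup.

The same is available as a library:

```python
from lungtwin import run_verification

report = run_verification("higher", n_cycles=20, seed=1)
print(report.overall_max_mm)   # max deviation after the 2 transient cycles
```

Other CLI subcommands: `steps` (pulse-stream CSV), `simulate`
(trajectory CSV), `render` (PNG sequence), `track` (CSV from frames),
`sweep` (loop families over `r` or `d1`). All accept a flat key-value
`--config` file (see `lungtwin.config`).

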