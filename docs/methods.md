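# Methods

## The model

`ecmigrate` simulates the collective migration of endothelial cells (ECs)
on the wall of a perfused flow chamber. The motivating application is
reendothelialization of stented arteries: stent struts disturb the
near-wall flow and create recirculation zones whose reversed velocity cue
traps migrating cells, delaying recovery of the monolayer.

Each cell is a spherical particle of radius `r_cell = 15 µm`. Three
ingredients drive the dynamics.

**Cell–cell and cell–substrate interaction.** Particles interact through a
pair force along the centre line with three branches: a truncated
Lennard-Jones 12/6 tail for `2 r_cell < r ≤ r_cutoff = 4 r_cell`
(attractive — nearby cells tend to stay together and adhere to surfaces), a
finite neo-Hookean soft-core repulsion for overlapping particles
(`r < 2 r_cell`), and zero beyond the cut-off, where the residual LJ force
is below 1e-6 a.u. Both inner branches vanish at the equilibrium distance
`σ = 2 r_cell`, so the force is continuous there. Forces are in arbitrary
units (a.u.): the interaction model is phenomenological and only relative
magnitudes matter. Our sign convention is positive = repulsive; under it
the LJ tail is negative (attractive), which is the behaviour the
equilibrium at `σ` requires.

Two variants of the contact-area approximation used by the soft-core branch
are implemented, `a = sqrt((r_cell/2)(2 r_cell − r))` (default) and
`a = sqrt(r_cell (2 r_cell − r))`. At complete overlap the default gives a
repulsion of `15.35 C r_cell² ≈ 3.45e-4 a.u.`, the alternate
`≈ 1.658e-3 a.u.` The two are inconsistent in the source material the
parameter set derives from, so both are kept behind a named switch and each
is validated against an independent closed-form evaluation; nothing in the
shipped scenarios depends on the choice, because the interaction forces are
two orders of magnitude below the migration force (see *Limitations*).

**Persistent random walk with a flow cue.** Each cell carries a persistent
random force with three independent `N(0, c)` components (`c = 9e-4 a.u.²`),
giving a Maxwell–Boltzmann-type magnitude distribution with mean
`sqrt(8c/π) ≈ 0.048 a.u.` The force is replaced by a fresh draw at rate
`p_change = 0.075 per hour` (exact exponential refresh probability
`1 − exp(−p_change·dt)` per step, so the statistics are step-size
independent; mean persistence time `1/p_change ≈ 13.3 h`). The migration
direction blends the random-force unit vector with the local flow unit
vector, `d = (1−w) e_rand + w e_vel`, with weight

    w(v) = (v / v_max)(w_max − w_min) + w_min   for v < v_max,  else w_max,

where `v` is the local flow speed, `v_max = 0.036 m/s` (the speed whose
first-node wall shear stress is `ν v_max / Δ = 2.4 Pa`), `w_min = 0.3`,
`w_max = 0.7`. The migration force has the magnitude of the random force
and the direction `d/|d|`. The total force adds the pairwise interactions
over all cells and obstacle elements within the cut-off.

**Overdamped motion.** Velocities are proportional to forces with mobility
1 mm/h per a.u. The drag constant is not part of the published parameter
table; this unit choice is the one that makes the table self-consistent —
the mean migration force of 0.048 a.u. then yields ≈ 48 µm/h, matching the
calibrated mean migration speed of ~50 µm/h. Time integration is classical
RK4 with step-doubling error control: tolerance 1e-5 mm on the max
per-cell position discrepancy between one full step and two half steps,
step clamped to [1e-5, 0.05] h, shrink factor `0.9 (tol/err)^{1/5}` on
rejection. Because the error estimate is noisy wherever a cell's flow cue
crosses a grid-cell boundary of the bilinear velocity field, the step size
is grown (capped ×1.5) only every fifth accepted step and only when the
error is below 0.6 tol; eager doubling mostly buys rejected step-doubling
chains. The persistent force is frozen within a step; the flow cue is
re-sampled at substep positions.

**Geometry and confinement.** Channel surfaces (substrate, ridge faces,
step riser) are tiled with *obstacle elements*: fixed spheres of radius
`r_cell` on a hexagonal lattice with spacing `r_cell`, which interact with
cells through the same pair law but never move. Cells are confined to a
monolayer as a position restriction, not a force: after every accepted
step, any mobile cell farther than `3 r_cell` from the nearest obstacle
element is projected back onto that band *and the outward component of its
persistent random force is mirrored* (a reflecting boundary). The
reflection matters quantitatively: a plain sliding projection leaves a cell
whose persistent force points outward pinned at the band edge for the rest
of its ~13 h persistence time, which drains the measured migration speed by
roughly 20% and breaks the calibration by which the random-force variance
encodes the ~50 µm/h mean speed. Mirroring a component of an isotropic
Gaussian leaves the Maxwell speed distribution intact, so confined and free
cells migrate at the same mean speed. The spanwise channel sides
are frictionless force walls (a purely normal spring, 10 a.u./mm; cells
penetrate them by only a few µm under the typical forces and feel no
tangential drag).

**Flow.** The steady channel flow is solved on the x–y plane with a D2Q9
BGK lattice-Boltzmann (LB) method (halfway bounce-back walls, parabolic
equilibrium velocity inlet with the density extrapolated from the interior,
zero-velocity-gradient outlet with the density anchored at 1 to pin the
pressure level) and extruded uniformly across the span. The flat channel
returns the analytic plane-Poiseuille profile directly. Lattice spacing
`Δ = 0.015 mm`; the peak inlet speed defaults to the value that makes the
flat-channel first-node speed equal `v_max` (the 2.4 Pa ceiling). The
lattice peak velocity is fixed at 0.04 (Mach ≈ 0.07) and the relaxation
time follows from the physical Reynolds number (τ ≈ 0.53 for the default
chambers at Re ≈ 150–230; a τ far above 0.5 would force lattice velocities
out of the low-Mach regime on this grid). Iteration stops when the maximum
relative velocity change over 100 steps falls below 1e-7. A converged
2Δ-grid solution warm-starts the fine grid; the fixed point and tolerance
are unchanged, only the transient is shorter. With halfway bounce-back the
no-slip plane sits half a link beyond the first fluid node; inlet profiles
and the Poiseuille comparisons account for the inset. Wall shear stress
uses the first-node gradient rule `ν · u_tangential / Δ`. Recirculation
zones are maximal intervals of reversed near-wall streamwise velocity,
their downstream zero crossing being the reattachment point. A
user-supplied gridded field (CSV) can replace the solver.

## Scenarios and default geometries

The chamber dimensions are not fully specified by the source experiments,
so the package fixes defaults (all configurable, all recorded in the output
header):

- **flat_calibration** — 10 × 0.5 × 0.9 mm channel, no ridges; 24 h.
- **ridged** — same channel with three ridges 0.1 mm high × 0.1 mm wide,
  1.5 mm pitch, the first ridge 5 mm from the inlet; 24 h. Cells are seeded
  in a hexagonal sheet (spacing `4 r_cell = 60 µm`, centres `r_cell` above
  the substrate) over the 2 mm directly upstream of the first ridge; the
  four leftmost rows are immobile anchors.
- **ridged_rock** — ROCK inhibition, modelled purely as `w_min` 0.3 → 0.05.
- **backward_step** — 12 mm long chamber, 0.5 mm upstream height expanding
  by a 0.25 mm step drop 2 mm from the inlet; 48 h. The sheet is seeded
  downstream of the step: 3 mm of axial extent starting `2 r_cell` past the
  step face (spanning the recirculation bubble and the analysis window with
  margin, ~900 mobile cells), full width, no immobile rows (the pile-up at
  the face anchors itself).

Angular statistics use 24 × 15° bins with 180° = downstream; for ridged
analyses the origin is 50 µm past the ridge's trailing face and only cells
starting downstream of it are counted. Migration speed is sampled path
length / duration over mobile cells (the standard migration-assay reading,
and the one the calibration reproduces). Axial density profiles use
0.06 mm bins (one cell spacing); the density-minimum locator applies a
3-bin moving average and searches 0.2–3.0 mm downstream of the step face,
excluding the pile-up at the face and the sheet's trailing edge.

## What the simulations show

With the default parameter set the flat-channel grand-mean migration speed
is ≈ 46 µm/h (three seeds, ~540 mobile cells), inside the calibrated
50 ± 5 µm/h window — essentially the Maxwell mean of the random-force
magnitude (47.9 µm/h), since interactions are weak; the small deficit is
per-track statistical noise plus residual confinement interactions. In the
step chamber the LB flow reattaches ≈ 0.88 mm downstream of the face
(the solver reproduces the classic laminar backward-step benchmark at
expansion ratio 1.94, Re = 100, to within ~7% of the measured reattachment
length). Over 48 h, cells inside the recirculation migrate upstream and
pile against the step while cells beyond reattachment migrate downstream,
carving a density minimum that tracks the reattachment point:
≈ 0.8 ± 0.1 mm downstream of the face with the default chamber. A longer
recirculation bubble — a taller step, a higher Reynolds number, or a
three-dimensional flow — moves the minimum correspondingly downstream; in
this model the minimum is a read-out of the reattachment length, not an
independent prediction. These numbers are produced by
`scripts/acceptance.py` and the test suite at run time; none are
hard-coded.

## Numerical and design choices

- Units: lengths mm, time h, forces a.u., flow speeds m/s (entering only
  through `v/v_max` and the flow unit vector).
- Coincident centres (undefined force direction) are nudged apart by
  `1e-6 r_cell` in a seeded random direction after the step; a collapsed
  blended direction (`e_rand` anti-parallel to the cue at w = 0.5) falls
  back to the random direction for that evaluation and the cell's force is
  resampled post-step.
- One RNG seed per run; every cell owns a child stream (`SeedSequence`
  spawning), so refresh patterns are reproducible and population-size
  changes do not reshuffle unrelated draws. Identical (config, seed) give
  bit-identical trajectories on one platform.
- Neighbour lists (cell–cell and cell–obstacle) use a k-d tree with a
  `r_cell` skin, rebuilt when any cell moves more than half the skin; list
  forces are verified against all-pairs summation to 1e-12.
- Output frames land exactly on multiples of the output interval (0.1 h
  default) by capping the adaptive step at frame boundaries.
- Both the LB solver and the cell-force evaluation are fused numba kernels
  with `fastmath` enabled; runs are deterministic for identical inputs on a
  given platform, and the fused force kernel agrees with the pure-numpy
  reference path to ~1e-15 relative (asserted in the test suite). The LB
  warm start solves a 2Δ grid to a loose tolerance purely as the fine
  grid's initial state; the fine grid's 1e-7 convergence criterion is
  unchanged.

## Limitations

- With the published parameter set the maximum contact repulsion
  (≈ 3.5e-4 a.u., or 1.7e-3 under the alternate contact area) is two orders
  of magnitude below the mean migration force (0.048 a.u.), so the contact
  forces cannot mechanically prevent interpenetration: cells can transiently
  overlap each other and the obstacle lattice, and a cell pushed downward
  can dip below the substrate plane (the confinement band extends `3 r_cell`
  on either side of the obstacle surface; flow samples are zero there, so
  such cells revert to an unbiased walk until they resurface). Entrapment
  and monolayer cohesion in this model are consequences of the flow cue and
  the confinement band, not of contact mechanics.
- The flow is two-dimensional (x–y) and extruded across the span; spanwise
  secondary flows are absent. Cells do not disturb the flow, and blood is
  treated as a homogeneous fluid (no suspended-cell rheology).
- Cells are points with spherically symmetric interactions: the flat,
  spread morphology of real ECs — and with it the less peaked axial
  distributions seen in experiments — is not represented.
- No proliferation, apoptosis, or phenotype change: real ECs stop migrating
  once confluent (~40 h); the model's cells keep walking, so long-horizon
  densities should be read as migration-only predictions.
- The synthetic monolayers are perfect hexagonal sheets with deterministic
  seeding; real seeding density fluctuations, cell-size dispersity and
  substrate heterogeneity are not emulated. Passing tests therefore
  validate the model's mechanics and statistics, not its fidelity to any
  particular experimental preparation.
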