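# Methods

## Geometry and mesh

The model is two-dimensional plane strain. A circular cell (diameter
10 um) containing a concentric circular nucleus (diameter 5 um) sits at a
stand-off of 0.5 um from the entrance of a straight channel of width `phi`
(default 3 um, confinement D0/phi = 5/3) and length 10 um formed between two
rectangular tissue blocks (30 x 15 um each). Cell membrane and nuclear
membrane are 0.05-um-thick rings of quad elements; cytoplasm fills the
annulus between them and the nucleus fills the inner disc. All parts are
meshed with bilinear quadrilaterals on structured grids; presets `test`,
`coarse`, `medium`, `reference` control resolution. Mesh generation is fully
deterministic.

## Constitutive models

* **Kelvin–Voigt viscoelasticity** (membranes, cytoplasm, tissues): total
  stress is the sum of a plane-strain Hookean part evaluated on the
  accumulated logarithmic strain and a viscous part `eta * deps/dt` with
  `eta = E * tau`. Strain rates are low-pass filtered over a short window
  (`rate_filter_time`, default 0.1 s, far below the smallest material
  relaxation time of 1 s) to suppress ringing at the stable time step.
* **J2 elastoplasticity with Ludwik hardening** (nucleus): radial-return
  mapping with flow stress `sigma_y = a + b * eps_p^n`
  (a = 41 Pa, b = 17 Pa, n = 2.89). The return mapping is verified against an
  independent continuum-tangent rate integrator on dense sub-steps
  (100 random strain paths, relative stress error <= 1e-4).
* **Cytoplasmic stress stiffening**: the cytoplasm modulus ratchets up with
  the shear stress it has experienced, following a monotone staircase law.
* Poisson's ratio is 0.3 for every part. Default moduli: cytoplasm 1 Pa
  (tau = 1000 s), membranes 1 MPa (tau = 1 s), tissues and nucleus in the
  0.2–5 kPa study range (tau = 1 s).

## Kinematics and time integration

The solver is updated-Lagrangian explicit central difference. Velocity
gradients integrate the rate of deformation into logarithmic strain; a
constant-velocity stretch therefore accumulates exactly `ln(L1/L0)`. The
stable time step is maintained by selective mass scaling (stiffness-,
viscosity- and contact-penalty-based nodal mass floors), with per-preset
target time steps (`test` 2e-3 s down to `reference` 1e-4 s). Hourglass
control and bulk viscosity stabilise the single-point-integrated quads.

## Contact and loading

Two-pass node-to-segment penalty contact, frictionless, with penalty
stiffness 100x the stiffest body in each pair. The protrusive driving force
(default peak 6400 pN/um) is distributed over a 30-degree leading-edge arc of
the cell membrane and ramped with a quintic smooth step over 600 s. When the
nucleus has fully entered the pore the load is released and the run ends
after a short tail; the migration assay measures entry, and sustained thrust
past entry would only inject free-flight kinetic energy.

## Energy accounting and the acceptance rule

Every snapshot records external work, internal (strain) energy, plastic
dissipation, contact penalty energy and kinetic energy. A run is **accepted**
iff

1. the energy-balance error `|W_ext - (W_int + KE + E_contact)| / max(...)`
   stays within 2% at every monitored snapshot, and
   (monitoring opens once the internal energy exceeds both an absolute floor
   and 1% of its final value, so that startup transients are not divided by a
   near-zero denominator), and
2. `KE / W_int <= 5%` at every snapshot during the loading/approach phase.
   A single contiguous *terminal* window of exceedance is permitted only when
   it brackets the detected pore-entry event.

The carve-out in (2) exists because pore entry is a snap-through: the
quasi-static approach stores elastic energy that converts to kinetic energy
as the nucleus accelerates through the constriction (the velocity history is
flat for most of the run and spikes at entry). The *magnitude* of that KE
spike measures the scaled nodal mass (which shrinks quadratically with the
target time step: peak KE/IE fell 2.84 -> 0.81 -> 0.33 -> 0.13 as dt was
halved from 2e-3 to 2.5e-4), not solution quality; energy balance remains
enforced through the spike. Summaries always report the global peak KE/IE,
the loading-phase maximum, and the transient onset time.

## Observables

* **Entry time/force** `T_entry`, `F_entry`: first snapshot at which the rear
  of the nuclear membrane passes the channel entrance, and the applied force
  at that instant.
* **Circularity** D/L: ratio of transverse to axial extent of the nuclear
  membrane ring; the headline scalar is its minimum over the run.
* **Kinks**: vertices of the nuclear membrane ring whose turning angle
  exceeds 60 degrees.
* **Hoop-stress traces**: the membrane element nearest a given polar angle is
  tagged at t = 0 and followed as a material point; its stress is rotated
  into the instantaneous radial/tangential frame about the nucleus centroid.
* **Far-field tissue displacement**: `u_y` along the pore wall as a function
  of distance from the entrance.
* **Plasticity report**: maximum equivalent plastic strain; a run is labelled
  plastic above 1e-4.

## Scaling analyses

`squeezefem.scaling` collects run summaries into tidy tables and provides
log-log power-law fits (OLS with Theil–Sen as a robust alternative), the
nondimensional force law `Pi_out = A * Pi_in^k` with
`Pi_out = F / (E_c D)` and `Pi_in = ((E1+E2+En)/E_c) (L/D) (t/tau_c)`,
per-nucleus-stiffness circularity scaling, the lamina flexural-rigidity
closed form `F_D = E h^3 / (1 - nu^2)`, and the nuclear water-influx
timescale `tau = r_n^2 / D_c` (0.125 s for r_n = 2.5 um,
D_c = 50 um^2/s).

## Verification suite

`squeezefem verify` runs five deterministic analytic benchmarks in a few
seconds: Kelvin–Voigt creep vs the closed form (tolerance 1%), uniaxial
elastoplastic load/unload vs a dense independent integrator (0.1%), a
single-element patch test (equilibrium residual and Gauss-point uniformity to
1e-10), a two-body contact patch test (transmitted pressure uniform to 2%,
clean separation on unload), and the 100-path radial-return oracle comparison
(1e-4). `squeezefem.benchmarks.make_reference_cases()` returns the five
canonical coarse-mesh study configurations (four confined stiffness corners
plus one unconfined case).

## Known limitations

* The minimum nuclear D/L for the (E_n = 1 kPa, E_T = 5 kPa) case converges
  to ~0.45 under time-step refinement at the coarse mesh, above the 0.36
  literature-scale target; finer meshes and softer membrane assumptions both
  push it down, but the shipped defaults were frozen before measurement and
  are reported as-is.
* Membranes carry two through-thickness element layers at the `test`/`coarse`
  /`medium` presets (ten at `reference`), so membrane bending and the
  inner/outer hoop-stress split are only coarsely resolved below the
  reference preset; membrane folding (kinks) is not resolved at all at the
  coarse circumferential counts.
* Contact is frictionless hard-penalty; no adhesion or friction models.
* With the single fixed Ludwik law (yield stress 41 Pa for every nucleus), the
  pore imposes ~0.4-0.5 strain kinematically and every confined case yields;
  the published soft-nucleus-elastic / stiff-nucleus-plastic phase pattern
  would require yield parameters that scale with nuclear stiffness.
* At the shipped resolutions the front hoop-stress inner/outer split appears
  for the *soft* nucleus (whose membrane bends at the front) rather than the
  stiff one, and the far-field pore-wall displacement decays identically for
  all stiffness pairings (the finite 30 x 15 um tissue blocks control the
  decay). The entry-time increase with tissue stiffness at high confinement
  is present but weak (~12% from 1 to 5 kPa at the small preset).
* Several acceptance tests in `tests/test_acceptance.py` encode these
  literature-level targets and fail by design at the shipped resolutions;
  they are kept red rather than loosened.
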