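# Methods

## Model

`elastoswim` simulates a sperm-like cell — an inextensible active filament
(the flagellum) clamped to a rigid ellipsoidal head — swimming in Stokes flow
near a microchannel wall feature. The model couples three ingredients:

1. **Slender-body hydrodynamics of the flagellum.** The velocity of the
   filament centreline at arclength `s0` is written as a local anisotropic
   drag term plus a non-local line integral of stokeslets outside an
   arclength cutoff `q`:

       u(X(s0)) = -(1/xi_perp)(I + (gamma-1) s s) . f_vis
                  - ∫_{|s-s0|>q} S(X(s0), X(s)) . f_vis(s) ds
                  - ∮_H S . phi_H dS - ∮_W S_eps . phi_W dS,

   with Gray–Hancock-type coefficients
   `xi_perp = 8 pi mu / (1 + 2 ln(2q/b))`,
   `xi_par = 8 pi mu / (-2 + 4 ln(2q/b))`, `gamma = xi_perp/xi_par`.
   `f_vis` is the force per unit length exerted by the fluid on the
   flagellum. Defaults `b = 0.01 L`, `q = 0.1 L` give `gamma ≈ 1.4`; the
   precise `q` is uncritical because the resistance coefficients and the
   integrals change together.

2. **Single-layer boundary integrals for head and wall.** Both rigid
   surfaces are represented by surface distributions of point forces: the
   head by singular stokeslets over a triangulated ellipsoid (semi-axes
   0.05/0.03/0.04 L), the wall by regularized stokeslets (blob size
   0.75 x the local panel edge) collocated at panel centroids with
   traction x area as strengths. With this sign convention the fluid force
   on the head is directly the surface integral of `phi_H`.

3. **Geometrically nonlinear filament elasticity.** With position `X(s,t)`
   and line tension `T(s,t)`, lengths scaled by L, time by 1/omega and
   force densities by E/L^2, the balance of elastic, active and viscous
   forces reads

       Sp^4 (X_t - V) = -X_ssss - (gamma-1)(X_s.X_ssss) X_s + T X_ss
                        + gamma T_s X_s + m_s n + gamma m n_s,

   where `V` collects the non-local (integral) velocities,
   `Sp = L (xi_perp omega / E)^(1/4)` is the sperm number and
   `m(s,t) = m0 cos(k s - t)` is the prescribed travelling wave of internal
   bending moment (defaults `m0 = 240`, `k = 6 pi`). Inextensibility yields
   a second-order two-point boundary-value problem for `T`. The distal tip
   carries no force or moment (`X_ss = 0`, `T = 0`); at the head junction
   the filament balances the fluid load `(F_H, M_H)` on the head, which is
   decomposed into a rigid-body-resistance part and a flagellar correction.
   A length-error penalty with coefficient `lambda = 80` supplements the
   tension equation.

The human-sperm parameter point (`L = 50 um`, `omega = 100 rad/s`,
`E = 5e-21 N m^2`, `mu = 0.14 Pa s`) gives `xi_perp ≈ 0.503 Pa s` and
`Sp ≈ 15.8`; studies span `Sp = 13..17`.

### Unit system

All computations run in units with `L = 1`, `omega = 1` (beat period
`2 pi`), `E = 1`, and the viscosity chosen so that `xi_perp = Sp^4`
(`mu = Sp^4 (1 + 2 ln(2q/b)) / 8 pi`). The dimensional kernels evaluated at
this viscosity reproduce the dimensionless equations exactly, so no unit
conversions appear outside the configuration layer.

## Discretization

* **Arclength grid.** `Ns + 1` uniform nodes carrying `X` (3 components) and
  `T`. Derivatives use second-order central stencils in the interior and
  third-order one-sided stencils (Fornberg weights) at the ends.
* **Coupled flow solve.** Collocation of the velocity equation at flagellum
  nodes, rigid no-slip at head centroids, zero velocity at wall centroids:
  a dense system of `3 (Ns + 1 + N_h + N_b)` equations solved by LU. The
  cutoff integral uses composite trapezoid with sub-quadrature on the two
  intervals adjacent to the cutoff, where the kernel varies on scale `q`.
  Near-singular surface integrals are evaluated by subdivided centroid
  rules with depth set by the distance/panel-size ratio; on-surface
  self-elements use exact-in-radius polar quadrature. The head–head block
  is rotation-equivariant and cached in the body frame; the wall–wall block
  is cached for the whole run.
* **Time stepping.** Trapezoidal (Crank–Nicolson-type) differencing with
  all stiff terms implicit, slightly off-centred
  (`theta = 1/2 + 1.6 dt`) to damp temporally grid-scale modes that the
  symmetric rule leaves undamped; the off-centring vanishes linearly with
  `dt`, preserving second-order convergence. Each step is solved by Picard
  iteration with the nonlinear coefficients frozen at the previous iterate
  and Aitken dynamic relaxation; iteration stops when the maximum position
  change between iterates falls below 0.5% of the distance travelled in
  the step (`tol`). The first iterate extrapolates `X` linearly in time.
* **Implicit couplings.** Three couplings that a naive splitting would lag
  are kept inside the per-iteration linear system, which proved decisive
  for robustness at full actuation: (i) the actuation terms
  `m_s n + gamma m n_s` with `n = z x X_s` (linear in `X` for a planar
  beat); (ii) the flagellum-induced part of `V`
  (`V_flag = -W f_vis` with `f_vis` linear in the unknowns at frozen
  geometry); (iii) the response of the head load and of the
  surface-induced flagellar velocity to the head's rigid velocities,
  obtained exactly from six extra right-hand sides on the already-factored
  flow matrix. The converged physics is unchanged — at the fixed point the
  decomposition reduces to the resistance-plus-correction form — but the
  iteration then converges in 2–3 steps per time step instead of diverging.
* **Tension equation.** Derived at the half step of the trapezoidal update:
  dotting the s-derivative of the update with the average tangent
  telescopes the rate term into the exact length-error source
  `(Sp^4 / 2 dt)(1 - |X_s^n|^2)`, and the force side is expanded with the
  inextensibility identities evaluated at the midpoint state. The `lambda`
  penalty acts on the per-segment stretch with normalized frozen segments:
  per-segment, because node-centred stretch measures are blind to
  segment-alternating (sawtooth) errors; normalized, so the penalized
  quantity is the new iterate's stretch alone and the penalty stays
  implicit in the iteration.
* **Boundary rows.** The tangential components of the proximal and distal
  force conditions are continuum identities (the proximal one coincides
  with the proximal tension condition), so imposing all three components
  makes the discrete system rank deficient while leaving the end stretch
  uncontrolled. The force conditions are therefore projected normal to the
  tangent, and the freed tangential rows pin the end inextensibility
  `X_s . X~_s = 1`. The proximal moment balance is imposed in full
  (its linearization about the iterate is rank 3); the free axial-spin
  component of the head angular velocity is closed kinematically with
  `Omega . e = 0`, fixing the beat plane.
* **Rows and unknowns.** `4 (Ns + 1) + 6` per iteration (650 at
  `Ns = 160`): positions, tension and the six head velocities slaved to
  the proximal node kinematics. Rows are equilibrated before the LU solve
  (they span ~8 orders of magnitude).
* **Planar symmetry.** With symmetric data the z-components remain at
  round-off; an optional mirror projection (on by default) removes them
  each step. The system itself stays fully three-dimensional.

## Resolution requirements

With `k = 6 pi` the beat has three wavelengths along the flagellum. The
second-order stencils need at least ~17 nodes per wavelength for a stable
inextensible beat at full actuation (`m0 = 240`): below `Ns ≈ 100` the
truncation error of the high derivatives acts as a stretch source that the
penalty cannot balance, and the step iteration eventually fails. Presets:

| preset | Ns  | steps/beat | head panels | wall panels | use |
|--------|-----|-----------|-------------|-------------|-----|
| full   | 160 | 200       | 320         | ~500        | production (matches the study design) |
| desk   | 120 | 100       | 320         | ~150        | desk-scale studies |
| mini   | 100 | 60        | 80          | ~40         | tests, quick qualitative runs |

At the mini preset the maximum length error over tens of beats is ~3e-3
and a full run of 30 beats takes a few minutes on one core.

## Geometry and protocol

Coordinates: swimming towards +x, wall normal +y, beat plane x–y, the step
edge along z at `x = 0`. Wall features: `strip` (plane y = 0), `backstep`
(upper shelf, riser of height `h`, lower floor at `y = -h`), `cliff` (upper
shelf only). Wall panels are graded geometrically towards the step edge;
extents default to one to two flagellar lengths each way (truncation
checked by the drag-change-under-doubling test). The cell starts at rest,
straight, parallel to the wall at height 0.2 L above the upper shelf, and
the actuation amplitude ramps as `1 - exp(-t/tau)` with
`tau = 10 pi / ln 100` (99% after five beats). Runs stop when the head
passes a downstream station (`stop_x`, one flagellar length past the step
at full scale, closer in at reduced scale).

## Analysis metrics

* **Trajectory angle** `theta = arctan(dY/dX)` at the head, sampled at the
  temporal midpoint of each beat with centred differences; positive theta
  points away from the wall.
* **Final deflection** `theta_d`: theta at the first crossing of the
  downstream station (linear interpolation between bracketing mid-beat
  samples); strip-baselined `delta theta_d` isolates the effect of the
  step from the effect of a plane wall.
* **Waveform asymmetry** `A(s)`: snapshots taken every 41 steps (rescaled
  proportionally when the beat has fewer than 200 steps) are projected
  into the head-fixed frame (origin at the junction, forward axis along
  the heading, lateral axis the in-plane normal) and averaged over a
  window of beats (82–90 at full scale, the post-transient tail at reduced
  scale). A symmetric beat in unbounded fluid gives `A ≈ 0`; a nearby wall
  induces `A != 0`, growing with Sp.

## What the reduced-scale runs do and do not show

The qualitative mechanisms — hydrodynamic attraction to a plane wall,
downward deflection relative to a strip when the floor drops away at a
backstep, boundary-induced waveform asymmetry increasing with Sp — are
resolved at the mini preset with short approach distances. What reduced
scale cannot provide is the quantitative deflection-versus-height map of
the full-scale study (hundreds of beats per trajectory at `Ns = 160`); the
`full` preset reproduces those study conditions for overnight runs.

## Known limitations

* The global force balance of a converged step
  (`∫ f_vis ds + ∮ phi_H dS = 0`) holds only to the compatibility error
  between the collocated finite-difference operators and the quadrature,
  measured at ~0.5% of `∫|f_vis| ds` at `Ns = 100` and decaying as
  `ds^2` (~0.2% at `Ns = 160`); the proximal force balance itself is
  enforced to the Picard tolerance.
* Wall and head interact with the flagellum purely hydrodynamically: no
  steric or electrostatic contact forces, so trajectories that approach a
  boundary closer than about one regularization length are outside the
  model's validity.
* The beat is planar by construction of the actuation; out-of-plane
  dynamics are representable but untested.
* The analytic tension equation printed in the classical derivation has a
  `gamma` factor on the `m n_ss . X_s` coupling term per our derivation;
  the standalone `tension_solve` uses the derived form. The production
  stepper derives its tension rows from the discrete update and does not
  depend on that term's coefficient.
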