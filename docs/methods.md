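# Methods

## Scope and model overview

`pbrflash` evaluates how well a tubular photobioreactor cross-section
drives the flashing-light effect: the rapid shuttling of algal cells
between the illuminated outer layer (light zone) and the interior (dark
zone) of the culture.  The pipeline has four stages — cross-section
geometry, a 2-D liquid flow/turbulence field, Lagrangian cell tracking,
and metric extraction — followed by scenario comparison.

The package deliberately does **not** solve two-phase momentum or k–ε
transport.  Reference solutions for these reactors come from 3-D
commercial CFD; the contribution here is the evaluation layer (zone
partitioning, cycle statistics, field synergy, mixing metrics), which is
testable only against controlled fields.  The synthetic generator supplies
such fields with the structural features reported for aerated double-tube
reactors; external CFD cross-section exports enter the same pipeline as
CSV tables.

## Geometry

All layouts live in one cross-sectional frame: a vertical *depth axis*
(positive toward the illuminated top of the outer tube) and a horizontal
*lateral axis*, origin on the outer-tube axis, lengths in mm.  Defaults:
outer radius 100 mm, inner radius 40 mm.

- *plain*: culture region is the outer disc.
- *concentric*: annulus between coaxial tubes.
- *tangent*: the inner tube internally tangent to the outer tube at the
  bottom (inner centre at depth −60 mm).  A 60° arc removed at the bottom
  of the inner tube is modelled as the closing chord across the removed
  arc; everything below that chord (the chord strip and the two cusp
  corners between the tubes) is excluded from the culture region.  The
  fillet is toggleable.

Illumination is simplified to normal incidence from the top: the light
path of a point is the vertical distance to the outer circle.  The
light/dark interface is a horizontal line through the outer-tube axis by
default (configurable).  Area quantities (culture area, zone-area ratio
for a given penetration depth) reduce exactly to 1-D integrals of
per-column interval lengths and are evaluated by adaptive quadrature; a
Monte-Carlo membership oracle in the test suite cross-checks the tangent
layout.

The published zone-area ratios for these reactors (0.648 tangent, 0.493
plain under a 60 mm light path) are not reproducible from the stated
penetration rule under any single-direction light-path definition we
examined; the geometric operation implements the stated rule, and the
printed ratios are used only as inputs to comparison arithmetic.

## Synthetic flow fields

Velocities are the curl of a scalar streamfunction evaluated on a uniform
grid (default 2 mm spacing), so the central-difference divergence vanishes
identically on interior cells.  Kernels:

- Gaussian-core vortex: ψ = S·σ·exp(−r²/2σ²), S in m/s, σ in mm.
- Jet plume: a dipole ψ = S·(p̂·Δx)·exp(−r²/2σ²) whose centre velocity
  points along the jet axis.

A smoothstep taper on the wall distance (width 25 mm) holds the
streamfunction constant at the walls (no-penetration) and produces the
near-wall decay: in default scenarios the mean |V_r| on the ±85 mm
monitoring lines is several-fold below the ±40 mm lines, reflecting the
order-of-magnitude near-wall suppression seen in reference solutions
(enforced floor: 5×).

`default_scenario` assembles, for a given aeration direction θ (positive
up; −30° is the reference configuration) and rate (vvm):

1. A counter-rotating vortex pair (core 22 mm, centres at lateral ±20 mm)
   whose common edge produces a downwelling jet across the light/dark
   interface.  Its centre depth rises above the interface as the aeration
   rotates upward.
2. Pore jets at the aeration sites (two mirror-symmetric side pores for
   the tangent layout; one pore canted −45° for the concentric layout),
   with strength proportional to the vvm-derived superficial jet speed
   times a momentum-transfer coefficient (default 0.05).
3. For upward-rotated directions, a *dark-zone degradation* controlled by
   the upwardness u(θ) = x^0.35 with x the normalized sine distance from
   −30°: the deep dark-zone streamfunction is scaled by 1 − 0.75·u
   (sparse, sluggish dark flow), and a pair of closed recirculation eddies
   appears deep in the dark zone (strength ∝ u).  Cells that dip across
   the interface are captured by these closed eddies and released only by
   turbulent jitter — the settling/dead-zone behaviour of upward-aerated
   reactors.
4. Turbulent kinetic energy as Gaussian blobs riding the vortex cores and
   pore sites over a low ambient level, and dissipation from the standard
   k^{3/2}/ℓ closure with ℓ set to the aeration-pore radius: bubble-
   injected turbulence acts as fine-grained jitter rather than
   cross-section-scale transport.

Two calibrations are applied by exact linear rescaling: the peak |V_r| on
the ±40 mm monitoring lines matches its target (defaults 0.0393 / 0.045 /
0.049 m/s at 0.3 / 0.7 / 1.0 vvm), and the culture-average TKE matches its
target (default 80 cm²·s⁻² for the tangent reference scenario, 54 for the
concentric one, 50 for the 0.3-vvm direction sweep).

Mirror symmetry of tangent scenarios is exact by construction: the total
streamfunction is odd in the lateral coordinate on a laterally symmetric
grid.

## Particle tracking

Cell surrogates are rigid spheres, d = 10 µm, density matched to the
medium (1000 kg·m⁻³), 20 per scenario, tracked for 60 s with positions
recorded every 0.1 s.  Forces per unit particle mass:

- quadratic drag  (3 C_D ρ_f)/(4 d ρ_d)·|v_f − v_p|(v_f − v_p),
  C_D = 0.44 (constant Newton-regime coefficient);
- pressure-gradient force  (ρ_f/ρ_d)·Dv_f/Dt with the material
  acceleration (u·∇)u of the steady field (central-difference gradients,
  bilinear interpolation).

Gravity and buoyancy cancel for density-matched particles and are omitted.
Turbulent dispersion is the discrete random walk: the fluid velocity seen
by a particle is the mean field plus a Gaussian fluctuation with
per-component variance 2k/3, held for an eddy lifetime τ_e = 2·T_L,
T_L = 0.15 k/ε, then resampled (conventional constants; the model itself
fixes none).

Integration is explicit RK4 at a 0.01 s base step.  Because the drag
relaxation time at 10 µm is of order milliseconds — far stiffer than the
base step right after an eddy resampling — each step is internally
subdivided so that the local drag rate per substep stays bounded
(h ≤ 0.8/(A·max slip)); this keeps the explicit scheme stable while
preserving step-halving convergence (<0.1 % of the outer radius) and the
closed-form drag-relaxation and solid-body-orbit oracles (≤1 %).  Walls
reflect specularly; reflection preserves speed.  With a fixed seed, runs
are bit-reproducible.

Release positions: the model leaves them unspecified.  `track` draws
uniform seeded positions by default; scenario comparisons
(`run_scenario`, the pipeline, the sweep) instead release the same
deterministic stratified grid of positions in every scenario, so paired
comparisons are not confounded by release sampling.

## Metrics

- |cos α| per cell: |u·ĝ|/|u| with ĝ the (constant) light direction;
  cells slower than 10⁻⁹ m/s are undefined and excluded from means (their
  fraction is reported).  The measure is invariant under rescaling u.
- V_r profiles: bilinear samples of the depth-axis velocity component
  along vertical monitoring lines (±40 mm near the pores, ±85 mm near the
  wall).  V_r is interpreted as the depth-axis component — the component
  that carries cells across the light/dark interface.
- Mean TKE: area-weighted mean of k over culture cells (uniform cells).
- Dead-zone fraction: culture-area fraction with speed below 10⁻³ m/s.
- Light/dark cycles: interface crossings located by sign change of the
  depth coordinate against the boundary with linear interpolation between
  samples.  A cycle is the span between alternate crossings (one light and
  one dark interval).  The population period T pools all observed cycles
  (the defining sum runs over cycles); f = 1/T; φ is the light-time
  fraction over each particle's complete-cycle span, averaged with span
  weights.  A per-particle-mean variant of both is available
  (`per_particle=True`).  Particles that never cross are excluded and
  counted; at least three crossings are needed to hold a complete cycle.

## Scenario comparison

Percent change 100·(new−baseline)/baseline and fold ratio new/baseline,
displayed at one decimal with full-precision raw values serialized
alongside.  Missing metrics render as "—".  Literature metric rows for
other reactor designs ship as clearly labelled static metadata and are
never recomputed.

## What the synthetic generator does and does not emulate

It reproduces: divergence-free cross-sectional circulation with
counter-rotating vortices at the interface for downward aeration,
near-pore V_r peaks at calibrated magnitudes, near-wall suppression,
configurable mean TKE, mirror symmetry, and monotone degradation of
dark-zone transport as aeration rotates upward.  It does not reproduce:
two-phase coupling and gas holdup, 3-D axial development, wall boundary
layers beyond a smooth taper, turbulence anisotropy, or the absolute
light/dark cycle frequencies of the 3-D reference solutions (measured f
here is of order 0.1–0.3 Hz; the reference reactors cycle near 1–2 Hz).
Passing tests therefore validate the *evaluation machinery* and the
generator's structural contract, not hydrodynamic prediction of a real
reactor.

On ranking robustness: the five-direction sweep is designed so that the
30°-downward scenario maximizes the cycle frequency and light-time ratio
by construction.  With the study's 20 particles over 60 s, the sampling
noise of f is a few percent-relative and of φ several percentage points
(per-particle cycling is strongly autocorrelated, so the effective sample
size is the particle count, not the cycle count).  The f ranking is
robust across seeds; the φ ranking's systematic margin is of the same
order as its sampling noise — mirroring the small φ spread the reference
reactors themselves show across aeration directions — and can flip for
individual seeds.

## Numerical choices and degenerate inputs

- Grid spacing 2 mm (~100 cells across the outer diameter); a coarser
  grid than 20 cells across the diameter is rejected.
- Area quadrature: adaptive 1-D integration of column lengths; relative
  error well below 10⁻³ against closed forms.
- Zero-strength calibration with a nonzero target raises a calibration
  error; an all-lit geometry returns an infinite light/dark ratio rather
  than dividing by zero.
- Field tables are written at full float precision and re-read with the
  round-trip parser, so write-then-read is bit-exact; incomplete or
  non-numeric grids are rejected with the offending column and row.
- Exact-zero depth samples on the interface are attached to the previous
  side so a grazing touch is not double-counted as two crossings.

## Known limitations

Steady 2-D fields only; one-way coupling (particles do not affect the
fluid); no light attenuation model (the zone boundary is a line, not a
Beer–Lambert isophote); the vvm-to-liquid-momentum coupling is a single
tunable coefficient because no circulation correlation is available; pore
count/diameter/spacing are configurable defaults, not asserted facts.
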