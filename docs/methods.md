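# Methods

## Model

The device is modeled as a rectangular block partitioned into four voxel
regions: open vessel lumen, a uniform-thickness endothelial shell, porous
fibrin interstitium, and (optionally) solid exterior. Steady incompressible
flow is described by one unified momentum equation on the whole block:

* lumen (free flow): `0 = -grad p + mu lap(v)` with optional convective
  term `rho (v . grad) v`;
* porous regions: Brinkman with Forchheimer correction,
  `0 = -grad p + (mu/eps_p) lap(v) - (mu/kappa) v
  - rho eps_p Cf / sqrt(kappa) |v| v`, with
  `Cf = 1.75 / sqrt(150 eps_p^3)`;

plus continuity `div v = 0` in every cell. Writing both regimes as one
equation makes velocity and stress continuity at the free/porous interface
implicit — the standard single-domain Brinkman practice — so no explicit
interface conditions are needed.

At the device's scale (velocities of order 100 um/s, lengths of order
100 um) the Reynolds number is ~1e-3 and the convective and Forchheimer
terms are numerically negligible; the default `stokes_brinkman_linear`
mode therefore drops them and solves a single linear saddle-point system.
`picard_full` retains both with lagged coefficients (Forchheimer drag with
the previous iterate's |v|; first-order upwind convection with the lagged
advecting velocity) and iterates to a fixed point; it reproduces the linear
solution to <1e-4 relative at the physical density, and reduces to it
exactly as rho -> 0.

### Default parameters

| quantity | value | note |
|---|---|---|
| fluid density rho | 1000 kg/m^3 | culture medium |
| fluid viscosity mu | 1.002e-3 Pa s | medium at 37 C |
| endothelial viscosity | 3e-3 Pa s | taken similar to whole blood |
| porosity eps_p | 0.265 | fibrin gel and endothelial layer |
| kappa (fibrin) | 1.2e-7 m^2 | configured literature value; physically questionable (it implies near-free flow through fibrin — plausibly a unit slip in its source), kept as a plain config default |
| kappa (endothelium) | P_D mu L / eps_p | 5.66e-13 m^2 for the control P_D = 5e-8 m/s (mu = 3e-3 Pa s, L = 1 mm); 10x under IL-1beta |
| endothelial thickness | 5 um | typical confluent monolayer; uniform over the network |
| control pressures | 3.15 / 1.75 Pa | vessel / interstitial inlet; outlets 0 Pa |
| treated pressures | 0.35 / 0.075 Pa | the decayed head of the leakier device |

The `kappa = P_D mu L / eps_p` conversion follows the typeset source
formula read as a product over eps_p; dimensional bookkeeping is recorded
in the output metadata, and the alternative readings are one-line config
changes. Similarly the permeability estimator is read as
`P_D = (r/2)(1/I_vessel)(dI_gel/dt)` — the cylindrical volume-to-surface
form — with the literal `2r` reading available as a switch.

## Discretization and solver

MAC staggered grid on the voxel block: pressures at cell centers,
face-normal velocities on faces. Viscous coupling between neighboring
velocity unknowns uses the effective viscosity `mu/eps_p` averaged over the
cells adjacent to the connecting edge (symmetric); the Darcy drag on a face
is the arithmetic mean of the two adjacent cells' resistivities
`mu/kappa` (equivalently a harmonic-type average of kappa), so a
lumen-endothelium face carries half the shell's drag. Solid (EXTERIOR)
cells and untagged block boundaries are no-slip walls, imposed through
ghost-value reflection (wall plane half a cell beyond the last fluid
cell). Tangential boundaries of pressure-tagged faces are free-slip.

Boundary pressures act at ghost cell centers half a cell outside tagged
block faces, which keeps the gradient and divergence operators exact
transposes (a symmetric saddle-point system). Pressure-driven duct
fixtures exploit this by using `round(L/h) - 1` axial cells so the
ghost-to-ghost pressure drop spans exactly the physical length L.

The linear system is solved by a pressure Schur-complement conjugate
gradient: the velocity block A is SPD and decouples per component, so it is
factorized once (sparse LU in symmetric mode) and CG runs on
`G^T A^-1 G` with a diagonal (SIMPLE-type) preconditioner. The CG residual
*is* the discrete continuity residual, so mass conservation is enforced
directly; solved cases show boundary-flux imbalances of ~1e-12 relative.
Picard updates re-solve the perturbed (non-symmetric) system directly.

Verification: mean axial velocity in a voxelized 40-um tube converges to
the closed-form value with errors 5.8% / 2.6% / 0.09% at 8 / 16 / 32 cells
per diameter; a homogeneous porous slab reproduces the Darcy velocity to
0.15%. The convergence study uses a 100-um-long tube (the error is set by
the cross-section discretization, which these sizes isolate cheaply).

## Wall shear stress

At each lumen cell adjacent to the wall, the wall normal is the gradient of
the lumen distance transform and the tangential velocity is sampled one
cell inward along it, where the staggered solution is insensitive to the
staircase wall. The shear rate is the one-sided difference against the
no-slip interface value over the sampled wall distance, corrected for the
parabolic profile with the local vessel radius (distance-transform value at
the nearest medial-axis voxel): `wss = mu |v_t| / d * 2R/(2R - d)`. The
uncorrected wall-cell difference underestimates the Poiseuille value by
11-14% at practical resolutions (the staircase wall drags the first cell
layer); the corrected estimator is within +0.2% to +8% over 8-32 cells per
diameter, converging from above.

Per-link statistics assign lumen voxels to the nearest centerline; end
fluxes (faces to other links or through pressure boundaries) and wall
fluxes (faces into endothelium/interstitium) are summed from the discrete
face fluxes, so inflow - outflow - leakage closes to machine precision by
construction.

## Extraction pipeline

Isotropic resampling preserves physical extent to within one target voxel
(rounded shape). The adaptive threshold compares each voxel to its local
mean over a 64-voxel cube plus an offset of 0.2x the robust (1st-99th
percentile) intensity range — on sparse fluorescence stacks a zero offset
admits half the background. DRLSE refinement uses the double-well
distance-regularized formulation (dt = 1, mu = 0.2, lambda = 5,
alpha = -1.5, epsilon = 1.5) on the 0-255-normalized smoothed intensity;
it is off by default and exposed for low-contrast data. Cleaning fills
6-connected cavities and removes 26-connected components strictly smaller
than 500 voxels.

Skeletonization is homotopic 3D thinning; a perfectly symmetric component
can be annihilated by the thinning tie-break, so any mask component left
without skeleton voxels is re-anchored at its innermost voxel, keeping
component counts equal. Junction voxels (>= 3 skeleton neighbors) cluster
into branch nodes at their centroid; degree-1 voxels are terminals;
isolated cycles are anchored at an arbitrary voxel. Radii are the
mask distance transform evaluated along the centerline (3-point median
smoothed); points closer to a link end than the local radius are excluded
from the per-link mean because inside a junction the distance transform
reflects the union of the joining vessels. The nearest-perimeter-voxel
variant is available behind a flag and agrees within a voxel on tubes.
Tortuosity subdivision splits at exact path-length fractions, inserting
pass-through nodes (kind "through", not counted in the branch/terminal
ratio); children are not recursively subdivided.

On synthetic 20-link networks (radii 5-20 voxels, 2-um blur, 5% noise)
the round trip recovers per-link radii with R^2 ~ 0.98-0.99 and median
error 0.25-0.4 voxels, with per-point radii matched to ground-truth links
through their nearest centerline samples.

## Geometry reconstruction

The lumen is the union of capsules — a cylinder per centerline segment
with spheres at segment ends, which is exactly what removes seams at
branch points; the endothelium is the r + t_endo capsule union minus the
lumen. The construction is implicit (signed distance per segment over a
local bounding box), which is robust to the self-intersections that defeat
direct surface export. Links ending within one radius of a tagged block
face are extended through it so inlets/outlets open without an endothelial
cap. Per-point tapered sweeps are available; the default is the constant
per-link radius. Iso-surfaces are marching cubes at 0.5 occupancy after a
1-voxel Gaussian (a raw binary surface overestimates a sphere's area by
~9%); registration is point-to-surface ICP with a closed-form (SVD) rigid
step, and cloud-to-mesh distances are exact point-triangle distances on
KD-tree candidate triangles.

Rebuilding the label field from a graph and comparing its lumen surface
against the rasterized surface of the same graph puts 100% of sampled
points within 2 voxels after registration. Rebuilding from the *extracted*
graph of a noisy stack reaches ~93-97%: thinning retracts skeleton
endpoints at boundary-cut fat vessels, and junction blobs are not unions
of circular cross-sections — the same residual sources the bottom-up
approach is known for. Both numbers are reported by the acceptance script.

## Bead velocimetry

Detection is a difference-of-Gaussians band-pass at the bead scale with
plateau-collapsed local maxima, parabolic sub-pixel refinement, and a
relative quality floor (1% of the frame's strongest response). Linking is
greedy nearest-neighbor with mutual one-to-one assignment, a 150-um step
gate, and constant-velocity prediction of each track's next position
(deterministic; prevents identity swaps when a fast bead overtakes a slow
one in projection). Tracks shorter than 3 frames are dropped and tracks
with net displacement under 125 um are filtered before speeds are
reported. Tracking operates on 2D projections by default.

Greedy linking degrades at high bead density: many simultaneous beads in a
small projected area produce overlap merges and path-inflating identity
swaps. Velocimetry validation therefore perfuses beads in sparse cohorts
(5 at a time through a 1.2-mm tube at the 0.034-s control frame interval),
which matches how beads actually transit an imaged device; pooled over 50
beads the recovered mean speed is within ~1-4% of ground truth, and within
10% with 0.5-um localization noise.

## Synthetic data

Generators are pure functions of (config, seed) and always return ground
truth. The network generator grows a branching tree from the inlet face to
the outlet face with parent >= child radii (defaults: 20 links, radii
5-20 um, mild half-sine waviness, 2-um blur, 5% additive noise —
the imaging regime of the real networks, with diameters up to 40 um and
velocities of order 100 um/s). It emulates tubular fluorescence with
circular cross-sections; it does not emulate anisotropic PSFs, eccentric
lumens (real vessels have eccentricity ~0.8), intensity inhomogeneity, or
photobleaching, so passing round-trips bound algorithmic error, not
instrument error. Permeability timelapses ramp the gel intensity at the
slope implied by the prescribed P_D; bead movies render Gaussian blobs at
true sub-pixel positions of RK4-advected tracers (integer-pixel rendering
would itself bias slow-bead speeds by tens of percent).

## Cytokine scenario

The control vs IL-1beta comparison on the two-channel grid phantom is
composite, mirroring how the effects are actually observed:

* at equal (control) boundary pressures, the tenfold endothelial
  permeability strictly increases total transmural leakage (x2.7) and
  outlet discharge (x1.23) — the equal-head discharge comparison;
* across the two printed scenario parameter sets (control pressures +
  control kappa vs treated pressures + 10x kappa), mean intraluminal WSS
  and distal intraluminal velocity drop to ~0.10-0.12x;
* under the finite-reservoir protocol — both devices start from the same
  head, which decays as dp0 exp(-t/tau) with tau = A/(2 rho g C) set by
  each device's own conductance C — pooled bead speeds over three control
  time constants are ~10% lower for the treated device.

At strictly identical pressures a leakier wall *raises* intraluminal
velocity and WSS (it adds a parallel conductance), so the observed WSS and
velocity drops are consequences of the faster head decay, not of the wall
change alone; the lumped two-reservoir decay stands in for that transient
as a sequence of steady states.

## Problem sizes and limitations

Validation fixtures use 15k-250k unknowns (tube oracles), a ~420x200x200
voxel synthetic stack for the extraction round trip, and a 60x30x20-cell
phantom — sizes chosen so the full suite and the acceptance script each
run in minutes on one CPU while keeping discretization errors inside the
bands above. Known limitations: steady state only (no pulsatility or
fluid-structure interaction); circular cross-sections and uniform
endothelial thickness; 2D projection tracking; the voxel staircase limits
WSS accuracy to a few percent at 16 cells per diameter; and the fibrin
permeability default is a configured literature value whose magnitude is
suspect (see table) — conclusions that depend on it should be checked
against a literature-range value (1e-13 to 1e-11 m^2), which leaves every
scenario direction above unchanged.
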