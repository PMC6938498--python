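# Methods

This note records the model, the numerical choices, and the limits of what
the package's tests demonstrate.

## Geometry

The container is the intersection of two disks of radius
R = (Lx² + Ly²)/(4 Lx) centered at (±c, 0) with c = R − Lx/2, extruded to
depth h along z; the origin sits at the container center, y is the major
axis and z ∈ [0, h].  The cusp opening angle is α = 4 arccot(Ly/Lx), 180°
in the circular limit.  All lengths are in units of the rod diameter d —
only the dimensionless ratios L/d, h/d, Ly/L and Ly/Lx matter, which is
also what permits comparing rods of modest aspect ratio (L/d = 20) with
much more slender experimental particles: the wall-alignment layer scales
with the rod length, so matching confinement-size-to-rod-length ratios
reproduces the same regime.

The hard wall is enforced exactly: a capsule lies inside the container iff
both centerline endpoints lie in the lens eroded by d/2 (erosion of an
intersection of convex sets is the intersection of the erosions, and a
segment lies in a convex set iff its endpoints do).  The cusp needs no
special casing.  This is O(1) per rod and exact, in contrast to generic
distance-to-surface tests.

## Monte Carlo

Single-particle Metropolis moves combine a translation uniform in a cube of
half-edge `dr_max` with a rotation by a uniform angle in [0, `dtheta_max`]
about an isotropically random axis.  A sweep is N attempts on uniformly
random particles (detailed-balance-safe; no fixed particle order).
Defaults `dr_max = 0.5 d`, `dtheta_max = 0.1 rad` give ≈ 20–40% acceptance
at η = 0.16 depending on the local order; amplitudes are configuration
knobs, not observables.  Rotations are fully 3D — the shallow container
itself suppresses out-of-plane tilt (the global director's |n_z| stays
below ~0.05 in our runs), so no artificial 2D constraint is imposed.

Overlap tests use the exact segment–segment minimum distance (closest-point
parametrization with clamping).  A uniform cell grid with edge ≥ L + d over
the lens bounding box (one cell in z) makes the 3×3 neighborhood of a trial
center exhaustive for overlap candidates; an all-pairs O(N²) oracle is kept
for validation and is asserted against the cell-list path in the tests.
The RNG is a single counter-seeded stream per chunk of sweeps; runs are
bitwise reproducible given (seed, parameters, start).  Long experiments run
in chunks of `sample_every` sweeps whose child seeds derive
deterministically from the run seed.

## Initial states

Four controlled starts at target η: aligned with the major axis, aligned
with the minor axis, tilted 45° from the minor axis, and radial
("hedgehog", carrying a central +1 defect).  Placement is randomized
sequential insertion: uniform random centers (z uniform in [d/2, h − d/2]),
the mode's orientation jittered by ≤ 3° in plane, with per-particle
relocation retries that never change the orientation (preserving the
intended director field; for the hedgehog this preserves the central
charge).  At η = 0.16 and h/d = 6 the per-layer footprint coverage is ~0.25,
far below aligned-insertion saturation, so the target density is reached
reliably; if fewer than 90% of the target count can be placed the builder
raises with the realized volume fraction.

## Order fields and defects

The global tensor order parameter is Q = (1/N) Σᵢ (3/2 ûᵢ⊗ûᵢ − ½𝟙); its
top eigenvalue is the scalar order S and the corresponding eigenvector the
director (the 3D form so the out-of-plane component can be monitored).
The local field divides the bounding box into square cells of edge
`cell_size` (default L/2 — resolving defect cores, which extend about one
rod length, with ≥ 2 cells) spanning the full depth; each rod contributes
to cell k with weight equal to the centerline length lᵢᵏ inside k (exact
parametric clipping; Σₖ lᵢᵏ = L, asserted to 10⁻⁶ relative).  Because the
local tensor is defined with an ensemble average, the analysis accepts a
window of consecutive frames and accumulates the weighted sums before
diagonalizing; relaxation experiments average 3 consecutive samples.

The angular deficit pairs opposite neighbors: δ = min∠(n_W, n_E) +
min∠(n_S, n_N) with minimum line–line angles (radians).  This choice makes
δ vanish identically for uniform and smoothly bent fields and peak at
defect cores, and is invariant under director sign flips.

Defect detection is two-stage:

1. **Interior** — the nematic winding number of every 2×2 plaquette of
   occupied cells (director-angle increments folded into (−π/2, π/2],
   summed, divided by 2π).  Plaquettes with |w| ≥ 1/4 are clustered
   (8-connected); the cluster charge is the winding of a closed loop of
   cells enclosing the cluster (robust to folding noise at the core, and
   exactly half-integer for clean fields), the position the
   |w|-weighted centroid.
2. **Boundary** — the cores of surface boojums (e.g. the cusp defects of
   the bipolar pattern) lie outside every closed loop of occupied cells, so
   no plaquette can see them.  Instead, for candidate sites along the wall
   (spacing 0.75 cells, cusps always included) the director rotation across
   the occupied cells in an annulus (0.5–2.2 cells) around the site,
   nematically unwrapped along their polar order, divided by their angular
   span, estimates the local charge q̂; cyclic local maxima with |q̂| ≥ 1/4
   are kept.  Two guards reflect the physics: a candidate must co-localize
   with a depressed scalar order (defect cores are disordered; smooth
   strongly-bent fields such as a radial field at the wall are not), and
   only **positive** boundary charges are accepted, clamped to +1/2 —
   planar anchoring on a convex boundary admits +1/2 boojums, while
   negative open-arc readings are the anchoring bend of the wall layer
   (strongest at the cusps whenever the bulk director crosses them) and
   carry no bulk topological charge.  Negative charges in the catalogued
   patterns are always interior and are found by stage 1.

With this convention the detected charges of every complete pattern sum to
+1, the Euler characteristic of the lens; this is asserted on the full
fixture suite.

## Synthetic fields

Every pattern class has an analytic fixture: the harmonic multi-defect
solution θ(r) = Σⱼ qⱼ atan2(y − yⱼ, x − xⱼ) + π/2, which is tangential at
the wall for the two-boojum configurations.  The wavy S-type patterns add a
smooth serpentine modulation A sin(2πy/Ly) windowed in x (σ = Lx/6) so the
wall region stays tangentially anchored; A = 35°, comfortably above the
classifier's 15° wave threshold.  The scalar order ramps linearly to zero
over 1.5 cells around each core so the coarse grid always samples the
depressed-S halo.  Fixture geometries follow the sizes at which each
pattern actually occurs (Ly of 150–400 d); at much smaller containers the
six cores of M₆ fall below the L/2-cell resolution and merge, which only
inflates counts (the pathway classifier therefore uses a ≥ 6 rule, see
below).

The fixtures share the same data structure as simulation-derived fields, so
the entire analysis stack is input-agnostic and testable without MC.

## Classification

Decision tree on the defect list and field: no defects and mean director
within 10° of the major axis → H; two defects both within
max(L/2, 0.05 Ly) of a cusp → B (circle) or B∥ — or S if the wave
criterion fires; two defects at the minor-axis ends (tolerance
max(0.1 Lx, 1.2 cells) — the floor reflects the boundary-site quantization
of detected positions) → D_h; otherwise D* (one defect off-cusp) or D**
(both), upgraded to S** under the wave criterion; more than two defects →
M_n.  The wave ("S") criterion samples the director along the major axis,
folds the angle to the major axis into (−90°, 90°], discards cells within
two cells of a defect core and cells beyond ±70° (a transverse director is
not a wave — without this exclusion the nematic fold at ±90° fakes sign
changes on any minor-axis-aligned state), and requires sign-changing
excursions beyond 15° on both sides.

Pathways are classified from the defect series after the Dh stage,
majority-filtered over 5 samples.  The melt/slide split uses the number of
*negative* defects when per-sample defect lists are available: the M₆
droplet intermediate carries two interior −1/2 defects and M₄ exactly one,
and interior negatives come from plaquette winding, which stays reliable
where coarse cells merge neighboring boundary boojums (at Ly/L = 4.5 the
droplet's four +1/2 cores sit only ~2 cells apart).  With only total
counts, the equivalent rule applies to them: sustained ≥ 6 → *melt*, 3–5 →
*slide* (3 and 5 absorb single missed/extra detections).  A count never
exceeding 2 is *turn* provided the two-defect pattern actually passes
through displaced (D*/D**/D_h) states.  The
"Dh stage" used as the timing origin is operational: the first sample with
exactly two positive defects on opposite sides whose pair axis lies closer
to the minor than the major axis — the strict D_h label additionally pins
the cores to within about a cell of the minor-axis ends, which the coarse
grid can miss while the pattern is visibly formed.

Equilibration time is the first sample at which the global S ≥ 0.6 and the
director is within 5° of the major axis (any axis, for circles), sustained
for 10 consecutive samples; `inf` if never reached.  The thresholds are
set so a major-axis-aligned start in a slender spindle registers as
equilibrated essentially immediately.

## Problem sizes and what the tests show

The full-scale experiments (containers up to Ly = 20 L, equilibrations of
order weeks of CPU time) are far beyond a test suite.  The package's
relaxation experiments therefore run the smallest study geometries —
Ly/L = 4.5 (≈ 230 rods) and Ly/L = 6 (≈ 410 rods) at the study conditions
L/d = 20, η = 0.16, h/d = 6, aspect 1.5 — for a few times 10⁵ sweeps.
At these sizes the full melt/slide/turn phenomenology exists but with
caveats a reader should know:

* The Dh-formation-to-equilibration time ratio is scale-dependent: Dh
  assembly is a wall-local process of roughly size-independent duration,
  while equilibration slows strongly with container size.  At full scale
  the ratio is a few percent; at Ly/L = 4.5 the two scales are separated by
  only a factor of 5–10, so the measured ratio is of order 10–25%.  The
  acceptance script reports the measured value, not the full-scale one.
* At Ly/L = 4.5 the M₆ droplet's six cores sit at the edge of the L/2-cell
  resolution, so small containers tend to register their multi-defect
  intermediates with 3–5 counted defects (slide-like) even when a central
  droplet is transiently present.
* Pathway frequencies from a handful of seeds are coarse, and the
  melt-favoring-to-turn-favoring crossover lives at container sizes
  (Ly/L ≳ 12, thousands of rods, multi-million-sweep equilibrations) far
  beyond a test suite.  The size-trend test (melt non-increasing, turn
  non-decreasing) therefore compares only Ly/L = 4.5 and 6 with one or two
  seeds each, which cannot resolve frequencies; moreover at Ly/L = 4.5 the
  five-domain droplet barely fits the container (Lx = 3 L), so the melt
  route is suppressed there for a reason outside the monotone statement's
  range.  This test documents that limit rather than confirming the trend.

The synthetic-data generator (the fixture module) emulates the director
*fields* of the patterns, not the particle-level fluctuations of a real
nematic: its noise model is independent per-cell angular jitter, whereas MC
frames have correlated fluctuations, depleted walls and finite occupancy.
Passing the fixture suite therefore demonstrates the correctness of the
analysis stack's geometry and topology handling, not MC-frame robustness;
the latter is exercised separately by the relaxation experiments.

## Degenerate inputs and numerical details

Segment–segment distance uses the clamped closest-point algorithm with an
ε = 10⁻¹⁴ guard for degenerate (point-like or parallel) cases.  Cell
clipping uses half-open intervals along degenerate axes so a rod lying
exactly on a shared cell edge is counted once.  Directors of empty cells
are undefined and masked.  A synthetic field sampling point that coincides
with a defect core is nudged by 10⁻³ cells.  Eigen-decompositions use the
symmetric solver; the director sign is arbitrary and all consumers are
sign-free.  The equilibration sentinel is `inf`; pathway classification of
series shorter than the majority filter window raises.
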