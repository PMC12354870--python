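# Methods

This note documents the models, numerical choices and design decisions
behind `fiberpath`, and what the synthetic test conditions do and do not
show about real imaging data.

## Geometry conventions

All world geometry is in millimetres.  Voxel indices are 0-based; the
world coordinate of voxel `(i, j, k)` is `origin + index * spacing`.  A
continuous point belongs to a mask iff its nearest voxel does.  Trilinear
interpolation requires all 8 neighbouring voxels, so the outermost
half-voxel rim of a grid is never extrapolated; analytic test fields
therefore mask off a one-voxel border.

## Direction fields and sign coherence

Fiber orientation is axial: `v` and `-v` are the same fiber.  Every
interpolation call takes a reference direction and flips each of the 8
corner vectors so its dot product with the reference is nonnegative before
blending and normalizing.  Without this, antiparallel neighbours cancel
(the blend of `v` and `-v` is zero) and tractograms depend on the
arbitrary per-voxel eigenvector sign.  A blended magnitude below 1e-8
marks the support boundary and terminates tracking.  The invariance is
exact: flipping voxel signs at random changes no streamline by more than
floating-point identity, except that flipping the seed voxel's vector
swaps the forward and backward branch labels of that seed.

## Tensor fitting

The per-voxel diffusion tensor is estimated by unweighted log-linear least
squares on `ln S = ln S0 - b g^T D g` over all gradient volumes, with
non-positive signals clamped to a tiny positive floor before the
logarithm.  Weighted and nonlinear variants are deliberately out of scope:
with noiseless or high-SNR synthetic data the linear fit is exact (the
round-trip error against the generating tensors is at machine precision),
which is what the tests rely on.  A gradient scheme is accepted only with
at least one b = 0 volume and six independent nonzero directions (design
rank 6).  Voxels whose leading eigengap is below 1e-9 (relative) have no
meaningful principal direction; they get a zero vector so tracking stops
there rather than following noise.

The denoising residual diagnostic is computed as `sqrt(2 |X_orig -
X_denoised|)`: the absolute value guards the radicand, which can otherwise
be negative; the map is a visual diagnostic only and feeds nothing
downstream.

## Tractography

Streamlines follow `dp/ds = v(p)` with classic RK4 at fixed step Δs, all
four stage evaluations sharing the previous step's direction as the sign
reference (the seed uses the raw voxel vector times the branch sign).
Each seed propagates forward and backward as two separate streamlines.  A
step is committed only if every stage sample is valid and the endpoint
stays inside the mask; the step is discarded otherwise, which guarantees
no streamline point ever leaves the mask.  Tracking stops when the
accumulated chord length would exceed l_max.  Polylines with fewer than
two points are dropped (they cannot be printed).

Seeds form a global regular sub-grid with per-axis spacing
`voxel / cbrt(n_seed)`, so `n_seed` must be a perfect cube; 64 seeds per
0.8 mm voxel and 1 seed per 0.2 mm voxel give the same 125 seeds/mm³.

On an analytic unit-speed vortex the integrator's endpoint error after one
revolution contracts ~16x when Δs halves (4th order); the radial drift
itself contracts ~32x because RK4's amplitude error for circular motion is
one order higher than its phase error.  Convergence is measured on the
continuous analytic field: a voxelized vortex would add an O(h²)
interpolation bias unrelated to the integrator.

## Sweep exclusion

Thinning sweeps a cylinder of radius w_s along the current streamline and
removes every streamline with any sample strictly inside it; removal is
all-or-nothing.  The first streamline is the longest (ties: lowest input
index); each subsequent one is the remaining streamline with the smallest
MDF distance to the last swept (K = 20 resample points by default).
Intersection tests sample the candidate streamline at most `test_step`
apart (default w_s/2, never larger), so the guaranteed clearance between
kept streamlines is w_s − test_step.  A KD-tree over all candidate samples
prunes the search; the prefilter radius (half segment length + w_s) cannot
miss a true hit, so acceleration never changes the result.  All ties break
toward the lowest input index, making the procedure deterministic — but
not robust: distances near the w_s threshold can flip under coordinate
perturbation (e.g. the 4-decimal artifact precision), cascading into
slightly different kept sets.  This is inherent to the greedy geometric
definition; only the spacing guarantee, not the exact kept set, is stable.

w_s is a pure configuration value.  The quarter-scale preset uses 0.84 mm
with needle diameter 0.4 mm and bead width 0.548 mm; the full-scale preset
uses 1.0 / 0.84 / 1.0 mm.

## Collision model

The needle while printing a toolpath is the union, over its samples `s`,
of semi-infinite vertical cylinders `{horizontal distance <= d_n/2, z >=
s_z + tip_offset}`; the deposited material of another toolpath is the
union, over its samples `q`, of axis-aligned oblate spheroids with
horizontal semi-axis d_p/2 and vertical semi-axis h_p/2.  The pair test
evaluates the exact intersection condition of those two families: the
needle bottom must sit below the bead top, and the horizontal gap must be
smaller than d_n/2 plus the bead's horizontal radius at the lowest height
the needle reaches (`d_p/2 · sqrt(1 − clip(Δz / (h_p/2), 0, 1)²)`).
Keeping the z-dependent radius, rather than always inflating by the full
d_p/2, makes the fast test agree with a voxelized occupancy oracle built
from the same membership rules up to grid discretization, which is how the
model is validated (disagreements are only permitted within one voxel
pitch of the analytic margin).

The axis-aligned spheroid is itself a conservative simplification — the
physical bead cross-section is perpendicular to the local path tangent —
and false positives only add safe ordering constraints.  h_p is not
observable from above and defaults to d_p/2 (a flattened bead);
tip_offset defaults to 0; the needle is modeled at its inner diameter and
as infinitely long upward (shank taper, collar and gantry are not
modeled).  Sampling spacing defaults to min(d_n, d_p)/4.

Edges are directional: `A -> B` means printing B with A already deposited
would collide, i.e. A must print after B.  Both orientations of every pair
are tested.  With a cut plane, toolpaths are split at each transversal
crossing (the exact intersection point duplicated into both pieces — the
zero-thickness seam) and edges between opposite sides are prohibited;
points lying exactly in the plane inherit a neighbour's side.

## Acyclic reduction

Stage 1 repeatedly removes, among vertices in some 2-cycle, the one with
the largest in-degree × out-degree product (ties: lowest id) until no
2-cycles remain.  Stage 2 runs N independent iterations; each restarts
from the stage-1 graph and, while cyclic, deletes a uniformly random
vertex of one DFS-located cycle.  Targeting only cycle vertices (never
acyclic bystanders) is strictly more effective than deleting arbitrary
vertices and is the reading adopted here.  The best iteration (most
retained vertices, first attained on ties) wins; if some iteration removes
a single vertex the search stops early, since a cyclic graph must lose at
least one.  A single integer seed drives a PCG64 generator; cycle location
iterates vertices and neighbours in sorted order, so results are identical
across runs and platforms.  The default N is 10,000 — appropriate for the
few-hundred-vertex graphs of desk-scale runs (production-scale graphs
warrant orders of magnitude more); the demonstration pipeline uses 2,000,
where convergence (logged as best size vs iteration) is immediate because
its graphs have few or no cycles.  On 8-vertex random digraphs with
N = 5,000 the search matches the exhaustively enumerated maximum induced
acyclic subgraph in effectively every trial; exhaustive enumeration is a
test oracle only, never the implementation.

## Ordering and G-code

Among toolpaths whose dependencies are all placed, the greedy ordering
appends the one (and traversal direction, when reversal is allowed — the
default, since the swept needle volume is direction-independent) whose
entry point is nearest the nozzle, with ties broken by lowest id then
as-stored orientation.  This realizes a depth-first greedy descent whose
step cost is the travel gap; it minimizes travel locally, not globally.
The start position defaults to the minimum-x,y,z bounding-box corner.  The
output always contains every toolpath and respects every dependency edge.

G-code is plain `G1` with one travel move per toolpath, extrusion on/off
command strings around each extruded polyline, feeds converted from mm/s
to mm/min (print 3 mm/s -> F180, travel 10 mm/s -> F600 by default), and
4-decimal fixed-point coordinates, so a parse of the file recovers the
sequence to 5e-5 mm.  Hardware-specific pressure control belongs in the
configurable header/footer/on/off strings.

## Synthetic data

The phantom is the wall between two half-ellipsoid shells truncated at the
equator (long axis = z, apex down) — an idealized smooth-walled left
ventricle without trabeculation, papillary muscles or sheetlet structure.
Wall depth t solves, by vectorized bisection, for the interpolated shell
`inner + t (outer − inner)` through each voxel center.  The fiber at depth
t lies in that shell's tangent plane, combining the local circumferential
direction with the in-surface longitudinal direction; the in-surface pitch
is chosen so that the *measured* helical angle — the inclination from the
short-axis plane, `atan2(d·ẑ, d·ĉ)` with the fiber flipped to a
nonnegative circumferential component — equals the prescribed linear
profile HA(t) from +60° (endo) to −60° (epi) everywhere, not only near the
equator where the surface is vertical.  Voxels the long axis passes
through (the apex cap) have no circumferential direction and are excluded
from the mask.

The demonstration phantom has outer radii 14 × 14 × 15 mm and an 8 mm
wall at 0.5 mm voxels: thick enough for at least eight printable
transmural layers at the 0.84 mm line spacing, so the binned helical-angle
profile of the *final toolpaths* (10 quantile bins of per-toolpath mean
wall depth) stays monotone and spans well over 100° of the prescribed 120°
range.  A thinner wall would quantize the surviving layers too coarsely to
resolve the gradient.  The demonstration's cut plane is a finite vertical
half-plane through one side of the shell, cutting each circumferential
loop once, as a septal cut does for ventricular models.

The DWI simulator is the Stejskal–Tanner decay with optional additive
Gaussian noise (Rician noise is out of scope; tensor-fit tests use
noiseless data).  What passing tests show, and what they do not: synthetic
fields are smooth, exactly axial and noise-free, and the phantom graph has
few interference cycles.  Real DTMRI brings measurement noise, partial
voluming, disordered fiber crossings and much longer helical fibers —
retention after acyclic reduction on real ventricular data is expected
below the phantom's, and tensor-fit accuracy depends on SNR in ways these
tests do not probe.

## Problem sizes

Default test and demonstration sizes were chosen as the smallest that
still exercise every mechanism: the demo phantom yields ~90k streamlines,
~1,000 toolpaths and a ~4,500-edge graph and runs in about two minutes on
one CPU; the reduction oracle uses 8-vertex graphs where exhaustive
enumeration is trivial; collision validation uses sub-millimetre random
path pairs so the voxel oracle stays fine-grained at 1/8 of the smallest
geometric feature.

## Known limitations

* No probabilistic or crossing-fiber tractography, curvature stopping, or
  denoising; masks are inputs, never segmented here.
* The collision model ignores needle shank, collar and gantry, and uses
  axis-aligned bead cross-sections.
* Cut-plane placement is manual; no optimality metric is computed.
* Greedy ordering gives no global travel-optimality guarantee.
* Sweep exclusion's kept set is deterministic but threshold-sensitive;
  only the minimum-spacing guarantee is robust.
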