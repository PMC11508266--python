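# Methods

## Problem and model

The package plans straight percutaneous needle routes on a 3-D CT volume.
The model is purely geometric and intensity-based: a voxel either may or may
not be traversed by a needle, decided solely by its Hounsfield value, and a
route is a straight segment from the target voxel's center to a skin-entry
voxel adjacent to exterior air. There is no model of needle deflection,
tissue deformation, breathing motion, or needle length limits beyond the
maximum ray length; those are out of scope.

### Coordinate conventions

Voxel indices are 0-based with axes (i, j, k) ↔ (x, y, z). Voxel (i, j, k)
occupies the half-open cell [i·sx, (i+1)·sx) × [j·sy, (j+1)·sy) ×
[k·sz, (k+1)·sz) in volume-local millimetres and its center is
(index + 0.5) · spacing. Cell-based geometry (rather than point samples at
centers) is required for boundary-crossing traversal. DICOM pixel arrays are
row-major (y, x) and are transposed on load; slices are ordered by
ImagePositionPatient projected on the slice normal, never by filename. HU
values are clamped to [−2000, 4000] on load with a logged warning, since
scanners emit padding values (e.g. −3024) outside the calibrated range.
For export, volume-local mm is treated as LPS and converted to RAS (negate
x and y), matching 3D Slicer's internal frame.

## Tissue classification

Default HU bands (all configurable through `ThresholdConfig`):

| band | HU | label |
|---|---|---|
| air | (−∞, −900) | exterior or interior air |
| puncturable (low) | [−900, 30) | PUNCTURABLE |
| organ/vessel | [30, 60] | NON_PUNCTURABLE |
| puncturable (high) | (60, 100] | PUNCTURABLE |
| bone side | (100, ∞) | NON_PUNCTURABLE |

Published band edges collide at −900, 30, 60 and 100; the half-open choice
here is deliberate and conservative: an HU exactly on an organ-band edge
blocks the needle, and the five classes tile the whole HU axis (validated,
and property-tested). HU 100–250 (thyroid, coagulated blood) falls on the
bone side of the partition, i.e. non-puncturable. The adipose band
[−100, −50] is logged for skin-entry context but is not a requirement — skin
may present other puncturable HU.

Air is split by a 6-connected flood fill from the volume faces: connected
components touching any face are exterior (valid route terminus), the rest
interior (airway/gut gas, treated as an obstacle). 6-connectivity avoids
leaking the exterior through diagonal corner gaps. The split is idempotent.

## Supercover ray traversal

`traverse_ray` enumerates every voxel whose **closed** cell the segment
[origin, origin + t·u] intersects, in first-touch order. The implementation
is an incremental boundary-crossing walk (per-axis "next boundary" parameter
and per-axis increment), run natively in mm so anisotropic spacing needs no
rescaling. Numerical choices:

* exact corner/edge hits are detected with a 1e−9 mm tolerance on the
  crossing parameters; at an m-axis simultaneous crossing all 2^m − 1 cells
  sharing the corner/edge are emitted, ordered by entry parameter then
  lexicographic index;
* an origin lying exactly on a cell boundary touches the closures of all
  adjacent cells, which are emitted at t = 0;
* a ray running exactly inside a grid plane (zero direction component along
  an axis, origin on a boundary of that axis) touches both neighbouring
  rows for its whole length; the traversal expands every visited cell across
  those twin offsets;
* direction components within 1e−15 of zero are snapped to exact zero so
  axis-aligned rays take the degenerate-axis path deterministically.

The supercover choice is safety-driven: a voxel the needle could graze is
never skipped. Its central correctness property — set equality with an
analytic segment–cell slab-intersection oracle on random anisotropic grids —
is asserted in the tests and re-measured by the acceptance script. The
classic integer Bresenham voxelization (`bresenham_voxels`, exactly
max(|Δi|, |Δj|, |Δk|) + 1 voxels) is provided for comparison only; it is
always a subset of the supercover set and almost always a strict subset.

One consequence of corner emission: the number of traversed voxels is not a
proxy for path length. Grazed voxels share a first-touch parameter, so
length bounds must count distinct crossing parameters (each axis crosses at
most once per spacing step), not voxels; the tests use
distance ≥ (g − 4) · min-spacing / 3 for g distinct parameters.

## Route search

`search_routes` sweeps the (α, β) product grid (default 1° both axes; poles
evaluated once, so a 1° grid tries 179 × 360 + 2 = 64 442 directions). A
literal reading of the procedure as two great-circle fans (an in-plane sweep
plus one vertical fan) is available as `two_fan=True` for fidelity
comparison, but the full grid is the default: real candidate routes leave
both principal planes.

Walking outward from the target, TARGET and PUNCTURABLE voxels pass, the
first NON_PUNCTURABLE or INTERIOR_AIR voxel blocks the direction, and the
first EXTERIOR_AIR voxel closes a candidate: the entry voxel is the last
tissue voxel, the entry point its center, and the puncture distance the
Euclidean mm distance from the target center. Rays that leave the volume or
exhaust the maximum ray length (default: volume diagonal) are blocked.

Voxels first touched at the same ray parameter (shared corner/edge) are
decided as one atomic group with priority blocker > tissue > exterior air:
a corner graze of bone always blocks, and a corner graze of air cannot end
the route while tissue is still being crossed at that same point. Without
the group rule the outcome would depend on index orientation, breaking
rotation equivariance and the entry-adjacent-to-air invariant.

`brute_force_search` implements the iterative-extension strategy: per
direction the segment grows in increments of R (`extension_step_mm`,
default 5 mm) and after each extension the new portion is examined. Voxel
detection is by point sampling: the union of a uniform grid at half the
minimum spacing, every cell-boundary crossing parameter, and the chord
midpoints between consecutive crossings, with each sample mapped to every
voxel whose closed cell contains it. Uniform sampling alone provably misses
corner-clipped voxels (chord shorter than the step), which would create
sampler artifacts rather than genuine method differences; including the
boundary parameters makes the sampler exhaustive while remaining an
independent code path (global boundary enumeration vs incremental
stepping). The brute force is oracle-grade, not performance-grade — on a
48³ phantom at 5° it is roughly 5× slower than the sweep, and the gap grows
with volume size since it re-examines voxels across extensions.

Both searches are fully deterministic; the only randomness anywhere in the
package is phantom placement, driven by an explicit seed.

## Ranking

Clearance of a route is the minimum over its voxels of the Euclidean
distance (spacing-aware, center-to-center) to the nearest NON_PUNCTURABLE or
INTERIOR_AIR voxel, computed from one exact Euclidean distance transform of
the obstacle mask; an obstacle-free volume returns the volume diagonal as a
finite "unbounded" sentinel. Interior air counts as an obstacle: a needle
cannot traverse an airway, so proximity to one is a hazard.

Modes: *shortest* sorts ascending by distance; *safe* descending by
clearance; *optimal* ascends by w·distance-rank + (1−w)·clearance-rank with
w = 0.5 by default. The optimal mode is an explicit heuristic stand-in for
the physician's joint judgment of the two criteria — the weight is exposed
precisely because no principled value exists. All ties break by (distance,
α, β) for determinism. Sector partitioning buckets candidates by azimuth
(default 30° sectors, best route per sector), giving spatially diverse
suggestions; only β is sectored because elevation diversity is rarely the
presentation concern, though solid-angle sectoring would be a reasonable
alternative.

## Synthetic phantom

The generator emulates the features the search depends on: an exterior-air
background (−1000 HU), a soft-tissue body ellipsoid (20 HU, puncturable), an
optional fat skin shell (−75 HU), organ blobs in 30–60 HU, enclosed airway
blobs (−1000 HU, interior air after the split), and bone shells, rods, or
blobs above 100 HU. Spherical shells can be pierced by conical holes, which
gives phantoms with analytically known candidate cones. Painting order is
background → body → skin → organs → airways → bone, later shapes overwriting
earlier ones; specs validate that every shape's HU lies in its declared band
and that the target is strictly inside the body.

What the phantom does **not** emulate: CT noise and partial-volume effects,
anatomically shaped organs, HU non-uniformity of diseased tissue, contrast
phases, or gantry tilt. Passing tests therefore demonstrate the geometry and
the search logic, not robustness to the intensity ambiguities of clinical
CT, where organ HU can overlap puncturable bands.

Problem sizes in the test suite and acceptance script — 32³–48³ phantoms,
5°–15° angular grids, 500–1000 random segments, three to five random
phantoms per property — were chosen so the full verification cycle runs in
about a minute while every property is exercised at meaningful resolution;
results at these sizes are not resolution-limited for the properties tested
(set equalities, exact distances, status agreement).

## Known limitations

* Thresholding is the only segmentation; boundary-HU tissue is classified
  conservatively but diseased-organ non-uniformity can still mislabel.
* Entry points are voxel centers; sub-voxel skin localisation is not
  attempted.
* The optimal mode's rank combination is a configurable heuristic, not a
  clinically validated score.
* Patient-specific constraints (needle length, approach windows, physician
  preference) are not modeled.
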