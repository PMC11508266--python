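# punctureplan

Three-dimensional puncture-route search for CT-guided percutaneous
interventions.

In CT-guided percutaneous puncture a physician inserts a needle from the skin
toward a target (a lung, liver, or renal lesion, an abscess) while checking CT
images. Planned on single 2-D slices, candidate routes stay confined to one
cross-section; `punctureplan` searches the full 3-D volume built from the
slice stack, casting rays outward from the target in every direction and
reporting which straight needle paths reach the skin without crossing tissue a
needle must not traverse.

It is a research/teaching tool for medical-image analysis: it operates on HU
thresholds only, models no needle deflection or tissue deformation, and is not
a medical device.

## Method

1. **Classification.** Each voxel of the CT volume is labeled by its
   Hounsfield value: HU < −900 is air, split by 6-connectivity into exterior
   air (reachable from the volume boundary — outside the body) and interior
   air (enclosed airway/gut gas, not puncturable); HU in [30, 60] is the
   organ/vessel band and HU > 100 the bone side, both non-puncturable;
   HU in [−900, 30) ∪ (60, 100] is puncturable tissue.
2. **Ray sweep.** Directions are parameterized by elevation α ∈ [−π/2, π/2]
   and azimuth β ∈ [0, 2π), u = (cos α cos β, cos α sin β, sin α), on a
   configurable grid (default 1°; the two poles evaluated once). Each ray is
   traced from the target with a *supercover* traversal — every voxel whose
   closed cell the segment intersects, in first-touch order, including
   corner/edge grazes — so no voxel a needle could graze is skipped. The
   first non-puncturable voxel blocks the direction; reaching exterior air
   yields a candidate route whose skin-entry voxel is the last tissue voxel,
   with puncture distance ‖entry − target‖ in mm.
3. **Ranking.** Candidates are ordered by puncture distance (*shortest*), by
   clearance — the minimum Euclidean distance from any route voxel to the
   nearest non-puncturable voxel, from one exact distance transform —
   (*safe*), or by a weighted combination of the two rank positions
   (*optimal*). Routes can be thinned to the best few per azimuthal sector
   for spatially diverse suggestions.
4. **Verification oracle.** A brute-force search grows each trial segment
   outward in fixed increments and re-examines every voxel the segment
   touches via dense point sampling. It finds the same candidate set as the
   sweep and exists to check it (and to make the cost difference
   measurable). A classic integer Bresenham voxelization is included to
   demonstrate why approximate line drawing is unsafe here: it provably
   misses voxels the segment passes through.
5. **Export.** Ranked routes are written as CSV/JSON and as 3D Slicer
   markups (`.mrk.json`, one Line per route plus a Fiducial of entry
   points), with volume-local mm coordinates converted LPS → RAS.

Because no patient volumes ship with the package, a parametric phantom
generator provides test volumes: an air background, a soft-tissue body
ellipsoid with an optional fat skin shell, organ blobs (HU 30–60), enclosed
airways (HU < −900), and bone shells/rods (HU > 100), all painted
deterministically from a seedable spec.

## Worked example

```sh
punctureplan phantom --out phantom.nii.gz --shape 64,64,64 --spacing 1,1,1 --seed 0
punctureplan plan --input phantom.nii.gz --target 30,32,32 \
    --alpha-step 3 --beta-step 3 --mode shortest --out-dir plan
```

The `plan` command prints a run summary (abridged):

```json
{
  "n_directions_proposed": 7082,
  "n_candidates_proposed": 5955,
  "n_ranked": 5955,
  "best_distance_mm": 24.2899,
  "best_clearance_mm": 1.0,
  "best_entry_voxel": [17, 46, 47]
}
```

7082 directions were swept (a 3° grid: 59 × 120 off-pole pairs plus the two
poles); 5955 reached exterior air without touching bone, the organ blob, or
the enclosed airway. The best route enters the skin at voxel (17, 46, 47),
24.29 mm from the target, and never comes closer than 1.0 mm to a
non-puncturable voxel. `plan/ranked_routes.csv` lists every candidate:

```
alpha_deg,beta_deg,status,entry_i,entry_j,entry_k,entry_x_mm,entry_y_mm,entry_z_mm,distance_mm,clearance_mm
39.000000,135.000000,candidate,17,46,47,17.500000,46.500000,47.500000,24.289916,1.000000
```

and `plan/markups/route_01.mrk.json` … hold the top routes for drag-and-drop
display in 3D Slicer. `punctureplan compare --input … --target …` runs the
sweep and the brute-force oracle side by side and reports per-direction
agreement; `punctureplan traverse` prints the voxels a single ray touches.

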