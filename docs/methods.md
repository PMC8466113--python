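# Methods

## Problem and pipeline

Transcranial direct current stimulation (tDCS) injects a weak current
(1–3 mA) through scalp electrodes.  How much of it reaches the intended
brain region — and how much leaks into others — varies strongly between
individuals.  `focaldose` post-processes a voxel-wise current-density
field J (mA/m²), produced for one montage and one injected dose I (mA)
by an external FEM simulator or by the built-in spherical phantom, into
regional dosimetry:

1. **Registration.**  The subject's native space is mapped to the atlas
   reference space through three anatomical landmarks (anterior
   commissure, posterior commissure, mid-sagittal point).
2. **Labelling.**  Each in-head voxel centre is transformed and assigned
   the atlas parcel label at its nearest reference voxel.
3. **Regional statistics.**  For each region r, the arithmetic mean
   ρ_r = mean over assigned voxels of |J| — the *average magnitude* of
   the current density — plus the voxel count.
4. **Focality.**  The dose–target determination index

       DTDI = ρ_target / max_r ρ_r

   with the maximum taken over *all* regions including the target, so
   DTDI ∈ [0, 1] and DTDI = 1 exactly when the target is (one of) the
   peak region(s).
5. **Titration.**  DTDI is computed per candidate dose; the profile is
   classified (constant / increasing / decreasing / mixed) and the dose
   with the highest DTDI is recommended, ties broken toward the lowest
   dose (minimum injected current for equal focality).

The reverse-dose rule, valid under the linear dose–field relationship,
scales a reference dose to reach a desired target density:
`dose = (desired / actual) × reference`; results above a safety cap
(default 4 mA, the upper end of currents participants tolerate) are
clipped and flagged.

## Landmark registration

Three point pairs identify at most a 7-parameter similarity transform
(proper rotation, isotropic scale, translation) — shear is
unidentifiable and reflections are anatomically inadmissible — so the
transform class is fixed to similarity and fitted with Umeyama's
closed-form least-squares construction.  The landmark residual RMS is
part of the fit result; pipelines should treat a residual of more than a
few millimetres as a landmarking error.

One subtlety: because any three points are coplanar, a mirrored landmark
triple is *exactly* reproducible by a proper rotation (flip the plane),
so clean mirrored input never needs the reflection correction.  The
correction applies when the SVD optimum of the rank-2 cross-covariance
is improper (generic noisy input); it is then replaced by the nearest
proper rotation and flagged.

Atlas labels are categorical, so assignment is nearest-neighbour only.
Voxels mapping outside the parcellation or onto background are reported
as unassigned and excluded from every regional average; more than 50 %
unassigned triggers a warning.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `epsilon` | 0.05 | – | DTDI swing classified as "no change" across doses |
| `threshold` | 0.75 | – | DTDI screening level for dose recommendations |
| `cap` | 4.0 | mA | safety clip on reverse-calculated doses |
| `min_voxels` | 1 | voxels | smallest region kept in statistics (raise to suppress spurious single-voxel peaks) |
| `fraction` | 0.1 | – | hotspot table size: top `ceil(fraction × n_regions)` regions, ties at the cut included |

`epsilon` is a pragmatic tolerance: dose–response profiles are called
constant when the total DTDI excursion stays within it.  It is
configurable because the sensible value scales with the simulator's own
reproducibility.

## The spherical phantom

The synthetic generator replaces FEM simulation with the exact field of
a point-source electrode pair in an infinite homogeneous medium, masked
to a sphere (default radius 80 mm, 4 mm isotropic grid, grey-matter
conductivity 0.276 S/m):

    J(r) = (I / 4π) · [ (r − r₊)/|r − r₊|³ − (r − r₋)/|r − r₋|³ ]

with distances in metres and I in mA, giving J in mA/m².  The matching
scalar potential V(r) = (I/4πσ)[1/|r−r₊| − 1/|r−r₋|] provides an
independent finite-difference oracle (J = −σ∇V).  Properties the
pipeline tests lean on:

- **exact linearity in I** — regional means scale with dose, so DTDI is
  dose-invariant: the "linear" archetype's ground truth;
- **antisymmetry** under electrode swap (magnitudes unchanged);
- a **closed form** at the electrode midpoint, |J| = I/(2πd²) for
  electrodes 2d apart.

Voxels within one voxel spacing of an electrode are masked out (the
point-source field diverges there).  Electrodes default to unit
directions 60° apart in the x–z plane near the top of the sphere; the
geometry keeps the target parcel (under the surface point midway between
the electrodes) well separated from the near-electrode peak parcels
while still receiving enough current for archetype-induced DTDI swings
to clear `epsilon`.

The parcellation partitions in-sphere voxels into 116 parcels (mirroring
a whole-brain anatomical atlas) by farthest-point seeding plus
nearest-seed assignment — deterministic given the seed.

**What the phantom does not emulate.**  The infinite-medium field
violates the no-flux scalp boundary condition; there are no skull/CSF
compartments, no conductivity contrasts, no realistic anatomy, and the
native/reference discrepancy is a pure similarity warp with exactly
corresponding landmarks.  Passing tests therefore certify the
*post-processing* — registration, labelling, averaging, index
arithmetic, titration logic — not the accuracy of any head model.  Real
analyses still require an FEM field and a licensed atlas.

## Dose–response archetypes

Three archetypes emulate the qualitative individual profiles seen in
practice, by perturbing the otherwise-linear phantom fields:

- `linear` — untouched; DTDI constant across doses.
- `target_gain` — target-region voxels × (1 + β·(dose − d₀)), defaults
  β = 0.3 /mA, d₀ = 1 mA; the target catches up with the peak, DTDI
  rises.
- `hotspot_emerge` — a designated non-target region × (1 + γ·max(0,
  dose − d_thr)), defaults γ = 1 /mA, d_thr = 1 mA; silent at 1 mA, the
  region surges at 2–3 mA, steals the regional peak and DTDI falls.

The designated hotspot is the non-target parcel with the highest
baseline regional mean (a near-electrode parcel).  Designating a
low-current parcel instead can fail to move the peak at all; seeding the
surge where current already concentrates guarantees the denominator of
the DTDI grows with dose and matches the observed phenomenology of an
already-strong region overtaking the target.  β and γ are sized so the
induced DTDI swings (≈ 0.15–0.4 at default geometry) are comparable to
the between-dose differences reported for real subjects, without
matching any particular individual.

Subject generation draws a random similarity warp (rotation ≤ 10°,
scale 0.9–1.1, translation ≤ 10 mm) for the native space, applies it to
the reference landmarks and to the field affine, and keeps the
ground-truth transform for parameter-recovery tests.  Everything is
reproducible from one integer seed.

## Numerical choices

- Voxel indices are 0-based; affines map voxel → world mm (RAS+), the
  NIfTI convention.
- Coordinate-table rows snap to the nearest voxel centre with
  round-half-away-from-zero (symmetric, unlike banker's rounding); rows
  sharing a voxel are averaged.
- NIfTI input masking: voxels that are non-finite *or exactly zero* are
  outside the head (FEM exports zero-fill the exterior).
- Regional means use `numpy.bincount` accumulation, which matches a
  sequential per-voxel sum bit for bit (verified against an independent
  brute-force oracle).
- Peak ties are reported together, sorted lexicographically; the DTDI
  value is unaffected.  Hotspot-table ties at the cut are included, so
  the table can exceed its nominal size.
- Dose-recommendation ties go to the lowest dose.
- CSV round-trips use 17-significant-digit output and round-trip float
  parsing, so written values re-read exactly.

## Validation problem sizes

The test suite exercises the default phantom (41³ grid, 116 parcels) for
the dose-invariance and archetype-recovery checks (30-subject cohort, 10
per archetype, one fixed master seed), a 2 mm grid for the
finite-difference field oracle (2 % tolerance ≥ 15 mm from the
electrodes, where the central-difference truncation error h²/r² is
comfortably below 1 %), and coarser 30–40 mm spheres for unit tests.
Randomized DTDI bound checks run ≥ 1000 tables/fields per session.

## Known limitations

- The phantom's absolute densities are not physiological (no bounded
  conductor, singular sources); only ratios and scalings are meaningful.
- Landmark-based similarity registration cannot correct nonlinear
  anatomical differences; for real data it is a coarse stand-in for
  SPM-style normalization.
- All labelled regions compete in the peak search; there is no option to
  exclude subcortical or cerebellar parcels.
- Group statistics (mixed ANOVA etc.) are out of scope: export the
  per-subject DTDI tables and use a statistics package.
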