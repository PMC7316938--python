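# Methods

## Deviation geometry

A pose is (shoulder, apex) in millimetres in a right-handed frame; the
unit axis is always oriented shoulder→apex. All four metrics are pure
functions of the two poses and are rigid-motion invariant, so post-op
data must be registered into the planning frame *before* measurement
(the pipeline order is: fit analogue poses on the post-op data, align
datasets, then measure).

- Angular deviation uses atan2(‖u×v‖, u·v): near-parallel axes are the
  clinically relevant regime and arccos of a dot product loses half the
  significant digits there. The angle is reported in [0, 180°) and not
  folded into [0, 90°]; a value above 90° means the placed axis points
  against the planned one and raises a warning rather than being
  silently reflected — folding would make a grossly misplaced implant
  look accurate.
- Point C is the line–plane intersection of the placed axis with the
  planned shoulder plane. When the placed axis lies within 1e-6 of that
  plane the intersection is unbounded, so the lateral metric is
  reported as explicitly missing (the record keeps the other three
  metrics). A projection shortcut is deliberately *not* used: when the
  axes diverge, ‖A−C‖ genuinely exceeds the perpendicular component of
  B−A, and the tests validate against a root-finding line–plane oracle,
  not the projection.
- Depth is the signed axial component (B−A)·u, positive apical.
  Printed tables carry the magnitude only, matching field convention;
  the sign is retained in the record because depth control is the
  unguided step in a semi-guided protocol and its direction matters for
  interpretation.
- Tolerances: 1e-6 for parallelism guards, 1e-9 for geometric
  identities — appropriate for double precision at millimetre scale.
- "Shoulder centre" is taken as supplied; platform geometry (bevels,
  switching) is not modelled.

## Registration

`closed_form_align` solves the correspondence-given problem by SVD of
the cross-covariance matrix with reflection correction (globally
optimal least squares). `iterative_surface_align` is trimmed ICP: exact
nearest neighbours (kd-tree; exactness keeps tests deterministic), keep
the (1−trim) closest pairs, closed-form update, stop when the trimmed
rmsd improves by less than `tol_mm` (default 1e-6) or `max_iter` is
reached. The trimmed rmsd sequence is non-increasing; non-convergence
is a flag, not an exception. `trim_fraction` defaults to 0.2 because
titanium implants scatter in CBCT and a fifth of segmented surface
points being junk is realistic; 0 disables trimming. ICP is a local
method: the intended use is refining the small residual misalignment
between two scans of the same anatomy, optionally after centroid
pre-alignment (`prealign=True`).

`fit_analogue_pose` estimates an implant pose from a roughly
cylindrical segmentation: PCA gives the initial axis (clouds with
principal-SD anisotropy below 1.5 are rejected as axis-free), then a
least-squares cylinder fit on the wall points (central 70% of the
axial extent) refines axis, centreline and radius — the PCA axis alone
carries a few tenths of a degree of sampling error at 2,000 points,
while the refined fit is exact on noiseless data. The shoulder plane is
located from the *cap disc*: within the coronal 10% slab of the axial
extent, points radially interior to 0.8× the fitted radius belong to
the flat shoulder face, and their mean axial coordinate is unbiased
under surface noise. (Averaging the whole slab would be biased ~0.4 mm
apical by the wall points that fall in it.) Axis polarity comes from
`apex_hint`; without a hint the fit is returned flagged
`orientation_ambiguous` instead of guessing.

## Agreement statistics

`describe` defaults to the population SD (divisor n): recomputing the
reference table's footer from its printed per-implant values gives 3.38
with divisor n versus 3.46 with n−1 against the printed 3.39, so the
population form is adopted and the sample form exposed as an option.
Report rounding (angular to 2 decimals, distances to 1) happens only in
the report writer; everything upstream is full precision.

The ICC is McGraw–Wong ICC(A,1): two-way decomposition into subject,
observer and residual mean squares,
ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)), with the
standard F-quantile confidence bounds using Satterthwaite degrees of
freedom. The "two-way mixed" versus "two-way random" distinction does
not change this absolute-agreement single-measures point estimate.
Degenerate inputs: identical columns with subject variance → exactly
1.0 (CI collapses to the point); zero total variance → error. Missing
subjects are dropped listwise before matrix construction, mirroring the
per-metric listwise policy of the cohort summary (an implant missing
only its lateral metric leaves the other three rows).

## Synthetic cohorts

The generator emulates the error anatomy of semi-guided surgery in an
atrophic maxilla, where the template braces against the nasal aperture:

| parameter | default | meaning |
|---|---|---|
| `n_patients` / `implants_per_patient` | 11 / 2 | study-sized cohort (22–24 implants) |
| `arch_radius_mm` | 25 | schematic anterior arch |
| `fulcrum_offset_mm` | (0, 8, 18) | nasal-aperture fulcrum above/behind the arch centre |
| `sigma_seat_deg` | 1.0 | per-patient seating rotation SD about a random horizontal axis through the fulcrum |
| `sigma_seat_trans_mm` | 0.3 | per-component seating translation SD |
| `sigma_sleeve_deg` | 8.0 | per-implant drill tilt SD, uniform azimuth |
| `sigma_depth_mm` | 0.7 | unguided insertion-depth SD along the drilled axis |
| `sigma_observer_mm` / `sigma_observer_deg` | 0.1 / 0.5 | per-observer pose-reading noise |

Rotation and tilt magnitudes are half-normal, so a single active source
has mean deviation σ·√(2/π) — the closed form the calibration tests pin
at n = 10,000 within 3 standard errors. The defaults were chosen once
so the default cohort's summary means land in the broad brackets around
the reference footer (angular 4–11°, global 0.5–1.8 mm); this is a
smoke calibration, not a fit — the generator makes no claim to the
reference study's actual error decomposition, which is unpublished.
Draws are consumed in a fixed documented order (per patient: seating
angle, axis azimuth, translation; per implant: tilt angle, azimuth,
depth slide), making cohorts bit-reproducible from the seed.

`lever_arm_check` isolates the seating rotation: mean lateral deviation
at distance d from the fulcrum is ≈ d·E|θ| at small angles (within 5%
for σ ≤ 2°) and doubles with distance — the quantitative version of the
argument for bracing the template close to the implants.

What the simulator does **not** emulate: anatomy (the arch is a
circular arc), bone-density effects on drilling, template undercut /
misfit events (categorical, like the reference cohort's excluded
implant), segmentation error structure beyond isotropic surface noise
plus uniform scatter. Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery*, not clinical
accuracy claims.

## Fixtures and problem sizes

The packaged per-implant table stores printed 1-decimal deviations
only — no coordinates exist for the reference cohort — so it exercises
the statistics and report paths; geometry and registration are
exercised by simulation. (The reference study's running text gives the
depth mean as 0.7 ± 0.4 mm while its own table footer computes to
0.600; the package follows the table.) The raw two-observer
measurements behind the reference ICC of 0.84 are likewise unpublished,
so the tests validate the ICC machinery against a from-definitions
ANOVA oracle and an independent library implementation instead of
reproducing that coefficient.

Test and acceptance problem sizes — 1,000 random pose pairs for the
geometry oracle sweep, 10,000 implants for half-normal calibration,
1,500–2,000-point clouds for registration and pose fitting — were
chosen so Monte-Carlo error is far below the tolerances being asserted
while the whole suite stays interactive (~30 s).

## Known limitations

- ICP offers no global-convergence guarantee; gross initial
  misalignment needs `prealign` or a better `init`.
- The analogue fitter assumes a capped-cylinder geometry; heavily
  incomplete segmentations (missing shoulder cap) degrade the shoulder
  estimate to the slab fallback.
- The confidence interval for ICC(A,1) is the standard asymptotic
  F construction; at n = 5 subjects it is wide and only approximate.
- Mesio-distal / bucco-lingual decomposition of the lateral deviation
  is intentionally out of scope: it requires anatomical plane
  definitions that reintroduce human interpretation.
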