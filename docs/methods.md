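# Methods

## Scope and design

`qasense` studies the *intrinsic* sensitivity of two QA detector archetypes —
a sparse cylindrical diode array and a dense flat-panel imager — to
controlled VMAT delivery errors.  Intrinsic means measured-vs-measured: every
error variant is gamma-compared against the baseline measurement of the same
detector, so treatment-planning dose calculation, detector calibration
chains, and prediction models drop out of the comparison by construction.
Everything those components would contribute is explicitly out of scope; the
pipeline's purpose is to expose what spatial sampling, export interpolation,
gamma-criteria choice and resolution conversion do on their own.

## The delivery model

A synthetic patient is a two-arc plan for a 40-leaf-pair MLC with 5 mm
projected leaf width (200 mm of leaf-bank coverage).  Each arc holds
`n_control_points` control points (default 24), each with:

* leaf positions tracking the elliptical projection of a spherical-ish target
  (diameter 20–60 mm, default 35 mm — a typical peripheral lung SBRT PTV),
  modulated by a seeded smooth perturbation field bounded by ±3 mm per leaf
  (a mild modulation level; SBRT apertures are close to conformal);
* a non-zero collimator angle drawn once per arc from ±[10°, 45°], as
  SBRT-VMAT plans are typically delivered with rotated collimators;
* a positive MU weight; weights are normalized to sum to one.

Leaf pairs outside the target rows are parked closed at the minimum gap
(0.5 mm) on the bank midline.

**Rendering.**  The delivered dose is approximated by a single planar
relative-dose surrogate.  Per control point, the aperture (a disjoint union
of axis-aligned rectangles, one per open leaf pair) is convolved analytically
with an isotropic Gaussian penumbra kernel — the convolution of a rectangle
with a Gaussian is a separable product of error-function differences — then
rotated by the control point's collimator angle about the isocenter
(bilinear), and accumulated with its MU weight.  Because the kernel is
isotropic, blurring before rotating is mathematically identical to the
rotate-then-blur order; doing the blur analytically removes rasterization
error entirely (the single-rectangle rendering matches the closed form to
machine precision).  The penumbra sigma default is 2.5 mm, giving an 80–20 %
penumbra of about 6 mm, a realistic figure for a 6 MV beam in low-density
surroundings.  Pairs at the minimum gap are treated as fully shielded by the
backup jaw and contribute nothing; a plan whose apertures are all closed
renders an all-zero matrix with a warning flag rather than an exception, so
cohort runs survive degenerate variants.

A plan that collapses both physical geometry (cylindrical phantom surface,
panel at extended SDD) onto one plane cannot reproduce absolute dose or
arc-angle-resolved effects.  It preserves exactly what the study design
needs: both "measurements" of a comparison see the same geometry, so the
studied effects (sampling density, DD vs DTA response, interpolation) act on
identical footing.

**Errors.**  Three error families, applied uniformly to every control point:

| type | meaning | units |
| --- | --- | --- |
| `COLLIMATOR` | additive collimator-angle offset | degrees |
| `MLCFS` | total field-width change; each bank moves half of it | mm |
| `MLCSHIFT` | both banks translated together | mm |

The `MLCFS` magnitude is interpreted as the *total* width change (each bank
m/2), keeping the nominal magnitude equal to the geometric size change; the
per-bank convention also circulates in the error-sensitivity literature.
Closing below the minimum gap clamps both leaves symmetrically at the pair
midpoint.

## The detector models

**Diode array.**  The helical diode cylinder is unwrapped to a plane: 21 rows
at 10 mm axial pitch (200 mm span) × 66 columns at 10 mm pitch along the
unwrapped circumference, odd rows offset by half a pitch as a helix
surrogate — 1386 diodes.  Readings are bilinear samples of the dose
surrogate; the vendor-style export interpolates the scattered readings
linearly (Delaunay) onto a 5 mm grid, with nearest-neighbour fill at the
convex-hull fringe.

**Flat panel.**  1024×1024 pixels of 0.4 mm (409.6 mm sensitive length per
axis).  Pixels inside a centered crop (default 120 mm, full panel available)
are sampled bilinearly and resampled to the 0.255 mm export grid.  Reported
resolutions of 0.255 mm and 0.244 mm both circulate for this imager class;
0.255 mm is adopted.

**Noise.**  Each sampled reading is scaled by `1 + ε`, ε ~ N(0, σ_rel),
default σ_rel = 0.1 %, independently per sample point and measurement, with
seeded streams.  This is the stand-in for measurement reproducibility and is
deliberately small: it is calibrated by the requirement that two independent
baseline measurements pass 1%/1mm global gamma at 100 %, the no-error
standard that defines error detection.  No spatial correlation, dead pixels,
angular response or field-size dependence is modelled.

## The gamma engine

Global gamma with DD% normalized to the *reference* (baseline) maximum,
10 % low-dose threshold applied to reference points only, inclusive pass
boundary (γ ≤ 1).  Comparisons are directional — variant evaluated against
baseline — and the engine makes no symmetry assumption.

Candidates for the DTA minimization are nodes of the evaluated grid,
optionally subdivided bilinearly to `interp_step` (default DTA/10).  The
candidate set is limited to nodes within `max_radius` of the reference point
(default: the DTA distance), with the nearest node always included so γ is
defined everywhere and the search never steps outside the evaluated extent.
An optional one-shot radius doubling (`expand_once`) helps isolated points
with no improving candidate.  Three properties drove these defaults:

* **Sparse-grid structural equality.**  With a DTA-limited candidate set, a
  5 mm evaluated grid has no off node within either 2 mm or 1 mm, so 2%/2mm
  and 2%/1mm give *identical* gamma maps — the characteristic sparse-array
  behaviour the study reproduces.  An uncapped search would break the GMV
  half of that identity for large errors (a matching dose 5 mm away scores
  γ = 2.5 at 2 mm DTA but 5.0 at 1 mm).
* **Criteria monotonicity.**  Candidate radii nest as DTA tightens, each
  candidate's γ is monotone in DD and DTA, and the study runner shares one
  interpolation step (tightest DTA/10) across all criteria of a comparison —
  together these make γ pointwise monotone under criteria tightening, with
  no exceptions.  Expansion is off by default in study runs because expanded
  radii can break the nesting.
* **Exactness.**  With `max_radius=inf` and interpolation off, the ring-walk
  search provably terminates only when no farther node can improve any
  point, and agrees with the exhaustive brute-force oracle
  (`gamma_brute_force`, capped at 64×64 grids) to 1e-12.  The analytic
  check: for a linear ramp of slope *a* shifted by *t*, interior gamma is
  |a·t| / √((DD·D_max/100)² + a²·DTA²), matched within 1 %.

Search mode per detector in study runs: node-only for the array's native
export (mirroring observed sparse-grid behaviour), interpolated for the
panel.  Degenerate inputs raise typed errors: a zero reference maximum
(undefined normalization), an empty assessed set, or an array sample point
outside the dose extent (reported with its coordinates).

## The study runner

For each patient: render the baseline, measure it twice with independent
noise (first = reference, second = the no-error self-comparison), then for
each roster variant render, measure once, and gamma against the reference
for every detector × criteria × resolution × mode cell.  Resolution "1mm"
resamples *both* matrices bilinearly (no anti-aliasing prefilter — the naive
conversion under study) before gamma.  Detection is strict: GPR below the
cell's no-error standard.  Seeding is hierarchical
(master → patient → measurement role) and recorded per record; reruns with
the same master seed are identical.  Failures abort only their cell,
emitting a failure row.

The default error grid is full-factorial (every patient × type × ±1/±2/±5).
The physical study's bookkeeping (15 baselines + 88 selected variants → 206
comparisons, 824 analyses at four criteria) is reproduced by an explicit
roster; the per-cell patient counts of the 88 are not recoverable from the
published aggregates (zero-SD rows pin several cells at n = 1), so the
remaining 80 are spread near-uniformly over the six multi-patient cells and
the counts are configurable.

Aggregation reports mean ± SD of GPR and GMV per cell (sample SD, with
single-patient cells reporting 0).  Composite-vs-individual-arc runs pair
per-arc records with composite records for the same plans and seeds and
report GPR deltas plus the fraction of cells where detection calls agree.

## What a green test establishes — and what it does not

The synthetic world reproduces *structural and directional* findings: the
100 % no-error standard, the sparse grid's DD-dominance and exact 2%/2mm ≡
2%/1mm behaviour, the panel's DTA sensitivity, monotone degradation with
error magnitude, and the opposite directions of the resampling effect
(upsampling the 5 mm array export inflates pass rates; downsampling the
panel export deflates them at tight DTA).  Magnitudes are *not* calibrated:
the planar surrogate, the simplified helix, the noise model and the absence
of detector physics mean absolute GPR values differ from physical
measurements — the array model here is notably more sensitive than a
physical array, and the panel's resampling deficit is weaker than measured,
because the synthetic dose fields are smoother than real imager signals.
Direction-of-effect tests therefore assert inequalities only.  Small
collimator errors are nearly invisible to both models: a rotation of a
near-elliptical target centered on the isocenter moves its boundary mostly
tangentially — consistent with the physical finding that ±1–2° collimator
errors go undetected, but our centered targets understate what asymmetric
anatomy would show at ±5°.

## Known limitations

* Planar 2D surrogate: no cylindrical geometry, no entry/exit summation, no
  gantry-angle-resolved scoring, no 3D dose or DVH metrics.
* No MLC transmission, tongue-and-groove, or rounded-leaf physics; closed
  pairs are perfectly shielded.
* Noise is uncorrelated and multiplicative only.
* Global-normalization gamma only; no local-dose normalization.
* The vendor export and search internals of commercial analysis software are
  unpublished; the linear scattered export and DTA-limited search are
  reasoned stand-ins, and the interpolation step/radius are configurable to
  probe that dependence.
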