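# Methods

This note documents the models, conventions, parameters and deliberate
design choices behind `protonqa`, and what the synthetic test conditions do
and do not demonstrate about clinical data.

## Coordinate and grid conventions

All geometry lives in the DICOM patient coordinate system (LPS), in mm,
with a voxel-center convention and 0-based indices. Arrays are C-ordered
`(nz, ny, nx)` so x varies fastest, matching the PVB1 raster order. Only
axis-aligned HFS acquisitions are supported; dose and LET grids are always
co-registered to the CT voxelization they were scored on (clinically
512 × 512 × N slices; fixtures use 48 × 80 × 24 at 3 mm). Oblique
orientations and inter-frame registration are out of scope.

## CT preprocessing

The planning CT is edited, in a fixed order, into the treatment-condition
CT:

1. **Outside-body air override.** Every voxel outside the body contour is
   set to −1000 HU. This removes the simulation couch, blankets and other
   external artifacts. Idempotent by construction.
2. **Treatment-couch burn-in.** A slab-stack couch model is placed below
   the posterior-most body surface. The default model — a 10 mm, 200 HU
   shell over a 50 mm, −700 HU foam core, 400 mm wide, offset 5 mm — is a
   configurable placeholder: couch composition is institution-specific and
   no canonical values exist, so the model is a named parameter rather
   than a constant. A couch that would intersect the body is a
   configuration error and raises; slabs falling outside the grid are
   skipped with a warning.
3. **Range-shifter board.** An on-couch board (slab perpendicular to the
   beam axis, default −100 HU) is burned in on the beam-entry side. A
   nozzle-mounted shifter is *not* burned into the CT; it is handled by
   the engine as an upstream water-equivalent offset, reflecting where the
   device physically sits.
4. **Structure HU overrides** (surgical clips, shifting devices) applied
   in list order, later overrides winning.

Every step appends a machine-readable provenance entry (rule, voxel count)
so the edit trail is auditable. The invariant enforced by tests: no voxel
inside the body changes except through a named override.

**HU → density.** Piecewise-linear, clamped at the endpoints. The default
5-point curve (air −1000/0.00121, lung −700/0.30, water 0/1.00, bone
1500/1.85, metal cap 3000/2.8 g/cm³) stands in for the scanner-specific
calibration a clinic would configure. The mock engine further approximates
relative stopping power by mass density; both are per-scanner
configurables, not physics claims.

## Batch model and the PVB1 format

A plan's histories per field (clinical default 2×10⁸) are split as evenly
as integers allow among n batches (default 50; the first `total mod n`
batches take one extra). Seeds are `base_seed + field·n + batch` —
deterministic and pairwise distinct. Fixtures default to 5 batches of
2×10⁴ histories to keep the suite fast; the split logic is identical at
both scales.

PVB1 is this package's own little-endian interchange format (magic,
dims, spacing, origin, histories, seed, field, batch; float32 dose then
LET rasters, x fastest). Real scorer outputs are converted by a
user-supplied reader hook. Round trips are bit-exact; truncation and
header/payload mismatches raise a corrupt-batch error naming the byte
offset.

## The mock engine

The built-in engine is an analytical pencil-beam stand-in whose purpose is
to make combination, calibration, gamma and orchestration exactly
testable. Per spot:

- **Range**: Bragg–Kleeman R = α·Eᵖ with α = 0.0022 cm/MeVᵖ, p = 1.77
  (R in water-equivalent depth; ~7.6 cm at 100 MeV).
- **Water-equivalent depth**: density integrated along the (cardinal)
  beam axis through the preprocessed CT; a nozzle-mounted shifter adds
  46 mm WET (40 mm × relative density 1.15, ABS-like).
- **Depth dose**: entrance plateau (0.30 of peak, rising 70% toward the
  peak) plus a Gaussian Bragg peak at R (σ = max(1.5 mm, 1.2% of R)),
  with a ~1 mm distal sigmoid cut.
- **Lateral profile**: Gaussian, σ(WET) = 3 mm + 0.02·WET.
- **LET_d(depth)**: sigmoid from 1.2 keV/µm at entrance to 12 keV/µm
  distally (midpoint 3 mm upstream of R, width 2.5 mm), monotone in depth
  and above 6 keV/µm around and beyond the peak — chosen so distal-edge
  LET_d sits in the clinically reported 10–15 keV/µm band and the
  6 keV/µm review threshold is meaningful.
- **Noise**: multiplicative Gaussian per voxel, relative σ =
  2/√histories, clipped to keep dose positive, seeded per batch. This
  reproduces the 1/√N uncertainty scaling of independent-history
  transport; it does *not* model correlated noise, nuclear halo, or
  multiple-Coulomb-scattering tails.

The noiseless core is deterministic and cached per (CT, field); a batch
run is core × seeded noise, so identical JobSpecs are bit-identical.
None of the parameterizations above are physics claims; each is a
documented config default (`MockEngineConfig`). The machine energy list
defaults to 96 nominal energies, 70–212.5 MeV in 1.5 MeV steps — the count
matches a clinical synchrotron energy ladder, the values are this
package's choice.

## Combination and calibration

Dose combines as the arithmetic voxel mean; LET_d as the dose-weighted
mean, zero where the summed dose is zero (the choice is invisible
downstream of the 10%-of-prescription mask). The printed equal-histories
mean is used whenever batch histories are equal; unequal batches (possible
via the integer split) fall back to a histories-weighted mean with a
logged warning, since the unweighted form is only unbiased for even
splits. Uncertainty is the across-batch SEM relative to mean dose; it
requires ≥ 2 batches.

Calibration tables (CSV: `energy_mev,dose_per_mu_gy,dose_per_particle_gy,
particles_per_mu`) are validated row-wise (ratio consistency, distinct
energies) and must cover every plan energy — checked at intake by the
integrity report, not at combine time. Absolute dose =
per-particle dose × Σ_spots MU·ppMU(E); the simulated-histories count
cancels in this per-particle formulation and is retained for provenance.
CSV round trips use round-trip float parsing, so a persisted table is
bit-identical.

## Gamma implementation

Global gamma normalizes the dose difference to a single reference dose
D_ref — by default the maximum of the *measured* plane (configurable to
the prescription); points below 10% of D_ref are excluded (both are
conventions the measurement-comparison literature leaves open; defaults are
exposed on `GammaCriteria`). The reference is the 2D measurement, the
evaluated distribution the 3D calculation, searched in 3D.

The production search (`gamma_map`) visits a cubic lattice of offsets
(step Δd/10, radius 3·Δd) in order of increasing distance, sampling the
evaluated dose by trilinear interpolation, and stops once the pure
distance term exceeds every point's current best γ² — an exact bound, so
early termination cannot change the result. The test oracle
(`brute_force_gamma`) scans every offset with no ordering or shortcuts;
on a shared lattice the two must agree exactly, and the acceptance suite
holds them to 0.02 γ-units on randomized fixtures. Candidates outside the
evaluated grid are excluded; a plane whose zero-offset sample already
falls outside raises rather than silently passing.

Sub-voxel step Δd/10 at 3 mm DTA means a worst-case discretization of
0.15 mm ≈ 0.05 γ-units in the distance term; the oracle-equivalence test
pins the implementation, while the flat-field (+3% scale ⇒ γ = 1.000) and
pure-shift (3 mm shift on a 10%/mm ramp ⇒ γ = 1.000) closed-form cases pin
the metric itself.

## Measurement-plane fixtures

Array-style measured planes are produced by trilinear extraction from a
noiseless reference calculation, optionally perturbed by a global scale or
lateral shift for negative controls. The CSV header carries `depth_mm` and
`spacing_mm` plus two fields this package adds so a plane is localizable in
3D: `origin_mm` (patient-space position of element [0,0]) and `axis` (the
plane normal). Because fixture planes derive from the same analytical
model, a 100% unperturbed pass rate demonstrates pipeline self-consistency
— not agreement with an ionization-chamber array, detector spatial
response, or setup error, none of which are modeled. The +1%/+5% global
perturbations bracket the 3% dose tolerance and verify the metric's
sensitivity direction on flat fields.

## Orchestration

The run state machine is RECEIVED → INTEGRITY_CHECKED → PREPROCESSED →
SIMULATING → COMBINING → EXPORTED, FAILED reachable from anywhere, with
one append-only log line per transition (`ISO8601|LEVEL|STATE|message`)
and the JobRecord persisted as JSON after every change. Re-invoking
`run_pipeline` on a run directory resumes: the preprocessed CT series and
PVB1 batch files are the durable intermediates, and a batch file is always
written *before* its completion is acknowledged, so a crash at any state
resumes to bit-identical outputs. Batch execution is an opaque
`BatchRunner`; the orchestrator polls statuses at a configurable interval
(default 600 s — tests use milliseconds) and a failed batch fails the run
naming the batch. Notification is a hook (default: structured log line);
hook exceptions are logged and never fatal — mail transport and job-ID
tracking against a real scheduler are integration concerns outside this
package.

The integrity check (CT present and contiguous within 0.01 mm slice
tolerance, body contour present and non-empty, ion spot plan present,
single frame of reference, calibration covering all plan energies) is a
reconstruction of what such a pre-flight must cover; it reports rather
than raises, and the orchestrator refuses to start on a failed report.

## DICOM choices

RT Dose is written as 32-bit unsigned integers with
`DoseGridScaling = max/(2³² − 1)`, bounding quantization at ~1.2×10⁻¹⁰ of
the grid maximum (the acceptance bound of 10⁻⁴ is generous). LET_d grids
are exported as RT-Dose-shaped objects labeled `LETD_KEV_UM` in
`DoseComment` — a pragmatic convention (no standard DICOM LET object
exists at this level) that lets a TPS display LET like a dose. Spot MU is
recovered from meterset weights × beam meterset / final cumulative weight.
Full IOD conformance, anonymization and DIMSE networking are non-goals;
written datasets contain what the package's own readers (and pydicom)
need.

## Problem sizes and numerical choices

Fixture problem sizes — 48 × 80 × 24 grid, 75 spots, 5 × 2×10⁴ histories,
6 × 6 to 20 × 20 measurement planes, 64 batches × 3 history levels for the
noise-slope fit, 0.5 mm oracle lattices on ≤ 25³ grids — were chosen so the
full suite exercises every code path at interactive speed while keeping
statistical tests well-powered (the noise-slope estimator's standard error
at these sizes is ≈ 0.03 against a ±0.05 acceptance band). Bit-exactness
claims (regrouping, noiseless combination vs a single run) are tested with
power-of-two batch counts, where pairwise summation makes the float mean
of identical addends exact; general regrouping is held to 10⁻¹⁰ relative.

## Known limitations

- The mock engine supports cardinal gantry angles and couch angle 0 only;
  spot positions map to the two axes perpendicular to the beam.
- Relative stopping power ≈ mass density; no nuclear interactions, MCS,
  or halo.
- Per-structure overlap volumes are voxel counts × voxel volume; no
  partial-volume correction or contour clipping.
- Gamma assumes both distributions share one frame of reference; no
  registration is performed.
- The uncertainty grid is exported as a NumPy array rather than DICOM
  (no standard target object).
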