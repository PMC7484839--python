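# protonqa

Automated plan-verification pipeline for spot-scanning (pencil-beam
scanning) proton therapy. `protonqa` re-creates, as a testable desk-scale
tool, the workflow a clinic uses to run an independent Monte-Carlo-style
secondary check of a treatment plan: it preprocesses the planning CT to
treatment conditions, splits transport into seeded parallel batches,
combines per-batch dose and dose-averaged LET grids, calibrates to absolute
dose, exports DICOM RT Dose, compares against measured planes with a 3D
gamma index, and reports high-LET regions for biological-robustness review.

It is written for medical physicists and research software engineers who
want the *post-processing and QA machinery* of such a system — the particle
transport itself is abstracted behind an engine interface with a built-in
analytical mock engine, so the entire pipeline runs and is tested without
any external Monte-Carlo code or patient data.

## The computations at the core

**Batch combination.** Transport is split into N parallel batches with
distinct seeds. Per voxel, with Dose_i and LET_i the i-th batch's dose and
dose-averaged LET:

    D̄     = (1/N) Σᵢ Doseᵢ
    LET̄_d = Σᵢ LETᵢ · Doseᵢ / Σᵢ Doseᵢ

Dose averages arithmetically; LET_d must be dose-weighted, which makes the
combination exactly invariant under regrouping batches. Statistical
uncertainty is the across-batch standard error of the mean, relative to the
mean dose (1σ).

**Absolute-dose calibration.** For each nominal beam energy, the ratio of a
measured single-spot dose per monitor unit (MU) to the simulated single-spot
dose per particle gives particles/MU. A field's per-particle dose grid is
scaled by Σ_spots MU·(particles/MU)(E) — exactly linear in plan MU.

**3D gamma index (global 3%/3 mm).** For each measured point m above a
low-dose cutoff,

    γ(m) = min over r_c of sqrt( ‖r_c − r_m‖²/Δd² + (D_c(r_c) − D_m)²/(ΔD·D_ref/100)² )

minimized over a sub-voxel 3D lattice in the calculated volume, with
trilinear dose interpolation. A point passes if γ ≤ 1; the clinical goal is
more than 95% of evaluated points passing.

**LET reporting.** LET_d maps are masked to in-field (dose > 10% of the
prescription) and the overlap of high dose (> 80% of prescription) with
high LET_d (> 6 keV/µm) is reported per structure in cm³ — the region a
planner inspects when a critical organ sits at a beam's end of range.

## Worked example

Everything below is synthetic — a cylindrical water phantom with bone/clip
inserts, a 3-layer × 25-spot plan normalized to a 2 Gy prescription, a
calibration table, and an array-style measured plane:

```bash
$ protonqa fixtures --out demo/inputs
ct: demo/inputs/ct
structures: demo/inputs/structures.dcm
plan: demo/inputs/plan.dcm
calibration: demo/inputs/calibration.csv
plane_d20: demo/inputs/plane_d20.csv

$ protonqa run --config demo/config.json
INFO protonqa.orchestrate: [RECEIVED] run created
INFO protonqa.orchestrate: [INTEGRITY_CHECKED] integrity check passed
INFO protonqa.orchestrate: [PREPROCESSED] 2 preprocessing rules applied
INFO protonqa.orchestrate: [SIMULATING] 5 batch jobs prepared
INFO protonqa.orchestrate: [SIMULATING] poll: {"PENDING": 0, "DONE": 5, "FAILED": 0}
INFO protonqa.orchestrate: [COMBINING] all batch jobs complete
INFO protonqa.orchestrate: [EXPORTED] outputs written: dose, LET, uncertainty, report
run run: EXPORTED

$ protonqa gamma --reference demo/inputs/plane_d20.csv \
                 --evaluated demo/run/output/dose.dcm --dd 3 --dta 3
pass rate: 100.0% (140 points evaluated)

$ protonqa report --dose demo/run/output/dose.dcm \
                  --let demo/run/output/let.dcm --rx 2.0
{
  "rx_dose_gy": 2.0,
  "dose_fraction": 0.8,
  "let_threshold_kev_um": 6.0,
  "overlap_volume_cm3": 1.512,
  ...
}
```

(`demo/config.json` holds the field list of
`protonqa.orchestrate.PipelineConfig`; see that docstring for the schema.)

Reading the output: the run exported an absolute dose grid with maximum
2.01 Gy against the 2 Gy prescription (the residual is the seeded batch
noise; the relative 1σ uncertainty at the maximum is 0.9%), the measured
plane at 2 cm depth passes the global 3%/3 mm gamma at 100% — comfortably
above the 95% action level — and 1.5 cm³ of the phantom sees both > 80% of
the prescription and LET_d above 6 keV/µm, the distal-edge region one would
review against critical structures.

## Scope

The transport engine included here is an analytical pencil-beam stand-in
(Bragg–Kleeman range, parameterized Bragg curve, depth-growing lateral
Gaussian, sigmoidal LET_d rise, seeded 1/√histories noise) — it exists to
make the surrounding pipeline exact and testable, not to model physics.
Production engines (e.g. a TOPAS/Geant4 wrapper) plug in through
`protonqa.engine.EngineInterface` and the PVB1 batch interchange format.
Beamline/nozzle modeling, phase-space generation, HPC schedulers, TPS
scripting integration and DICOM networking are out of scope. See
`docs/methods.md` for models, parameters, and limitations.
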