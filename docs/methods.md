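# Methods

`rtmc` is a desk-scale re-creation of a map/reduce Monte Carlo (MC)
verification workflow for radiotherapy treatments.  A treatment plan is
broken into independently calculable static beams, the beams are spread
over worker processes that each run an MC dose engine with private random
seeds, and the per-worker dose files are statistically merged, exported as
DICOM RTDOSE and evaluated with dose-volume histograms (DVH).  Cloud
worker VMs are replaced by local processes and the commercial linac MC
models by a bundled toy engine, so every stage of the pipeline — the
bookkeeping, the statistics and the file formats — is testable on one CPU
in minutes.

## Plan model and discretization

Plans are read from DICOM RTPLAN with pydicom.  Angles follow IEC 61217 as
stored in DICOM, normalized internally to [0, 360); positions are DICOM
patient (LPS) coordinates in millimetres.

The classification and discretization contract is built on control
points.  A *beam-on interval* is a maximal run of consecutive control
points joined by nonzero increments of the cumulative meterset weight:

* **Static** — every beam is a single 2-control-point segment at a fixed
  gantry angle; it maps to one static beam, geometry copied verbatim.
* **Step-and-shoot** — a beam holds several segments at a fixed gantry;
  each control-point pair with a nonzero weight increment is one
  deliverable segment and maps to one static beam.
* **mArc** — a rotational beam delivered in short *arclets*: the beam is
  on only while the gantry crosses an arclet (a few degrees wide), and off
  while the leaves travel to the next shape.  Each beam-on run is one
  arclet; it maps to a static beam at the arclet's *central* gantry angle
  (circular midpoint, so an arclet spanning 358° → 2° centres at 0°) with
  the monitor units (MU) delivered during the arclet.  The aperture of the
  arclet is the state at its first control point, held constant.

Segment MU is the DICOM semantics: beam meterset × increment of the
cumulative meterset weight.  To make MU conservation *bit-exact* rather
than merely approximate, the last segment of every beam absorbs the float
residual (`meterset − Σ earlier segment MUs`), and the plan's `total_mu`
is defined as the exact float sum over this same decomposition.  The sum
of discretized beam MUs therefore equals `total_mu` to the last bit, which
the tests assert with `==`, not with a tolerance.  Continuously modulated
deliveries (VMAT-style MLC motion while the beam is on, spanning ≥ 360°
runs) are rejected with an explicit unsupported-technique error rather
than silently approximated.

## CT to voxel phantom

CT slices are sorted by the z component of ImagePositionPatient; stored
values are mapped to Hounsfield units (HU) through RescaleSlope/Intercept.
Slice gaps must be uniform to 1%.  All volume arrays are indexed
`[ix, iy, iz]` and flattened x-fastest (Fortran order) — the same
convention the phantom and dose file formats use.

Resampling builds, per axis, a row-normalized fractional-overlap matrix
between old and new voxel edges.  Downsampling is then a volume-weighted
HU mean and upsampling degenerates to replication of the containing voxel;
requesting the identical spacing returns a bit-identical copy.  HU is
averaged *before* the conversion table is applied (resample-then-convert);
total phantom mass is conserved to well under 0.5% on smooth volumes, the
residual coming from the nonlinearity of the density ramp.

The HU conversion table carries contiguous material bins and strictly
increasing density breakpoints; density is piecewise-linear in HU and
clamps at the outermost breakpoints, while an HU outside every material
bin is a hard error that reports the value.  A four-material default
(air / lung / soft tissue / bone, bilinear density ramp) ships in
`ct_phantom.DEFAULT_TABLE`; users supply their own as YAML.

Two phantom file formats are written and read back:

* **egsphant** — the standard EGS text layout (material count and names, a
  dummy ESTEPE line, voxel counts, boundary arrays in cm, per-slice
  single-character material maps, per-slice density blocks).  Material
  codes are digits 1–9, letters, then the remaining printable ASCII — 94
  codes; more materials raise a capacity error.  Densities are printed
  with 8 significant digits so a write→read round trip is exact for
  materials and ≤ 1e-6 relative for density, and re-writing a read phantom
  is byte-identical.
* **PenVox dialect** — since the PenVox layout is not publicly specified,
  the package defines its own documented dialect: a `# PenVox` marker
  line; `nx ny nz`; `dx dy dz` (cm); `ox oy oz` (voxel-centre origin, cm);
  the material count and an `index name` table; then one
  `material density` record per voxel, x-fastest.  The same round-trip
  guarantees as egsphant apply.

## Work distribution (map)

Beams are distributed over `n_nodes` computing nodes in one of two modes:
**Equal** (every beam the same number of nodes, remainder to the earliest
beams) or **MUWeighted** (nodes proportional to each beam's share of the
plan MU).  MUWeighted uses Hamilton largest-remainder apportionment with a
floor of one node per beam: integer parts of the quotas
`n_nodes · MU_b / ΣMU` first, leftovers to the largest fractional
remainders (ties to the lowest index), then beams still below the floor
are topped up one node at a time from the beam with the largest surplus
over its own quota.  Node sums are conserved exactly and every beam gets
at least one node; when no beam is forced to the floor every beam is
within one node of its quota (the classic Hamilton property), and each
floored beam can push a donor at most one further node from quota.

The history budget follows the same weights (per-beam totals by
largest-remainder with a floor of one history per node, even split within
a beam, remainder on the beam's first node), so `Σ histories` is exact.

Seeds are counter-based: candidate values are SHA-256 of
`(master_seed, counter)` reduced to 31 bits, skipping duplicates, so every
simulation gets pairwise-distinct positive seed pairs as a pure function
of the master seed.

Template binding writes one concrete input directory per work item.  A
parameter descriptor names a file, a printf-style format and either a
(line, token) locator (1-based; MLC bank vectors replace the token through
the end of the line) or a literal placeholder string.  All locators are
resolved and all values formatted *before* any file is written, so a
broken template leaves no partial output; a formatted value wider than an
explicit format width is an error rather than a silently widened field.

## Execution (local map phase)

Work items run as subprocesses in their bound directories under a thread
pool (`max_parallel` at a time), standing in for cloud worker nodes.  The
simulation advances through INACTIVE → DOWNLOADING_FILES → SIMULATING →
UPLOADING_RESULTS → FINISHED; outputs matching the model's declared
patterns are staged into per-node result directories as each worker
finishes, and state transitions plus per-worker wall times are appended to
a JSONL log.  Any nonzero worker exit marks the simulation failed with the
offending node ids; FINISHED is reserved for fully collected runs, partial
outputs are kept for diagnosis, and there is no retry policy (fail fast).
Because workers are bound to disjoint directories and merging is
permutation-invariant, results are independent of `max_parallel`, and with
fixed seeds they are bit-identical across re-runs.

## Statistical reduction

A worker's binary dose file is an opaque header (copied verbatim from the
first input into the merged output, never modified), the dose array, then
the absolute 1σ uncertainty array, little-endian, single or double
precision.  Runs with history counts `h_i` combine with weights
`w_i = h_i/Σh`:

    dose  = Σ w_i d_i ,      sigma = sqrt( Σ w_i² s_i² )

which is the exact pooled estimate when each run reports a per-history
mean and the standard error of that mean: the merged dose equals the plain
mean over the pooled histories, and the merged sigma equals the
independent-estimate propagation of the per-run standard errors.  The same
formulas merge column-format text tallies (key columns must match exactly
and are copied through).  Merging is permutation-invariant and associative
up to float rounding.

Phase spaces use a simplified IAEA-style two-file dialect — a text header
(`.header`: original-history count, particle count, field list) beside
packed little-endian float32 records (`.phsp`: type, energy, position,
direction cosines, weight).  Merging concatenates records and sums the
original-history counters; mismatched record layouts are rejected.  Real
IAEA files carry extra long variables; adapting the reader is an extension
point, not a goal.

Stored uncertainty is always absolute 1σ; the coverage factor k enters
only at reporting time.  The region uncertainty metric — the number quoted
for a target volume — is the mean of `100·k·σ/D` over the masked voxels
receiving more than half the maximum dose inside the mask, the usual
convention for quoting MC dose uncertainty in a PTV.

## Toy MC engine

The bundled engine honours the same parametrized-model contract as a real
MC back-end — two text input files (`engine.in`: histories, time limit,
two seeds; `beam.in`: gantry/collimator/table, isocenter, jaws, MLC banks,
source-axis distance, phantom and output paths) — and emits
reducer-compatible outputs.  Its physics is deliberately non-physical but
statistically honest: single effective mass attenuation coefficient
(default 0.049 cm²/g, the order of a 6 MV beam in water), no scatter, no
secondary transport.  Each history is one ray from a point source at
source-axis distance SAD aimed at a point sampled uniformly over the
*open* aperture (jaw rectangle ∩ MLC opening, leaf rows picked with
probability proportional to their open area; a fully closed aperture
yields a warning and an all-zero dose).  Rays are walked through the
density grid with an exact 3-D DDA (Amanatides–Woo) traversal; the energy
deposited in a voxel is the attenuated-fraction difference
`E0·(e^{−μR_in} − e^{−μR_out})` across it, with R the radiological depth
in g/cm², so total deposited energy can never exceed `histories × E0`.
Dose is deposit/voxel-mass per history; the per-voxel uncertainty is the
history-by-history estimator `s² = (Σd² − (Σd)²/n)/(n(n−1))`.

The RNG is a counter-based splitmix64 keyed by the two input seeds, so a
run is a pure function of its inputs and bit-reproducible across
platforms; no RNG state is carried between histories.  Two validation
modes exist: a closed-form expectation for homogeneous phantoms and
near-parallel beams (`analytic_depth_dose`, exponential depth dose divided
by the open aperture area), and a per-history deposit *ledger*
(`LEDGER 1`) that dumps every history's per-voxel dose so the whole
file-write→read→merge chain can be checked against statistics computed
directly from raw deposits.

TIME_LIMIT is accepted in templates and bound, but execution is driven by
histories only; wall-time-driven termination would break bit-level
reproducibility and is out of scope.

## Dose export and DVH

Merged dose is exported as DICOM RTDOSE: 32-bit unsigned pixels with
`DoseGridScaling = max(dose)/(2³²−1)` (a configurable positive floor when
the grid is all zero), GridFrameOffsetVector from the z spacing, geometry
tags consistent with the reference CT.  A write→read round trip errs by at
most one quantization step per voxel, far below MC noise — the reason for
choosing 32-bit over 16-bit pixels.  Absolute calibration (per-history
dose to Gy) is a single multiplicative constant supplied by the caller.

Structures from RTSTRUCT are rasterized per slice by the even–odd (parity)
rule at voxel centres: each contour is assigned to the nearest dose slice
within half a slice spacing, and a voxel centre is inside if an odd number
of that slice's contours contain it, so nested contours subtract (holes).
There is no partial-volume weighting — voxel-centre membership is
deterministic and oracle-checkable; partial volume is a noted extension.

The cumulative DVH uses fixed-width bins (default 0.01 Gy) and uniform
voxel volume: `V(d)` is the percentage of masked voxels with dose ≥ d, so
the curve starts at 100%, is non-increasing and reaches 0 above the
maximum dose.  Metrics: Dmax is the highest bin edge still covered; D95 is
the highest dose with `V ≥ 95%`; Dmean comes from the differential of the
curve (and therefore agrees with the plain voxel mean to within half a
bin); `V_x` is linearly interpolated, with out-of-range queries clamped
and flagged.

## Synthetic fixtures

The fixture module generates complete DICOM inputs deterministically from
a seed (UIDs included, so regeneration is byte-identical): a CT series of
a water cylinder in air (optional bone rod; HU exact by construction), an
RTPLAN for each of three treatment archetypes, and an RTSTRUCT with a
cylindrical PTV of known analytic volume.  The three archetypes mirror the
classic verification triplet — a rotational-arclet head-and-neck delivery
(45 arclets, 4° wide, every 8° around a full circle), a step-and-shoot
prostate plan (25 segments over 7 gantry incidences) and a 9-beam static
SBRT lung plan.  Default grid 32×32×16 at 4×4×5 mm (≤ 64³ by
construction): anatomy is geometric, not anthropomorphic, because the
pipeline's guarantees are statistical and bookkeeping ones, not dosimetric
accuracy on realistic tissue.

Per-segment weights and apertures are drawn from seeded generators with
plausible clinical ranges (segment weights within a 3:1 ratio, beam
metersets of tens to hundreds of MU, central leaves open 10–35 mm with
parked edge leaves).

## What the tests do and do not show

The synthetic data exercises every interface of a real verification —
DICOM parsing, discretization, voxelization, distribution, reduction,
export, DVH — and the statistical properties that any correct MC pipeline
must have (exact MU/history conservation, 1/√N uncertainty scaling, split
invariance of the merged estimate, unbiased error propagation).  Passing
them says nothing about dosimetric realism: there is no scatter, no
heterogeneity correction worth the name, no penumbra model and no linac
head; real-engine integration would replace only the toy model directory
and manifest, which is the point of the parametrized-model contract.

## Problem sizes and numerical choices

Statistical checks run at desk scale, chosen so the whole suite completes
in a couple of minutes on one CPU while keeping every estimator deep in
its asymptotic regime: 16³ water phantom with 10 mm voxels; 4 × 2 500
histories for the reduce-oracle identity; 6 000 vs 24 000 histories over 5
seeds for the scaling law; 48 000 histories (1 × N vs 8 × N/8) for split
invariance, with z-scores taken on one depth slice of a broad beam because
a history deposits along its entire depth column and in-column voxels
share the same fluctuation; 100 random plans per technique for MU
conservation; 100 000 histories over 45 workers for the end-to-end
rotational case, which lands the PTV 2σ region uncertainty around 7–8%.
Ties and degenerate inputs are decided, not left to chance: remainder ties
go to the lowest index, zero-MU vectors fall back to equal weights, empty
masks and all-zero dose regions raise rather than return NaN, and the
identity resample/merge paths return bit-identical data.

## Known limitations

* No continuous-MLC (VMAT) interpolation; such plans are rejected.
* No couch-kick geometry fidelity beyond a rigid table rotation about z.
* The toy engine has no scatter, buildup or penumbra physics.
* The PenVox dialect and phase-space dialect are this package's own
  documented formats, not vendor-exact ones.
* Region uncertainty weights every qualifying voxel equally; no
  dose-weighted variant is provided.
* The runner has no retries and no wall-time budget enforcement.
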