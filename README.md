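# rtmc — desk-scale map/reduce Monte Carlo verification of radiotherapy plans

Monte Carlo (MC) dose calculation is the reference standard for verifying
radiotherapy treatment plans, but a single verification needs 10⁵–10⁹
particle histories.  The classic remedy is map/reduce: split the plan's
beams and the history budget over many independent worker runs with
distinct random seeds (*map*), then statistically combine their dose
distributions (*reduce*).  `rtmc` implements that whole workflow as a
local Python library and CLI for medical-physics developers: DICOM-RT
plan discretization, CT-to-voxel-phantom conversion, parametrized MC
input generation, parallel execution over worker processes, statistical
reduction of dose and phase-space outputs, DICOM RTDOSE export and DVH
evaluation.  A bundled toy MC dose engine and synthetic DICOM fixture
generators stand in for commercial linac models and cloud VMs, so the
pipeline's statistics and bookkeeping are fully testable on one CPU.

## The core quantities

A dynamic plan is reduced to static beams a MC engine can compute: a
step-and-shoot plan maps segment-by-segment, and a rotational *mArc* plan
maps each beam-on arclet to a static beam at the arclet's central gantry
angle carrying the monitor units (MU) delivered during the arclet.  MU is
conserved bit-exactly: `Σ MU(static beams) == total_mu(plan)`.

Beams go to computing nodes either evenly ("Equal") or proportionally to
MU ("MUWeighted", Hamilton largest-remainder apportionment with a 1-node
floor per beam).  Worker runs with history counts `hᵢ` merge with weights
`wᵢ = hᵢ/Σh`:

    D = Σ wᵢ Dᵢ           (per-history mean dose, per voxel)
    σ = √( Σ wᵢ² σᵢ² )    (absolute 1σ standard error, per voxel)

The quoted uncertainty of a target volume is the mean of `100·k·σ/D` over
the voxels above half the maximum dose in the structure (coverage factor
`k = 2` by default), and the DVH `V(d)` is the percent of structure volume
receiving at least dose `d`.

## Worked example

Generate a synthetic rotational-arclet case (CT series, RTPLAN with 45
arclets 8° apart, cylindrical PTV) and verify it with 10⁵ histories over
45 worker processes, 4 running at a time:

```
$ rtmc make-fixtures --case marc_hn --out marc --seed 1
$ rtmc verify --rtplan marc/rtplan.dcm --ct marc/ct --rtstruct marc/rtstruct.dcm \
      --nodes 45 --parallel 4 --histories 100000 --seed 1 --workdir wmarc
beams: 45  histories: 100000
region uncertainty (k=2): 7.48%
Dmean 1.304e-03  Dmax 1.519e-03  D95 1.124e-03
```

The plan's 45 arclets became 45 static beams and the full 10⁵-history
budget was spent exactly.  The PTV dose is known to a 2σ statistical
uncertainty of 7.5%; the DVH metrics are per-history dose (multiply by a
Gy-per-history × MU calibration constant for absolute dose).  Re-running
with the same `--seed` reproduces `wmarc/merged_dose.bin` bit-for-bit.

The stages are also available individually — `rtmc plan
inspect/discretize`, `rtmc phantom` (egsphant or PenVox output), `rtmc
reduce`, `rtmc dvh` — and as library functions (`rtmc.parse_rtplan`,
`rtmc.discretize_plan`, `rtmc.distribute_work`, `rtmc.merge_binary_dose`,
`rtmc.run_verification`, ...).  `rtmc-toyengine <dir>` runs one bound
worker input directly.  See `docs/methods.md` for the model, the file
dialects and the numerical contracts.

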