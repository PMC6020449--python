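"""End-to-end verification pipeline: plan -> phantom -> map -> run -> reduce.

Glue used by the command-line interface and by scripted studies; every
stage is the public function of the corresponding module, so this file
contains orchestration only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


from .ct_phantom import (
    HUConversionTable,
    VoxelPhantom,
    apply_conversion,
    load_ct_series,
    resample_volume,
)
from .errors import SimulationError
from .geometry_mapper import (
    DistributionMode,
    ParametrizedModel,
    bind_parameters,
    distribute_work,
    load_model,
)
from .mapreduce_runner import Simulation, run_simulation
from .plan_eval import cumulative_dvh, dose_metrics, rasterize_structure, read_rtstruct
from .reducer import BinaryDoseLayout, DoseGrid, merge_binary_dose, region_uncertainty
from .rtplan_model import StaticBeam, discretize_plan, parse_rtplan
from .toy_engine import create_toy_model

__all__ = ["VerificationResult", "build_phantom", "run_verification"]


@dataclass
class VerificationResult:
    grid: DoseGrid
    simulation: Simulation
    beams: list[StaticBeam]
    region_uncertainty_pct: float | None = None
    dvh_metrics: dict | None = None


def build_phantom(ct_dir, table: HUConversionTable | None = None, spacing_mm=None) -> VoxelPhantom:
    vol = load_ct_series(ct_dir)
    if spacing_mm is not None:
        vol = resample_volume(vol, spacing_mm)
    return apply_conversion(vol, table)


def run_verification(
    rtplan_path,
    ct_dir,
    work_dir,
    rtstruct_path=None,
    structure: str = "PTV",
    n_nodes: int = 4,
    max_parallel: int = 4,
    total_histories: int = 100_000,
    mode: DistributionMode = DistributionMode.MU_WEIGHTED,
    master_seed: int = 1,
    table: HUConversionTable | None = None,
    spacing_mm=None,
    coverage_k: float = 2.0,
) -> VerificationResult:
    """Run the whole MC verification of one plan with the toy engine.

    ``n_nodes`` local worker directories stand in for computing nodes; the
    merged dose, the region uncertainty in the structure (coverage factor
    ``coverage_k``) and the structure DVH metrics are returned.
    """
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)

    plan = parse_rtplan(rtplan_path)
    beams = discretize_plan(plan)
    n_nodes = max(n_nodes, len(beams))
    phantom = build_phantom(ct_dir, table=table, spacing_mm=spacing_mm)
    manifest = create_toy_model(work_dir / "model", phantom, n_leaves=len(beams[0].mlc_a_mm))
    model = load_model(manifest)

    items = distribute_work(
        beams, n_nodes, mode=mode, total_histories=total_histories, master_seed=master_seed
    )
    beam_by_id = {b.beam_id: b for b in beams}
    for item in items:
        bind_parameters(
            model, beam_by_id[item.beam_id], item, work_dir / f"work/node_{item.node_id}"
        )
    sim = run_simulation(
        model, items, results_dir=work_dir / "results", max_parallel=max_parallel
    )
    if not sim.ok:
        raise SimulationError(f"workers failed: {sim.failed_nodes}")

    layout = BinaryDoseLayout.from_dict(model.layout)
    files = [work_dir / "results" / f"node_{it.node_id}" / "dose.bin" for it in items]
    grid = merge_binary_dose(
        files, layout, [it.histories for it in items], out_path=work_dir / "merged_dose.bin"
    )

    result = VerificationResult(grid=grid, simulation=sim, beams=beams)
    if rtstruct_path is not None:
        sset = read_rtstruct(rtstruct_path)
        mask = rasterize_structure(sset[structure], grid)
        if mask.any() and grid.dose[mask].max() > 0:
            result.region_uncertainty_pct = region_uncertainty(grid, mask, k=coverage_k)
            curve = cumulative_dvh(grid, mask, bin_width_gy=max(grid.dose.max() / 200.0, 1e-12))
            result.dvh_metrics = dose_metrics(curve)
        sim.evaluation = {
            "structure": structure,
            "region_uncertainty_pct": result.region_uncertainty_pct,
            "metrics": {
                k: v for k, v in (result.dvh_metrics or {}).items() if not isinstance(v, list)
            },
        }
        (work_dir / "evaluation.json").write_text(json.dumps(sim.evaluation, indent=1))
    return result
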