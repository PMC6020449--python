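"""Map-phase orchestration: run bound worker inputs as local processes.

Each work item is executed exactly once in its own bound directory by a
pool of worker processes; outputs matching the model's ``output_spec`` are
staged into a per-node results directory as workers finish, and the
simulation advances through the canonical state machine::

    INACTIVE -> DOWNLOADING_FILES -> SIMULATING -> UPLOADING_RESULTS -> FINISHED

State transitions and per-worker wall times are appended to a JSONL log
next to the results.  Workers fail fast: any nonzero exit marks the whole
simulation failed, with partial outputs retained for diagnosis.
"""

from __future__ import annotations

import enum
import json
import shutil
import subprocess
import time
from concurrent.futures import ThreadPoolExecutor, as_completed
from dataclasses import dataclass, field
from pathlib import Path

from .errors import SimulationError
from .geometry_mapper import ParametrizedModel, WorkItem

__all__ = ["SimulationState", "Simulation", "run_simulation"]


class SimulationState(enum.Enum):
    INACTIVE = 0
    DOWNLOADING_FILES = 1
    SIMULATING = 2
    UPLOADING_RESULTS = 3
    FINISHED = 4


@dataclass
class WorkerResult:
    node_id: int
    returncode: int
    elapsed_s: float
    output_files: list[Path] = field(default_factory=list)
    stderr: str = ""


@dataclass
class Simulation:
    id: str
    work_items: list[WorkItem]
    results_dir: Path
    state: SimulationState = SimulationState.INACTIVE
    state_log: list[tuple[str, float]] = field(default_factory=list)
    outputs: list[WorkerResult] = field(default_factory=list)
    failed_nodes: list[int] = field(default_factory=list)
    evaluation: dict | None = None

    def advance(self, new_state: SimulationState) -> None:
        if new_state.value < self.state.value:
            raise SimulationError(
                f"illegal state transition {self.state.name} -> {new_state.name}"
            )
        self.state = new_state
        stamp = (new_state.name, time.time())
        self.state_log.append(stamp)
        log = self.results_dir / "simulation.jsonl"
        with open(log, "a") as fh:
            fh.write(json.dumps({"event": "state", "state": stamp[0], "t": stamp[1]}) + "\n")

    @property
    def ok(self) -> bool:
        return self.state is SimulationState.FINISHED and not self.failed_nodes


def _run_worker(model: ParametrizedModel, item: WorkItem) -> WorkerResult:
    t0 = time.perf_counter()
    proc = subprocess.run(
        model.executable,
        cwd=item.bound_dir,
        capture_output=True,
        text=True,
    )
    return WorkerResult(
        node_id=item.node_id,
        returncode=proc.returncode,
        elapsed_s=time.perf_counter() - t0,
        stderr=proc.stderr[-2000:],
    )


def _collect(model: ParametrizedModel, item: WorkItem, dest: Path) -> list[Path]:
    dest.mkdir(parents=True, exist_ok=True)
    staged = []
    for pattern, _fmt in model.output_spec:
        for src in sorted(Path(item.bound_dir).glob(pattern)):
            target = dest / src.name
            shutil.copy2(src, target)
            staged.append(target)
    return staged


def run_simulation(
    model: ParametrizedModel,
    items: list[WorkItem],
    results_dir,
    max_parallel: int = 2,
    sim_id: str = "sim",
) -> Simulation:
    """Execute all bound work items and collect their outputs.

    Results are staged into ``results_dir/node_<id>/`` in completion order
    (the reducer can start as soon as files appear); the merged result of a
    later reduce is independent of that order and of ``max_parallel``.
    """
    if not items:
        raise SimulationError("nothing to simulate: empty work item list")
    for item in items:
        if item.bound_dir is None or not Path(item.bound_dir).is_dir():
            raise SimulationError(f"work item {item.node_id} is not bound")
    results_dir = Path(results_dir)
    results_dir.mkdir(parents=True, exist_ok=True)
    sim = Simulation(id=sim_id, work_items=items, results_dir=results_dir)
    sim.advance(SimulationState.DOWNLOADING_FILES)  # inputs staged into bound dirs
    sim.advance(SimulationState.SIMULATING)

    log = results_dir / "simulation.jsonl"
    with ThreadPoolExecutor(max_workers=max(1, max_parallel)) as pool:
        futures = {pool.submit(_run_worker, model, item): item for item in items}
        for fut in as_completed(futures):
            item = futures[fut]
            result = fut.result()
            if result.returncode == 0:
                result.output_files = _collect(model, item, results_dir / f"node_{item.node_id}")
            else:
                sim.failed_nodes.append(item.node_id)
            sim.outputs.append(result)
            with open(log, "a") as fh:
                fh.write(
                    json.dumps(
                        {
                            "event": "worker",
                            "node": item.node_id,
                            "beam": item.beam_id,
                            "histories": item.histories,
                            "returncode": result.returncode,
                            "elapsed_s": round(result.elapsed_s, 4),
                        }
                    )
                    + "\n"
                )

    sim.advance(SimulationState.UPLOADING_RESULTS)
    sim.failed_nodes.sort()
    sim.outputs.sort(key=lambda r: r.node_id)
    if sim.failed_nodes:
        # FINISHED is reserved for fully collected simulations; a failed run
        # stops here with partial outputs retained for diagnosis.
        with open(log, "a") as fh:
            fh.write(json.dumps({"event": "failed", "nodes": sim.failed_nodes}) + "\n")
        return sim
    sim.advance(SimulationState.FINISHED)
    return sim
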