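"""A minimal voxel dose engine honoring the parametrized-model contract.

The engine reads two text input files (``engine.in``: histories, time
limit, two random seeds; ``beam.in``: beam geometry, aperture, phantom and
output paths) from a bound input directory, transports primary rays through
a voxelized phantom and writes a reducer-compatible binary dose file.

Transport model (deliberately non-physical but statistically honest): each
history is one ray from a virtual point source at source-axis distance SAD,
aimed at a point sampled uniformly over the jaw rectangle in the collimator
plane; rays landing on a closed MLC leaf pair are absorbed (zero-dose
history).  The ray is walked through the density grid with an exact
3-D DDA (Amanatides-Woo) traversal, and the energy deposited in a voxel is
the attenuated-fraction difference across it,

    e_v = E0 * ( exp(-mu * R_in) - exp(-mu * R_out) )

with ``mu`` a single effective mass attenuation coefficient (cm^2/g) and
``R`` the radiological depth (g/cm^2) along the ray.  Dose per history is
``e_v`` divided by the voxel mass; the per-voxel uncertainty is the
history-by-history estimator of the standard error of the mean:

    s^2 = ( sum d_i^2 - (sum d_i)^2 / n ) / ( n (n-1) )

The engine's RNG is a counter-based splitmix64 keyed by the two input
seeds, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

import json
import sys
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ct_phantom import VoxelPhantom, read_penvox
from .reducer import PHSP_FIELDS, BinaryDoseLayout, PhaseSpace, write_binary_dose, write_phsp

__all__ = [
    "ToyBeamConfig",
    "toy_mc_run",
    "analytic_depth_dose",
    "create_toy_model",
    "dose_layout_for",
    "main",
]

HEADER_BYTES = 256
_BATCH = 20000


# --------------------------------------------------------------------------
# Counter-based RNG (splitmix64)

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    z = x
    z = z ^ (z >> np.uint64(30))
    z = z * np.uint64(0xBF58476D1CE4E5B9)
    z = z ^ (z >> np.uint64(27))
    z = z * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return z


def uniform01(seed1: int, seed2: int, counters: np.ndarray) -> np.ndarray:
    """Deterministic U(0,1) stream indexed by absolute counter values."""
    key = (np.uint64(seed1) << np.uint64(32)) ^ np.uint64(seed2)
    with np.errstate(over="ignore"):
        x = key + (np.asarray(counters, dtype=np.uint64) + np.uint64(1)) * _GOLDEN
        z = _splitmix64(x)
    return (z >> np.uint64(11)).astype(np.float64) / float(1 << 53)


# --------------------------------------------------------------------------
# Configuration


@dataclass
class ToyBeamConfig:
    gantry_deg: float = 0.0
    collimator_deg: float = 0.0
    table_deg: float = 0.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    jaws_mm: tuple[float, float, float, float] = (-20.0, 20.0, -20.0, 20.0)
    leaf_width_mm: float = 8.0
    mlc_a_mm: tuple[float, ...] = ()
    mlc_b_mm: tuple[float, ...] = ()
    sad_mm: float = 1000.0
    histories: int = 1000
    seeds: tuple[int, int] = (1, 2)
    time_limit_s: float = -1.0
    mu_attenuation_cm2_g: float = 0.049
    energy_per_history: float = 1.0
    phantom_path: str = "phantom.penvox"
    output_path: str = "dose.bin"
    emit_phsp: bool = False
    ledger: bool = False
    precision: str = "single"

    def __post_init__(self) -> None:
        if self.histories <= 0:
            raise ValueError("histories must be positive")
        if self.mu_attenuation_cm2_g <= 0:
            raise ValueError("attenuation coefficient must be positive")

    def jaw_area_mm2(self) -> float:
        x1, x2, y1, y2 = self.jaws_mm
        return max(0.0, x2 - x1) * max(0.0, y2 - y1)

    def open_area_mm2(self) -> float:
        """Jaw rectangle intersected with the MLC opening, per leaf."""
        x1, x2, y1, y2 = self.jaws_mm
        n = len(self.mlc_a_mm)
        if n == 0:
            return self.jaw_area_mm2()
        half = n * self.leaf_width_mm / 2.0
        area = 0.0
        for i, (a, b) in enumerate(zip(self.mlc_a_mm, self.mlc_b_mm)):
            ylo = -half + i * self.leaf_width_mm
            yhi = ylo + self.leaf_width_mm
            dy = max(0.0, min(yhi, y2) - max(ylo, y1))
            dx = max(0.0, min(b, x2) - max(a, x1))
            area += dx * dy
        return area


def _parse_kv(path: Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        out[parts[0].upper()] = parts[1:]
    return out


def load_config(input_dir) -> ToyBeamConfig:
    input_dir = Path(input_dir)
    eng = _parse_kv(input_dir / "engine.in")
    beam = _parse_kv(input_dir / "beam.in")
    return ToyBeamConfig(
        gantry_deg=float(beam["GANTRY"][0]),
        collimator_deg=float(beam["COLL"][0]),
        table_deg=float(beam["TABLE"][0]),
        isocenter_mm=tuple(float(v) for v in beam["ISO"][:3]),
        jaws_mm=tuple(float(v) for v in beam["JAWS"][:4]),
        leaf_width_mm=float(beam["LEAFW"][0]),
        mlc_a_mm=tuple(float(v) for v in beam["MLCA"]),
        mlc_b_mm=tuple(float(v) for v in beam["MLCB"]),
        sad_mm=float(beam["SAD"][0]),
        histories=int(eng["NHIST"][0]),
        seeds=(int(eng["SEED1"][0]), int(eng["SEED2"][0])),
        time_limit_s=float(eng["TIME"][0]),
        mu_attenuation_cm2_g=float(beam["MU_EN"][0]),
        energy_per_history=float(beam["EPH"][0]),
        phantom_path=beam["PHANTOM"][0],
        output_path=beam["OUTPUT"][0],
        emit_phsp=bool(int(beam.get("PHSP", ["0"])[0])),
        ledger=bool(int(beam.get("LEDGER", ["0"])[0])),
        precision=beam.get("PREC", ["single"])[0],
    )


def dose_layout_for(phantom: VoxelPhantom, precision: str = "single") -> BinaryDoseLayout:
    nx, ny, nz = phantom.dims
    return BinaryDoseLayout(
        header_bytes=HEADER_BYTES,
        n_values=nx * ny * nz,
        precision=precision,
        dims=phantom.dims,
        spacing_mm=phantom.spacing_mm,
        origin_mm=phantom.origin_mm,
    )


# --------------------------------------------------------------------------
# Geometry helpers


def _rotz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _beam_frame(cfg: ToyBeamConfig):
    """Source position and collimator-plane basis vectors (LPS mm).

    Gantry 0 places the source anterior to the patient (-y in LPS); the
    gantry rotates in the axial plane, the table about the patient z axis.
    """
    g = np.radians(cfg.gantry_deg)
    rt = _rotz(cfg.table_deg)
    s_hat = rt @ np.array([np.sin(g), -np.cos(g), 0.0])
    e1 = rt @ np.array([np.cos(g), np.sin(g), 0.0])  # cross-line (x) direction
    e2 = np.array([0.0, 0.0, 1.0])  # in-line (y) direction = patient z
    iso = np.asarray(cfg.isocenter_mm, dtype=float)
    src = iso + cfg.sad_mm * s_hat
    return src, iso, e1, e2


def _open_segments(cfg: ToyBeamConfig):
    """Open aperture rectangles (x_lo, x_hi, y_lo, y_hi), one per open leaf."""
    x1, x2, y1, y2 = cfg.jaws_mm
    nleaf = len(cfg.mlc_a_mm)
    if nleaf == 0:
        return np.asarray([[x1, x2, y1, y2]]) if (x2 > x1 and y2 > y1) else np.empty((0, 4))
    half = nleaf * cfg.leaf_width_mm / 2.0
    rects = []
    for i, (a, b) in enumerate(zip(cfg.mlc_a_mm, cfg.mlc_b_mm)):
        ylo = max(-half + i * cfg.leaf_width_mm, y1)
        yhi = min(-half + (i + 1) * cfg.leaf_width_mm, y2)
        xlo = max(a, x1)
        xhi = min(b, x2)
        if xhi > xlo and yhi > ylo:
            rects.append([xlo, xhi, ylo, yhi])
    return np.asarray(rects) if rects else np.empty((0, 4))


def _sample_aperture(cfg: ToyBeamConfig, start: int, n: int):
    """Sample collimator-frame aperture points for histories [start, start+n).

    Points are uniform over the *open* aperture (jaw rectangle intersected
    with the MLC opening): a leaf row is picked with probability
    proportional to its open area, then (x, y) uniform within it.  With a
    fully closed aperture no points exist and every history is blocked.
    """
    rects = _open_segments(cfg)
    if rects.shape[0] == 0:
        return np.empty((0, 2)), np.zeros(n, dtype=bool)
    areas = (rects[:, 1] - rects[:, 0]) * (rects[:, 3] - rects[:, 2])
    cdf = np.cumsum(areas)
    s1, s2 = cfg.seeds
    idx = np.arange(start, start + n, dtype=np.uint64)
    upick = uniform01(s1, s2, idx * np.uint64(3))
    ux = uniform01(s1, s2, idx * np.uint64(3) + np.uint64(1))
    uy = uniform01(s1, s2, idx * np.uint64(3) + np.uint64(2))
    which = np.searchsorted(cdf, upick * cdf[-1], side="right")
    which = np.clip(which, 0, rects.shape[0] - 1)
    r = rects[which]
    xs = r[:, 0] + ux * (r[:, 1] - r[:, 0])
    ys = r[:, 2] + uy * (r[:, 3] - r[:, 2])
    return np.stack([xs, ys], axis=1), np.ones(n, dtype=bool)


# --------------------------------------------------------------------------
# DDA transport


def _trace(cfg: ToyBeamConfig, phantom: VoxelPhantom, points_xy: np.ndarray):
    """Trace one batch of rays; returns per-deposit sparse triplets.

    Output: (ray_index, flat_voxel, dose_per_history) arrays plus the final
    radiological depth of every ray (for phase-space emission).
    """
    src, iso, e1, e2 = _beam_frame(cfg)
    c, s = np.cos(np.radians(cfg.collimator_deg)), np.sin(np.radians(cfg.collimator_deg))
    a = c * points_xy[:, 0] - s * points_xy[:, 1]
    b = s * points_xy[:, 0] + c * points_xy[:, 1]
    targets = iso[None, :] + a[:, None] * e1[None, :] + b[:, None] * e2[None, :]
    dirs = targets - src[None, :]
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    dims = np.asarray(phantom.dims)
    spacing = np.asarray(phantom.spacing_mm, dtype=float)
    corner = np.asarray(phantom.origin_mm, dtype=float) - spacing / 2.0
    nx, ny, _nz = phantom.dims
    density_flat = phantom.density.ravel(order="F")
    mu = cfg.mu_attenuation_cm2_g
    e0 = cfg.energy_per_history
    vol_cm3 = phantom.voxel_volume_cm3

    B = dirs.shape[0]
    tiny = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(np.abs(dirs) > tiny, 1.0 / dirs, np.inf)
        t_a = (corner[None, :] - src[None, :]) * inv
        t_b = (corner[None, :] + spacing[None, :] * dims[None, :] - src[None, :]) * inv
    lo = np.minimum(t_a, t_b)
    hi = np.maximum(t_a, t_b)
    zero = np.abs(dirs) <= tiny
    inside = (src[None, :] >= corner[None, :]) & (
        src[None, :] <= corner[None, :] + spacing[None, :] * dims[None, :]
    )
    lo = np.where(zero, np.where(inside, -np.inf, np.inf), lo)
    hi = np.where(zero, np.where(inside, np.inf, -np.inf), hi)
    t0 = np.maximum(lo.max(axis=1), 0.0)
    t1 = hi.min(axis=1)
    eps = 1e-6 * spacing.min()
    active = t0 + eps < t1

    p_entry = src[None, :] + (t0 + eps)[:, None] * dirs
    idx = np.floor((p_entry - corner[None, :]) / spacing[None, :]).astype(np.int64)
    idx = np.clip(idx, 0, dims[None, :] - 1)
    step = np.sign(dirs).astype(np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_delta = np.where(np.abs(dirs) > tiny, spacing[None, :] / np.abs(dirs), np.inf)
        next_edge = corner[None, :] + (idx + (step > 0)) * spacing[None, :]
        t_max = np.where(np.abs(dirs) > tiny, (next_edge - src[None, :]) * inv, np.inf)

    t_cur = t0.copy()
    depth = np.zeros(B)  # radiological depth, g/cm^2
    rows_r: list[np.ndarray] = []
    rows_v: list[np.ndarray] = []
    rows_d: list[np.ndarray] = []
    ray_ids = np.arange(B)
    max_steps = int(dims.sum()) + 4
    for _ in range(max_steps):
        if not active.any():
            break
        act = np.nonzero(active)[0]
        t_next = np.minimum(t_max[act].min(axis=1), t1[act])
        seg_mm = np.clip(t_next - t_cur[act], 0.0, None)
        flat = idx[act, 0] + nx * (idx[act, 1] + ny * idx[act, 2])
        rho = density_flat[flat]
        dr = rho * seg_mm / 10.0
        d0 = depth[act]
        dep = e0 * (np.exp(-mu * d0) - np.exp(-mu * (d0 + dr)))
        mass = rho * vol_cm3
        dose = np.where(mass > 0, dep / np.where(mass > 0, mass, 1.0), 0.0)
        keep = dose > 0
        rows_r.append(ray_ids[act][keep])
        rows_v.append(flat[keep])
        rows_d.append(dose[keep])
        depth[act] = d0 + dr
        t_cur[act] = t_next
        axis = np.argmin(t_max[act], axis=1)
        idx[act, axis] += step[act, axis]
        t_max[act, axis] += t_delta[act, axis]
        out = (
            (idx[act, 0] < 0)
            | (idx[act, 0] >= dims[0])
            | (idx[act, 1] < 0)
            | (idx[act, 1] >= dims[1])
            | (idx[act, 2] < 0)
            | (idx[act, 2] >= dims[2])
            | (t_cur[act] >= t1[act] - 1e-12)
        )
        active[act[out]] = False

    if rows_r:
        return (
            np.concatenate(rows_r),
            np.concatenate(rows_v),
            np.concatenate(rows_d),
            depth,
            dirs,
            t1,
            src,
        )
    return (
        np.empty(0, dtype=int),
        np.empty(0, dtype=int),
        np.empty(0),
        depth,
        dirs,
        t1,
        src,
    )


# --------------------------------------------------------------------------
# Run


def toy_mc_run(input_dir, phantom: VoxelPhantom | None = None) -> dict:
    """Execute one worker run from a bound input directory.

    Writes the binary dose file (plus its JSON layout sidecar and a run
    log; optionally a per-history deposit ledger and an exit phase space)
    into the input directory and returns a small summary dict.
    """
    input_dir = Path(input_dir)
    cfg = load_config(input_dir)
    if phantom is None:
        phantom = read_penvox(input_dir / cfg.phantom_path)
    layout = dose_layout_for(phantom, precision=cfg.precision)
    n = cfg.histories
    nvox = layout.n_values

    t_start = time.perf_counter()
    s1_acc = np.zeros(nvox)
    s2_acc = np.zeros(nvox)
    ledger_h: list[np.ndarray] = []
    ledger_v: list[np.ndarray] = []
    ledger_d: list[np.ndarray] = []
    phsp_rows: list[np.ndarray] = []
    n_blocked = 0

    if cfg.open_area_mm2() <= 0.0:
        warnings.warn("aperture fully closed: all histories absorbed, dose is zero")

    for start in range(0, n, _BATCH):
        count = min(_BATCH, n - start)
        pts, accepted = _sample_aperture(cfg, start, count)
        n_blocked += int((~accepted).sum())
        if not accepted.any():
            continue
        ridx, vidx, dose, depth, dirs, t1, src = _trace(cfg, phantom, pts[accepted])
        np.add.at(s1_acc, vidx, dose)
        np.add.at(s2_acc, vidx, dose * dose)
        if cfg.ledger:
            abs_ids = np.nonzero(accepted)[0][ridx] + start
            ledger_h.append(abs_ids.astype(np.int64))
            ledger_v.append(vidx.astype(np.int64))
            ledger_d.append(dose)
        if cfg.emit_phsp:
            exiting = np.isfinite(t1) & (t1 > 0)
            pos = src[None, :] + t1[exiting, None] * dirs[exiting]
            e_out = cfg.energy_per_history * np.exp(
                -cfg.mu_attenuation_cm2_g * depth[exiting]
            )
            rec = np.column_stack(
                [
                    np.ones(exiting.sum()),  # particle type: photon
                    e_out,
                    pos,
                    dirs[exiting],
                    np.ones(exiting.sum()),  # statistical weight
                ]
            )
            phsp_rows.append(rec)

    mean = s1_acc / n
    if n > 1:
        var = (s2_acc - s1_acc**2 / n) / (n * (n - 1))
        sigma = np.sqrt(np.clip(var, 0.0, None))
    else:
        sigma = np.zeros(nvox)

    header_doc = {
        "magic": "RTMCDOSE",
        "histories": n,
        "dims": list(phantom.dims),
        "spacing_mm": list(phantom.spacing_mm),
        "origin_mm": list(phantom.origin_mm),
        "seeds": list(cfg.seeds),
        "unit": "eph_per_g_per_history",
    }
    header = json.dumps(header_doc).encode()
    if len(header) > HEADER_BYTES:
        header = header[:HEADER_BYTES]
    header = header.ljust(HEADER_BYTES, b" ")
    out_path = input_dir / cfg.output_path
    write_binary_dose(out_path, header, mean, sigma, layout)
    layout_doc = {
        "header_bytes": layout.header_bytes,
        "n_values": layout.n_values,
        "precision": layout.precision,
        "uncertainty_kind": layout.uncertainty_kind,
        "dims": list(layout.dims),
        "spacing_mm": list(layout.spacing_mm),
        "origin_mm": list(layout.origin_mm),
    }
    (out_path.parent / (out_path.name + ".layout.json")).write_text(
        json.dumps(layout_doc, indent=1)
    )

    if cfg.ledger:
        np.savez(
            input_dir / "ledger.npz",
            history=np.concatenate(ledger_h) if ledger_h else np.empty(0, dtype=np.int64),
            voxel=np.concatenate(ledger_v) if ledger_v else np.empty(0, dtype=np.int64),
            dose=np.concatenate(ledger_d) if ledger_d else np.empty(0),
            n_histories=np.int64(n),
        )
    if cfg.emit_phsp:
        records = (
            np.concatenate(phsp_rows, axis=0)
            if phsp_rows
            else np.empty((0, len(PHSP_FIELDS)), dtype=np.float32)
        )
        write_phsp(
            PhaseSpace(n_original_histories=n, records=records), input_dir / "exit.phsp"
        )

    elapsed = time.perf_counter() - t_start
    summary = {
        "histories": n,
        "blocked": n_blocked,
        "elapsed_s": round(elapsed, 4),
        "seeds": list(cfg.seeds),
        "output": str(out_path),
    }
    (input_dir / "run.log").write_text(json.dumps(summary, indent=1) + "\n")
    return summary


# --------------------------------------------------------------------------
# Closed-form expectation for validation


def analytic_depth_dose(
    depth_cm: float,
    cfg: ToyBeamConfig,
    density_g_cm3: float = 1.0,
    voxel_dz_cm: float = 0.1,
    phantom: VoxelPhantom | None = None,
) -> float:
    """Expected per-history dose in a central-axis voxel slab (parallel beam).

    For a homogeneous phantom of density ``rho`` the expected dose of a
    voxel whose beam-axis extent is [d, d + dz] is::

        E[dose] = E0 * ( e^{-mu rho d} - e^{-mu rho (d+dz)} ) / ( rho * A_open * dz )

    with ``A_open`` the open aperture area in cm^2 (histories are sampled
    uniformly over the open aperture).  Only meaningful when SAD is large
    relative to the phantom (negligible divergence) and for voxels whose
    beam's-eye footprint lies fully inside the opening.
    """
    if phantom is not None:
        if not np.allclose(phantom.density, phantom.density.flat[0]):
            raise ValueError("analytic expectation requires a homogeneous phantom")
        density_g_cm3 = float(phantom.density.flat[0])
    rho = density_g_cm3
    mu = cfg.mu_attenuation_cm2_g
    area_cm2 = cfg.open_area_mm2() / 100.0
    if rho <= 0 or area_cm2 <= 0 or voxel_dz_cm <= 0:
        return 0.0
    e0 = cfg.energy_per_history
    d = depth_cm
    return (
        e0
        * (np.exp(-mu * rho * d) - np.exp(-mu * rho * (d + voxel_dz_cm)))
        / (rho * area_cm2 * voxel_dz_cm)
    )


# --------------------------------------------------------------------------
# Model template scaffolding


def create_toy_model(
    model_dir,
    phantom: VoxelPhantom,
    n_leaves: int,
    leaf_width_mm: float = 8.0,
    sad_mm: float = 1000.0,
    mu_attenuation_cm2_g: float = 0.049,
    emit_phsp: bool = False,
    ledger: bool = False,
    precision: str = "single",
) -> Path:
    """Write a toy-engine model directory (templates + manifest).

    Returns the path of the YAML manifest; the phantom is stored inside the
    template directory in the PenVox dialect so every bound worker copy is
    self-contained.
    """
    from .ct_phantom import write_penvox  # local import to avoid cycle at module load

    model_dir = Path(model_dir)
    tmpl = model_dir / "template"
    tmpl.mkdir(parents=True, exist_ok=True)
    write_penvox(phantom, tmpl / "phantom.penvox")
    (tmpl / "engine.in").write_text(
        "# rtmc toy engine: run control\n"
        "NHIST 1000\n"
        "TIME -1.0\n"
        "SEED1 1\n"
        "SEED2 2\n"
    )
    zeros = " ".join("0.000000" for _ in range(n_leaves))
    (tmpl / "beam.in").write_text(
        "# rtmc toy engine: beam geometry and transport model\n"
        "GANTRY 0.000000\n"
        "COLL 0.000000\n"
        "TABLE 0.000000\n"
        "ISO 0.000000 0.000000 0.000000\n"
        "JAWS -20.000000 20.000000 -20.000000 20.000000\n"
        f"NLEAF {n_leaves}\n"
        f"LEAFW {leaf_width_mm:.6f}\n"
        f"MLCA {zeros}\n"
        f"MLCB {zeros}\n"
        f"SAD {sad_mm:.1f}\n"
        "PHANTOM phantom.penvox\n"
        "OUTPUT dose.bin\n"
        f"MU_EN {mu_attenuation_cm2_g:.6f}\n"
        "EPH 1.0\n"
        f"PHSP {1 if emit_phsp else 0}\n"
        f"LEDGER {1 if ledger else 0}\n"
        f"PREC {precision}\n"
    )
    layout = dose_layout_for(phantom, precision=precision)
    manifest = {
        "template_dir": "template",
        "executable": ["{python}", "-m", "rtmc.toy_engine", "."],
        "descriptors": [
            {"file": "engine.in", "line": 2, "token": 2, "kind": "HISTORIES", "format": "%d"},
            {"file": "engine.in", "line": 3, "token": 2, "kind": "TIME_LIMIT", "format": "%.1f"},
            {"file": "engine.in", "line": 4, "token": 2, "kind": "SEED1", "format": "%d"},
            {"file": "engine.in", "line": 5, "token": 2, "kind": "SEED2", "format": "%d"},
            {"file": "beam.in", "line": 2, "token": 2, "kind": "GANTRY", "format": "%.6f"},
            {"file": "beam.in", "line": 3, "token": 2, "kind": "COLLIMATOR", "format": "%.6f"},
            {"file": "beam.in", "line": 4, "token": 2, "kind": "TABLE", "format": "%.6f"},
            {"file": "beam.in", "line": 5, "token": 2, "kind": "ISOCENTER_X", "format": "%.6f"},
            {"file": "beam.in", "line": 5, "token": 3, "kind": "ISOCENTER_Y", "format": "%.6f"},
            {"file": "beam.in", "line": 5, "token": 4, "kind": "ISOCENTER_Z", "format": "%.6f"},
            {"file": "beam.in", "line": 6, "token": 2, "kind": "JAW_X1", "format": "%.6f"},
            {"file": "beam.in", "line": 6, "token": 3, "kind": "JAW_X2", "format": "%.6f"},
            {"file": "beam.in", "line": 6, "token": 4, "kind": "JAW_Y1", "format": "%.6f"},
            {"file": "beam.in", "line": 6, "token": 5, "kind": "JAW_Y2", "format": "%.6f"},
            {"file": "beam.in", "line": 9, "token": 2, "kind": "MLC_BANK_A", "format": "%.6f"},
            {"file": "beam.in", "line": 10, "token": 2, "kind": "MLC_BANK_B", "format": "%.6f"},
        ],
        "output_spec": [
            {"pattern": "dose.bin", "format": "BINARY_DOSE"},
            {"pattern": "dose.bin.layout.json", "format": "BINARY_DOSE"},
            {"pattern": "run.log", "format": "COLUMN_TEXT"},
        ]
        + ([{"pattern": "exit.*", "format": "IAEA_PHSP"}] if emit_phsp else [])
        + ([{"pattern": "ledger.npz", "format": "BINARY_DOSE"}] if ledger else []),
        "layout": {
            "header_bytes": layout.header_bytes,
            "n_values": layout.n_values,
            "precision": layout.precision,
            "dims": list(layout.dims),
            "spacing_mm": list(layout.spacing_mm),
            "origin_mm": list(layout.origin_mm),
        },
    }
    import yaml

    manifest_path = model_dir / "model.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def main(argv=None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 1:
        print("usage: rtmc-toyengine <input_dir>", file=sys.stderr)
        return 2
    try:
        summary = toy_mc_run(argv[0])
    except Exception as exc:  # worker contract: nonzero exit on any failure
        print(f"toy engine failed: {exc}", file=sys.stderr)
        return 1
    print(json.dumps(summary))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
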