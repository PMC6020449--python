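"""Reduce phase: statistical combination of independent worker outputs.

Workers return binary dose files (an opaque header followed by the dose
array and its absolute 1-sigma uncertainty array), column-format text
tallies, and phase-space files.  Independent runs with history counts
``h_i`` are combined with weights ``w_i = h_i / sum(h)``::

    dose  = sum_i w_i * d_i
    sigma = sqrt( sum_i w_i**2 * s_i**2 )

which is the exact pooled estimate when each run reports the per-history
mean and the standard error of that mean.  Phase spaces are concatenated
with their original-history counters summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EvaluationError, FormatError

__all__ = [
    "BinaryDoseLayout",
    "DoseGrid",
    "PhaseSpace",
    "PHSP_FIELDS",
    "read_binary_dose",
    "write_binary_dose",
    "merge_binary_dose",
    "merge_column_tallies",
    "read_phsp",
    "write_phsp",
    "merge_phsp",
    "region_uncertainty",
]


@dataclass(frozen=True)
class BinaryDoseLayout:
    """Byte layout of one worker's binary dose file (little-endian)."""

    header_bytes: int = 256
    n_values: int = 0
    precision: str = "single"  # or "double"
    uncertainty_kind: str = "ABSOLUTE_1SIGMA"
    dims: tuple[int, int, int] | None = None
    spacing_mm: tuple[float, float, float] | None = None
    origin_mm: tuple[float, float, float] | None = None

    @property
    def dtype(self) -> np.dtype:
        return np.dtype("<f4" if self.precision == "single" else "<f8")

    @property
    def file_size(self) -> int:
        return self.header_bytes + 2 * self.n_values * self.dtype.itemsize

    @classmethod
    def from_dict(cls, d: dict) -> "BinaryDoseLayout":
        return cls(
            header_bytes=int(d.get("header_bytes", 256)),
            n_values=int(d.get("n_values", 0)),
            precision=str(d.get("precision", "single")),
            uncertainty_kind=str(d.get("uncertainty_kind", "ABSOLUTE_1SIGMA")),
            dims=tuple(d["dims"]) if d.get("dims") else None,
            spacing_mm=tuple(d["spacing_mm"]) if d.get("spacing_mm") else None,
            origin_mm=tuple(d["origin_mm"]) if d.get("origin_mm") else None,
        )


@dataclass
class DoseGrid:
    """Dose and absolute 1-sigma uncertainty per voxel, ``[ix, iy, iz]``."""

    dose: np.ndarray
    sigma: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    histories: int
    unit: str = "per_history"
    sigma_present: bool = True

    def __post_init__(self) -> None:
        if self.dose.shape != self.sigma.shape:
            raise ValueError("dose and sigma shapes differ")
        if np.any(self.sigma < 0):
            raise ValueError("negative sigma")
        if self.histories <= 0:
            raise ValueError("histories must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.dose.shape


# --------------------------------------------------------------------------
# Binary dose files


def read_binary_dose(path, layout: BinaryDoseLayout) -> tuple[bytes, np.ndarray, np.ndarray]:
    """Return (header, dose, sigma) flat arrays as laid out in the file."""
    raw = Path(path).read_bytes()
    if len(raw) != layout.file_size:
        raise FormatError(
            f"{path}: {len(raw)} bytes, layout expects {layout.file_size}"
        )
    header = raw[: layout.header_bytes]
    data = np.frombuffer(raw, dtype=layout.dtype, offset=layout.header_bytes)
    return header, data[: layout.n_values].copy(), data[layout.n_values :].copy()


def write_binary_dose(path, header: bytes, dose, sigma, layout: BinaryDoseLayout) -> None:
    if len(header) != layout.header_bytes:
        raise FormatError(
            f"header is {len(header)} bytes, layout expects {layout.header_bytes}"
        )
    dose = np.asarray(dose, dtype=layout.dtype).ravel(order="F")
    sigma = np.asarray(sigma, dtype=layout.dtype).ravel(order="F")
    if dose.size != layout.n_values or sigma.size != layout.n_values:
        raise FormatError("array size does not match layout n_values")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(dose.tobytes())
        fh.write(sigma.tobytes())


def _to_grid(dose_flat, sigma_flat, layout: BinaryDoseLayout, histories: int) -> DoseGrid:
    dims = layout.dims or (layout.n_values, 1, 1)
    return DoseGrid(
        dose=np.asarray(dose_flat, dtype=float).reshape(dims, order="F"),
        sigma=np.asarray(sigma_flat, dtype=float).reshape(dims, order="F"),
        spacing_mm=layout.spacing_mm or (1.0, 1.0, 1.0),
        origin_mm=layout.origin_mm or (0.0, 0.0, 0.0),
        histories=histories,
    )


def merge_binary_dose(
    files: list,
    layout: BinaryDoseLayout,
    histories: list[int],
    out_path=None,
) -> DoseGrid:
    """History-weighted merge of per-worker binary dose files.

    The header of the first file is copied verbatim into the merged output
    (when ``out_path`` is given); dose and uncertainty are combined with the
    weighted formulas in the module docstring.
    """
    if len(files) != len(histories):
        raise ValueError("need one history count per file")
    if not files:
        raise ValueError("no files to merge")
    if any(h <= 0 for h in histories):
        raise ValueError("history counts must be positive")
    total = sum(int(h) for h in histories)
    dose_acc = np.zeros(layout.n_values, dtype=np.float64)
    var_acc = np.zeros(layout.n_values, dtype=np.float64)
    first_header = None
    for path, h in zip(files, histories):
        header, d, s = read_binary_dose(path, layout)
        if first_header is None:
            first_header = header
        w = h / total
        dose_acc += w * d.astype(np.float64)
        var_acc += (w * s.astype(np.float64)) ** 2
    sigma = np.sqrt(var_acc)
    if out_path is not None:
        write_binary_dose(out_path, first_header, dose_acc, sigma, layout)
    return _to_grid(dose_acc, sigma, layout, total)


# --------------------------------------------------------------------------
# Column-text tallies


def merge_column_tallies(
    files: list,
    histories: list[int],
    value_cols: list[int],
    sigma_cols: list[int],
    out_path=None,
) -> np.ndarray:
    """Merge whitespace-separated column tallies row by row.

    ``value_cols``/``sigma_cols`` are 0-based column indices of paired value
    and absolute-1-sigma columns; every other column is a key column that
    must match across files exactly and is copied through.
    """
    if len(files) != len(histories):
        raise ValueError("need one history count per file")
    if len(value_cols) != len(sigma_cols):
        raise ValueError("value/uncertainty column lists differ in length")
    tables = []
    for path in files:
        rows = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
        tables.append(np.asarray(rows, dtype=float))
    ref = tables[0]
    stat_cols = set(value_cols) | set(sigma_cols)
    key_cols = [c for c in range(ref.shape[1]) if c not in stat_cols]
    for k, tab in enumerate(tables[1:], start=1):
        if tab.shape != ref.shape:
            raise FormatError(
                f"{files[k]}: {tab.shape[0]} rows, expected {ref.shape[0]}"
            )
        diff = np.nonzero(tab[:, key_cols] != ref[:, key_cols])
        if diff[0].size:
            raise FormatError(
                f"{files[k]}: key mismatch first at row {int(diff[0][0])}"
            )
    total = sum(histories)
    weights = np.asarray(histories, dtype=float) / total
    merged = ref.copy()
    for vc, sc in zip(value_cols, sigma_cols):
        merged[:, vc] = sum(w * t[:, vc] for w, t in zip(weights, tables))
        merged[:, sc] = np.sqrt(sum((w * t[:, sc]) ** 2 for w, t in zip(weights, tables)))
    if out_path is not None:
        np.savetxt(out_path, merged, fmt="%.9g")
    return merged


# --------------------------------------------------------------------------
# Phase-space files (simplified IAEA-style dialect: text header sidecar +
# packed little-endian float32 records)

PHSP_FIELDS = ("type", "E", "x", "y", "z", "u", "v", "w", "wt")
_PHSP_MAGIC = "$RTMC_PHSP v1"


@dataclass
class PhaseSpace:
    """Particle records plus the original-history counter of their source."""

    n_original_histories: int
    records: np.ndarray  # (n, n_fields) float32
    fields: tuple[str, ...] = PHSP_FIELDS

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=np.float32).reshape(
            (-1, len(self.fields))
        )
        if self.records.size:
            i = {f: k for k, f in enumerate(self.fields)}
            norms = np.sqrt(
                self.records[:, i["u"]] ** 2
                + self.records[:, i["v"]] ** 2
                + self.records[:, i["w"]] ** 2
            )
            if np.any(np.abs(norms - 1.0) > 1e-5):
                raise ValueError("direction cosines are not unit-norm")

    @property
    def n_particles(self) -> int:
        return self.records.shape[0]


def _phsp_paths(path) -> tuple[Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix == ".phsp" else p
    return stem.with_suffix(".phsp"), stem.with_suffix(".header")


def write_phsp(phsp: PhaseSpace, path) -> None:
    """Write ``<stem>.phsp`` (binary records) + ``<stem>.header`` (text)."""
    bin_path, hdr_path = _phsp_paths(path)
    hdr_path.write_text(
        f"{_PHSP_MAGIC}\n"
        f"$ORIG_HISTORIES: {phsp.n_original_histories}\n"
        f"$PARTICLES: {phsp.n_particles}\n"
        f"$RECORD_FIELDS: {' '.join(phsp.fields)}\n"
        "$RECORD_DTYPE: float32-le\n"
        "$END_HEADER\n"
    )
    bin_path.write_bytes(np.ascontiguousarray(phsp.records, dtype="<f4").tobytes())


def read_phsp(path) -> PhaseSpace:
    bin_path, hdr_path = _phsp_paths(path)
    lines = hdr_path.read_text().splitlines()
    if not lines or lines[0] != _PHSP_MAGIC:
        raise FormatError(f"{hdr_path}: not an rtmc phase-space header")
    meta = {}
    for ln in lines[1:]:
        if ln == "$END_HEADER":
            break
        key, _, val = ln.partition(":")
        meta[key.strip("$ ")] = val.strip()
    fields = tuple(meta["RECORD_FIELDS"].split())
    raw = np.frombuffer(bin_path.read_bytes(), dtype="<f4")
    if raw.size % len(fields):
        raise FormatError(f"{bin_path}: byte count not a multiple of the record size")
    records = raw.reshape((-1, len(fields)))
    n = int(meta["PARTICLES"])
    if records.shape[0] != n:
        raise FormatError(
            f"{bin_path}: header declares {n} particles, file holds {records.shape[0]}"
        )
    return PhaseSpace(
        n_original_histories=int(meta["ORIG_HISTORIES"]),
        records=records,
        fields=fields,
    )


def merge_phsp(files: list, out_path=None) -> PhaseSpace:
    """Concatenate phase spaces; original-history counters are summed."""
    if not files:
        raise ValueError("no phase spaces to merge")
    parts = [read_phsp(f) for f in files]
    fields = parts[0].fields
    for f, p in zip(files, parts):
        if p.fields != fields:
            raise FormatError(
                f"{f}: record layout {p.fields} differs from {fields}"
            )
    merged = PhaseSpace(
        n_original_histories=sum(p.n_original_histories for p in parts),
        records=np.concatenate([p.records for p in parts], axis=0)
        if parts
        else np.empty((0, len(fields)), dtype=np.float32),
        fields=fields,
    )
    if out_path is not None:
        write_phsp(merged, out_path)
    return merged


# --------------------------------------------------------------------------
# Region uncertainty metric


def region_uncertainty(grid: DoseGrid, mask: np.ndarray, k: float = 2.0) -> float:
    """Mean relative uncertainty (percent, coverage factor ``k``) in a region.

    Only voxels receiving more than half the maximum dose inside the mask
    contribute, which is the usual convention for quoting the statistical
    uncertainty of an MC dose distribution in a target volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.dose.shape:
        raise ValueError("mask shape does not match the dose grid")
    if not mask.any():
        raise EvaluationError("empty mask")
    dmax = float(grid.dose[mask].max())
    if dmax <= 0:
        raise EvaluationError("no positive dose inside the mask")
    sel = mask & (grid.dose > 0.5 * dmax)
    rel = grid.sigma[sel] / grid.dose[sel]
    return float(100.0 * k * rel.mean())
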