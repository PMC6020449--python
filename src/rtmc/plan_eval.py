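"""Dose export/import, structure rasterization and DVH evaluation.

The merged Monte Carlo dose grid is written as a DICOM RTDOSE object
(32-bit unsigned pixels with a ``DoseGridScaling`` factor) so any external
evaluation tool can read it; structures from an RTSTRUCT are rasterized
onto the dose grid by the even-odd (parity) rule at voxel centers, and
cumulative dose-volume histograms with standard point metrics (Dmean, Dmax,
D95, V_x) are computed from the masked voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import EvaluationError, FormatError
from .reducer import DoseGrid

__all__ = [
    "Structure",
    "StructureSet",
    "DVHCurve",
    "export_rtdose",
    "read_rtdose",
    "read_rtstruct",
    "rasterize_structure",
    "cumulative_dvh",
    "dose_metrics",
]

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


@dataclass
class Structure:
    """One named structure: a list of closed planar contours (mm, LPS)."""

    name: str
    contours: list[np.ndarray]  # each (n_points, 3), constant z per contour

    def __post_init__(self) -> None:
        for c in self.contours:
            if c.shape[0] < 3:
                raise ValueError(f"{self.name}: contour with fewer than 3 vertices")
            if np.ptp(c[:, 2]) > 1e-3:
                raise ValueError(f"{self.name}: contour not coplanar in z")


@dataclass
class StructureSet:
    structures: dict[str, Structure] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Structure:
        return self.structures[name]

    def names(self) -> list[str]:
        return list(self.structures)


@dataclass
class DVHCurve:
    """Cumulative DVH: percent volume receiving at least each bin-edge dose."""

    bin_edges: np.ndarray  # Gy, uniform width, starts at 0
    volume_fraction: np.ndarray  # percent, same length as bin_edges

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


# --------------------------------------------------------------------------
# RTDOSE


def export_rtdose(
    grid: DoseGrid,
    path,
    dose_scale: float = 1.0,
    zero_scale_floor: float = 1e-12,
    patient_id: str = "",
) -> None:
    """Write the dose grid as a DICOM RTDOSE file.

    ``dose_scale`` converts the grid's per-history dose to Gy (the absolute
    calibration, Gy/history times total MU, is a single multiplicative
    constant).  Pixels are 32-bit unsigned with ``DoseGridScaling =
    max(dose) / (2**32 - 1)`` so quantization stays far below MC noise.
    """
    dose = np.asarray(grid.dose, dtype=np.float64) * dose_scale
    if not np.all(np.isfinite(dose)):
        raise EvaluationError("dose grid contains NaN or infinite values")
    if np.any(dose < 0):
        raise EvaluationError("dose grid contains negative values")
    maxdose = float(dose.max())
    scaling = maxdose / (2**32 - 1) if maxdose > 0 else zero_scale_floor
    pixels = np.round(dose / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    nx, ny, nz = grid.dims
    dx, dy, dz = grid.spacing_mm
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [dy, dx]  # row spacing, column spacing
    ds.ImagePositionPatient = list(grid.origin_mm)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(k * dz) for k in range(nz)]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseGridScaling = scaling
    # frames are z-major, rows are y, columns are x
    frames = np.transpose(pixels, (2, 1, 0))  # (nz, ny, nx)
    ds.PixelData = np.ascontiguousarray(frames, dtype="<u4").tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_rtdose(path) -> DoseGrid:
    """Read an RTDOSE file back into a DoseGrid (sigma absent -> zeros)."""
    ds = pydicom.dcmread(path, force=True)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError(f"{path}: modality {getattr(ds, 'Modality', None)!r}, expected RTDOSE")
    if not hasattr(ds, "GridFrameOffsetVector"):
        raise FormatError(f"{path}: missing GridFrameOffsetVector (3004,000C)")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if offsets.size > 1:
        gaps = np.diff(offsets)
        dz = float(gaps.mean())
        if np.any(np.abs(gaps - dz) > 0.01 * abs(dz)):
            raise FormatError(f"{path}: non-uniform GridFrameOffsetVector")
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    dy, dx = (float(v) for v in ds.PixelSpacing)
    scaling = float(ds.DoseGridScaling)
    frames = ds.pixel_array  # (nz, ny, nx) or (ny, nx)
    if frames.ndim == 2:
        frames = frames[None, ...]
    dose = np.transpose(frames.astype(np.float64) * scaling, (2, 1, 0))
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    origin = (origin[0], origin[1], origin[2] + float(offsets[0]))
    return DoseGrid(
        dose=dose,
        sigma=np.zeros_like(dose),
        spacing_mm=(dx, dy, dz),
        origin_mm=origin,
        histories=1,
        unit="Gy",
        sigma_present=False,
    )


# --------------------------------------------------------------------------
# RTSTRUCT


def read_rtstruct(path) -> StructureSet:
    ds = pydicom.dcmread(path, force=True)
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise FormatError(f"{path}: modality {getattr(ds, 'Modality', None)!r}, expected RTSTRUCT")
    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in getattr(ds, "StructureSetROISequence", [])
    }
    out = StructureSet()
    for roi in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(roi.ReferencedROINumber), f"ROI{roi.ReferencedROINumber}")
        contours = []
        for c in getattr(roi, "ContourSequence", []):
            pts = np.asarray([float(v) for v in c.ContourData]).reshape((-1, 3))
            contours.append(pts)
        if contours:
            out.structures[name] = Structure(name=name, contours=contours)
    return out


def rasterize_structure(structure: Structure, grid: DoseGrid) -> np.ndarray:
    """Voxel-center mask of a structure on the dose grid (even-odd rule).

    Each contour is assigned to the nearest dose slice within half a slice
    spacing; on a slice, a voxel center is inside if an odd number of that
    slice's contours contain it, so nested contours subtract (holes).
    """
    nx, ny, nz = grid.dims
    dx, dy, dz = grid.spacing_mm
    ox, oy, oz = grid.origin_mm
    xs = ox + dx * np.arange(nx)
    ys = oy + dy * np.arange(ny)
    zs = oz + dz * np.arange(nz)
    pts = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    mask = np.zeros((nx, ny, nz), dtype=bool)
    assigned = 0
    for contour in structure.contours:
        zc = float(contour[:, 2].mean())
        k = int(np.round((zc - oz) / dz))
        if k < 0 or k >= nz or abs(zc - zs[k]) > dz / 2 + 1e-9:
            continue
        assigned += 1
        poly = MplPath(contour[:, :2])
        inside = poly.contains_points(pts).reshape(nx, ny)
        mask[:, :, k] ^= inside  # parity across contours of the same slice
    if assigned == 0:
        import warnings

        warnings.warn(
            f"structure {structure.name!r} does not overlap the dose grid z range"
        )
    return mask


# --------------------------------------------------------------------------
# DVH


def cumulative_dvh(grid: DoseGrid, mask: np.ndarray, bin_width_gy: float = 0.01) -> DVHCurve:
    """Cumulative DVH over the masked voxels (uniform voxel volume)."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EvaluationError("empty structure mask")
    doses = grid.dose[mask].ravel()
    dmax = float(doses.max())
    n_bins = int(np.ceil(dmax / bin_width_gy)) + 2
    edges = bin_width_gy * np.arange(n_bins + 1)
    frac = 100.0 * (doses[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(bin_edges=edges, volume_fraction=frac)


def dose_metrics(curve: DVHCurve, v_at: tuple[float, ...] = ()) -> dict:
    """Standard DVH point metrics with linear interpolation between bins.

    Returns Dmax, Dmean (from the differential of the curve), D95 (the
    highest dose still covering 95% of the volume) and ``V_x`` for each
    requested dose level ``x`` (clamped, with a flag, outside the curve).
    """
    edges = curve.bin_edges
    vf = curve.volume_fraction
    # differential volume per bin, at bin centers
    dv = vf[:-1] - vf[1:]
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = dv.sum()
    dmean = float((dv * centers).sum() / total) if total > 0 else 0.0
    nz = np.nonzero(vf > 0)[0]
    dmax = float(edges[nz[-1]]) if nz.size else 0.0

    def d_at(level_pct: float) -> float:
        ok = np.nonzero(vf >= level_pct)[0]
        return float(edges[ok[-1]]) if ok.size else 0.0

    out = {"Dmax": dmax, "Dmean": dmean, "D95": d_at(95.0), "clamped": []}
    for x in v_at:
        if x < edges[0] or x > edges[-1]:
            out["clamped"].append(x)
            x_eff = min(max(x, edges[0]), edges[-1])
        else:
            x_eff = x
        out[f"V{x:g}"] = float(np.interp(x_eff, edges, vf))
    return out
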