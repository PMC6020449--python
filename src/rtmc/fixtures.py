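"""Synthetic DICOM fixture generation: CT series, RT plans, structure sets.

Three verification-case archetypes are emulated at desk scale with purely
geometric anatomy (a water cylinder in air, optional bone rod):

* ``MARC_HN`` — one rotational beam chopped into short beam-on arclets
  (default 4 degrees wide, centered every 8 degrees around a full circle);
* ``STEP_AND_SHOOT_PROSTATE`` — 25 control-point segments spread over
  seven fixed gantry incidences;
* ``STATIC_SBRT_LUNG`` — nine static conformal beams.

All content, including UIDs, is a deterministic function of the fixture
seed, so regenerated fixtures are byte-identical.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

__all__ = ["CaseKind", "FixtureSpec", "make_ct", "make_plan", "make_structset", "make_case"]

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"


class CaseKind(enum.Enum):
    MARC_HN = "MARC_HN"
    STEP_AND_SHOOT_PROSTATE = "STEP_AND_SHOOT_PROSTATE"
    STATIC_SBRT_LUNG = "STATIC_SBRT_LUNG"


@dataclass
class FixtureSpec:
    case_kind: CaseKind = CaseKind.MARC_HN
    dims: tuple[int, int, int] = (32, 32, 16)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 5.0)
    n_arclets: int = 45
    arclet_width_deg: float = 4.0
    arclet_spacing_deg: float = 8.0
    n_segments: int = 25
    n_incidences: int = 7
    n_beams: int = 9
    n_leaves: int = 10
    leaf_width_mm: float = 8.0
    cylinder_radius_mm: float = 50.0
    ptv_radius_mm: float = 20.0
    bone_insert: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        if any(n > 64 for n in self.dims):
            raise ValueError("fixture dims capped at 64 per axis (desk scale)")


def _uid(seed: int, *tags) -> str:
    h = hashlib.sha256(":".join(str(t) for t in (seed, *tags)).encode()).hexdigest()
    return "2.25." + str(int(h[:30], 16))


def _rng(spec: FixtureSpec, stream: str) -> np.random.Generator:
    h = hashlib.sha256(f"{spec.seed}:{stream}".encode()).digest()
    return np.random.Generator(np.random.PCG64(int.from_bytes(h[:8], "little")))


def _file_dataset(path, sop_class: str, sop_instance: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    ds.PatientID = "RTMC-FIXTURE"
    ds.PatientName = "RTMC^FIXTURE"
    ds.StudyInstanceUID = _uid(0, "study")
    return ds


# --------------------------------------------------------------------------
# CT series


def make_ct(spec: FixtureSpec, out_dir, z_positions=None) -> Path:
    """Write a synthetic CT series: water cylinder in air, optional bone rod.

    HU values are exact by construction (air -1000, water 0, bone +800).
    ``z_positions`` overrides slice z coordinates (fault-injection hook for
    non-uniform slice gaps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = spec.dims
    dx, dy, dz = spec.spacing_mm
    ox = -dx * (nx - 1) / 2.0
    oy = -dy * (ny - 1) / 2.0
    oz = -dz * (nz - 1) / 2.0
    if z_positions is None:
        z_positions = [oz + k * dz for k in range(nz)]

    xs = ox + dx * np.arange(nx)
    ys = oy + dy * np.arange(ny)
    r2 = xs[:, None] ** 2 + ys[None, :] ** 2
    hu_plane = np.where(r2 <= spec.cylinder_radius_mm**2, 0.0, -1000.0)
    if spec.bone_insert:
        hu_plane = np.where(r2 <= (spec.cylinder_radius_mm / 5.0) ** 2, 800.0, hu_plane)
    stored = (hu_plane + 1024.0).astype(np.uint16)  # intercept -1024, slope 1

    series_uid = _uid(spec.seed, "ct-series")
    for k, z in enumerate(z_positions):
        sop = _uid(spec.seed, "ct-slice", k)
        ds = _file_dataset(out_dir / f"ct_{k:03d}.dcm", _CT_SOP, sop)
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = _uid(spec.seed, "frame")
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [ox, oy, float(z)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.Rows = ny
        ds.Columns = nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = np.ascontiguousarray(stored.T, dtype="<u2").tobytes()  # (rows, cols)
        ds.save_as(out_dir / f"ct_{k:03d}.dcm", enforce_file_format=True)
    return out_dir


# --------------------------------------------------------------------------
# RT plan


def _bld_sequence(spec: FixtureSpec) -> list[Dataset]:
    """BeamLimitingDeviceSequence: jaws + MLCX with leaf boundaries."""
    half = spec.n_leaves * spec.leaf_width_mm / 2.0
    mlcx = Dataset()
    mlcx.RTBeamLimitingDeviceType = "MLCX"
    mlcx.NumberOfLeafJawPairs = spec.n_leaves
    mlcx.LeafPositionBoundaries = [
        -half + i * spec.leaf_width_mm for i in range(spec.n_leaves + 1)
    ]
    asymx = Dataset()
    asymx.RTBeamLimitingDeviceType = "ASYMX"
    asymx.NumberOfLeafJawPairs = 1
    asymy = Dataset()
    asymy.RTBeamLimitingDeviceType = "ASYMY"
    asymy.NumberOfLeafJawPairs = 1
    return [asymx, asymy, mlcx]


def _positions(jaws, mlc_a, mlc_b) -> list[Dataset]:
    out = []
    for kind, vals in (
        ("ASYMX", [jaws[0], jaws[1]]),
        ("ASYMY", [jaws[2], jaws[3]]),
        ("MLCX", list(mlc_a) + list(mlc_b)),
    ):
        item = Dataset()
        item.RTBeamLimitingDeviceType = kind
        item.LeafJawPositions = [f"{v:.4f}" for v in vals]
        out.append(item)
    return out


def _random_aperture(rng: np.random.Generator, spec: FixtureSpec):
    """A plausible random aperture: open central leaves, closed edge leaves."""
    n = spec.n_leaves
    open_lo = int(rng.integers(0, 3))
    open_hi = n - int(rng.integers(0, 3))
    a = np.zeros(n)
    b = np.zeros(n)
    for i in range(n):
        if open_lo <= i < open_hi:
            a[i] = -float(rng.uniform(10.0, 35.0))
            b[i] = float(rng.uniform(10.0, 35.0))
        else:  # closed leaf pair parked off-axis
            a[i] = b[i] = 40.0
    jaws = (float(a.min()) - 1.0, float(b.max()) + 1.0,
            -spec.n_leaves * spec.leaf_width_mm / 2.0,
            spec.n_leaves * spec.leaf_width_mm / 2.0)
    return jaws, a, b


def _control_point(index, weight, gantry, jaws, mlc_a, mlc_b, first: bool) -> Dataset:
    cp = Dataset()
    cp.ControlPointIndex = index
    cp.CumulativeMetersetWeight = f"{weight:.6f}"
    cp.GantryAngle = f"{gantry % 360.0:.4f}"
    if first:
        cp.BeamLimitingDeviceAngle = "0.0"
        cp.PatientSupportAngle = "0.0"
        cp.IsocenterPosition = ["0.0", "0.0", "0.0"]
        cp.GantryRotationDirection = "CW"
    cp.BeamLimitingDevicePositionSequence = _positions(jaws, mlc_a, mlc_b)
    return cp


def make_plan(spec: FixtureSpec, path) -> Path:
    """Write a DICOM RTPLAN for the spec's case kind.

    Control points follow the beam-on-run contract: nonzero cumulative
    weight increments while the beam is on, zero increments while only the
    machine moves.
    """
    rng = _rng(spec, "plan")
    path = Path(path)
    sop = _uid(spec.seed, "rtplan", spec.case_kind.value)
    ds = _file_dataset(path, _RTPLAN_SOP, sop)
    ds.Modality = "RTPLAN"
    ds.SeriesInstanceUID = _uid(spec.seed, "rtplan-series")
    ds.FrameOfReferenceUID = _uid(spec.seed, "frame")
    ds.RTPlanLabel = {
        CaseKind.MARC_HN: "MARC_HN",
        CaseKind.STEP_AND_SHOOT_PROSTATE: "SS_PROSTATE",
        CaseKind.STATIC_SBRT_LUNG: "SBRT_LUNG",
    }[spec.case_kind]
    ds.RTPlanGeometry = "PATIENT"

    beams: list[Dataset] = []
    refs: list[Dataset] = []

    def add_beam(number: int, cps: list[Dataset], meterset: float) -> None:
        beam = Dataset()
        beam.BeamNumber = number
        beam.BeamName = f"B{number}"
        beam.BeamType = "STATIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.SourceAxisDistance = "1000.0"
        beam.BeamLimitingDeviceSequence = _bld_sequence(spec)
        beam.NumberOfControlPoints = len(cps)
        beam.FinalCumulativeMetersetWeight = "1.0"
        beam.ControlPointSequence = cps
        beams.append(beam)
        ref = Dataset()
        ref.ReferencedBeamNumber = number
        ref.BeamMeterset = f"{meterset:.4f}"
        refs.append(ref)

    if spec.case_kind is CaseKind.STATIC_SBRT_LUNG:
        for b in range(spec.n_beams):
            gantry = b * 360.0 / spec.n_beams
            jaws, a, bk = _random_aperture(rng, spec)
            cps = [
                _control_point(0, 0.0, gantry, jaws, a, bk, first=True),
                _control_point(1, 1.0, gantry, jaws, a, bk, first=False),
            ]
            add_beam(b + 1, cps, float(rng.uniform(50.0, 150.0)))
    elif spec.case_kind is CaseKind.STEP_AND_SHOOT_PROSTATE:
        per_beam = [spec.n_segments // spec.n_incidences] * spec.n_incidences
        for i in range(spec.n_segments - sum(per_beam)):
            per_beam[i] += 1
        for b, n_seg in enumerate(per_beam):
            gantry = b * 360.0 / spec.n_incidences
            dw = rng.uniform(0.5, 1.5, size=n_seg)
            dw /= dw.sum()
            cps = []
            w = 0.0
            for k in range(n_seg):
                jaws, a, bk = _random_aperture(rng, spec)
                cps.append(
                    _control_point(2 * k, w, gantry, jaws, a, bk, first=(k == 0))
                )
                w += float(dw[k])
                cps.append(_control_point(2 * k + 1, min(w, 1.0), gantry, jaws, a, bk, False))
            cps[-1].CumulativeMetersetWeight = "1.0"
            add_beam(b + 1, cps, float(rng.uniform(80.0, 200.0)))
    elif spec.case_kind is CaseKind.MARC_HN:
        n = spec.n_arclets
        dw = rng.uniform(0.5, 1.5, size=n)
        dw /= dw.sum()
        half = spec.arclet_width_deg / 2.0
        cps = []
        w = 0.0
        cp_index = 0
        for k in range(n):
            center = k * spec.arclet_spacing_deg
            jaws, a, bk = _random_aperture(rng, spec)
            cps.append(
                _control_point(cp_index, w, center - half, jaws, a, bk, first=(k == 0))
            )
            cp_index += 1
            w = min(w + float(dw[k]), 1.0)
            cps.append(_control_point(cp_index, w, center + half, jaws, a, bk, False))
            cp_index += 1
            if k < n - 1:  # beam-off travel to the next arclet start
                nxt = (k + 1) * spec.arclet_spacing_deg - half
                cps.append(_control_point(cp_index, w, nxt, jaws, a, bk, False))
                cp_index += 1
        cps[-1].CumulativeMetersetWeight = "1.0"
        add_beam(1, cps, float(rng.uniform(300.0, 600.0)))
    else:  # pragma: no cover
        raise ValueError(spec.case_kind)

    ds.BeamSequence = beams
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(beams)
    fg.ReferencedBeamSequence = refs
    ds.FractionGroupSequence = [fg]
    ds.save_as(path, enforce_file_format=True)
    return path


# --------------------------------------------------------------------------
# RT structure set


def make_structset(spec: FixtureSpec, path, n_vertices: int = 72) -> Path:
    """Write an RTSTRUCT with a cylindrical PTV of known analytic volume.

    The PTV is a cylinder of radius ``ptv_radius_mm`` centered on the
    isocenter spanning the central half of the CT z range; one closed
    circular contour per covered slice.
    """
    path = Path(path)
    nx, ny, nz = spec.dims
    dz = spec.spacing_mm[2]
    oz = -dz * (nz - 1) / 2.0
    ks = [k for k in range(nz) if abs(oz + k * dz) <= dz * nz / 4.0]

    sop = _uid(spec.seed, "rtstruct")
    ds = _file_dataset(path, _RTSTRUCT_SOP, sop)
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = _uid(spec.seed, "rtstruct-series")
    ds.StructureSetLabel = "FIXTURE"
    roi = Dataset()
    roi.ROINumber = 1
    roi.ROIName = "PTV"
    roi.ReferencedFrameOfReferenceUID = _uid(spec.seed, "frame")
    roi.ROIGenerationAlgorithm = "AUTOMATIC"
    ds.StructureSetROISequence = [roi]

    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    contour_items = []
    for k in ks:
        z = oz + k * dz
        pts = np.column_stack(
            [
                spec.ptv_radius_mm * np.cos(theta),
                spec.ptv_radius_mm * np.sin(theta),
                np.full(n_vertices, z),
            ]
        )
        item = Dataset()
        item.ContourGeometricType = "CLOSED_PLANAR"
        item.NumberOfContourPoints = n_vertices
        item.ContourData = [f"{v:.4f}" for v in pts.ravel()]
        contour_items.append(item)
    rc = Dataset()
    rc.ReferencedROINumber = 1
    rc.ContourSequence = contour_items
    ds.ROIContourSequence = [rc]
    ds.save_as(path, enforce_file_format=True)
    return path


def make_case(spec: FixtureSpec, out_dir) -> dict:
    """Generate CT + RTPLAN + RTSTRUCT for one case under ``out_dir``."""
    out_dir = Path(out_dir)
    ct_dir = make_ct(spec, out_dir / "ct")
    plan = make_plan(spec, out_dir / "rtplan.dcm")
    struct = make_structset(spec, out_dir / "rtstruct.dcm")
    return {"ct_dir": ct_dir, "rtplan": plan, "rtstruct": struct}
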