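"""RT plan parsing and discretization into MC-calculable static beams.

A treatment plan read from a DICOM RTPLAN is reduced to an ordered list of
:class:`StaticBeam` records, each of which a Monte Carlo engine can compute
independently: static and step-and-shoot plans map segment-by-segment, while
mArc plans (a rotational delivery chopped into short beam-on "arclets") map
each arclet to a static beam placed at the arclet's central gantry angle and
carrying the monitor units delivered during the arclet.

Control-point contract
----------------------
A beam-on interval is a maximal run of consecutive control points joined by
nonzero cumulative-meterset-weight increments.  Static and step-and-shoot
beams therefore encode one segment per beam-on control-point pair; an mArc
beam encodes arclets as beam-on runs separated by zero-increment gaps during
which the gantry keeps rotating with the beam held off.  Angles follow the
IEC 61217 convention as stored in DICOM and are normalized to [0, 360);
positions are DICOM patient (LPS) coordinates in mm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pydicom

from .errors import FormatError, PlanContentError, UnsupportedTechniqueError

__all__ = [
    "Technique",
    "ControlPoint",
    "BeamRecord",
    "TreatmentPlan",
    "StaticBeam",
    "Arclet",
    "parse_rtplan",
    "discretize_plan",
    "plan_from_beams",
    "circular_midpoint",
]


class Technique(enum.Enum):
    STATIC = "STATIC"
    STEP_AND_SHOOT = "STEP_AND_SHOOT"
    MARC = "MARC"


def _norm_angle(a: float) -> float:
    """Normalize an angle in degrees to [0, 360)."""
    a = float(a) % 360.0
    return a if a != 360.0 else 0.0


def circular_midpoint(start_deg: float, end_deg: float) -> float:
    """Midpoint of the arc travelled from ``start_deg`` to ``end_deg``.

    The arc is taken in the direction of increasing angle (mod 360), so an
    arclet spanning 358 -> 2 degrees has midpoint 0.
    """
    s = _norm_angle(start_deg)
    width = (_norm_angle(end_deg) - s) % 360.0
    return _norm_angle(s + width / 2.0)


@dataclass(frozen=True)
class ControlPoint:
    """State of the machine at one plan control point."""

    cum_weight: float
    gantry_deg: float
    collimator_deg: float
    table_deg: float
    isocenter_mm: tuple[float, float, float]
    jaws_mm: tuple[float, float, float, float]  # X1, X2, Y1, Y2
    mlc_a_mm: tuple[float, ...]
    mlc_b_mm: tuple[float, ...]


@dataclass
class BeamRecord:
    beam_id: str
    meterset_mu: float
    control_points: list[ControlPoint]

    def beam_on_runs(self) -> list[tuple[int, int]]:
        """Maximal runs (i, j) of control points with nonzero weight increments."""
        cps = self.control_points
        runs: list[tuple[int, int]] = []
        i = 0
        while i < len(cps) - 1:
            if cps[i + 1].cum_weight > cps[i].cum_weight:
                j = i + 1
                while j < len(cps) - 1 and cps[j + 1].cum_weight > cps[j].cum_weight:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        return runs

    def segments(self) -> list[tuple[int, int]]:
        """Consecutive control-point pairs with nonzero weight increment."""
        cps = self.control_points
        return [
            (i, i + 1)
            for i in range(len(cps) - 1)
            if cps[i + 1].cum_weight > cps[i].cum_weight
        ]


@dataclass
class TreatmentPlan:
    technique: Technique
    beams: list[BeamRecord]
    patient_id: str = ""

    @property
    def total_mu(self) -> float:
        """Total deliverable monitor units of the plan.

        Computed as the exact float sum over the plan's deliverable
        segments (or arclets), the same decomposition ``discretize_plan``
        emits, so MU conservation under discretization is bit-exact; each
        beam's segment MUs themselves sum to the beam meterset (the last
        segment absorbs the float residual).
        """
        return math.fsum(
            mu for beam in self.beams for mu in _beam_mus(beam, self.technique)
        )

    @property
    def n_segments(self) -> int:
        return sum(len(b.segments()) for b in self.beams)


@dataclass
class StaticBeam:
    """One static, MC-calculable beam: fixed geometry plus monitor units."""

    beam_id: str
    gantry_deg: float
    collimator_deg: float
    table_deg: float
    isocenter_mm: tuple[float, float, float]
    jaws_mm: tuple[float, float, float, float]
    mlc_a_mm: tuple[float, ...]
    mlc_b_mm: tuple[float, ...]
    mu: float

    def __post_init__(self) -> None:
        self.gantry_deg = _norm_angle(self.gantry_deg)
        if self.mu < 0:
            raise ValueError(f"negative MU ({self.mu}) in beam {self.beam_id!r}")
        x1, x2, y1, y2 = self.jaws_mm
        if x1 > x2 or y1 > y2:
            raise ValueError(f"inverted jaws {self.jaws_mm} in beam {self.beam_id!r}")
        if len(self.mlc_a_mm) != len(self.mlc_b_mm):
            raise ValueError("MLC banks have different leaf counts")
        for a, b in zip(self.mlc_a_mm, self.mlc_b_mm):
            if a > b + 1e-9:
                raise ValueError("crossed MLC leaf pair (bank A beyond bank B)")

    def to_dict(self) -> dict:
        return {
            "beam_id": self.beam_id,
            "gantry_deg": self.gantry_deg,
            "collimator_deg": self.collimator_deg,
            "table_deg": self.table_deg,
            "isocenter_mm": list(self.isocenter_mm),
            "jaws_mm": list(self.jaws_mm),
            "mlc_a_mm": list(self.mlc_a_mm),
            "mlc_b_mm": list(self.mlc_b_mm),
            "mu": self.mu,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StaticBeam":
        return cls(
            beam_id=d["beam_id"],
            gantry_deg=d["gantry_deg"],
            collimator_deg=d["collimator_deg"],
            table_deg=d["table_deg"],
            isocenter_mm=tuple(d["isocenter_mm"]),
            jaws_mm=tuple(d["jaws_mm"]),
            mlc_a_mm=tuple(d["mlc_a_mm"]),
            mlc_b_mm=tuple(d["mlc_b_mm"]),
            mu=d["mu"],
        )


@dataclass(frozen=True)
class Arclet:
    """A short beam-on gantry arc with a fixed aperture."""

    start_deg: float
    end_deg: float
    mu: float
    jaws_mm: tuple[float, float, float, float]
    mlc_a_mm: tuple[float, ...]
    mlc_b_mm: tuple[float, ...]

    @property
    def central_deg(self) -> float:
        return circular_midpoint(self.start_deg, self.end_deg)

    @property
    def width_deg(self) -> float:
        return (_norm_angle(self.end_deg) - _norm_angle(self.start_deg)) % 360.0


# --------------------------------------------------------------------------
# DICOM parsing


def _read_jaws_mlc(cp_ds, n_leaves_hint=None):
    jaws = None
    mlc_a = mlc_b = None
    for item in getattr(cp_ds, "BeamLimitingDevicePositionSequence", []):
        kind = item.RTBeamLimitingDeviceType
        pos = [float(v) for v in item.LeafJawPositions]
        if kind in ("X", "ASYMX"):
            jx = (pos[0], pos[1])
        elif kind in ("Y", "ASYMY"):
            jy = (pos[0], pos[1])
        elif kind in ("MLCX", "MLCY"):
            n = len(pos) // 2
            mlc_a = tuple(pos[:n])
            mlc_b = tuple(pos[n:])
    try:
        jaws = (jx[0], jx[1], jy[0], jy[1])
    except UnboundLocalError:
        jaws = None
    return jaws, mlc_a, mlc_b


def parse_rtplan(path) -> TreatmentPlan:
    """Read a DICOM RTPLAN and classify its delivery technique.

    Per-segment monitor units follow DICOM semantics: the increment of the
    cumulative meterset weight across a segment, times the beam meterset
    from the fraction group.
    """
    ds = pydicom.dcmread(path, force=True)
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise FormatError(f"{path}: modality {getattr(ds, 'Modality', None)!r}, expected RTPLAN")
    if not hasattr(ds, "BeamSequence"):
        raise PlanContentError(f"{path}: missing BeamSequence (300A,00B0)")

    metersets: dict[str, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[str(rb.ReferencedBeamNumber)] = float(getattr(rb, "BeamMeterset", 0.0))

    beams: list[BeamRecord] = []
    for beam_ds in ds.BeamSequence:
        beam_num = str(beam_ds.BeamNumber)
        if not hasattr(beam_ds, "ControlPointSequence"):
            raise PlanContentError(
                f"beam {beam_num}: missing ControlPointSequence (300A,0111)"
            )
        final_w = float(getattr(beam_ds, "FinalCumulativeMetersetWeight", 1.0)) or 1.0
        cps: list[ControlPoint] = []
        # Geometry attributes may be given only at the first control point
        # and inherited afterwards (standard DICOM-RT behaviour).
        gantry = coll = table = 0.0
        iso = (0.0, 0.0, 0.0)
        jaws = None
        mlc_a = mlc_b = None
        for cp_ds in beam_ds.ControlPointSequence:
            if hasattr(cp_ds, "GantryAngle"):
                gantry = float(cp_ds.GantryAngle)
            if hasattr(cp_ds, "BeamLimitingDeviceAngle"):
                coll = float(cp_ds.BeamLimitingDeviceAngle)
            if hasattr(cp_ds, "PatientSupportAngle"):
                table = float(cp_ds.PatientSupportAngle)
            if hasattr(cp_ds, "IsocenterPosition"):
                iso = tuple(float(v) for v in cp_ds.IsocenterPosition)
            j, a, b = _read_jaws_mlc(cp_ds)
            if j is not None:
                jaws = j
            if a is not None:
                mlc_a, mlc_b = a, b
            if jaws is None:
                raise PlanContentError(
                    f"beam {beam_num}: no jaw positions "
                    "(BeamLimitingDevicePositionSequence, 300A,011A)"
                )
            if mlc_a is None:
                raise PlanContentError(
                    f"beam {beam_num}: no MLC positions (MLCX in 300A,011A)"
                )
            cps.append(
                ControlPoint(
                    cum_weight=float(cp_ds.CumulativeMetersetWeight) / final_w,
                    gantry_deg=_norm_angle(gantry),
                    collimator_deg=_norm_angle(coll),
                    table_deg=_norm_angle(table),
                    isocenter_mm=iso,
                    jaws_mm=jaws,
                    mlc_a_mm=mlc_a,
                    mlc_b_mm=mlc_b,
                )
            )
        weights = [cp.cum_weight for cp in cps]
        if any(b < a - 1e-12 for a, b in zip(weights, weights[1:])):
            raise PlanContentError(f"beam {beam_num}: cumulative weights decrease")
        beams.append(BeamRecord(beam_num, metersets.get(beam_num, 0.0), cps))

    technique = _classify(beams)
    return TreatmentPlan(
        technique=technique,
        beams=beams,
        patient_id=str(getattr(ds, "PatientID", "")),
    )


def _classify(beams: list[BeamRecord]) -> Technique:
    rotating = any(
        len({cp.gantry_deg for cp in b.control_points}) > 1 for b in beams
    )
    if rotating:
        return Technique.MARC
    if any(len(b.segments()) > 1 for b in beams):
        return Technique.STEP_AND_SHOOT
    return Technique.STATIC


# --------------------------------------------------------------------------
# Discretization


def _segment_mus(meterset: float, dws: list[float]) -> list[float]:
    """MU per segment with the residual folded into the last segment.

    Summing ``meterset * dw`` naively can drift by a few ulps away from the
    beam meterset; assigning the last segment its residual makes the sum
    exact bit-for-bit whenever the weight increments span the full delivery.
    """
    if not dws:
        return []
    total_dw = math.fsum(dws)
    mus = [meterset * dw for dw in dws[:-1]]
    if abs(total_dw - 1.0) < 1e-9:
        mus.append(meterset - math.fsum(mus))
    else:  # partial delivery: no exactness anchor, scale the last one too
        mus.append(meterset * dws[-1])
    return mus


def _beam_mus(beam: BeamRecord, technique: Technique) -> list[float]:
    """Deliverable MU decomposition of one beam (segments or arclet runs)."""
    if technique is Technique.MARC:
        intervals = beam.beam_on_runs()
    else:
        intervals = beam.segments()
    dws = [
        beam.control_points[j].cum_weight - beam.control_points[i].cum_weight
        for i, j in intervals
    ]
    return _segment_mus(beam.meterset_mu, dws)


def extract_arclets(beam: BeamRecord) -> list[Arclet]:
    """Arclets of an mArc beam: one per maximal beam-on control-point run."""
    runs = beam.beam_on_runs()
    dws = [
        beam.control_points[j].cum_weight - beam.control_points[i].cum_weight
        for i, j in runs
    ]
    mus = _segment_mus(beam.meterset_mu, dws)
    arclets = []
    for (i, j), mu in zip(runs, mus):
        first = beam.control_points[i]
        width = (beam.control_points[j].gantry_deg - first.gantry_deg) % 360.0
        if width <= 0.0 or width >= 360.0:
            raise UnsupportedTechniqueError(
                f"beam {beam.beam_id}: beam-on run spans {width} degrees; "
                "not expressible as an arclet"
            )
        arclets.append(
            Arclet(
                start_deg=first.gantry_deg,
                end_deg=beam.control_points[j].gantry_deg,
                mu=mu,
                jaws_mm=first.jaws_mm,
                mlc_a_mm=first.mlc_a_mm,
                mlc_b_mm=first.mlc_b_mm,
            )
        )
    return arclets


def discretize_plan(plan: TreatmentPlan) -> list[StaticBeam]:
    """Transform a plan into the ordered list of static beams to simulate.

    Static and step-and-shoot plans yield one beam per deliverable segment
    with geometry copied verbatim; mArc plans yield one beam per arclet at
    the arclet central gantry angle with the arclet's MU.  The summed MU of
    the output equals the plan total MU exactly.
    """
    out: list[StaticBeam] = []
    if plan.technique in (Technique.STATIC, Technique.STEP_AND_SHOOT):
        for beam in plan.beams:
            segs = beam.segments()
            mus = _beam_mus(beam, plan.technique)
            for k, ((i, _j), mu) in enumerate(zip(segs, mus)):
                cp = beam.control_points[i]
                out.append(
                    StaticBeam(
                        beam_id=f"{beam.beam_id}.{k + 1}" if len(segs) > 1 else beam.beam_id,
                        gantry_deg=cp.gantry_deg,
                        collimator_deg=cp.collimator_deg,
                        table_deg=cp.table_deg,
                        isocenter_mm=cp.isocenter_mm,
                        jaws_mm=cp.jaws_mm,
                        mlc_a_mm=cp.mlc_a_mm,
                        mlc_b_mm=cp.mlc_b_mm,
                        mu=mu,
                    )
                )
    elif plan.technique is Technique.MARC:
        for beam in plan.beams:
            ref = beam.control_points[0]
            for k, arclet in enumerate(extract_arclets(beam)):
                out.append(
                    StaticBeam(
                        beam_id=f"{beam.beam_id}.{k + 1}",
                        gantry_deg=arclet.central_deg,
                        collimator_deg=ref.collimator_deg,
                        table_deg=ref.table_deg,
                        isocenter_mm=ref.isocenter_mm,
                        jaws_mm=arclet.jaws_mm,
                        mlc_a_mm=arclet.mlc_a_mm,
                        mlc_b_mm=arclet.mlc_b_mm,
                        mu=arclet.mu,
                    )
                )
    else:  # pragma: no cover - enum is closed
        raise UnsupportedTechniqueError(str(plan.technique))
    return out


def plan_from_beams(beams: list[StaticBeam]) -> TreatmentPlan:
    """Rebuild a (static) plan from discretized beams.

    Discretizing the rebuilt plan returns the same beams, which makes
    discretization idempotent.
    """
    records = []
    for sb in beams:
        cp0 = ControlPoint(
            cum_weight=0.0,
            gantry_deg=sb.gantry_deg,
            collimator_deg=sb.collimator_deg,
            table_deg=sb.table_deg,
            isocenter_mm=sb.isocenter_mm,
            jaws_mm=sb.jaws_mm,
            mlc_a_mm=sb.mlc_a_mm,
            mlc_b_mm=sb.mlc_b_mm,
        )
        cp1 = ControlPoint(
            cum_weight=1.0,
            gantry_deg=sb.gantry_deg,
            collimator_deg=sb.collimator_deg,
            table_deg=sb.table_deg,
            isocenter_mm=sb.isocenter_mm,
            jaws_mm=sb.jaws_mm,
            mlc_a_mm=sb.mlc_a_mm,
            mlc_b_mm=sb.mlc_b_mm,
        )
        records.append(BeamRecord(sb.beam_id, sb.mu, [cp0, cp1]))
    return TreatmentPlan(technique=Technique.STATIC, beams=records)
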