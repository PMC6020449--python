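"""Map phase: bind beam geometry into MC input templates and apportion work.

An MC model is a directory of text input files plus a table of parameter
descriptors saying *where* inside those files the tunable values live
(histories, random seeds, gantry/collimator/table angles, jaw and MLC
positions, paths).  ``distribute_work`` splits the beams of a discretized
plan over computing nodes — either evenly ("Equal") or proportionally to
each beam's monitor units ("MUWeighted") — and ``bind_parameters`` writes
one concrete input directory per node.
"""

from __future__ import annotations

import enum
import hashlib
import re
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import FormattingError, InfeasibleError, TemplateError
from .rtplan_model import StaticBeam

__all__ = [
    "DistributionMode",
    "ParameterKind",
    "ParameterDescriptor",
    "ParametrizedModel",
    "WorkItem",
    "largest_remainder",
    "distribute_work",
    "assign_seeds",
    "bind_parameters",
    "load_model",
]


class DistributionMode(enum.Enum):
    EQUAL = "EQUAL"
    MU_WEIGHTED = "MU_WEIGHTED"


class ParameterKind(enum.Enum):
    HISTORIES = "HISTORIES"
    TIME_LIMIT = "TIME_LIMIT"
    SEED1 = "SEED1"
    SEED2 = "SEED2"
    GANTRY = "GANTRY"
    COLLIMATOR = "COLLIMATOR"
    TABLE = "TABLE"
    ISOCENTER_X = "ISOCENTER_X"
    ISOCENTER_Y = "ISOCENTER_Y"
    ISOCENTER_Z = "ISOCENTER_Z"
    JAW_X1 = "JAW_X1"
    JAW_X2 = "JAW_X2"
    JAW_Y1 = "JAW_Y1"
    JAW_Y2 = "JAW_Y2"
    MLC_BANK_A = "MLC_BANK_A"
    MLC_BANK_B = "MLC_BANK_B"
    PHSP_PATH = "PHSP_PATH"
    OUTPUT_PATH = "OUTPUT_PATH"


_VECTOR_KINDS = {ParameterKind.MLC_BANK_A, ParameterKind.MLC_BANK_B}


@dataclass(frozen=True)
class ParameterDescriptor:
    """Location and format of one tunable parameter inside a template file.

    ``line``/``token`` are 1-based; alternatively ``placeholder`` names a
    literal marker string replaced wherever it occurs in the file.
    """

    file_name: str
    kind: ParameterKind
    line: int | None = None
    token: int | None = None
    placeholder: str | None = None
    fmt: str = "%s"

    def __post_init__(self) -> None:
        if self.placeholder is None and (self.line is None or self.token is None):
            raise ValueError("descriptor needs either (line, token) or a placeholder")


@dataclass
class ParametrizedModel:
    template_dir: Path
    descriptors: list[ParameterDescriptor]
    executable: list[str]
    output_spec: list[tuple[str, str]]  # (glob pattern, BINARY_DOSE|COLUMN_TEXT|IAEA_PHSP)
    layout: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.template_dir = Path(self.template_dir)
        if not self.output_spec:
            raise ValueError("output_spec must not be empty")
        for d in self.descriptors:
            if not (self.template_dir / d.file_name).is_file():
                raise TemplateError(
                    f"descriptor file {d.file_name!r} missing from {self.template_dir}"
                )


@dataclass
class WorkItem:
    node_id: int
    beam_id: str
    histories: int
    seeds: tuple[int, int]
    bound_dir: Path | None = None
    time_limit_s: float = -1.0

    def __post_init__(self) -> None:
        if self.histories <= 0:
            raise ValueError("work item needs histories > 0")


# --------------------------------------------------------------------------
# Apportionment


def largest_remainder(weights, total: int, floors=None) -> list[int]:
    """Hamilton (largest-remainder) integer apportionment with lower bounds.

    Quotas are ``total * w_i / sum(w)``; integer parts are assigned first and
    the leftover units go to the largest fractional remainders (ties to the
    lowest index).  Entries below their floor are then topped up by taking
    units, one at a time, from the entry with the largest surplus over its
    quota that still sits above its own floor (ties to the lowest index).
    """
    weights = [float(w) for w in weights]
    n = len(weights)
    floors = [0] * n if floors is None else list(floors)
    if sum(floors) > total:
        raise InfeasibleError(f"floors {floors} exceed total {total}")
    wsum = sum(weights)
    if wsum <= 0:
        quotas = [total / n] * n
    else:
        quotas = [total * w / wsum for w in weights]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    leftover = total - sum(counts)
    for i in sorted(range(n), key=lambda i: (-remainders[i], i))[:leftover]:
        counts[i] += 1
    # repair entries under their floor
    while True:
        deficits = [i for i in range(n) if counts[i] < floors[i]]
        if not deficits:
            break
        donor = max(
            (j for j in range(n) if counts[j] > floors[j]),
            key=lambda j: (counts[j] - quotas[j], -j),
        )
        counts[donor] -= 1
        counts[deficits[0]] += 1
    return counts


def distribute_work(
    beams: list[StaticBeam],
    n_nodes: int,
    mode: DistributionMode = DistributionMode.MU_WEIGHTED,
    total_histories: int = 10**6,
    master_seed: int = 1,
) -> list[WorkItem]:
    """Split the beams over ``n_nodes`` computing nodes.

    EQUAL gives every beam the same number of nodes (remainder to the
    earliest beams); MU_WEIGHTED apportions nodes proportionally to each
    beam's MU with a floor of one node per beam.  The total history budget
    follows the same weighting and is divided evenly across a beam's nodes
    with the remainder on its first node.  Node counts and histories are
    conserved exactly.
    """
    n_beams = len(beams)
    if n_beams == 0:
        raise InfeasibleError("no beams to distribute")
    if n_nodes < n_beams:
        raise InfeasibleError(
            f"{n_nodes} nodes < {n_beams} beams; every beam needs at least one node"
        )
    if total_histories < n_nodes:
        raise InfeasibleError("fewer histories than nodes")

    if mode is DistributionMode.EQUAL:
        base, extra = divmod(n_nodes, n_beams)
        nodes_per_beam = [base + (1 if i < extra else 0) for i in range(n_beams)]
        hist_weights = [1.0] * n_beams
    else:
        mus = [b.mu for b in beams]
        nodes_per_beam = largest_remainder(mus, n_nodes, floors=[1] * n_beams)
        hist_weights = mus
    hist_per_beam = largest_remainder(hist_weights, total_histories, floors=nodes_per_beam)

    seeds = assign_seeds(n_nodes, master_seed)
    items: list[WorkItem] = []
    node = 0
    for beam, n_b, h_b in zip(beams, nodes_per_beam, hist_per_beam):
        base, extra = divmod(h_b, n_b)
        for k in range(n_b):
            items.append(
                WorkItem(
                    node_id=node,
                    beam_id=beam.beam_id,
                    histories=base + (extra if k == 0 else 0),
                    seeds=seeds[node],
                )
            )
            node += 1
    return items


def assign_seeds(n_items: int, master_seed: int) -> list[tuple[int, int]]:
    """Derive ``n_items`` pairwise-distinct positive seed pairs.

    Counter-based: each candidate is SHA-256(master_seed, counter) reduced
    to 31 bits; collisions (astronomically rare) advance the counter, so the
    result is a pure function of ``master_seed``.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    seen: set[int] = set()
    values: list[int] = []
    counter = 0
    while len(values) < 2 * n_items:
        digest = hashlib.sha256(f"{master_seed}:{counter}".encode()).digest()
        v = (int.from_bytes(digest[:4], "little") & 0x7FFFFFFF) or 1
        counter += 1
        if v in seen:
            continue
        seen.add(v)
        values.append(v)
    return [(values[2 * i], values[2 * i + 1]) for i in range(n_items)]


# --------------------------------------------------------------------------
# Template binding

_TOKEN_RE = re.compile(r"\S+")
_FMT_RE = re.compile(r"^%([-+0 #]*)(\d+)?(?:\.(\d+))?([diouxXeEfFgGs])$")


def _format_value(fmt: str, value) -> str:
    m = _FMT_RE.match(fmt)
    if not m:
        raise FormattingError(f"unsupported format {fmt!r}")
    text = fmt % value
    width = m.group(2)
    if width is not None and len(text) > int(width):
        raise FormattingError(
            f"value {value!r} formatted as {text!r} exceeds width {width} of {fmt!r}"
        )
    return text


def _descriptor_value(desc, beam: StaticBeam, item: WorkItem, extra: dict):
    K = ParameterKind
    scalar = {
        K.HISTORIES: item.histories,
        K.TIME_LIMIT: item.time_limit_s,
        K.SEED1: item.seeds[0],
        K.SEED2: item.seeds[1],
        K.GANTRY: beam.gantry_deg,
        K.COLLIMATOR: beam.collimator_deg,
        K.TABLE: beam.table_deg,
        K.ISOCENTER_X: beam.isocenter_mm[0],
        K.ISOCENTER_Y: beam.isocenter_mm[1],
        K.ISOCENTER_Z: beam.isocenter_mm[2],
        K.JAW_X1: beam.jaws_mm[0],
        K.JAW_X2: beam.jaws_mm[1],
        K.JAW_Y1: beam.jaws_mm[2],
        K.JAW_Y2: beam.jaws_mm[3],
    }
    if desc.kind in scalar:
        return scalar[desc.kind]
    if desc.kind is K.MLC_BANK_A:
        return list(beam.mlc_a_mm)
    if desc.kind is K.MLC_BANK_B:
        return list(beam.mlc_b_mm)
    if desc.kind in (K.PHSP_PATH, K.OUTPUT_PATH):
        try:
            return extra[desc.kind.value]
        except KeyError:
            raise TemplateError(f"no value supplied for {desc.kind.value}") from None
    raise TemplateError(f"unhandled parameter kind {desc.kind}")  # pragma: no cover


def _substitute(text: str, desc: ParameterDescriptor, rendered: str, path_label: str) -> str:
    if desc.placeholder is not None:
        if desc.placeholder not in text:
            raise TemplateError(
                f"{path_label}: placeholder {desc.placeholder!r} not found"
            )
        return text.replace(desc.placeholder, rendered)
    lines = text.split("\n")
    if desc.line < 1 or desc.line > len(lines):
        raise TemplateError(f"{path_label}: line {desc.line} out of range")
    line = lines[desc.line - 1]
    tokens = list(_TOKEN_RE.finditer(line))
    if desc.token < 1 or desc.token > len(tokens):
        raise TemplateError(
            f"{path_label}: line {desc.line} has {len(tokens)} tokens, "
            f"token {desc.token} requested"
        )
    start = tokens[desc.token - 1].start()
    if desc.kind in _VECTOR_KINDS:
        lines[desc.line - 1] = line[:start] + rendered  # vector spans to end of line
    else:
        end = tokens[desc.token - 1].end()
        lines[desc.line - 1] = line[:start] + rendered + line[end:]
    return "\n".join(lines)


def bind_parameters(
    model: ParametrizedModel,
    beam: StaticBeam,
    item: WorkItem,
    dest_dir,
    extra: dict | None = None,
) -> Path:
    """Concretize the model templates for one work item.

    The template directory is copied to ``dest_dir`` and every descriptor's
    value is substituted in place; all other bytes are untouched.  All
    locators are resolved (and all values formatted) before any file is
    written, so a bad template leaves no partial output.
    """
    extra = extra or {}
    dest = Path(dest_dir)
    per_file: dict[str, list[tuple[ParameterDescriptor, str]]] = {}
    for desc in model.descriptors:
        value = _descriptor_value(desc, beam, item, extra)
        if desc.kind in _VECTOR_KINDS:
            rendered = " ".join(_format_value(desc.fmt, v) for v in value)
        else:
            rendered = _format_value(desc.fmt, value)
        per_file.setdefault(desc.file_name, []).append((desc, rendered))

    # dry-run every substitution against the pristine templates first
    staged: dict[str, str] = {}
    for fname, subs in per_file.items():
        text = (model.template_dir / fname).read_text()
        for desc, rendered in subs:
            text = _substitute(text, desc, rendered, fname)
        staged[fname] = text

    if dest.exists():
        shutil.rmtree(dest)
    shutil.copytree(model.template_dir, dest)
    for fname, text in staged.items():
        (dest / fname).write_text(text)
    item.bound_dir = dest
    return dest


# --------------------------------------------------------------------------
# Model manifest


def load_model(manifest_path) -> ParametrizedModel:
    """Load a model manifest (YAML).

    ``executable`` entries may contain ``{python}``, replaced with the
    running interpreter so bundled Python engines work without a PATH
    lookup.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    template_dir = manifest_path.parent / doc["template_dir"]
    descriptors = [
        ParameterDescriptor(
            file_name=d["file"],
            kind=ParameterKind(d["kind"]),
            line=d.get("line"),
            token=d.get("token"),
            placeholder=d.get("placeholder"),
            fmt=d.get("format", "%s"),
        )
        for d in doc.get("descriptors", [])
    ]
    executable = [str(part).replace("{python}", sys.executable) for part in doc["executable"]]
    output_spec = [(o["pattern"], o["format"]) for o in doc["output_spec"]]
    return ParametrizedModel(
        template_dir=template_dir,
        descriptors=descriptors,
        executable=executable,
        output_spec=output_spec,
        layout=doc.get("layout", {}),
    )
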