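"""Voxelized phantom construction from CT images.

A CT series is loaded into an :class:`ImageVolume` (HU on a regular grid,
LPS patient coordinates, mm), optionally resampled, and converted through a
user HU -> material/density table into a :class:`VoxelPhantom` that can be
written out as an EGS ``egsphant`` file or in the PenVox dialect documented
in ``docs/methods.md``.

Array convention: all 3-D arrays are indexed ``[ix, iy, iz]``; flattened
representations are x-fastest (Fortran order).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import yaml

from .errors import CapacityError, ConversionError, GeometryError, SeriesError

__all__ = [
    "ImageVolume",
    "HUConversionTable",
    "VoxelPhantom",
    "DEFAULT_TABLE",
    "load_ct_series",
    "resample_volume",
    "apply_conversion",
    "write_egsphant",
    "read_egsphant",
    "write_penvox",
    "read_penvox",
    "load_table",
]

# single-character material codes for egsphant maps: digits and letters
# first (the conventional codes), then the remaining printable ASCII
_EGS_CODES = (
    "123456789"
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "abcdefghijklmnopqrstuvwxyz"
    "!\"#$%&'()*+,-./0:;<=>?@[\\]^_`{|}~"
)
assert len(_EGS_CODES) == 94, len(_EGS_CODES)


@dataclass
class ImageVolume:
    """A scalar HU volume on a regular axis-aligned grid."""

    hu: np.ndarray  # (nx, ny, nz), float
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]  # center of voxel (0,0,0)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.dims, self.spacing_mm))


@dataclass
class HUConversionTable:
    """Contiguous HU bins -> material, plus piecewise-linear HU -> density."""

    material_bins: list[tuple[float, float, str, int]]  # (hu_low, hu_high, name, index)
    density_breakpoints: list[tuple[float, float]]  # (hu, g/cm3), increasing HU

    def __post_init__(self) -> None:
        bins = sorted(self.material_bins, key=lambda b: b[0])
        for (lo, hi, *_), (lo2, *_rest) in zip(bins, bins[1:]):
            if hi > lo2 + 1e-9 or hi < lo2 - 1e-9:
                raise ValueError("material bins must be contiguous and non-overlapping")
        hus = [h for h, _ in self.density_breakpoints]
        dens = [d for _, d in self.density_breakpoints]
        if any(b <= a for a, b in zip(hus, hus[1:])):
            raise ValueError("density breakpoints must be strictly increasing in HU")
        if any(d < 0 for d in dens):
            raise ValueError("densities must be nonnegative")
        self.material_bins = bins

    @property
    def material_names(self) -> dict[int, str]:
        return {idx: name for _lo, _hi, name, idx in self.material_bins}

    def density_of(self, hu: np.ndarray) -> np.ndarray:
        xs = np.asarray([h for h, _ in self.density_breakpoints], dtype=float)
        ys = np.asarray([d for _, d in self.density_breakpoints], dtype=float)
        return np.interp(np.asarray(hu, dtype=float), xs, ys)  # clamps outside range

    def material_of(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu, dtype=float)
        edges = np.asarray([b[0] for b in self.material_bins] + [self.material_bins[-1][1]])
        which = np.searchsorted(edges, hu, side="right") - 1
        # the top edge belongs to the last bin
        which[hu == edges[-1]] = len(self.material_bins) - 1
        bad = (which < 0) | (which >= len(self.material_bins))
        if np.any(bad):
            val = float(np.asarray(hu)[bad].flat[0])
            raise ConversionError(f"HU value {val} falls outside every material bin")
        idx = np.asarray([b[3] for b in self.material_bins])
        return idx[which]


#: Four-material table (air / lung / soft tissue / bone) used when the user
#: supplies none; breakpoints follow the usual bilinear HU-density ramp.
DEFAULT_TABLE = HUConversionTable(
    material_bins=[
        (-1100.0, -900.0, "AIR", 0),
        (-900.0, -200.0, "LUNG", 1),
        (-200.0, 250.0, "SOFT_TISSUE", 2),
        (250.0, 3100.0, "BONE", 3),
    ],
    density_breakpoints=[
        (-1000.0, 0.00121),
        (-800.0, 0.20),
        (-200.0, 0.95),
        (0.0, 1.00),
        (250.0, 1.10),
        (1000.0, 1.60),
        (3000.0, 2.90),
    ],
)


def load_table(path) -> HUConversionTable:
    """Load a HU conversion table from YAML.

    Expected keys: ``materials`` (list of ``[hu_low, hu_high, name, index]``)
    and ``density`` (list of ``[hu, g_per_cm3]``).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return HUConversionTable(
        material_bins=[(float(a), float(b), str(n), int(i)) for a, b, n, i in doc["materials"]],
        density_breakpoints=[(float(h), float(d)) for h, d in doc["density"]],
    )


@dataclass
class VoxelPhantom:
    """Material index + mass density per voxel on a regular grid."""

    material: np.ndarray  # (nx, ny, nz) int
    density: np.ndarray  # (nx, ny, nz) float, g/cm3
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    material_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.material.shape != self.density.shape:
            raise ValueError("material and density arrays differ in shape")
        if np.any(self.density < 0):
            raise ValueError("negative density in phantom")
        present = set(np.unique(self.material).tolist())
        missing = present - set(self.material_names)
        if missing:
            raise ValueError(f"material indices {sorted(missing)} have no name")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.material.shape

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return (dx / 10.0) * (dy / 10.0) * (dz / 10.0)

    def total_mass_g(self) -> float:
        return float(self.density.sum() * self.voxel_volume_cm3)


# --------------------------------------------------------------------------
# CT loading


def load_ct_series(directory) -> ImageVolume:
    """Load one CT series from a directory of DICOM slice files.

    Slices are sorted by the z component of ImagePositionPatient; stored
    values are rescaled to HU through RescaleSlope/RescaleIntercept.  All
    slices must share a SeriesInstanceUID and in-plane geometry, and slice
    gaps must be uniform to within 1%.
    """
    directory = Path(directory)
    slices = []
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        try:
            ds = pydicom.dcmread(p, force=True)
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "CT" and hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise SeriesError(f"{directory}: no readable CT slices")
    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in slices}
    if len(uids) != 1:
        raise SeriesError(f"{directory}: mixed series UIDs {sorted(uids)}")

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.asarray([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.any(gaps <= 0):
            raise GeometryError("slice positions not strictly monotone in z")
        if (gaps.max() - gaps.min()) > 0.01 * gaps.mean():
            raise GeometryError(
                f"non-uniform slice spacing: gaps range {gaps.min():g}..{gaps.max():g} mm"
            )
        dz = float(gaps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    first = slices[0]
    # PixelSpacing is (row, col) = (dy, dx)
    dy, dx = (float(v) for v in first.PixelSpacing)
    for ds in slices[1:]:
        if [float(v) for v in ds.PixelSpacing] != [dy, dx]:
            raise GeometryError("in-plane pixel spacing varies across slices")

    planes = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = ds.pixel_array.astype(np.float64) * slope + intercept
        planes.append(arr.T)  # (rows, cols) -> (x, y) with x = column index
    hu = np.stack(planes, axis=2)  # (nx, ny, nz)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return ImageVolume(hu=hu, spacing_mm=(dx, dy, dz), origin_mm=origin)


# --------------------------------------------------------------------------
# Resampling


def _overlap_matrix(n_old: int, d_old: float, n_new: int, d_new: float) -> np.ndarray:
    """Row-normalized fractional-overlap matrix mapping old to new voxels.

    Row i holds the fraction of new-voxel i covered by each old voxel along
    one axis.  Downsampling becomes a volume-weighted mean; a new voxel that
    lies entirely within one old voxel copies it (nearest / replication).
    """
    old_edges = np.arange(n_old + 1) * d_old
    new_edges = np.arange(n_new + 1) * d_new
    lo = np.maximum.outer(new_edges[:-1], old_edges[:-1])
    hi = np.minimum.outer(new_edges[1:], old_edges[1:])
    w = np.clip(hi - lo, 0.0, None)
    sums = w.sum(axis=1, keepdims=True)
    # a trailing new voxel may extend past the old extent; normalize by what
    # it actually covers
    sums[sums == 0.0] = 1.0
    return w / sums


def resample_volume(vol: ImageVolume, new_spacing_mm) -> ImageVolume:
    """Resample to a new voxel spacing, preserving the physical extent.

    Downsampling averages HU with volume-fraction weights; upsampling
    replicates the containing source voxel.  Requesting the identical
    spacing returns a bit-identical copy.
    """
    new_spacing = tuple(float(s) for s in new_spacing_mm)
    if any(s <= 0 for s in new_spacing):
        raise ValueError(f"non-positive target spacing {new_spacing}")
    if any(s > e for s, e in zip(new_spacing, vol.extent_mm)):
        raise GeometryError(
            f"target spacing {new_spacing} exceeds volume extent {vol.extent_mm}"
        )
    if new_spacing == tuple(float(s) for s in vol.spacing_mm):
        return ImageVolume(vol.hu.copy(), vol.spacing_mm, vol.origin_mm)

    dims_new = tuple(
        max(1, int(np.ceil(round(e / s, 9)))) for e, s in zip(vol.extent_mm, new_spacing)
    )
    out = vol.hu
    for axis in range(3):
        w = _overlap_matrix(vol.dims[axis], vol.spacing_mm[axis], dims_new[axis], new_spacing[axis])
        out = np.moveaxis(np.tensordot(w, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
    corner = tuple(o - 0.5 * s for o, s in zip(vol.origin_mm, vol.spacing_mm))
    origin_new = tuple(c + 0.5 * s for c, s in zip(corner, new_spacing))
    return ImageVolume(hu=out, spacing_mm=new_spacing, origin_mm=origin_new)


def apply_conversion(vol: ImageVolume, table: HUConversionTable | None = None) -> VoxelPhantom:
    """Map HU to material indices and mass densities through the table."""
    table = table or DEFAULT_TABLE
    material = table.material_of(vol.hu)
    density = table.density_of(vol.hu)
    return VoxelPhantom(
        material=material,
        density=density,
        spacing_mm=vol.spacing_mm,
        origin_mm=vol.origin_mm,
        material_names=table.material_names,
    )


# --------------------------------------------------------------------------
# egsphant writer/reader (EGS convention: boundaries in cm, density g/cm3)


def _compact_indices(phantom: VoxelPhantom) -> tuple[list[int], np.ndarray]:
    """Order the phantom's material indices and remap voxels to 0..m-1."""
    order = sorted(phantom.material_names)
    lut = {idx: k for k, idx in enumerate(order)}
    remapped = np.vectorize(lut.get, otypes=[int])(phantom.material)
    return order, remapped


def write_egsphant(phantom: VoxelPhantom, path) -> None:
    """Write the phantom in the standard egsphant text layout."""
    order, remapped = _compact_indices(phantom)
    if len(order) > len(_EGS_CODES):
        raise CapacityError(
            f"{len(order)} materials exceed the {len(_EGS_CODES)}-character egsphant code space"
        )
    nx, ny, nz = phantom.dims
    dx, dy, dz = (s / 10.0 for s in phantom.spacing_mm)  # mm -> cm
    ox, oy, oz = (o / 10.0 for o in phantom.origin_mm)
    buf = io.StringIO()
    buf.write(f"{len(order)}\n")
    for idx in order:
        buf.write(f"{phantom.material_names[idx]}\n")
    buf.write("  " + " ".join("0.25" for _ in order) + "\n")  # dummy ESTEPE
    buf.write(f"{nx} {ny} {nz}\n")
    for n, d, o in ((nx, dx, ox), (ny, dy, oy), (nz, dz, oz)):
        edges = o - d / 2.0 + d * np.arange(n + 1)
        buf.write(" ".join(f"{e:.6f}" for e in edges) + "\n")
    for iz in range(nz):
        for iy in range(ny):
            buf.write("".join(_EGS_CODES[remapped[ix, iy, iz]] for ix in range(nx)))
            buf.write("\n")
        buf.write("\n")
    for iz in range(nz):
        for iy in range(ny):
            buf.write(" ".join(f"{phantom.density[ix, iy, iz]:.8e}" for ix in range(nx)))
            buf.write("\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def read_egsphant(path) -> VoxelPhantom:
    lines = Path(path).read_text().splitlines()
    pos = 0

    def take() -> str:
        nonlocal pos
        while lines[pos].strip() == "":
            pos += 1
        line = lines[pos]
        pos += 1
        return line

    nmat = int(take().strip())
    names = [take().strip() for _ in range(nmat)]
    take()  # ESTEPE
    nx, ny, nz = (int(v) for v in take().split())
    edges = []
    vals: list[float] = []
    for n in (nx, ny, nz):
        vals = []
        while len(vals) < n + 1:
            vals.extend(float(v) for v in take().split())
        edges.append(np.asarray(vals))
    spacing = tuple(float(np.diff(e).mean()) * 10.0 for e in edges)  # cm -> mm
    origin = tuple(float(e[0] + np.diff(e).mean() / 2.0) * 10.0 for e in edges)

    material = np.empty((nx, ny, nz), dtype=int)
    for iz in range(nz):
        for iy in range(ny):
            row = take()
            material[:, iy, iz] = [_EGS_CODES.index(c) for c in row[:nx]]
    density = np.empty((nx, ny, nz), dtype=float)
    for iz in range(nz):
        for iy in range(ny):
            vals = []
            while len(vals) < nx:
                vals.extend(float(v) for v in take().split())
            density[:, iy, iz] = vals[:nx]
    return VoxelPhantom(
        material=material,
        density=density,
        spacing_mm=spacing,
        origin_mm=origin,
        material_names={k: n for k, n in enumerate(names)},
    )


# --------------------------------------------------------------------------
# PenVox dialect (documented in docs/methods.md)


def write_penvox(phantom: VoxelPhantom, path) -> None:
    """Write the PenVox-dialect phantom: ASCII header then one
    ``material density`` record per voxel, x-fastest."""
    if np.any(phantom.density < 0):  # phantom invariant, re-checked at the boundary
        raise ValueError("negative density in phantom")
    order, remapped = _compact_indices(phantom)
    nx, ny, nz = phantom.dims
    dx, dy, dz = (s / 10.0 for s in phantom.spacing_mm)
    ox, oy, oz = (o / 10.0 for o in phantom.origin_mm)
    buf = io.StringIO()
    buf.write("# PenVox voxel phantom (rtmc dialect v1)\n")
    buf.write(f"{nx} {ny} {nz}\n")
    buf.write(f"{dx:.6f} {dy:.6f} {dz:.6f}\n")
    buf.write(f"{ox:.6f} {oy:.6f} {oz:.6f}\n")
    buf.write(f"{len(order)}\n")
    for k, idx in enumerate(order):
        buf.write(f"{k + 1} {phantom.material_names[idx]}\n")
    flat_mat = remapped.ravel(order="F")
    flat_den = phantom.density.ravel(order="F")
    for m, d in zip(flat_mat, flat_den):
        buf.write(f"{m + 1} {d:.8e}\n")
    Path(path).write_text(buf.getvalue())


def read_penvox(path) -> VoxelPhantom:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# PenVox"):
            raise ConversionError(f"{path}: not a PenVox-dialect file")
        nx, ny, nz = (int(v) for v in fh.readline().split())
        dx, dy, dz = (float(v) * 10.0 for v in fh.readline().split())
        ox, oy, oz = (float(v) * 10.0 for v in fh.readline().split())
        nmat = int(fh.readline())
        names = {}
        for _ in range(nmat):
            k, name = fh.readline().split(maxsplit=1)
            names[int(k) - 1] = name.strip()
        n = nx * ny * nz
        mat = np.empty(n, dtype=int)
        den = np.empty(n, dtype=float)
        for i in range(n):
            m, d = fh.readline().split()
            mat[i] = int(m) - 1
            den[i] = float(d)
    return VoxelPhantom(
        material=mat.reshape((nx, ny, nz), order="F"),
        density=den.reshape((nx, ny, nz), order="F"),
        spacing_mm=(dx, dy, dz),
        origin_mm=(ox, oy, oz),
        material_names=names,
    )
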