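"""Image containers and file-format plumbing.

Conventions used throughout the package:

* canonical axis order is ``(z, y, x)``, 0-based voxel indices,
  half-open bounding boxes;
* physical units are millimetres for geometry and Hounsfield units (HU)
  for CT attenuation;
* NIfTI is read/written with :mod:`nibabel`, DICOM with :mod:`pydicom`,
  and calcification annotations arrive as Apple-plist XML exports
  (one ROI dictionary per lesion polygon, grouped per slice).
"""

from __future__ import annotations

import plistlib
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pydicom

__all__ = [
    "CTVolume",
    "LabelVolume",
    "Polygon",
    "CocaAnnotation",
    "FormatError",
    "InvalidMetadataError",
    "ARTERY_LABELS",
    "apply_rescale",
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "parse_coca_xml",
    "rasterize_polygons",
]

#: Fixed vocabulary for the four major coronary branches.
ARTERY_LABELS = ("RCA", "LAD", "LCX", "LM")

HU_MIN, HU_MAX = -2048.0, 8192.0


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class InvalidMetadataError(ValueError):
    """Image metadata (rescale tags, geometry) is unusable."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D grid of HU intensities with physical geometry.

    ``voxels`` is indexed ``[z, y, x]``; ``spacing`` and ``origin`` are
    ``(z, y, x)`` in millimetres.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float32)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D voxel array, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel values must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        return replace(self, voxels=voxels)


@dataclass(frozen=True)
class LabelVolume:
    """A 3D grid of small non-negative integer labels on a CT grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D label array, got ndim={v.ndim}")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v)):
                raise ValueError("label volume must hold integers")
            v = np.round(v).astype(np.int16)
        if v.min() < 0:
            raise ValueError("labels must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def labels(self) -> set[int]:
        return set(int(v) for v in np.unique(self.voxels))


@dataclass(frozen=True)
class Polygon:
    """One annotated lesion outline on one axial slice.

    Vertices are ordered ``(x, y)`` pixel coordinates, matching the
    plist-XML convention of the source annotations.
    """

    slice_index: int
    vertices: tuple[tuple[float, float], ...]
    artery: str = "RCA"

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if self.artery not in ARTERY_LABELS:
            raise ValueError(
                f"artery {self.artery!r} not in {ARTERY_LABELS}"
            )
        object.__setattr__(
            self,
            "vertices",
            tuple((float(x), float(y)) for x, y in self.vertices),
        )


@dataclass(frozen=True)
class CocaAnnotation:
    """Per-slice polygon annotations for one CT volume."""

    polygons: tuple[Polygon, ...] = ()

    @property
    def n_lesions(self) -> int:
        return len(self.polygons)

    @property
    def annotated_slices(self) -> tuple[int, ...]:
        return tuple(sorted({p.slice_index for p in self.polygons}))

    @property
    def n_annotated_slices(self) -> int:
        return len(self.annotated_slices)

    def on_slice(self, z: int) -> tuple[Polygon, ...]:
        return tuple(p for p in self.polygons if p.slice_index == z)


def apply_rescale(raw: np.ndarray, slope: float, intercept: float,
                  spacing: Sequence[float] = (1.0, 1.0, 1.0),
                  origin: Sequence[float] = (0.0, 0.0, 0.0)) -> CTVolume:
    """Convert stored pixel values to Hounsfield units ``raw*slope + intercept``."""
    if slope == 0:
        raise InvalidMetadataError("rescale slope must be non-zero")
    hu = np.asarray(raw, dtype=np.float32) * np.float32(slope) + np.float32(intercept)
    hu = np.clip(hu, HU_MIN, HU_MAX)
    return CTVolume(hu, spacing=tuple(spacing), origin=tuple(origin))


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Read one axial DICOM series as a CTVolume.

    Slices are sorted by the projection of ImagePositionPatient onto the
    slice normal (robust to renumbered InstanceNumbers); rescale slope and
    intercept are applied per slice.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"no DICOM images found in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"directory holds {len(uids)} series, expected exactly 1")

    ref = datasets[0]
    try:
        orient = np.asarray(ref.ImageOrientationPatient, dtype=float)
        row, col = orient[:3], orient[3:]
        normal = np.cross(row, col)
        positions = [float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal))
                     for ds in datasets]
    except AttributeError as exc:
        raise FormatError(f"missing geometry tags: {exc}") from exc

    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) != 1:
        raise FormatError("inconsistent slice shapes within series")

    slope = float(getattr(ref, "RescaleSlope", 1.0))
    intercept = float(getattr(ref, "RescaleIntercept", 0.0))
    raw = np.stack([ds.pixel_array for ds in datasets], axis=0)

    py, px = (float(v) for v in ref.PixelSpacing)
    if len(datasets) > 1:
        dz = float(np.median(np.diff(positions)))
        if dz <= 0:
            raise FormatError("non-increasing slice positions")
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0))
    origin_zyx = tuple(float(v) for v in reversed(ref.ImagePositionPatient))
    return apply_rescale(raw, slope, intercept, spacing=(dz, py, px), origin=origin_zyx)


def _affine_from_geometry(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    # nibabel arrays are stored (x, y, z); we keep (z, y, x) in memory and
    # transpose at the boundary.
    dz, dy, dx = spacing
    oz, oy, ox = origin
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = (ox, oy, oz)
    return aff


def read_nifti(path: str | Path, kind: str = "image") -> CTVolume | LabelVolume:
    """Read a NIfTI file as a CTVolume (``kind='image'``) or LabelVolume (``'label'``)."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    voxels = np.transpose(data, (2, 1, 0))
    if kind == "image":
        return CTVolume(voxels.astype(np.float32), spacing=spacing, origin=origin)
    if kind == "label":
        return LabelVolume(np.round(voxels).astype(np.int16), spacing=spacing, origin=origin)
    raise ValueError(f"kind must be 'image' or 'label', got {kind!r}")


def write_nifti(vol: CTVolume | LabelVolume, path: str | Path) -> Path:
    """Write a volume to ``.nii``/``.nii.gz``; roundtrips voxels exactly."""
    path = Path(path)
    data = np.transpose(vol.voxels, (2, 1, 0))
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine_from_geometry(vol.spacing, vol.origin))
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# COCA-style plist XML annotations
# ---------------------------------------------------------------------------

_POINT_RE = re.compile(r"\(?\s*([-+0-9.eE]+)\s*,\s*([-+0-9.eE]+)\s*\)?")


def _parse_point(text: str) -> tuple[float, float]:
    m = _POINT_RE.search(text)
    if m is None:
        raise FormatError(f"cannot parse point {text!r}")
    return float(m.group(1)), float(m.group(2))


def parse_coca_xml(xml_text: str | bytes) -> CocaAnnotation:
    """Parse an Apple-plist ROI annotation export.

    The accepted dialect is a plist whose "Images" array holds one dict per
    annotated slice with an "ImageIndex" and an array of "ROIs"; each ROI
    carries a "Point_px" array of "(x, y)" vertex strings and a "Name"
    artery label. Unknown keys are ignored.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = plistlib.loads(xml_text)
    except Exception as exc:
        raise FormatError(f"not a plist XML document: {exc}") from exc
    if not isinstance(root, dict):
        raise FormatError("plist root must be a dictionary")

    polygons: list[Polygon] = []
    for image in root.get("Images", []):
        z = int(image.get("ImageIndex", -1))
        for i, roi in enumerate(image.get("ROIs", [])):
            pts = roi.get("Point_px")
            if pts is None:
                raise FormatError(f"ROI {i} on slice {z} has no Point_px coordinates")
            verts = [_parse_point(p) for p in pts]
            if len(verts) < 3:
                raise FormatError(
                    f"ROI {i} on slice {z} has {len(verts)} vertices (need >= 3)"
                )
            name = str(roi.get("Name", "RCA"))
            artery = name if name in ARTERY_LABELS else "RCA"
            polygons.append(Polygon(slice_index=z, vertices=tuple(verts), artery=artery))
    return CocaAnnotation(polygons=tuple(polygons))


def _points_in_polygon(xs: np.ndarray, ys: np.ndarray,
                       vertices: Sequence[tuple[float, float]]) -> np.ndarray:
    """Vectorized even-odd (ray crossing) containment test.

    Points whose centre lies exactly on an edge are treated as inside.
    """
    vx = np.array([v[0] for v in vertices], dtype=float)
    vy = np.array([v[1] for v in vertices], dtype=float)
    n = len(vx)
    inside = np.zeros(xs.shape, dtype=bool)
    on_edge = np.zeros(xs.shape, dtype=bool)
    for i in range(n):
        x1, y1 = vx[i], vy[i]
        x2, y2 = vx[(i + 1) % n], vy[(i + 1) % n]
        # point exactly on the closed segment
        cross = (x2 - x1) * (ys - y1) - (y2 - y1) * (xs - x1)
        within = (
            (np.minimum(x1, x2) - 1e-12 <= xs) & (xs <= np.maximum(x1, x2) + 1e-12)
            & (np.minimum(y1, y2) - 1e-12 <= ys) & (ys <= np.maximum(y1, y2) + 1e-12)
        )
        on_edge |= within & (np.abs(cross) < 1e-9)
        # horizontal ray toward +x; half-open in y to count each crossing once
        cond = (y1 <= ys) != (y2 <= ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (xs < xint)
    return inside | on_edge


def rasterize_polygons(annotation: CocaAnnotation,
                       shape: tuple[int, int, int],
                       spacing: Sequence[float] = (1.0, 1.0, 1.0),
                       origin: Sequence[float] = (0.0, 0.0, 0.0),
                       per_artery: bool = False) -> LabelVolume:
    """Rasterize polygon annotations onto a voxel grid.

    A pixel is foreground iff its centre lies inside the closed polygon
    under the even-odd rule (centres exactly on an edge count as inside).
    With ``per_artery=True`` labels are 1..4 following :data:`ARTERY_LABELS`;
    otherwise the mask is binary.
    """
    nz, ny, nx = shape
    out = np.zeros(shape, dtype=np.int16)
    ys, xs = np.mgrid[0:ny, 0:nx]
    xs = xs.astype(float)
    ys = ys.astype(float)
    for poly in annotation.polygons:
        # zero-area (degenerate) polygons rasterize to nothing
        px = np.array([v[0] for v in poly.vertices])
        py = np.array([v[1] for v in poly.vertices])
        area2 = np.abs(np.dot(px, np.roll(py, -1)) - np.dot(py, np.roll(px, -1)))
        if area2 < 1e-12:
            continue
        z = poly.slice_index
        if not (0 <= z < nz):
            warnings.warn(f"polygon slice index {z} outside volume depth {nz}; skipped")
            continue
        pxs = [v[0] for v in poly.vertices]
        pys = [v[1] for v in poly.vertices]
        if min(pxs) < -0.5 or max(pxs) > nx - 0.5 or min(pys) < -0.5 or max(pys) > ny - 0.5:
            warnings.warn(
                f"polygon on slice {z} extends outside the {ny}x{nx} grid; clipped"
            )
        x0 = max(int(np.floor(min(pxs))) - 1, 0)
        x1 = min(int(np.ceil(max(pxs))) + 2, nx)
        y0 = max(int(np.floor(min(pys))) - 1, 0)
        y1 = min(int(np.ceil(max(pys))) + 2, ny)
        if x0 >= x1 or y0 >= y1:
            continue
        sub = _points_in_polygon(xs[y0:y1, x0:x1], ys[y0:y1, x0:x1], poly.vertices)
        label = ARTERY_LABELS.index(poly.artery) + 1 if per_artery else 1
        region = out[z, y0:y1, x0:x1]
        region[sub] = label
    return LabelVolume(out, spacing=tuple(spacing), origin=tuple(origin))
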