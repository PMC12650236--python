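"""Seeded synthetic cardiac-CT phantoms with full ground truth.

Each phantom emulates the image properties the pipeline exploits, not
anatomy: a soft-tissue background with two lung fields, an ellipsoidal
heart, a handful of smooth tubular coronary-like branches inside the
heart, calcified blobs (>= 160 HU) attached to vessel walls, bright
extracardiac decoys (the bone/valve-like confounders that vessel priors
are meant to suppress), and additive Gaussian noise. Every random draw
flows from ``PhantomSpec.seed``, so a spec fully determines its phantom.

The HU palette (-800 lung, 40 soft tissue, 60 heart, 80 lumen — 300 in
contrast mode, 160-800 calcium, 700-1200 decoys) keeps calcium at least
3 noise sigmas above the 130 HU scoring threshold while nothing else
inside the vessel neighbourhood crosses it, so thresholding the noiseless
phantom at 130 HU inside the dilated vessel prior recovers the calcium
mask exactly.
"""

from __future__ import annotations

import plistlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.measure import find_contours

from .imaging_io import ARTERY_LABELS, CocaAnnotation, CTVolume, Polygon

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "BenchmarkSuite",
    "GenerationError",
    "generate_phantom",
    "generate_coca_like_xml",
    "make_benchmark_suite",
    "positive_slice_dataset",
]


class GenerationError(RuntimeError):
    """Feasible placement could not be found within the retry budget."""


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # heart ellipsoid
    heart_semiaxes_mm: tuple[float, float, float] = (18.0, 20.0, 20.0)
    heart_hu: float = 60.0
    # coronary-like branches
    n_branches: int = 3
    vessel_radius_mm: tuple[float, float] = (1.0, 2.0)
    lumen_hu: float = 80.0           # 300 in contrast-enhanced mode
    # calcifications (attached to vessel walls)
    n_calcifications: int = 4
    calc_radius_mm: tuple[float, float] = (1.0, 2.5)
    calc_hu: tuple[float, float] = (160.0, 800.0)
    prior_radius_mm: float = 2.0     # lesions stay within this reach of the tree
    # extracardiac decoys
    n_decoys: int = 2
    decoy_radius_mm: tuple[float, float] = (2.0, 4.0)
    decoy_hu: tuple[float, float] = (700.0, 1200.0)
    # acquisition
    noise_sigma_hu: float = 10.0
    soft_tissue_hu: float = 40.0
    lung_hu: float = -800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calc_hu[0] < 130.0 + 3.0 * self.noise_sigma_hu:
            raise ValueError(
                "calcification HU floor must be >= 130 + 3*noise sigma so "
                "lesions survive threshold-based scoring under noise"
            )
        if self.decoy_hu[0] < 130.0:
            raise ValueError("decoys must be scoring-threshold bright (>= 130 HU)")
        if min(self.shape) < 16:
            raise ValueError("phantom must be at least 16 voxels per axis")


@dataclass(frozen=True)
class PhantomCase:
    spec: PhantomSpec
    ct: CTVolume                     # noisy HU volume
    ct_clean: CTVolume               # noiseless HU volume
    heart: np.ndarray
    vessel: np.ndarray
    calcium: np.ndarray
    decoy: np.ndarray
    annotation: CocaAnnotation

    @property
    def positive_slices(self) -> tuple[int, ...]:
        return tuple(int(z) for z in np.where(self.calcium.any(axis=(1, 2)))[0])


@dataclass(frozen=True)
class BenchmarkSuite:
    train: tuple[PhantomCase, ...]
    test: tuple[PhantomCase, ...]
    seed: int


def _ellipsoid(shape: tuple[int, int, int], spacing: Sequence[float],
               center_mm: np.ndarray, semi_mm: Sequence[float]) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                             indexing="ij")
    return (((zz - center_mm[0]) / semi_mm[0]) ** 2
            + ((yy - center_mm[1]) / semi_mm[1]) ** 2
            + ((xx - center_mm[2]) / semi_mm[2]) ** 2) <= 1.0


def _sphere(shape: tuple[int, int, int], spacing: Sequence[float],
            center_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)),
                             indexing="ij")
    return ((zz - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2
            + (xx - center_mm[2]) ** 2) <= radius_mm ** 2


def _branch_centerline(rng: np.random.Generator, center_mm: np.ndarray,
                       semi_mm: np.ndarray, n_ctrl: int = 6) -> np.ndarray:
    """A C1-smooth polyline inside the heart ellipsoid (dense mm samples)."""
    start = center_mm + rng.uniform(-0.3, 0.3, 3) * semi_mm
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    step = float(np.mean(semi_mm)) / (n_ctrl - 1) * 1.4
    pts = [start]
    for _ in range(n_ctrl - 1):
        direction += rng.normal(0, 0.45, 3)
        direction /= np.linalg.norm(direction)
        p = pts[-1] + direction * step
        # keep inside the ellipsoid: pull back toward the centre if needed
        rel = (p - center_mm) / semi_mm
        r = np.linalg.norm(rel)
        if r > 0.9:
            p = center_mm + rel / r * 0.9 * semi_mm
        pts.append(p)
    ctrl = np.array(pts)
    tck, _ = splprep(ctrl.T, s=0.0, k=min(3, len(ctrl) - 1))
    u = np.linspace(0, 1, 250)
    return np.array(splev(u, tck)).T


def _tube_mask(shape: tuple[int, int, int], spacing: Sequence[float],
               centerline_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    marks = np.ones(shape, dtype=bool)
    idx = np.round(centerline_mm / np.asarray(spacing)).astype(int)
    idx = idx[np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)]
    if len(idx) == 0:
        return np.zeros(shape, dtype=bool)
    marks[idx[:, 0], idx[:, 1], idx[:, 2]] = False
    dist = ndimage.distance_transform_edt(marks, sampling=spacing)
    return dist <= radius_mm


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render a phantom and all of its ground-truth masks."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    extent = np.asarray(shape) * np.asarray(spacing)
    center = extent / 2.0
    semi = np.asarray(spec.heart_semiaxes_mm)

    hu = np.full(shape, spec.soft_tissue_hu, dtype=np.float32)
    # two lateral lung fields flanking the heart
    lung_semi = np.array([extent[0] * 0.45, extent[1] * 0.35, extent[2] * 0.18])
    for sign in (-1, 1):
        lc = center + np.array([0.0, 0.0, sign * extent[2] * 0.36])
        hu[_ellipsoid(shape, spacing, lc, lung_semi)] = spec.lung_hu

    heart = _ellipsoid(shape, spacing, center, semi)
    hu[heart] = spec.heart_hu

    vessel = np.zeros(shape, dtype=bool)
    centerlines = []
    radii = []
    for _ in range(spec.n_branches):
        cl = _branch_centerline(rng, center, semi)
        r = float(rng.uniform(*spec.vessel_radius_mm))
        vessel |= _tube_mask(shape, spacing, cl, r)
        centerlines.append(cl)
        radii.append(r)
    vessel &= heart
    hu[vessel] = spec.lumen_hu

    # calcifications live on vessel walls, i.e. within the dilated tree a
    # downstream vessel prior of the same radius is guaranteed to cover
    marks = np.ones(shape, dtype=bool)
    marks[vessel] = False
    vessel_reach = ndimage.distance_transform_edt(
        marks, sampling=spacing) <= spec.prior_radius_mm
    calcium = np.zeros(shape, dtype=bool)
    calc_hu = np.zeros(shape, dtype=np.float32)
    placed = 0
    for _ in range(200):
        if placed == spec.n_calcifications:
            break
        b = int(rng.integers(spec.n_branches))
        cl = centerlines[b]
        p = cl[int(rng.integers(20, len(cl) - 20))]
        perp = rng.normal(size=3)
        tangent = cl[-1] - cl[0]
        perp -= perp.dot(tangent) / (tangent.dot(tangent) + 1e-12) * tangent
        norm = np.linalg.norm(perp)
        if norm < 1e-6:
            continue
        c = p + perp / norm * radii[b]      # on the vessel wall
        r = float(rng.uniform(*spec.calc_radius_mm))
        blob = _sphere(shape, spacing, c, r) & vessel_reach
        if not blob.any() or not (blob & vessel).any():
            continue
        level = float(rng.uniform(*spec.calc_hu))
        calcium |= blob
        calc_hu[blob] = np.maximum(calc_hu[blob], level)
        placed += 1
    if placed < spec.n_calcifications:
        raise GenerationError(
            f"placed only {placed}/{spec.n_calcifications} calcifications "
            f"after 200 attempts (seed {spec.seed})"
        )
    hu[calcium] = calc_hu[calcium]

    # decoys: bright blobs strictly outside the heart, away from the tree
    forbid = ndimage.binary_dilation(heart, iterations=2)
    vessel_zone = ndimage.binary_dilation(
        vessel, structure=np.ones((3, 3, 3), bool), iterations=6)
    decoy = np.zeros(shape, dtype=bool)
    placed = 0
    for _ in range(400):
        if placed == spec.n_decoys:
            break
        c = rng.uniform([0, 0, 0], extent)
        r = float(rng.uniform(*spec.decoy_radius_mm))
        blob = _sphere(shape, spacing, c, r)
        if not blob.any() or (blob & forbid).any() or (blob & vessel_zone).any():
            continue
        hu[blob] = float(rng.uniform(*spec.decoy_hu))
        decoy |= blob
        placed += 1
    if placed < spec.n_decoys:
        raise GenerationError(
            f"placed only {placed}/{spec.n_decoys} decoys after 400 attempts "
            f"(seed {spec.seed})"
        )

    clean = CTVolume(hu.copy(), spacing=spacing)
    if spec.noise_sigma_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sigma_hu, shape).astype(np.float32)
    ct = CTVolume(hu, spacing=spacing)

    annotation = _annotate_calcium(calcium)
    return PhantomCase(spec=spec, ct=ct, ct_clean=clean, heart=heart,
                       vessel=vessel, calcium=calcium, decoy=decoy,
                       annotation=annotation)


def _annotate_calcium(calcium: np.ndarray) -> CocaAnnotation:
    """One polygon per per-slice 8-connected calcium component."""
    polygons: list[Polygon] = []
    struct = np.ones((3, 3), dtype=int)
    lesion_idx = 0
    for z in range(calcium.shape[0]):
        labels, n = ndimage.label(calcium[z], structure=struct)
        for i in range(1, n + 1):
            comp = labels == i
            contours = find_contours(np.pad(comp.astype(float), 1), 0.5)
            if not contours:
                continue
            contour = max(contours, key=len) - 1.0   # undo padding
            verts = [(float(x), float(y)) for y, x in contour[:-1]]
            if len(verts) > 40:
                stride = int(np.ceil(len(verts) / 40))
                verts = verts[::stride]
            if len(verts) < 3:
                continue
            polygons.append(Polygon(
                slice_index=z, vertices=tuple(verts),
                artery=ARTERY_LABELS[lesion_idx % len(ARTERY_LABELS)],
            ))
            lesion_idx += 1
    return CocaAnnotation(polygons=tuple(polygons))


def generate_coca_like_xml(annotation: CocaAnnotation) -> str:
    """Serialize an annotation as the accepted Apple-plist ROI dialect."""
    images = []
    for z in annotation.annotated_slices:
        rois = []
        for poly in annotation.on_slice(z):
            rois.append({
                "Name": poly.artery,
                "NumberOfPoints": len(poly.vertices),
                "Point_px": [f"({x!r}, {y!r})" for x, y in poly.vertices],
            })
        images.append({"ImageIndex": z, "NumberOfROIs": len(rois), "ROIs": rois})
    return plistlib.dumps({"Images": images}).decode("utf-8")


def make_benchmark_suite(n_cases: int, base_spec: PhantomSpec = PhantomSpec(),
                         seed: int = 0) -> BenchmarkSuite:
    """Generate ``n_cases`` phantoms with derived seeds and an 80/20 split."""
    if n_cases < 2:
        raise ValueError("a benchmark suite needs at least 2 cases")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cases) % (2 ** 31)
    cases = [generate_phantom(replace(base_spec, seed=int(s))) for s in child_seeds]
    n_train = max(1, int(round(0.8 * n_cases)))
    if n_train == n_cases:
        n_train = n_cases - 1
    return BenchmarkSuite(train=tuple(cases[:n_train]),
                          test=tuple(cases[n_train:]), seed=seed)


def positive_slice_dataset(cases: Sequence[PhantomCase],
                           ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Calcification-positive axial slices as (1-channel input, mask) pairs.

    Inputs are per-case min-max normalized HU slices, the representation
    the calcification stage trains on.
    """
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for case in cases:
        v = case.ct.voxels
        lo, hi = float(v.min()), float(v.max())
        norm = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        for z in case.positive_slices:
            out.append((norm[z][None].astype(np.float32),
                        case.calcium[z].astype(np.float32)))
    return out
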