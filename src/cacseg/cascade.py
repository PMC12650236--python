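"""Three-stage anatomical cascade with exact coordinate bookkeeping.

Stage 1 localizes the heart and crops a region of interest (ROI); stage 2
segments the coronary tree inside the ROI and dilates it into a vessel
prior; stage 3 runs the calcification ensemble inside the prior. All
stage models are pluggable: :class:`OracleModel` wraps a ground-truth mask
as a probability map so the plumbing can be verified independently of any
learned weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import CTVolume
from .preprocess import ConfigError
from .unet_zoo import SegmentationModel, predict_proba
from .vesselness import VesselnessParams, frangi_vesselness, compose_vessel_input

__all__ = [
    "ROIBox",
    "VesselPrior",
    "RoiNotFoundError",
    "OracleModel",
    "SliceModel",
    "predict_volume",
    "extract_heart_roi",
    "segment_vessels",
    "dilate_vessel_prior",
    "map_to_original",
    "stack_slices",
    "pad_to_multiple",
    "crop_to_box",
]


class RoiNotFoundError(RuntimeError):
    """The heart stage produced an empty mask; no silent fallback."""


@dataclass(frozen=True)
class ROIBox:
    """Half-open per-axis (start, stop) voxel bounds on a source grid."""

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not (0 <= lo < hi):
                raise ValueError(f"invalid half-open bounds {self.bounds}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in self.bounds)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.bounds)


@dataclass(frozen=True)
class VesselPrior:
    """Dilated coronary-tree mask constraining plausible lesion locations."""

    mask: np.ndarray
    dilation_radius_mm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


class SliceModel(Protocol):
    """Anything that maps a slice stack (N, C, H, W) to probabilities (N, H, W)."""

    def predict_slices(self, x: np.ndarray) -> np.ndarray: ...

    @property
    def in_channels(self) -> int: ...


@dataclass
class OracleModel:
    """Ground-truth passthrough stage model for plumbing tests.

    Ignores image content and returns the stored mask's axial slices as
    probabilities; the caller must feed slices in z order over the full
    grid the mask lives on.
    """

    mask: np.ndarray
    in_channels: int = 1

    def predict_slices(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        if n != self.mask.shape[0]:
            raise ValueError(
                f"oracle holds {self.mask.shape[0]} slices, got {n} inputs"
            )
        return self.mask.astype(np.float32)


@dataclass
class LearnedModel:
    """Adapter exposing a trained 2D network as a cascade stage model."""

    model: SegmentationModel

    @property
    def in_channels(self) -> int:
        return self.model.config.in_channels

    def predict_slices(self, x: np.ndarray) -> np.ndarray:
        f = 2 ** self.model.config.depth
        xp, (ph, pw) = pad_to_multiple(x, f)
        out = predict_proba(self.model, xp)
        return out[:, : x.shape[2], : x.shape[3]]


def pad_to_multiple(x: np.ndarray, f: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad trailing spatial axes of (N, C, H, W) up to multiples of f."""
    h, w = x.shape[2], x.shape[3]
    ph = (-h) % f
    pw = (-w) % f
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
    return x, (ph, pw)


def predict_volume(model: SliceModel, channels: np.ndarray) -> np.ndarray:
    """Run a slice model over every axial slice of a (C, Z, H, W) stack."""
    if channels.ndim == 3:
        channels = channels[None]
    c, z, h, w = channels.shape
    if c != model.in_channels:
        raise ValueError(f"model expects {model.in_channels} channels, got {c}")
    x = np.moveaxis(channels, 1, 0)  # (Z, C, H, W)
    return model.predict_slices(x.astype(np.float32))


def extract_heart_roi(ct: CTVolume, heart_model: SliceModel,
                      margin_mm: float = 10.0,
                      threshold: float = 0.5) -> tuple[ROIBox, CTVolume]:
    """Crop the heart: largest predicted component's bounding box + margin."""
    probs = predict_volume(heart_model, ct.voxels[None])
    mask = probs >= threshold
    if not mask.any():
        raise RoiNotFoundError("heart stage predicted no foreground")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = mask & (labels == (1 + int(np.argmax(sizes))))
    box = bounding_box(largest, margin_mm=margin_mm, spacing=ct.spacing)
    crop = crop_to_box(ct.voxels, box)
    origin = tuple(o + lo * s for o, (lo, _hi), s in zip(ct.origin, box.bounds, ct.spacing))
    return box, CTVolume(crop, spacing=ct.spacing, origin=origin)


def bounding_box(mask: np.ndarray, margin_mm: float = 0.0,
                 spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> ROIBox:
    """Tight half-open bounding box of a non-empty mask, expanded by a
    physical margin and clamped to the volume."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RoiNotFoundError("cannot bound an empty mask")
    bounds = []
    for ax, (n, sp) in enumerate(zip(mask.shape, spacing)):
        proj = mask.any(axis=tuple(i for i in range(3) if i != ax))
        idx = np.where(proj)[0]
        m = int(np.ceil(margin_mm / sp)) if margin_mm else 0
        bounds.append((max(int(idx[0]) - m, 0), min(int(idx[-1]) + 1 + m, n)))
    return ROIBox(tuple(bounds))


def crop_to_box(voxels: np.ndarray, box: ROIBox) -> np.ndarray:
    return voxels[box.slices()].copy()


def segment_vessels(roi_ct: CTVolume, vessel_model: SliceModel,
                    vparams: VesselnessParams = VesselnessParams(),
                    threshold: float = 0.5,
                    min_voxels: int = 10,
                    vessel_input_mode: str = "stack") -> np.ndarray:
    """Vessel mask on the ROI grid from the vesselness-enhanced stage.

    The model input follows :func:`compose_vessel_input`; small connected
    components (< ``min_voxels``, 26-connectivity) are removed.
    """
    if vessel_model.in_channels == 2 or vessel_input_mode == "stack":
        v = frangi_vesselness(roi_ct, vparams)
        channels = compose_vessel_input(roi_ct.voxels, v, mode="stack")
    else:
        channels = roi_ct.voxels[None]
    if channels.shape[0] != vessel_model.in_channels:
        channels = channels[: vessel_model.in_channels]
    probs = predict_volume(vessel_model, channels)
    mask = probs >= threshold
    if min_voxels > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_voxels
        keep[0] = False
        mask = keep[labels]
    return mask


def dilate_vessel_prior(vessel_mask: np.ndarray, radius_mm: float,
                        spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> VesselPrior:
    """Dilate with a discrete ball of physical radius; radius 0 is identity."""
    if radius_mm < 0:
        raise ConfigError("dilation radius must be >= 0")
    mask = np.asarray(vessel_mask, dtype=bool)
    if radius_mm == 0 or not mask.any():
        return VesselPrior(mask.copy(), radius_mm)
    rz, ry, rx = (int(np.floor(radius_mm / s)) for s in spacing)
    zz, yy, xx = np.mgrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
    ball = ((zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2
            + (xx * spacing[2]) ** 2) <= radius_mm ** 2 + 1e-9
    return VesselPrior(ndimage.binary_dilation(mask, structure=ball), radius_mm)


def map_to_original(roi_mask: np.ndarray, box: ROIBox,
                    source_shape: tuple[int, int, int]) -> np.ndarray:
    """Embed an ROI-grid mask back into the full grid (background outside)."""
    roi_mask = np.asarray(roi_mask)
    if roi_mask.shape != box.shape:
        raise ValueError(f"mask shape {roi_mask.shape} != box extents {box.shape}")
    for (lo, hi), n in zip(box.bounds, source_shape):
        if hi > n:
            raise ValueError(f"box {box.bounds} exceeds source shape {source_shape}")
    out = np.zeros(source_shape, dtype=roi_mask.dtype)
    out[box.slices()] = roi_mask
    return out


def stack_slices(slices: Sequence[tuple[int, np.ndarray]] | Sequence[np.ndarray],
                 order: Sequence[int] | None = None) -> np.ndarray:
    """Assemble per-slice 2D masks into a 3D volume.

    Accepts ``(z, slice)`` pairs or a plain sequence with an explicit
    ``order`` of z indices (default: given order). Every z in
    ``0..len-1`` must occur exactly once.
    """
    items: list[tuple[int, np.ndarray]]
    if order is not None:
        items = list(zip(order, slices))  # type: ignore[arg-type]
    elif slices and isinstance(slices[0], tuple):
        items = list(slices)  # type: ignore[assignment]
    else:
        items = list(enumerate(slices))  # type: ignore[arg-type]
    zs = sorted(z for z, _ in items)
    if zs != list(range(len(items))):
        raise ValueError(f"z indices must cover 0..{len(items) - 1} exactly once, got {zs}")
    shapes = {s.shape for _, s in items}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes {shapes}")
    out = np.empty((len(items),) + items[0][1].shape, dtype=items[0][1].dtype)
    for z, s in items:
        out[z] = s
    return out
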