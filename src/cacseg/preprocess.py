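"""Geometry and contrast standardization.

The pipeline converts every scan to a common representation before any
model sees it: HU clipping to a broad CT window, resampling to an
isotropic grid (linear interpolation for images, nearest-neighbour for
label masks, so no new labels are invented), and per-scan intensity
normalization to tame scanner variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import CTVolume, LabelVolume

__all__ = [
    "PreprocessConfig",
    "ConfigError",
    "DegenerateInputError",
    "clip_window",
    "resample_isotropic",
    "normalize",
    "preprocess_volume",
]

DEFAULT_WINDOW = (-1024.0, 3071.0)


class ConfigError(ValueError):
    """A configuration value violates its contract."""


class DegenerateInputError(ValueError):
    """The input admits no well-defined answer (e.g. z-scoring a constant)."""


@dataclass(frozen=True)
class PreprocessConfig:
    window: tuple[float, float] = DEFAULT_WINDOW
    target_spacing_mm: float = 1.0
    normalization: str = "minmax"  # or "zscore"

    def __post_init__(self) -> None:
        lo, hi = self.window
        if lo >= hi:
            raise ConfigError(f"window lo must be < hi, got ({lo}, {hi})")
        if self.target_spacing_mm <= 0:
            raise ConfigError("target spacing must be positive")
        if self.normalization not in ("minmax", "zscore"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")


def clip_window(vol: CTVolume, lo: float, hi: float) -> CTVolume:
    """Clamp HU intensities to ``[lo, hi]``. Idempotent."""
    if lo >= hi:
        raise ConfigError(f"window lo must be < hi, got ({lo}, {hi})")
    return vol.with_voxels(np.clip(vol.voxels, lo, hi))


def resample_isotropic(vol: CTVolume | LabelVolume, target_mm: float = 1.0,
                       mode: str | None = None) -> CTVolume | LabelVolume:
    """Resample to an isotropic ``target_mm`` grid.

    Images use linear interpolation; label volumes use nearest-neighbour so
    that no label value absent from the input can appear in the output.
    """
    if target_mm <= 0:
        raise ConfigError("target spacing must be positive")
    is_label = isinstance(vol, LabelVolume)
    if mode is None:
        mode = "nearest" if is_label else "linear"
    if is_label and mode != "nearest":
        raise ConfigError("label volumes must be resampled with nearest-neighbour")
    if (not is_label) and mode != "linear":
        raise ConfigError("image volumes must be resampled with linear interpolation")

    factors = tuple(s / target_mm for s in vol.spacing)
    out_shape = tuple(max(1, int(round(n * f))) for n, f in zip(vol.shape, factors))
    if out_shape == vol.shape and all(abs(f - 1.0) < 1e-12 for f in factors):
        return vol

    zoom = tuple(o / n for o, n in zip(out_shape, vol.shape))
    order = 0 if mode == "nearest" else 1
    data = ndimage.zoom(vol.voxels.astype(np.float32 if not is_label else vol.voxels.dtype),
                        zoom, order=order, mode="nearest", grid_mode=True)
    spacing = (target_mm,) * 3
    if is_label:
        return LabelVolume(np.round(data).astype(vol.voxels.dtype),
                           spacing=spacing, origin=vol.origin)
    return CTVolume(data.astype(np.float32), spacing=spacing, origin=vol.origin)


def normalize(vol: CTVolume, method: str = "minmax") -> CTVolume:
    """Per-scan intensity normalization.

    ``minmax`` maps the range onto [0, 1] (a constant scan maps to all
    zeros); ``zscore`` standardizes to mean 0, population std 1 and raises
    on constant input.
    """
    v = vol.voxels
    if method == "minmax":
        lo, hi = float(v.min()), float(v.max())
        if hi - lo <= 0:
            return vol.with_voxels(np.zeros_like(v))
        return vol.with_voxels((v - lo) / (hi - lo))
    if method == "zscore":
        std = float(v.std())  # population convention, ddof=0
        if std == 0:
            raise DegenerateInputError("cannot z-score a constant volume")
        return vol.with_voxels((v - float(v.mean())) / std)
    raise ConfigError(f"unknown normalization {method!r}")


def preprocess_volume(vol: CTVolume, cfg: PreprocessConfig = PreprocessConfig()) -> CTVolume:
    """window -> isotropic resample -> normalize, in that order."""
    out = clip_window(vol, *cfg.window)
    out = resample_isotropic(out, cfg.target_spacing_mm)
    return normalize(out, cfg.normalization)
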