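"""Image conditioning: dual-view fusion, anisotropic resampling, percentile
intensity normalization and gamma correction.

Default targets follow the acquisition geometry of dual-view light-sheet
blastocyst movies: data are resampled to 0.381 μm lateral / 1.9 μm axial
spacing before segmentation.  Normalization is per-frame by default.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import zoom

from .core import ConfigError, DataFormatError, LabelVolume, VolumetricFrame

#: resampling target used before segmentation (dz, dy, dx) in μm
DEFAULT_TARGET_SPACING = (1.9, 0.381, 0.381)


def fuse_dual_view(a: VolumetricFrame, b: VolumetricFrame) -> VolumetricFrame:
    """Voxelwise mean of two views of the same volume (contrast enhancement).

    Both frames must share grid shape and spacing; no implicit resampling or
    registration is performed.  Metadata is taken from ``a``.
    """
    if a.intensity.shape != b.intensity.shape:
        raise DataFormatError(
            f"shape mismatch {a.intensity.shape} vs {b.intensity.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise DataFormatError(f"spacing mismatch {a.spacing} vs {b.spacing}")
    return VolumetricFrame(intensity=0.5 * (a.intensity + b.intensity),
                           spacing=a.spacing.copy(),
                           time_index=a.time_index, time_minutes=a.time_minutes)


def _resample_array(arr: np.ndarray, spacing: np.ndarray, target: np.ndarray,
                    order: int) -> np.ndarray:
    in_shape = np.array(arr.shape)
    out_shape = np.round(in_shape * spacing / target).astype(int)
    if np.any(out_shape < 1):
        raise ConfigError(
            f"target spacing {target} larger than the field of view {in_shape * spacing}")
    if np.array_equal(out_shape, in_shape) and np.allclose(spacing, target):
        return arr.copy()
    factors = out_shape / in_shape
    out = zoom(arr, factors, order=order, mode="nearest", grid_mode=True,
               prefilter=(order > 1))
    assert out.shape == tuple(out_shape)
    return out


def resample_to_target(f: VolumetricFrame, target_spacing=DEFAULT_TARGET_SPACING,
                       order: int = 1) -> VolumetricFrame:
    """Resample to the requested voxel spacing.

    The output grid has ``round(shape * spacing / target)`` voxels per axis.
    ``order`` 0 (nearest, for labels), 1 (linear) or 3 (cubic spline).
    """
    if order not in (0, 1, 3):
        raise ConfigError("interpolation order must be 0, 1 or 3")
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ConfigError("target_spacing must be 3 positive values")
    out = _resample_array(f.intensity, f.spacing, target, order)
    return VolumetricFrame(intensity=out, spacing=target,
                           time_index=f.time_index, time_minutes=f.time_minutes)


def resample_labels(lv: LabelVolume, target_spacing=DEFAULT_TARGET_SPACING) -> LabelVolume:
    """Nearest-neighbour resampling of a label volume (label set preserved)."""
    target = np.asarray(target_spacing, dtype=float)
    out = _resample_array(lv.labels, lv.spacing, target, order=0)
    return LabelVolume(labels=out, spacing=target, frame_index=lv.frame_index)


def normalize_intensity(f: VolumetricFrame, p_low: float = 1.0,
                        p_high: float = 99.8) -> VolumetricFrame:
    """Robust percentile rescale: p_low percentile → 0, p_high → 1, clipped.

    A constant image yields all zeros with a warning.
    """
    if not 0.0 <= p_low < p_high <= 100.0:
        raise ConfigError("need 0 <= p_low < p_high <= 100")
    lo, hi = np.percentile(f.intensity, [p_low, p_high])
    if hi <= lo:
        warnings.warn("constant image: normalization is degenerate, returning zeros")
        out = np.zeros_like(f.intensity, dtype=float)
    else:
        out = np.clip((f.intensity - lo) / (hi - lo), 0.0, 1.0)
    return VolumetricFrame(intensity=out, spacing=f.spacing.copy(),
                           time_index=f.time_index, time_minutes=f.time_minutes)


def gamma_correct(f: VolumetricFrame, gamma: float = 0.8) -> VolumetricFrame:
    """Elementwise v → v**gamma on intensities in [0, 1]."""
    if gamma <= 0:
        raise ConfigError("gamma must be positive")
    v = np.asarray(f.intensity)
    if v.min() < 0 or v.max() > 1:
        raise DataFormatError("gamma correction expects intensities in [0, 1]")
    return VolumetricFrame(intensity=v**gamma, spacing=f.spacing.copy(),
                           time_index=f.time_index, time_minutes=f.time_minutes)


def preprocess_frame(f: VolumetricFrame, target_spacing=None, p_low: float = 1.0,
                     p_high: float = 99.8, gamma: float = 0.8,
                     axial_factor: int = 1) -> VolumetricFrame:
    """Standard conditioning chain: optional resampling (with optional extra
    axial downsampling for axially degraded samples), percentile
    normalization, gamma correction."""
    if axial_factor < 1:
        raise ConfigError("axial_factor must be >= 1")
    if target_spacing is not None:
        t = np.asarray(target_spacing, dtype=float).copy()
        t[0] *= axial_factor
        f = resample_to_target(f, t, order=1)
    return gamma_correct(normalize_intensity(f, p_low, p_high), gamma)
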