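"""Shared domain types and conventions.

All coordinates are physical micrometres in right-handed (z, y, x) voxel
order; voxel indices are 0-based and a voxel's coordinate is its centre,
``index * spacing``.  Time is in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigError(ValueError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataFormatError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class NumericalError(RuntimeError):
    """Numerical failure, e.g. non-convergence (CLI exit code 4)."""


@dataclass
class VolumetricFrame:
    """One 3D intensity volume with physical voxel spacing and timestamp.

    Attributes
    ----------
    intensity : (Z, Y, X) ndarray
        Scalar intensity grid.
    spacing : (3,) ndarray
        Voxel spacing in micrometres, (dz, dy, dx).
    time_index : int
        Frame number within the movie.
    time_minutes : float
        Acquisition time in minutes.
    """

    intensity: np.ndarray
    spacing: np.ndarray
    time_index: int = 0
    time_minutes: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ConfigError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.intensity.ndim != 3 or self.intensity.size == 0:
            raise DataFormatError("intensity must be a non-empty 3D grid")
        if not np.all(np.isfinite(self.intensity)):
            raise DataFormatError("intensity contains non-finite values")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume:
    """Integer instance mask aligned to a :class:`VolumetricFrame` grid.

    Label 0 is background; positive labels are nucleus instances.
    """

    labels: np.ndarray
    spacing: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ConfigError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.labels.ndim != 3:
            raise DataFormatError("labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise DataFormatError("labels must be an integer grid")
        if self.labels.size and self.labels.min() < 0:
            raise DataFormatError("labels must be non-negative")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def ids(self) -> np.ndarray:
        """Sorted instance ids present (background excluded)."""
        u = np.unique(self.labels)
        return u[u > 0]

    def volumes(self) -> dict[int, float]:
        """Physical volume per instance in μm³."""
        counts = np.bincount(self.labels.ravel())
        vv = self.voxel_volume
        return {int(k): float(counts[k]) * vv for k in np.nonzero(counts)[0] if k > 0}


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent substream seeds (< 2**31) from a master seed.

    Adding a consumer at the end does not shift earlier consumers' streams.
    """
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1, dtype=np.uint32)[0] % (2**31)) for c in children]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def orthonormal_frame(axis: np.ndarray) -> np.ndarray:
    """Deterministic right-handed orthonormal basis whose first row is ``axis``."""
    u = unit(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e2 = unit(np.cross(u, helper))
    e3 = np.cross(u, e2)
    return np.stack([u, e2, e3])
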