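"""Movie readers/writers: multi-page TIFF sequences and HDF5 stacks.

HDF5 layout: datasets ``/intensity`` [T, Z, Y, X] float and/or ``/labels``
[T, Z, Y, X] integer, with a ``spacing`` attribute (dz, dy, dx in μm) and
``frame_interval_min``.  TIFF layout: one multi-page file per frame named
``t%04d.tif`` (labels: ``labels_t%04d.tif``); spacing must come from config.
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import ConfigError, DataFormatError, LabelVolume, VolumetricFrame

_TIFF_RE = re.compile(r"^t(\d{4})\.tif$")
_LABEL_TIFF_RE = re.compile(r"^labels_t(\d{4})\.tif$")


def write_movie_hdf5(path, frames=None, labels=None, frame_interval_min: float = 15.0):
    """Write intensity and/or label movies into one HDF5 file."""
    if frames is None and labels is None:
        raise ConfigError("nothing to write")
    spacing = (frames or labels)[0].spacing
    with h5py.File(path, "w") as h5:
        h5.attrs["spacing"] = spacing
        h5.attrs["frame_interval_min"] = frame_interval_min
        if frames is not None:
            arr = np.stack([f.intensity for f in frames]).astype(np.float32)
            h5.create_dataset("intensity", data=arr, compression="gzip")
        if labels is not None:
            arr = np.stack([lv.labels for lv in labels]).astype(np.int32)
            h5.create_dataset("labels", data=arr, compression="gzip")


def read_movie_hdf5(path, spacing=None):
    """Read (frames, labels) from an HDF5 stack; either may be None."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{path} does not exist")
    frames = labels = None
    with h5py.File(path, "r") as h5:
        sp = np.asarray(h5.attrs.get("spacing", spacing if spacing is not None else []))
        if sp.size != 3:
            raise ConfigError("voxel spacing missing from file and config")
        dt = float(h5.attrs.get("frame_interval_min", 15.0))
        if "intensity" in h5:
            data = h5["intensity"][...]
            frames = [VolumetricFrame(intensity=data[t], spacing=sp, time_index=t,
                                      time_minutes=t * dt)
                      for t in range(data.shape[0])]
        if "labels" in h5:
            data = h5["labels"][...]
            labels = [LabelVolume(labels=data[t], spacing=sp, frame_index=t)
                      for t in range(data.shape[0])]
    return frames, labels


def write_tiff_sequence(directory, frames=None, labels=None):
    """One multi-page TIFF per frame: ``t%04d.tif`` / ``labels_t%04d.tif``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for f in frames or []:
        tifffile.imwrite(directory / f"t{f.time_index:04d}.tif",
                         f.intensity.astype(np.float32))
    for lv in labels or []:
        tifffile.imwrite(directory / f"labels_t{lv.frame_index:04d}.tif",
                         lv.labels.astype(np.uint16))


def read_tiff_sequence(directory, spacing, frame_interval_min: float = 15.0,
                       labels: bool = False):
    """Read a ``t%04d.tif`` (or ``labels_t%04d.tif``) sequence.

    Frame numbering must be gapless from 0 and all shapes equal.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DataFormatError(f"{directory} is not a directory")
    if spacing is None:
        raise ConfigError("TIFF sequences carry no spacing; provide it in config")
    spacing = np.asarray(spacing, dtype=float)
    rx = _LABEL_TIFF_RE if labels else _TIFF_RE
    found = {}
    for p in directory.iterdir():
        m = rx.match(p.name)
        if m:
            found[int(m.group(1))] = p
    if not found:
        raise DataFormatError(f"no matching TIFF frames in {directory}")
    n = max(found) + 1
    missing = sorted(set(range(n)) - set(found))
    if missing:
        raise DataFormatError(f"gap in TIFF numbering: missing frames {missing}")
    out = []
    shape = None
    for t in range(n):
        arr = tifffile.imread(found[t])
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise DataFormatError(
                f"inconsistent frame shapes: {arr.shape} vs {shape} at t={t}")
        if labels:
            out.append(LabelVolume(labels=arr.astype(np.int32), spacing=spacing,
                                   frame_index=t))
        else:
            out.append(VolumetricFrame(intensity=arr.astype(np.float32),
                                       spacing=spacing, time_index=t,
                                       time_minutes=t * frame_interval_min))
    return out


def read_movie(path, layout: str = "auto", spacing=None,
               frame_interval_min: float = 15.0):
    """Read an intensity movie as a list of :class:`VolumetricFrame`.

    ``layout``: ``hdf5``, ``tiff`` or ``auto`` (by path type/suffix).
    """
    path = Path(path)
    if layout == "auto":
        layout = "hdf5" if path.suffix in (".h5", ".hdf5") else "tiff"
    if layout == "hdf5":
        frames, _ = read_movie_hdf5(path, spacing=spacing)
        if frames is None:
            raise DataFormatError(f"{path} has no /intensity dataset")
        return frames
    if layout == "tiff":
        return read_tiff_sequence(path, spacing, frame_interval_min)
    raise ConfigError(f"unknown layout {layout!r}")


def read_labels(path, layout: str = "auto", spacing=None):
    """Read a label movie as a list of :class:`LabelVolume`."""
    path = Path(path)
    if layout == "auto":
        layout = "hdf5" if path.suffix in (".h5", ".hdf5") else "tiff"
    if layout == "hdf5":
        _, labels = read_movie_hdf5(path, spacing=spacing)
        if labels is None:
            raise DataFormatError(f"{path} has no /labels dataset")
        return labels
    if layout == "tiff":
        return read_tiff_sequence(path, spacing, labels=True)
    raise ConfigError(f"unknown layout {layout!r}")
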