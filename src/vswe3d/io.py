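"""Container I/O: typed volumes in HDF5 or NPZ, masks in NIfTI or TIFF.

Every container carries its acquisition metadata (axis pitches, drive
frequency, PRF, centre frequency ...) as attributes so a file round-trips
to an identical object; a file missing required metadata is rejected with
the missing key names.  HDF5 is the primary format, NPZ the fallback
(chosen by file suffix).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import h5py
import nibabel as nib
import numpy as np
import tifffile

from .containers import ConformanceMap, DisplacementVolume, IQVolume, WaveField

__all__ = ["write_volume", "read_volume", "write_mask", "read_mask"]

_PathLike = Union[str, Path]

# container kind -> (metadata attributes, array fields)
_SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "WaveField": (("pitch_mm", "frequency_hz"), ("phasor",)),
    "DisplacementVolume": (("pitch_mm", "sample_rate_hz", "drive_frequency_hz"),
                           ("data", "valid")),
    "IQVolume": (("pitch_mm", "centre_frequency_hz", "sound_speed_m_s",
                  "prf_hz", "drive_frequency_hz"), ("data",)),
    "ConformanceMap": (("pitch_mm", "frequency_hz"), ("data", "defined")),
}
_CLASSES = {
    "WaveField": WaveField,
    "DisplacementVolume": DisplacementVolume,
    "IQVolume": IQVolume,
    "ConformanceMap": ConformanceMap,
}

Volume = Union[WaveField, DisplacementVolume, IQVolume, ConformanceMap]


def _container_kind(volume: Volume) -> str:
    kind = type(volume).__name__
    if kind not in _SCHEMAS:
        raise TypeError(f"unsupported container type {kind}")
    return kind


def write_volume(volume: Volume, path: _PathLike) -> None:
    """Write a typed volume to ``.h5``/``.hdf5`` or ``.npz``."""
    path = Path(path)
    kind = _container_kind(volume)
    meta_keys, array_keys = _SCHEMAS[kind]
    arrays = {k: getattr(volume, k) for k in array_keys if getattr(volume, k) is not None}
    meta = {k: np.asarray(getattr(volume, k)) for k in meta_keys}

    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["container"] = kind
            for k, v in meta.items():
                f.attrs[k] = v
            for k, v in arrays.items():
                f.create_dataset(k, data=v)
    elif path.suffix == ".npz":
        payload = {f"meta_{k}": v for k, v in meta.items()}
        payload.update(arrays)
        payload["container"] = np.array(kind)
        np.savez(path, **payload)
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r} (use .h5/.hdf5/.npz)")


def read_volume(path: _PathLike) -> Volume:
    """Read a typed volume written by :func:`write_volume`.

    Raises ``KeyError`` naming the missing metadata keys for incomplete
    (e.g. legacy) containers.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            kind = str(f.attrs.get("container", ""))
            if kind not in _SCHEMAS:
                raise KeyError(f"file does not declare a known container kind: {kind!r}")
            meta_keys, array_keys = _SCHEMAS[kind]
            missing = [k for k in meta_keys if k not in f.attrs]
            if missing:
                raise KeyError(f"container is missing metadata keys: {', '.join(missing)}")
            meta = {k: f.attrs[k] for k in meta_keys}
            arrays = {k: f[k][()] for k in array_keys if k in f}
    elif path.suffix == ".npz":
        with np.load(path) as f:
            if "container" not in f:
                raise KeyError("file does not declare a container kind")
            kind = str(f["container"])
            meta_keys, array_keys = _SCHEMAS[kind]
            missing = [k for k in meta_keys if f"meta_{k}" not in f]
            if missing:
                raise KeyError(f"container is missing metadata keys: {', '.join(missing)}")
            meta = {k: f[f"meta_{k}"] for k in meta_keys}
            arrays = {k: f[k] for k in array_keys if k in f}
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r} (use .h5/.hdf5/.npz)")

    kwargs: dict = {}
    for k, v in meta.items():
        v = np.asarray(v)
        kwargs[k] = tuple(float(x) for x in v) if v.ndim else float(v)
    kwargs.update(arrays)
    return _CLASSES[kind](**kwargs)


def write_mask(mask: np.ndarray, path: _PathLike,
               pitch_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a binary (z, x, y) mask as NIfTI (``.nii``/``.nii.gz``) or
    multipage TIFF (``.tif``/``.tiff``, pages along the elevational axis)."""
    path = Path(path)
    mask = np.asarray(mask, dtype=np.uint8)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag([*pitch_mm, 1.0])
        nib.save(nib.Nifti1Image(mask, affine), str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.moveaxis(mask, 2, 0),
                         metadata={"pitch_mm": list(pitch_mm)})
    else:
        raise ValueError(f"unsupported mask format {path.suffix!r}")


def read_mask(path: _PathLike) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to boolean (z, x, y)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        return data.astype(bool)
    if path.suffix in (".tif", ".tiff"):
        return np.moveaxis(tifffile.imread(path), 0, 2).astype(bool)
    raise ValueError(f"unsupported mask format {path.suffix!r}")
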