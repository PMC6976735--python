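"""NIfTI volume I/O.

NIfTI-1 is the single interchange format of the pipeline. On disk the array
axes follow the NIfTI (x, y, z) convention; in memory the package uses
(slice, row, col) = (z, y, x), so arrays are transposed on read/write and the
voxel spacing is reordered accordingly. Integer volumes round-trip bit-exactly.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .errors import VolumeDimensionError, VolumeIOError
from .volume import ImageVolume, MultiSequenceVolume

_SUPPORTED_DTYPES = ("int16", "int32", "uint8", "uint16", "float32", "float64")


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a 3D NIfTI file into an ImageVolume (axes z, y, x)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error surface varies
        raise VolumeIOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeDimensionError(f"{path}: expected 3D data, got ndim={data.ndim}")
    if data.dtype.name not in _SUPPORTED_DTYPES:
        raise VolumeIOError(f"{path}: unsupported dtype {data.dtype}")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return ImageVolume(
        data=np.ascontiguousarray(data.T),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin=(float(origin[2]), float(origin[1]), float(origin[0])),
    )


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write an ImageVolume as NIfTI-1, preserving spacing and origin."""
    path = os.fspath(path)
    data = np.asarray(vol.data)
    if data.dtype.name not in _SUPPORTED_DTYPES:
        raise VolumeIOError(f"unsupported dtype for NIfTI export: {data.dtype}")
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    img = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, path)


def write_sequences(mr: MultiSequenceVolume, out_dir: str | os.PathLike, prefix: str = "") -> dict:
    """Write each MR channel as its own NIfTI file; returns name -> path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in MultiSequenceVolume.CHANNELS:
        p = os.path.join(os.fspath(out_dir), f"{prefix}{name}.nii.gz")
        write_volume(mr.channel(name), p)
        paths[name] = p
    return paths


def read_sequences(t1: str, t2: str, flair: str) -> MultiSequenceVolume:
    """Read three co-registered sequence files into one MultiSequenceVolume."""
    vols = [read_volume(p) for p in (t1, t2, flair)]
    vols[0].check_geometry(vols[1])
    vols[0].check_geometry(vols[2])
    return MultiSequenceVolume(
        data=np.stack([v.data for v in vols], axis=0),
        spacing=vols[0].spacing,
        origin=vols[0].origin,
    )
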