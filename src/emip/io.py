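"""Readers and writers: volumes (TIFF/NIfTI), PNG renderings, surface sidecars.

Conventions (fixed so round-trips are bit-exact):

* Multi-page TIFF stores 32-bit float pages in increasing depth order;
  page ``k`` is the depth slice ``V[:, :, k]`` with shape ``(n_x, n_y)``.
* NIfTI-1 stores the array in ``(x, y, z)`` axis order with the voxel
  pitch (in mm) on the affine diagonal.
* PNG output is 8-bit RGB; channel values in [0, 1] quantize by
  round-half-up of ``value * 255``.
* The surface sidecar is JSON: polynomial degree, monomial index set,
  coefficients and the finalization offset.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import tifffile
from PIL import Image

from .projection import RGBImage
from .surface import SurfaceFunction, index_set
from .volume import Band, Volume3D, DEFAULT_VOXEL_SIZE_UM

__all__ = [
    "read_volume",
    "write_volume",
    "write_rgb_png",
    "save_surface_sidecar",
    "load_surface_sidecar",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_volume(path: Union[str, Path], band: Union[Band, str]) -> Volume3D:
    """Read a 3D reconstruction from multi-page TIFF or NIfTI-1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj).astype(np.float32)
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NIfTI payload, got ndim={arr.ndim}")
        zooms = img.header.get_zooms()[:3]
        voxel = tuple(float(z) * 1000.0 for z in zooms)  # mm -> um
        if not all(v > 0 for v in voxel):
            voxel = DEFAULT_VOXEL_SIZE_UM
        values = arr
    else:
        arr = tifffile.imread(str(path))
        if arr.ndim == 2:  # single page = single depth slice
            arr = arr[None, ...]
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a 3D TIFF stack, got ndim={arr.ndim}")
        values = np.moveaxis(arr, 0, 2).astype(np.float32)  # (k, x, y) -> (x, y, k)
        voxel = DEFAULT_VOXEL_SIZE_UM
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    return Volume3D(values, Band(band), voxel)


def write_volume(volume: Volume3D, path: Union[str, Path]) -> None:
    """Write a volume as multi-page float32 TIFF or NIfTI-1 (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        import nibabel as nib

        dx, dy, dz = (v / 1000.0 for v in volume.voxel_size_um)  # um -> mm
        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
        nib.save(img, str(path))
    else:
        pages = np.moveaxis(volume.values.astype(np.float32), 2, 0)  # (x,y,k) -> (k,x,y)
        tifffile.imwrite(str(path), pages, photometric="minisblack")


def write_rgb_png(image: RGBImage, path: Union[str, Path]) -> None:
    """Write an RGB rendering as 8-bit PNG (round-half-up quantization)."""
    arr = image.to_array()
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("channel values outside [0, 1]")
    bytes8 = np.floor(arr * 255.0 + 0.5).astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(bytes8, mode="RGB").save(str(path), format="PNG")


_SIDECAR_FIELDS = ("degree", "index_set", "coefficients", "offset")


def save_surface_sidecar(sfit: SurfaceFunction, path: Union[str, Path]) -> None:
    """Persist a surface function as a JSON sidecar (exact round-trip)."""
    payload = {
        "degree": list(sfit.degree),
        "index_set": [list(ik) for ik in index_set(*sfit.degree)],
        "coefficients": [float(c) for c in sfit.coefficients],
        "offset": float(sfit.offset),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))


def load_surface_sidecar(path: Union[str, Path]) -> SurfaceFunction:
    """Load a surface sidecar; raises naming any missing field."""
    data = json.loads(Path(path).read_text())
    for fieldname in _SIDECAR_FIELDS:
        if fieldname not in data:
            raise ValueError(f"surface sidecar missing field {fieldname!r}")
    degree = tuple(int(v) for v in data["degree"])
    stored = [tuple(ik) for ik in data["index_set"]]
    expected = index_set(*degree)
    if stored != expected:
        raise ValueError(
            "surface sidecar index_set does not match the canonical enumeration "
            f"for degree {degree}"
        )
    return SurfaceFunction(
        degree=degree,  # type: ignore[arg-type]
        coefficients=np.asarray(data["coefficients"], dtype=np.float64),
        offset=float(data["offset"]),
    )
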