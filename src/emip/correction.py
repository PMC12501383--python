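"""Surface correction: rasterize the surface and flatten z-columns.

Flattening shifts every z-column so the voxel at the rasterized surface
depth lands at a fixed zero level (default depth index 100, i.e. 400 um
at 4 um depth pitch).  Voxels shifted outside the volume are cut off and
vacated entries are zero-padded; both bands are flattened with the single
shared shift map, since one surface is fitted from the union of both
bands' points.

The shift map rasterizes the skin-level polynomial (without the recorded
conservative offset), so the detected skin lands exactly at the zero
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .surface import SurfaceFunction
from .volume import ScanPair, Volume3D

__all__ = ["ShiftMap", "rasterize_surface", "flatten_volume", "flatten_pair"]


@dataclass
class ShiftMap:
    """Per-column integer surface level ``s_ij`` and the flattening zero level."""

    s: np.ndarray  # (n_x, n_y) int64, 1-based depth indices
    zero_level: int

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.int64)
        if self.s.ndim != 2:
            raise ValueError("shift map must be 2D")
        if self.zero_level < 1:
            raise ValueError("zero_level must be a positive depth index")


def rasterize_surface(
    sfit: SurfaceFunction, lattice: Tuple[int, int, int], zero_level: int = 100
) -> ShiftMap:
    """Nearest depth index of the surface per column (ties to the smaller k).

    Values outside ``D_z`` clamp to the nearest bound.
    """
    n_x, n_y, n_z = lattice
    if not (1 <= zero_level <= n_z):
        raise ValueError(f"zero_level {zero_level} outside D_z = [1, {n_z}]")
    vals = sfit.evaluate_grid(n_x, n_y)
    s = np.ceil(vals - 0.5).astype(np.int64)  # round half down (tie to smaller k)
    s = np.clip(s, 1, n_z)
    return ShiftMap(s=s, zero_level=int(zero_level))


def flatten_volume(volume: Volume3D, shift: ShiftMap) -> Volume3D:
    """Shift each z-column so ``V[i, j, s_ij]`` lands at the zero level.

    ``V'[i, j, k] = V[i, j, k + (s_ij - zero_level)]`` where the source
    index lies in ``D_z``, else 0.
    """
    n_x, n_y, n_z = volume.shape
    if shift.s.shape != (n_x, n_y):
        raise ValueError(
            f"shift map shape {shift.s.shape} does not match lateral lattice "
            f"({n_x}, {n_y})"
        )
    kk = np.arange(1, n_z + 1, dtype=np.int64)[None, None, :]
    src = kk + (shift.s - shift.zero_level)[:, :, None]
    valid = (src >= 1) & (src <= n_z)
    gathered = np.take_along_axis(volume.values, np.clip(src, 1, n_z) - 1, axis=2)
    out = np.where(valid, gathered, np.float32(0.0))
    return Volume3D(out, volume.band, volume.voxel_size_um)


def flatten_pair(pair: ScanPair, shift: ShiftMap) -> ScanPair:
    """Flatten both bands with the shared shift map."""
    return ScanPair(
        lfr=flatten_volume(pair.lfr, shift),
        hfr=flatten_volume(pair.hfr, shift),
    )
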