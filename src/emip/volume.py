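"""Core 3D containers for dual-band optoacoustic reconstructions.

A raster-scan optoacoustic mesoscopy (RSOM) scan is reconstructed twice,
once per frequency band: the low-frequency reconstruction (LFR, large
vessels) and the high-frequency reconstruction (HFR, small vascular
structures).  Both live on the same lattice ``D_xyz = {1..n_x} x {1..n_y}
x {1..n_z}`` where ``x`` is the slow-scanning axis, ``y`` the fast-scanning
axis and ``z`` the depth axis with ``z = 1`` nearest the detector (depth
increases with the index).

Storage is 0-based NumPy (``values[x-1, y-1, z-1]``); every formula that
uses the 1-based lattice semantics converts exactly once at the API
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

import numpy as np

__all__ = ["Band", "Volume3D", "ScanPair", "DEFAULT_VOXEL_SIZE_UM"]

#: Default voxel geometry in micrometres (lateral step 20 um, depth step 4 um).
DEFAULT_VOXEL_SIZE_UM: Tuple[float, float, float] = (20.0, 20.0, 4.0)


class Band(str, Enum):
    """Frequency band of a reconstruction (LF: 10-40 MHz, HF: 40-99 MHz)."""

    LF = "LF"
    HF = "HF"


@dataclass
class Volume3D:
    """One frequency band's reconstruction ``V_ijk`` on the RSOM lattice.

    Parameters
    ----------
    values
        3D float array of shape ``(n_x, n_y, n_z)``.  Stored as float32.
    band
        Which frequency band this reconstruction belongs to.
    voxel_size_um
        ``(dx, dy, dz)`` voxel pitch in micrometres.
    """

    values: np.ndarray
    band: Band
    voxel_size_um: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(
                f"Volume3D requires a 3D array, got ndim={self.values.ndim}"
            )
        if min(self.values.shape) < 1:
            raise ValueError("all lattice dimensions must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite voxels")
        self.band = Band(self.band)
        dx, dy, dz = self.voxel_size_um
        if not (dx > 0 and dy > 0 and dz > 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def n_x(self) -> int:
        return self.values.shape[0]

    @property
    def n_y(self) -> int:
        return self.values.shape[1]

    @property
    def n_z(self) -> int:
        return self.values.shape[2]

    def zcolumn(self, x: int, y: int) -> np.ndarray:
        """Return the z-column ``[V_ij1, ..., V_ijn_z]`` at 1-based ``(x, y)``."""
        if not (1 <= x <= self.n_x and 1 <= y <= self.n_y):
            raise IndexError(f"({x}, {y}) outside lateral lattice")
        return self.values[x - 1, y - 1, :]


@dataclass
class ScanPair:
    """Co-registered LFR/HFR pair of one scan (identical lattice and pitch)."""

    lfr: Volume3D
    hfr: Volume3D

    def __post_init__(self) -> None:
        if self.lfr.band is not Band.LF:
            raise ValueError("ScanPair.lfr must carry band LF")
        if self.hfr.band is not Band.HF:
            raise ValueError("ScanPair.hfr must carry band HF")
        if self.lfr.shape != self.hfr.shape:
            raise ValueError(
                f"band lattices differ: {self.lfr.shape} vs {self.hfr.shape}"
            )
        if not np.allclose(self.lfr.voxel_size_um, self.hfr.voxel_size_um):
            raise ValueError("band voxel sizes differ")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.lfr.shape

    def band(self, band: Band) -> Volume3D:
        return self.lfr if Band(band) is Band.LF else self.hfr
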