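"""Raster tiling, restricted z-projections and local detection thresholds.

Surface-point thresholds are computed locally on a fixed 4 x 4 raster of
the lateral domain so that low-signal regions (edges, corners) still
contribute surface points while bright regions do not flood the detector
with noise hits.  The tile boundaries follow the relative splits
``d = [0, 0.15, 0.5, 0.85, 1]`` of each lateral axis.

All quantiles in the package go through :func:`quantile` (linear
interpolation between order statistics, the "type 7" convention), so that
thresholds, the adaptive quantile inversion and contrast percentiles are
mutually consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .volume import Volume3D

__all__ = [
    "quantile",
    "RasterTiling",
    "SurfaceRange",
    "ThresholdSet",
    "AdaptiveAlphaResult",
    "compute_tiling",
    "tile_of",
    "zmip_restricted",
    "local_thresholds",
    "adaptive_alpha",
]

#: Relative lateral split positions of the 4x4 raster.
TILE_SPLITS = np.array([0.0, 0.15, 0.5, 0.85, 1.0])


def quantile(values, q) -> np.ndarray:
    """Shared quantile routine: linear interpolation between order statistics."""
    return np.quantile(np.asarray(values, dtype=np.float64), q, method="linear")


def relaxed_alpha(alpha: float) -> float:
    """Relaxation used for the global threshold floor: alpha - (1 - alpha)/3."""
    return alpha - (1.0 - alpha) / 3.0


@dataclass(frozen=True)
class RasterTiling:
    """4x4 raster tiling of the lateral domain.

    Boundaries ``a`` (x-axis) and ``b`` (y-axis) hold 5 integers each,
    computed as ``a_j = floor(d_j * n + 1/2)``.  Tile ``t`` (1..16) covers
    the half-open box ``a[xb] < x <= a[xb+1]``, ``b[yb] < y <= b[yb+1]``
    with ``xb = (t-1) mod 4`` and ``yb = ceil(t/4) - 1`` (1-based lattice
    coordinates).
    """

    a: np.ndarray
    b: np.ndarray

    @property
    def n_x(self) -> int:
        return int(self.a[-1])

    @property
    def n_y(self) -> int:
        return int(self.b[-1])

    def tile_map(self) -> np.ndarray:
        """(n_x, n_y) int array of 1-based tile indices for every column."""
        xs = np.arange(1, self.n_x + 1)
        ys = np.arange(1, self.n_y + 1)
        xb = np.searchsorted(self.a, xs, side="left") - 1
        yb = np.searchsorted(self.b, ys, side="left") - 1
        return (4 * yb[None, :] + xb[:, None] + 1).astype(np.int64)


def compute_tiling(n_x: int, n_y: int) -> RasterTiling:
    """Compute the 16-tile raster boundaries for an ``n_x x n_y`` lateral lattice."""
    if n_x < 4 or n_y < 4:
        raise ValueError("lattice too small for a 4x4 raster (need n_x, n_y >= 4)")
    a = np.floor(TILE_SPLITS * n_x + 0.5).astype(np.int64)
    b = np.floor(TILE_SPLITS * n_y + 0.5).astype(np.int64)
    if np.any(np.diff(a) < 1) or np.any(np.diff(b) < 1):
        raise ValueError(
            f"lattice {n_x}x{n_y} too small for 4 distinct nonempty tiles per axis"
        )
    return RasterTiling(a=a, b=b)


def tile_of(tiling: RasterTiling, x: int, y: int) -> int:
    """1-based tile index of lateral position ``(x, y)`` (1-based)."""
    if not (1 <= x <= tiling.n_x and 1 <= y <= tiling.n_y):
        raise ValueError(f"({x}, {y}) outside the lateral domain")
    xb = int(np.searchsorted(tiling.a, x, side="left")) - 1
    yb = int(np.searchsorted(tiling.b, y, side="left")) - 1
    return 4 * yb + xb + 1


@dataclass
class SurfaceRange:
    """Per-column feasible depth interval ``[shallow, deep]`` (or full depth).

    ``shallow``/``deep`` are (n_x, n_y) float maps of 1-based depth indices,
    already clamped to ``D_z``; ``shallow`` is the detector-side bound.
    A ``None`` pair marks the full-depth range.
    """

    n_z: int
    shallow: Optional[np.ndarray] = None
    deep: Optional[np.ndarray] = None

    @classmethod
    def full_depth(cls, n_z: int) -> "SurfaceRange":
        return cls(n_z=n_z)

    @classmethod
    def from_bounds(cls, shallow, deep, n_z: int) -> "SurfaceRange":
        shallow = np.clip(np.asarray(shallow, dtype=np.float64), 1, n_z)
        deep = np.clip(np.asarray(deep, dtype=np.float64), 1, n_z)
        # degenerate columns fall back to the single nearest voxel
        deep = np.maximum(deep, shallow)
        return cls(n_z=n_z, shallow=shallow, deep=deep)

    @property
    def is_full(self) -> bool:
        return self.shallow is None

    def width(self) -> np.ndarray:
        if self.is_full:
            return np.full(1, float(self.n_z))
        return self.deep - self.shallow

    def noise_window(self, half_width: int = 20) -> Tuple[np.ndarray, np.ndarray]:
        """Integer noise interval centered on the shallow (detector-side) bound.

        Returns per-column (lo, hi) inclusive 1-based depth bounds spanning
        ``2*half_width + 1`` indices before clamping to ``D_z``.
        """
        if self.is_full:
            raise ValueError("noise window requires a proper (non-full) range")
        center = np.rint(self.shallow).astype(np.int64)
        lo = np.clip(center - half_width, 1, self.n_z)
        hi = np.clip(center + half_width, 1, self.n_z)
        return lo, hi


@dataclass
class ThresholdSet:
    """Per-tile surface-point thresholds of one band.

    ``thresholds[t-1]`` is the threshold of tile ``t``; ``alpha`` the tile
    quantile actually used and ``alpha_relaxed`` the relaxed quantile of the
    global floor term.
    """

    thresholds: np.ndarray
    alpha: float
    alpha_relaxed: float

    def threshold_map(self, tiling: RasterTiling) -> np.ndarray:
        """(n_x, n_y) map assigning each column its tile's threshold."""
        return self.thresholds[tiling.tile_map() - 1]


def _restriction_mask(volume: Volume3D, rng: SurfaceRange) -> Optional[np.ndarray]:
    if rng.is_full:
        return None
    kk = np.arange(1, volume.n_z + 1)
    return (kk[None, None, :] >= rng.shallow[:, :, None]) & (
        kk[None, None, :] <= rng.deep[:, :, None]
    )


def zmip_restricted(volume: Volume3D, rng: SurfaceRange) -> np.ndarray:
    """Maximum intensity projection along z restricted to the surface range.

    Columns whose restricted interval is empty after clamping fall back to
    the nearest single voxel (guaranteed non-empty by construction of
    :meth:`SurfaceRange.from_bounds`).
    """
    if rng.is_full:
        return volume.values.max(axis=2).astype(np.float64)
    mask = _restriction_mask(volume, rng)
    vals = np.where(mask, volume.values[...], -np.inf).max(axis=2)
    # clamped ranges always contain at least one voxel, but guard anyway
    empty = ~mask.any(axis=2)
    if np.any(empty):
        nearest = np.clip(np.rint(rng.shallow).astype(np.int64), 1, volume.n_z)
        vals = np.where(
            empty,
            np.take_along_axis(volume.values, nearest[:, :, None] - 1, axis=2)[:, :, 0],
            vals,
        )
    return vals.astype(np.float64)


def local_thresholds(
    volume: Volume3D,
    tiling: RasterTiling,
    rng: SurfaceRange,
    alpha: float,
    tau: float,
    sensitivity: float = 1.0,
) -> ThresholdSet:
    """Tile-local thresholds with a relaxed global floor.

    For tile ``t``::

        th_t = max( (tau/sensitivity) * q_alpha(zMIP_rho | tile t),
                    (0.15 * tau/sensitivity) * q_alpha_relaxed(zMIP_rho) )

    with ``alpha_relaxed = alpha - (1 - alpha)/3``.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    zmip = zmip_restricted(volume, rng)
    a_rel = relaxed_alpha(alpha)
    floor = (0.15 * tau / sensitivity) * quantile(zmip.ravel(), a_rel)
    tmap = tiling.tile_map()
    th = np.empty(16, dtype=np.float64)
    for t in range(1, 17):
        tile_vals = zmip[tmap == t]
        local = (tau / sensitivity) * quantile(tile_vals, alpha)
        th[t - 1] = max(local, floor)
    return ThresholdSet(thresholds=th, alpha=float(alpha), alpha_relaxed=float(a_rel))


def _invert_empirical_quantile(svals: np.ndarray, target: float) -> float:
    """Leftmost generalized inverse of the type-7 empirical quantile function.

    Where the quantile function is flat at ``target`` (tied order
    statistics), the smallest quantile attaining it is returned; a lower
    quantile yields lower tile thresholds and hence more surface points,
    which is the purpose of the adaptive quantile.  For distinct values
    this is the exact inverse of linear order-statistic interpolation.
    """
    n = svals.size
    idx = int(np.searchsorted(svals, target, side="left"))
    if idx >= n:
        return 1.0
    if svals[idx] == target:
        return idx / (n - 1)
    if idx == 0:
        return 0.0
    p0, p1 = (idx - 1) / (n - 1), idx / (n - 1)
    frac = (target - svals[idx - 1]) / (svals[idx] - svals[idx - 1])
    return float(p0 + frac * (p1 - p0))


@dataclass
class AdaptiveAlphaResult:
    alpha_adpt: float
    alpha_relaxed: float
    th_target: float
    th_noise: float
    th_min: float
    th_max: float


def adaptive_alpha(
    volume: Volume3D,
    rng: SurfaceRange,
    sensitivity: float,
    alpha_min: float,
    alpha_max: float,
    noise_half_width: int = 20,
) -> AdaptiveAlphaResult:
    """Choose the tile quantile from the noise level just above the surface.

    A 41-voxel window centered on the detector-side bound of the surface
    range samples the local noise floor; its 95th percentile, clamped
    between the ``alpha_min``/``alpha_max`` quantiles of the band's full
    z-MIP, defines a target threshold.  The relaxed quantile matching that
    target is found by inverting the empirical quantile function, and the
    relaxation is undone (``alpha = (3*alpha_relaxed + 1)/4``).
    """
    if rng.is_full:
        raise ValueError("adaptive alpha requires a proper (non-full) surface range")
    lo, hi = rng.noise_window(noise_half_width)
    noise_rng = SurfaceRange.from_bounds(lo, hi, volume.n_z)
    th_noise = float(quantile(zmip_restricted(volume, noise_rng).ravel(), 0.95))

    zmip = volume.values.max(axis=2).astype(np.float64).ravel()
    th_min = float(quantile(zmip, alpha_min)) / sensitivity
    th_max = float(quantile(zmip, alpha_max)) / sensitivity
    th_target = min(max(th_noise, th_min), th_max)

    svals = np.sort(zmip)
    if svals[0] == svals[-1]:
        warnings.warn(
            "degenerate z-MIP (all values equal); adaptive alpha clamped",
            RuntimeWarning,
        )
        a_rel = relaxed_alpha(alpha_min)
    else:
        a_rel = _invert_empirical_quantile(svals, sensitivity * th_target)
    alpha_adpt = float((3.0 * a_rel + 1.0) / 4.0)
    return AdaptiveAlphaResult(
        alpha_adpt=alpha_adpt,
        alpha_relaxed=float(a_rel),
        th_target=th_target,
        th_noise=th_noise,
        th_min=th_min,
        th_max=th_max,
    )
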