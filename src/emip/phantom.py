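"""Synthetic dual-band RSOM phantoms with a known skin surface.

The generator emulates the structures that drive (and stress) surface
detection in real scans: a bright melanin sheet at the skin surface, a
vascular bed below it (thick tubes in the low-frequency band, thin tubes
in the high-frequency band), bright hair shafts strictly above the
surface, additive Gaussian noise and isolated outlier voxels.  The true
surface is a known bivariate polynomial, so detection and flattening can
be scored exactly.

Default lattice (200, 100, 500) emulates a 4 mm x 2 mm field of view at
0.020 mm lateral steps with 4 um depth sampling.  Intensities are in
arbitrary reconstruction units; the melanin sheet is the global maximum
structure by default, and hairs default to 1.5x the melanin intensity to
stress outlier exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .volume import Band, ScanPair, Volume3D

__all__ = ["PhantomSpec", "GroundTruth", "generate_phantom", "evaluate_true_surface"]


@dataclass
class PhantomSpec:
    """Specification of one synthetic LFR/HFR phantom pair.

    ``surface_coefficients`` maps lateral monomials ``(i, k)`` to the
    coefficient of ``x^i y^k`` in the true surface polynomial
    ``z_true(x, y)`` (1-based lattice coordinates, total degree <= 3).
    """

    lattice: Tuple[int, int, int] = (200, 100, 500)
    surface_coefficients: Dict[Tuple[int, int], float] = field(
        default_factory=lambda: {(0, 0): 150.0}
    )
    melanin_intensity: float = 100.0
    melanin_thickness: int = 3
    vessel_intensity_lf: float = 60.0
    vessel_intensity_hf: float = 40.0
    n_vessels: int = 6
    n_hairs: int = 0
    hair_intensity: float = 150.0
    noise_sd: float = 0.0
    outlier_fraction: float = 0.0
    seed: int = 0

    def true_surface_map(self) -> np.ndarray:
        """Dense (n_x, n_y) evaluation of the true surface polynomial."""
        n_x, n_y, _ = self.lattice
        xs = np.arange(1, n_x + 1, dtype=np.float64)[:, None]
        ys = np.arange(1, n_y + 1, dtype=np.float64)[None, :]
        z = np.zeros((n_x, n_y), dtype=np.float64)
        for (i, k), c in self.surface_coefficients.items():
            z += c * xs**i * ys**k
        return z

    def validate(self) -> None:
        n_x, n_y, n_z = self.lattice
        if min(n_x, n_y) < 4 or n_z < 1:
            raise ValueError("lattice too small for a phantom")
        for (i, k) in self.surface_coefficients:
            if i + k > 3:
                raise ValueError("true surface degree is limited to 3")
        for name in (
            "melanin_intensity",
            "vessel_intensity_lf",
            "vessel_intensity_hf",
            "hair_intensity",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.melanin_thickness < 2 or self.melanin_thickness > 4:
            raise ValueError("melanin sheet thickness must be 2-4 voxels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.n_vessels < 0 or self.n_hairs < 0:
            raise ValueError("structure counts must be nonnegative")
        z = self.true_surface_map()
        if z.min() < 40 or z.max() > n_z - 100:
            raise ValueError(
                f"true surface [{z.min():.1f}, {z.max():.1f}] must stay within "
                f"[40, {n_z - 100}] to leave room above and below"
            )


@dataclass
class GroundTruth:
    """Known structure of a generated phantom."""

    true_surface: np.ndarray  # (n_x, n_y) float depth map
    hair_mask: np.ndarray  # boolean voxel mask
    vessel_mask: np.ndarray  # boolean voxel mask


def _render_capsule(
    canvas: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    radius: float,
    intensity: float,
    mask: np.ndarray,
) -> None:
    """Draw a capsule (segment dilated by ``radius``) into ``canvas`` (max blend)."""
    n_x, n_y, n_z = canvas.shape
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius).astype(int), 1)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius).astype(int), [n_x, n_y, n_z])
    if np.any(lo > hi):
        return
    xs = np.arange(lo[0], hi[0] + 1, dtype=np.float64)
    ys = np.arange(lo[1], hi[1] + 1, dtype=np.float64)
    zs = np.arange(lo[2], hi[2] + 1, dtype=np.float64)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0.0:
        t = np.zeros_like(gx)
    else:
        t = ((gx - p0[0]) * d[0] + (gy - p0[1]) * d[1] + (gz - p0[2]) * d[2]) / len2
        t = np.clip(t, 0.0, 1.0)
    dx = gx - (p0[0] + t * d[0])
    dy = gy - (p0[1] + t * d[1])
    dz = gz - (p0[2] + t * d[2])
    inside = dx * dx + dy * dy + dz * dz <= radius * radius
    sl = (slice(lo[0] - 1, hi[0]), slice(lo[1] - 1, hi[1]), slice(lo[2] - 1, hi[2]))
    canvas[sl] = np.where(inside, np.maximum(canvas[sl], intensity), canvas[sl])
    mask[sl] |= inside


def generate_phantom(spec: PhantomSpec) -> Tuple[ScanPair, GroundTruth]:
    """Generate a deterministic LFR/HFR phantom pair with ground truth.

    The melanin sheet occupies depth indices ``ceil(z_true) ..
    ceil(z_true) + thickness - 1`` in both bands, so with zero noise the
    first voxel at or above half the melanin intensity in every z-column
    sits at ``ceil(z_true(x, y))``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_x, n_y, n_z = spec.lattice
    z_true = spec.true_surface_map()

    lf = np.zeros(spec.lattice, dtype=np.float64)
    hf = np.zeros(spec.lattice, dtype=np.float64)
    kk = np.arange(1, n_z + 1)[None, None, :]

    # melanin sheet (both bands)
    top = np.ceil(z_true)[:, :, None]
    sheet = (kk >= top) & (kk <= top + spec.melanin_thickness - 1)
    lf[sheet] = spec.melanin_intensity
    hf[sheet] = spec.melanin_intensity

    vessel_mask = np.zeros(spec.lattice, dtype=bool)
    for band_canvas, radius_rng, intensity in (
        (lf, (3.0, 6.0), spec.vessel_intensity_lf),
        (hf, (1.0, 2.0), spec.vessel_intensity_hf),
    ):
        for _ in range(spec.n_vessels):
            x0 = rng.uniform(1, n_x)
            y0 = rng.uniform(1, n_y)
            x1 = float(np.clip(x0 + rng.uniform(-80, 80), 1, n_x))
            y1 = float(np.clip(y0 + rng.uniform(-80, 80), 1, n_y))
            zlo = max(float(z_true.max()) + spec.melanin_thickness + 20, 1.0)
            z0 = rng.uniform(zlo, min(zlo + 200, n_z - 5))
            z1 = float(np.clip(z0 + rng.uniform(-40, 40), zlo, n_z - 5))
            radius = rng.uniform(*radius_rng)
            _render_capsule(
                band_canvas,
                np.array([x0, y0, z0]),
                np.array([x1, y1, z1]),
                radius,
                intensity,
                vessel_mask,
            )

    # hairs: bright line segments strictly above the surface (smaller k)
    hair_mask = np.zeros(spec.lattice, dtype=bool)
    if spec.n_hairs > 0:
        above = kk < z_true[:, :, None]
        for _ in range(spec.n_hairs):
            x0 = rng.uniform(1, n_x)
            y0 = rng.uniform(1, n_y)
            ang = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(20, 60)
            x1 = float(np.clip(x0 + length * np.cos(ang), 1, n_x))
            y1 = float(np.clip(y0 + length * np.sin(ang), 1, n_y))
            # hairs float in the coupling medium, clearly above the skin line
            gap = rng.uniform(40, 90)
            z0 = float(z_true[int(round(x0)) - 1, int(round(y0)) - 1]) - gap
            z1 = float(z_true[int(round(x1)) - 1, int(round(y1)) - 1]) - gap
            one_hair = np.zeros(spec.lattice, dtype=bool)
            scratch = np.zeros(spec.lattice, dtype=np.float64)
            _render_capsule(
                scratch,
                np.array([x0, y0, z0]),
                np.array([x1, y1, z1]),
                1.5,
                spec.hair_intensity,
                one_hair,
            )
            # placement rule: hair voxels lie strictly above the local surface
            one_hair &= above
            lf[one_hair] = np.maximum(lf[one_hair], spec.hair_intensity)
            hf[one_hair] = np.maximum(hf[one_hair], spec.hair_intensity)
            hair_mask |= one_hair

    if spec.outlier_fraction > 0.0:
        n_out = int(round(spec.outlier_fraction * lf.size))
        for canvas in (lf, hf):
            idx = rng.integers(0, lf.size, size=n_out)
            flat = canvas.reshape(-1)
            flat[idx] = np.maximum(flat[idx], 2.0 * spec.melanin_intensity)

    if spec.noise_sd > 0.0:
        lf += rng.normal(0.0, spec.noise_sd, size=spec.lattice)
        hf += rng.normal(0.0, spec.noise_sd, size=spec.lattice)

    pair = ScanPair(
        lfr=Volume3D(lf, Band.LF),
        hfr=Volume3D(hf, Band.HF),
    )
    gt = GroundTruth(true_surface=z_true, hair_mask=hair_mask, vessel_mask=vessel_mask)
    return pair, gt


def evaluate_true_surface(gt: GroundTruth, x: int, y: int) -> float:
    """True surface depth at 1-based lateral position ``(x, y)``."""
    n_x, n_y = gt.true_surface.shape
    if not (1 <= x <= n_x and 1 <= y <= n_y):
        raise ValueError(f"({x}, {y}) outside the lateral lattice")
    return float(gt.true_surface[x - 1, y - 1])
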