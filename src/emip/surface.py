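"""Iterative skin-surface detection for dual-band RSOM volumes.

The detector alternates four building blocks over a fixed number of outer
iterations: (1) find candidate surface points — the first voxel per
z-column inside the current feasible range that exceeds its raster tile's
threshold, separately for the LF and HF band; (2) fit a bivariate
polynomial surface to the point cloud, either by RANSAC (planes only) or
by penalized least squares with data-driven degree selection; (3) exclude
outliers whose residual leaves a band derived from the global residual
spread and per-tile second moments; (4) narrow the per-column feasible
depth range around the current fit.  After the last iteration a small
offset (80th residual percentile + sd/5 + 3 voxels) is recorded on the
surface so that a conservative above-skin boundary is available alongside
the skin-level fit.

Polynomial fitting is performed in lateral coordinates centered and
scaled to [-1, 1] for conditioning; coefficients are reported back in raw
lattice coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import ADAPTIVE, DetectionConfig, FitMethod, IterationParams
from .tiling import (
    RasterTiling,
    SurfaceRange,
    ThresholdSet,
    adaptive_alpha,
    compute_tiling,
    local_thresholds,
    quantile,
)
from .volume import Band, ScanPair, Volume3D

__all__ = [
    "SurfacePointSet",
    "SurfaceFunction",
    "ResidualStats",
    "SurfaceNotFoundError",
    "index_set",
    "penalty",
    "find_surface_points",
    "fit_polyfit",
    "fit_ransac",
    "exclude_outliers",
    "feasible_range",
    "finalize_surface",
    "detect_surface",
]


class SurfaceNotFoundError(RuntimeError):
    """Raised when an iteration produces no surface points."""

    def __init__(self, iteration: int, message: str = ""):
        self.iteration = iteration
        super().__init__(
            message or f"surface not found: no surface points at iteration {iteration}"
        )


def index_set(n: int, m: int) -> List[Tuple[int, int]]:
    """Monomial exponents of a degree-(n, m) surface polynomial.

    ``I = {(i, k): i <= n, k <= m, i + k <= max(n, m)}`` enumerated
    row-major in ``i`` then ``k`` — the canonical coefficient ordering used
    throughout (fits, sidecars, evaluation).
    """
    cap = max(n, m)
    return [(i, k) for i in range(n + 1) for k in range(m + 1) if i + k <= cap]


def penalty(n: int, m: int) -> float:
    """Degree penalty ``1.01^((m-1)^2 + (n-1)^2)`` favoring low degrees."""
    return 1.01 ** ((m - 1) ** 2 + (n - 1) ** 2)


@dataclass
class SurfacePointSet:
    """Candidate surface voxels with per-point band origin and inclusion flag.

    Coordinates are 1-based lattice indices.  At most one point per
    (z-column, band).  ``included`` marks membership in the current
    ``S_inc``.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    band: np.ndarray  # array of "LF"/"HF" strings
    included: np.ndarray  # bool

    def __len__(self) -> int:
        return self.x.size

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def included_coords(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = self.included
        return self.x[m], self.y[m], self.z[m]


@dataclass
class SurfaceFunction:
    """Bivariate polynomial surface ``sfit(x, y) = sum c_ik x^i y^k``.

    ``offset`` is 0 until finalized; the finalized surface's conservative
    above-skin boundary is ``sfit(x, y) + offset`` (deeper by ``offset``
    voxels; see :func:`finalize_surface`).
    """

    degree: Tuple[int, int]
    coefficients: np.ndarray  # aligned with index_set(*degree)
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        n, m = self.degree
        if self.coefficients.size != len(index_set(n, m)):
            raise ValueError(
                f"degree {self.degree} requires {len(index_set(n, m))} coefficients, "
                f"got {self.coefficients.size}"
            )

    def evaluate(self, x, y, include_offset: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        out = np.zeros(np.broadcast(x, y).shape, dtype=np.float64)
        for (i, k), c in zip(index_set(*self.degree), self.coefficients):
            out += c * x**i * y**k
        if include_offset:
            out = out + self.offset
        return out

    def __call__(self, x, y) -> np.ndarray:
        return self.evaluate(x, y)

    def evaluate_grid(self, n_x: int, n_y: int, include_offset: bool = False) -> np.ndarray:
        xs = np.arange(1, n_x + 1, dtype=np.float64)[:, None]
        ys = np.arange(1, n_y + 1, dtype=np.float64)[None, :]
        return self.evaluate(xs, ys, include_offset=include_offset)


@dataclass
class ResidualStats:
    """Residuals ``r_j = sfit(x_j, y_j) - z_j`` of the included points."""

    residuals: np.ndarray
    sigma: float  # sample (n-1) standard deviation
    gamma: np.ndarray  # per-tile RMS roots, len 16 (empty tiles carry sigma)


# ---------------------------------------------------------------------------
# find surface points

def find_surface_points(
    pair: ScanPair,
    thresholds: Dict[Band, ThresholdSet],
    rng: SurfaceRange,
    tiling: RasterTiling,
) -> SurfacePointSet:
    """First suprathreshold voxel per z-column and band inside the range.

    Columns without a qualifying voxel contribute no point.  The union of
    both bands' points constitutes the candidate set ``S``.
    """
    xs_all: List[np.ndarray] = []
    ys_all: List[np.ndarray] = []
    zs_all: List[np.ndarray] = []
    bands_all: List[np.ndarray] = []
    kk = np.arange(1, pair.shape[2] + 1)[None, None, :]
    for band in (Band.LF, Band.HF):
        vol = pair.band(band)
        thmap = thresholds[band].threshold_map(tiling)
        cond = vol.values >= thmap[:, :, None]
        if not rng.is_full:
            cond &= (kk >= rng.shallow[:, :, None]) & (kk <= rng.deep[:, :, None])
        found = cond.any(axis=2)
        first = cond.argmax(axis=2) + 1  # 1-based depth of first hit
        fx, fy = np.nonzero(found)
        xs_all.append(fx + 1)
        ys_all.append(fy + 1)
        zs_all.append(first[found])
        bands_all.append(np.full(fx.size, band.value, dtype=object))
    return SurfacePointSet(
        x=np.concatenate(xs_all).astype(np.int64),
        y=np.concatenate(ys_all).astype(np.int64),
        z=np.concatenate(zs_all).astype(np.int64),
        band=np.concatenate(bands_all),
        included=np.ones(sum(a.size for a in xs_all), dtype=bool),
    )


# ---------------------------------------------------------------------------
# polynomial fitting

def _scaling(v: np.ndarray) -> Tuple[float, float]:
    lo, hi = float(v.min()), float(v.max())
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    return center, half if half > 0 else 1.0


def _design(xs: np.ndarray, ys: np.ndarray, n: int, m: int) -> np.ndarray:
    return np.column_stack([xs**i * ys**k for i, k in index_set(n, m)])


def _rescale_coefficients(
    coeffs: np.ndarray, n: int, m: int, cx: float, sx: float, cy: float, sy: float
) -> np.ndarray:
    """Convert coefficients on scaled coords ((x-cx)/sx, (y-cy)/sy) to raw coords."""
    idx = index_set(n, m)
    C = np.zeros((n + 1, m + 1))
    for (i, k), c in zip(idx, coeffs):
        C[i, k] = c

    def expansion(center: float, scale: float, deg: int) -> np.ndarray:
        # ((v - center)/scale)^i = sum_j M[i, j] v^j
        M = np.zeros((deg + 1, deg + 1))
        for i in range(deg + 1):
            for j in range(i + 1):
                M[i, j] = comb(i, j) * (-center) ** (i - j) / scale**i
        return M

    Mx = expansion(cx, sx, n)
    My = expansion(cy, sy, m)
    C_raw = Mx.T @ C @ My
    return np.array([C_raw[i, k] for i, k in idx])


def _ls_fit(
    xs: np.ndarray, ys: np.ndarray, zs: np.ndarray, n: int, m: int
) -> SurfaceFunction:
    """Least-squares polynomial fit (QR-based lstsq) with internal scaling."""
    cx, sx = _scaling(xs)
    cy, sy = _scaling(ys)
    A = _design((xs - cx) / sx, (ys - cy) / sy, n, m)
    coeffs, *_ = np.linalg.lstsq(A, zs.astype(np.float64), rcond=None)
    raw = _rescale_coefficients(coeffs, n, m, cx, sx, cy, sy)
    return SurfaceFunction(degree=(n, m), coefficients=raw)


def default_candidate_degrees(max_degree: int = 4) -> List[Tuple[int, int]]:
    return [(n, m) for n in range(1, max_degree + 1) for m in range(1, max_degree + 1)]


def fit_polyfit(
    points: SurfacePointSet,
    candidate_degrees: Optional[Sequence[Tuple[int, int]]] = None,
    train_fraction: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SurfaceFunction, List[dict]]:
    """Penalized least-squares fit with degree selection on a test split.

    The included points are split once (seeded) into a training set
    (``train_fraction``) and a test set; every candidate degree is fitted
    on the training set and scored by ``penalty(n, m) * SSE`` on the test
    set.  The minimal-cost degree (first in row-major (n, m) order on
    ties) is refitted on all included points.
    """
    if candidate_degrees is None:
        candidate_degrees = default_candidate_degrees()
    rng = rng or np.random.default_rng(0)
    xs, ys, zs = points.included_coords()
    N = xs.size
    if N < 3:
        raise ValueError(f"need at least 3 included points, got {N}")

    order = rng.permutation(N)
    n_test = max(1, int(round((1.0 - train_fraction) * N)))
    n_train = N - n_test
    tr, te = order[:n_train], order[n_train:]

    report: List[dict] = []
    costs: List[Tuple[float, Tuple[int, int]]] = []
    for (n, m) in candidate_degrees:
        n_coef = len(index_set(n, m))
        if n_train < n_coef + 2:
            report.append(
                {"degree": (n, m), "skipped": True, "reason": "underdetermined"}
            )
            continue
        sfit = _ls_fit(xs[tr], ys[tr], zs[tr], n, m)
        resid = sfit(xs[te], ys[te]) - zs[te]
        cost = penalty(n, m) * float(np.sum(resid**2))
        report.append({"degree": (n, m), "skipped": False, "cost": cost})
        costs.append((cost, (n, m)))
    if not costs:
        raise ValueError("all candidate degrees were underdetermined")
    # ties (within numerical resolution) go to the earliest candidate
    min_cost = min(c for c, _ in costs)
    tol = 1e-9 * (1.0 + min_cost)
    n_star, m_star = next(deg for c, deg in costs if c <= min_cost + tol)
    final = _ls_fit(xs, ys, zs, n_star, m_star)
    return final, report


def fit_ransac(
    points: SurfacePointSet,
    sample_size: int = 10,
    max_distance: float = 30.0,
    rng: Optional[np.random.Generator] = None,
    n_trials: int = 200,
) -> SurfaceFunction:
    """RANSAC plane fit (degree (1, 1)): consensus-maximal model refit on inliers.

    Falls back to a plain least-squares plane on all points when no trial
    reaches ``sample_size`` inliers.
    """
    rng = rng or np.random.default_rng(0)
    xs, ys, zs = points.included_coords()
    N = xs.size
    if N < sample_size:
        raise ValueError(f"RANSAC needs >= {sample_size} included points, got {N}")
    best_count = -1
    best_inliers: Optional[np.ndarray] = None
    for _ in range(n_trials):
        idx = rng.choice(N, size=sample_size, replace=False)
        model = _ls_fit(xs[idx], ys[idx], zs[idx], 1, 1)
        resid = np.abs(model(xs, ys) - zs)
        inliers = resid <= max_distance
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers
    if best_count < sample_size or best_inliers is None:
        warnings.warn(
            "RANSAC found no consensus model; falling back to least squares "
            "on all points",
            RuntimeWarning,
        )
        return _ls_fit(xs, ys, zs, 1, 1)
    return _ls_fit(xs[best_inliers], ys[best_inliers], zs[best_inliers], 1, 1)


# ---------------------------------------------------------------------------
# outlier exclusion

def exclude_outliers(
    points: SurfacePointSet,
    sfit: SurfaceFunction,
    tiling: RasterTiling,
    sigma_top: float,
    sigma_bot: float,
    gamma_top: float,
    gamma_bot: float,
    h_abs: float,
) -> Tuple[SurfacePointSet, ResidualStats]:
    """Drop included points whose residual leaves the (-h_bot, h_top) band.

    ``h_top = min(max(sigma_top*sigma, gamma_top*gamma(x, y)), h_abs)`` and
    ``h_bot = max(sigma_bot*sigma, gamma_bot*gamma(x, y))`` with ``sigma``
    the sample sd of the residuals and ``gamma`` the per-tile RMS residual
    (tiles without residuals inherit ``sigma``).  Inequalities are strict;
    a degenerate zero-width band retains exact-fit points.
    """
    xs, ys, zs = points.included_coords()
    r = sfit(xs, ys) - zs
    if r.size < 2:
        warnings.warn(
            "fewer than 2 residuals; outlier exclusion skipped", RuntimeWarning
        )
        stats = ResidualStats(
            residuals=r, sigma=float("nan"), gamma=np.full(16, np.nan)
        )
        return points, stats

    sigma = float(np.std(r, ddof=1))
    tmap = tiling.tile_map()
    tiles = tmap[xs - 1, ys - 1]
    gamma = np.full(16, sigma, dtype=np.float64)
    for t in range(1, 17):
        rt = r[tiles == t]
        if rt.size > 0:
            gamma[t - 1] = float(np.sqrt(np.mean(rt**2)))

    g = gamma[tiles - 1]
    h_top = np.minimum(np.maximum(sigma_top * sigma, gamma_top * g), h_abs)
    h_bot = np.maximum(sigma_bot * sigma, gamma_bot * g)
    keep = (-h_bot < r) & (r < h_top)
    degenerate = (h_top == 0) & (h_bot == 0)
    keep |= degenerate & (r == 0)

    included = points.included.copy()
    included[np.nonzero(points.included)[0][~keep]] = False
    newset = replace(points, included=included)
    return newset, ResidualStats(residuals=r, sigma=sigma, gamma=gamma)


# ---------------------------------------------------------------------------
# feasible range / finalization

def feasible_range(
    sfit: SurfaceFunction,
    theta_top,
    theta_bot,
    lattice: Tuple[int, int, int],
) -> SurfaceRange:
    """Per-column interval (sfit - theta_top, sfit + theta_bot), clamped to D_z.

    ``theta_top`` limits the detector side (shallow bound), ``theta_bot``
    the deep side; the string ``"unbounded"`` for either yields the full
    depth range.
    """
    n_x, n_y, n_z = lattice
    if theta_top == "unbounded" or theta_bot == "unbounded":
        return SurfaceRange.full_depth(n_z)
    vals = sfit.evaluate_grid(n_x, n_y)
    return SurfaceRange.from_bounds(vals - float(theta_top), vals + float(theta_bot), n_z)


def finalize_surface(sfit: SurfaceFunction, residuals: np.ndarray) -> SurfaceFunction:
    """Record the conservative offset: 80th residual percentile + sd/5 + 3.

    ``sfit(x, y) + offset`` bounds at least 80% of the included points from
    below (deeper side); the 3-voxel term guards against residual outliers.
    The skin-level polynomial itself is unchanged.
    """
    r = np.asarray(residuals, dtype=np.float64)
    if r.size < 2:
        warnings.warn("degenerate residuals; offset set to 3", RuntimeWarning)
        offset = 3.0
    else:
        offset = float(quantile(r, 0.80)) + float(np.std(r)) / 5.0 + 3.0
    return replace(sfit, offset=offset)


# ---------------------------------------------------------------------------
# orchestration

_MIN_POINTS = {"ransac": 10, "fit": 5}


def detect_surface(
    pair: ScanPair, config: Optional[DetectionConfig] = None
) -> Tuple[SurfaceFunction, dict]:
    """Run the full iterative surface detection on an LFR/HFR pair.

    Returns the finalized :class:`SurfaceFunction` (skin-level polynomial
    plus recorded offset) and a detection report with per-iteration
    thresholds, point counts, selected degree, residual spread and the
    hyperparameter provenance label.
    """
    config = config or DetectionConfig()
    config.validate()
    n_x, n_y, n_z = pair.shape
    tiling = compute_tiling(n_x, n_y)
    rng = np.random.default_rng(config.random_seed)
    search = SurfaceRange.full_depth(n_z)

    report: dict = {
        "hyperparameters": "non-canonical defaults",
        "defaulted_keys": sorted(config.defaulted_keys),
        "iterations": [],
    }
    sfit: Optional[SurfaceFunction] = None
    stats: Optional[ResidualStats] = None
    points: Optional[SurfacePointSet] = None

    for k in range(1, config.n_outer_iterations + 1):
        it: IterationParams = config.iterations[k - 1]
        iter_log: dict = {"iteration": k, "fit_method": FitMethod(it.fit_method).value}

        thresholds: Dict[Band, ThresholdSet] = {}
        for band in (Band.LF, Band.HF):
            vol = pair.band(band)
            if it.alpha == ADAPTIVE:
                ada = adaptive_alpha(
                    vol, search, config.sensitivity, config.alpha_min, config.alpha_max
                )
                alpha = ada.alpha_adpt
                iter_log[f"adaptive_{band.value}"] = {
                    "alpha_adpt": ada.alpha_adpt,
                    "th_target": ada.th_target,
                    "th_noise": ada.th_noise,
                    "th_min": ada.th_min,
                    "th_max": ada.th_max,
                }
            else:
                alpha = float(it.alpha)
            thresholds[band] = local_thresholds(
                vol, tiling, search, alpha, it.tau, config.sensitivity
            )
            iter_log[f"thresholds_{band.value}"] = thresholds[band].thresholds.tolist()
            iter_log[f"alpha_{band.value}"] = alpha

        points = find_surface_points(pair, thresholds, search, tiling)
        if len(points) == 0:
            raise SurfaceNotFoundError(k)
        iter_log["n_points_found"] = len(points)

        inner_logs: List[dict] = []
        for inner in range(1, config.max_inner_iterations + 1):
            n_before = points.n_included
            method = FitMethod(it.fit_method)
            if method is FitMethod.RANSAC_LINEAR:
                if n_before < config.ransac_sample_size:
                    raise SurfaceNotFoundError(
                        k, f"iteration {k}: too few points ({n_before}) for RANSAC"
                    )
                sfit = fit_ransac(
                    points,
                    sample_size=config.ransac_sample_size,
                    max_distance=config.ransac_max_distance,
                    rng=rng,
                    n_trials=config.ransac_trials,
                )
                degree = (1, 1)
                fit_report: List[dict] = []
            else:
                if method is FitMethod.POLYFIT_FIXED:
                    candidates = [(1, 1)]
                else:
                    candidates = default_candidate_degrees(config.max_degree)
                sfit, fit_report = fit_polyfit(
                    points,
                    candidate_degrees=candidates,
                    train_fraction=config.train_fraction,
                    rng=rng,
                )
                degree = sfit.degree
            points, stats = exclude_outliers(
                points,
                sfit,
                tiling,
                it.sigma_top,
                it.sigma_bot,
                it.gamma_top,
                it.gamma_bot,
                it.h_abs,
            )
            removed = n_before - points.n_included
            inner_logs.append(
                {
                    "inner": inner,
                    "degree": list(degree),
                    "n_included": points.n_included,
                    "removed": removed,
                    "sigma": stats.sigma,
                    "gamma": stats.gamma.tolist(),
                }
            )
            if removed == 0:
                break
            if points.n_included < _MIN_POINTS["fit"]:
                warnings.warn(
                    f"iteration {k}: only {points.n_included} points remain; "
                    "stopping inner loop",
                    RuntimeWarning,
                )
                break
        iter_log["inner"] = inner_logs
        report["iterations"].append(iter_log)

        if k < config.n_outer_iterations:
            search = feasible_range(sfit, it.theta_top, it.theta_bot, pair.shape)

    assert sfit is not None and points is not None
    xs, ys, zs = points.included_coords()
    final_resid = sfit(xs, ys) - zs
    final = finalize_surface(sfit, final_resid)
    report["offset"] = final.offset
    report["degree"] = list(final.degree)
    report["n_points_final"] = points.n_included
    coverage = float(np.mean(final_resid + final.offset >= 0)) if final_resid.size else 0.0
    report["offset_coverage"] = coverage
    report["points"] = points
    return final, report
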