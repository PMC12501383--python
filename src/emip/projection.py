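"""Maximum intensity projections and dual-band contrast fusion.

Two rendering pipelines share the per-band MIP primitive:

* **MIP** (conventional): per-axis projections of the raw volumes, the HF
  image rescaled by the least-squares factor ``alpha* = <im_LF, im_HF> /
  <im_HF, im_HF>``, both channels jointly scaled to [0, 1] between the
  joint minimum and maximum, then passed through a linear saturation
  window (defaults 0.06-0.35).
* **eMIP** (enhanced): the volumes are first flattened to the zero level
  using the detected surface; each band is then contrast-normalized
  independently by an outlier-robust upper threshold
  ``th+ = 1.25 * q_0.95(z-MIP)`` (zero-clip, cap, divide), avoiding the
  global rescale that lets one strong absorber dim the whole image.

The LF channel renders red, the HF channel green, blue stays zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .config import DetectionConfig
from .correction import flatten_pair, rasterize_surface
from .surface import SurfaceFunction
from .tiling import quantile
from .volume import Band, ScanPair, Volume3D

__all__ = [
    "Projection2D",
    "ContrastParams",
    "RGBImage",
    "mip",
    "alpha_optimize",
    "fuse_alpha_joint",
    "dynamic_thresholds",
    "fuse_dynamic",
    "render_mip",
    "render_emip",
]

_AXES = {"x": 0, "y": 1, "z": 2}

#: Default saturation window applied after joint scaling (MIP pipeline).
DEFAULT_SATURATION: Tuple[float, float] = (0.06, 0.35)


@dataclass
class Projection2D:
    """2D maximum intensity projection of one band along one axis."""

    values: np.ndarray
    axis: str
    band: Band


@dataclass
class ContrastParams:
    """Parameters of one of the two fusion modes.

    ``alpha_joint`` uses ``alpha_star`` and the saturation window;
    ``dynamic`` uses the per-band upper thresholds.
    """

    mode: str  # "alpha_joint" | "dynamic"
    alpha_star: Optional[float] = None
    th_lf_plus: Optional[float] = None
    th_hf_plus: Optional[float] = None
    saturation: Tuple[float, float] = DEFAULT_SATURATION

    def __post_init__(self) -> None:
        if self.mode not in ("alpha_joint", "dynamic"):
            raise ValueError(f"unknown contrast mode {self.mode!r}")
        low, high = self.saturation
        if not (0.0 <= low < high <= 1.0):
            raise ValueError("saturation window must satisfy 0 <= low < high <= 1")


@dataclass
class RGBImage:
    """Fused 2D rendering; channels in [0, 1], blue identically zero."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=np.float64)
        self.green = np.asarray(self.green, dtype=np.float64)
        if self.blue is None:
            self.blue = np.zeros_like(self.red)
        if self.red.shape != self.green.shape or self.red.shape != self.blue.shape:
            raise ValueError("channel shapes differ")
        for name, ch in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            if ch.size and (ch.min() < 0.0 or ch.max() > 1.0):
                raise ValueError(f"{name} channel outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.stack([self.red, self.green, self.blue], axis=-1)


def mip(volume: Volume3D, axis: str) -> Projection2D:
    """Maximum intensity projection along ``axis`` ('x', 'y' or 'z')."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    return Projection2D(
        values=volume.values.max(axis=_AXES[axis]).astype(np.float64),
        axis=axis,
        band=volume.band,
    )


def alpha_optimize(im_lf: Projection2D, im_hf: Projection2D) -> float:
    """Least-squares equalization factor ``argmin_a ||im_LF - a*im_HF||_2``."""
    lf, hf = im_lf.values, im_hf.values
    if lf.shape != hf.shape:
        raise ValueError("projections have different shapes")
    denom = float(np.sum(hf * hf))
    if denom == 0.0:
        warnings.warn("HF projection is identically zero; alpha* = 0", RuntimeWarning)
        return 0.0
    return float(np.sum(lf * hf) / denom)


def _saturate(v: np.ndarray, low: float, high: float) -> np.ndarray:
    return np.clip((v - low) / (high - low), 0.0, 1.0)


def fuse_alpha_joint(
    im_lf: Projection2D, im_hf: Projection2D, params: ContrastParams
) -> RGBImage:
    """Joint linear scaling of (alpha*-weighted HF, LF) followed by windowing."""
    if params.alpha_star is None:
        raise ValueError("alpha_joint fusion requires alpha_star")
    hf_star = params.alpha_star * im_hf.values
    lf = im_lf.values
    im_min = min(float(hf_star.min()), float(lf.min()))
    im_max = max(float(hf_star.max()), float(lf.max()))
    if im_max == im_min:
        warnings.warn(
            "degenerate joint range (max == min); rendering a zero image",
            RuntimeWarning,
        )
        zero = np.zeros_like(lf)
        return RGBImage(red=zero, green=zero.copy())
    low, high = params.saturation
    scale = lambda v: _saturate((v - im_min) / (im_max - im_min), low, high)
    return RGBImage(red=scale(lf), green=scale(hf_star))


def dynamic_thresholds(pair: ScanPair) -> Tuple[float, float]:
    """Outlier-robust per-band caps: ``1.25 * q_0.95`` of each band's z-MIP."""
    th = []
    for band in (Band.LF, Band.HF):
        zmip = pair.band(band).values.max(axis=2)
        t = 1.25 * float(quantile(zmip.ravel(), 0.95))
        if t <= 0.0:
            warnings.warn(
                f"nonpositive dynamic threshold for band {band.value}; "
                "channel will render black",
                RuntimeWarning,
            )
        th.append(t)
    return th[0], th[1]


def fuse_dynamic(
    im_lf: Projection2D, im_hf: Projection2D, params: ContrastParams
) -> RGBImage:
    """Per-channel zero-clip, cap at th+, divide by th+."""
    if params.th_lf_plus is None or params.th_hf_plus is None:
        raise ValueError("dynamic fusion requires both per-band thresholds")

    def channel(v: np.ndarray, th: float) -> np.ndarray:
        if th <= 0.0:
            return np.zeros_like(v)
        return np.clip(v, 0.0, th) / th

    return RGBImage(
        red=channel(im_lf.values, params.th_lf_plus),
        green=channel(im_hf.values, params.th_hf_plus),
    )


def render_mip(
    pair: ScanPair,
    axes: Iterable[str] = ("x", "y", "z"),
    saturation: Tuple[float, float] = DEFAULT_SATURATION,
) -> Dict[str, RGBImage]:
    """Conventional MIP rendering; alpha* is optimized per axis."""
    out: Dict[str, RGBImage] = {}
    for axis in axes:
        im_lf = mip(pair.lfr, axis)
        im_hf = mip(pair.hfr, axis)
        alpha = alpha_optimize(im_lf, im_hf)
        params = ContrastParams(
            mode="alpha_joint", alpha_star=alpha, saturation=saturation
        )
        out[axis] = fuse_alpha_joint(im_lf, im_hf, params)
    return out


def render_emip(
    pair: ScanPair,
    sfit: SurfaceFunction,
    config: Optional[DetectionConfig] = None,
    axes: Iterable[str] = ("x", "y", "z"),
    skip_flatten: bool = False,
) -> Dict[str, RGBImage]:
    """Enhanced MIP: flatten to the zero level, then dynamic dual-band contrast.

    Dynamic thresholds are computed on the corrected (flattened) volumes;
    ``skip_flatten`` renders the dynamic contrast without surface
    correction.
    """
    config = config or DetectionConfig()
    if skip_flatten:
        corrected = pair
    else:
        shift = rasterize_surface(sfit, pair.shape, config.zero_level)
        corrected = flatten_pair(pair, shift)
    th_lf, th_hf = dynamic_thresholds(corrected)
    params = ContrastParams(mode="dynamic", th_lf_plus=th_lf, th_hf_plus=th_hf)
    out: Dict[str, RGBImage] = {}
    for axis in axes:
        out[axis] = fuse_dynamic(
            mip(corrected.lfr, axis), mip(corrected.hfr, axis), params
        )
    return out
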