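"""Image-quality and electron-density evaluation.

PSNR and SSIM follow the standard definitions::

    PSNR(I1, I2) = 10 * log10(MAX^2 / RMSE(I1, I2)^2)

    SSIM(I1, I2) = (2*mu1*mu2 + c1)(2*sigma12 + c2)
                   / ((mu1^2 + mu2^2 + c1)(sigma1^2 + sigma2^2 + c2))

with local Gaussian-weighted moments (11x11 window, sigma 1.5) and
c1 = (K1*L)^2, c2 = (K2*L)^2.  The dynamic range defaults to L = MAX =
4000 HU (the CT range -1000..3000).  Both metrics support HU-banded
evaluation where band membership is decided by the *reference* image.

CT-number-to-RED conversion is a monotone piecewise-linear calibration
curve (HU, RED); separate default curves ship for CT and MV-CBCT because
their CT-ED relations differ.  The default curves are synthetic,
simulator-consistent placeholders, not clinical calibrations.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging

import numpy as np
from scipy import ndimage

from .core import ImageVolume, StructureMask, _require_same_shape

logger = logging.getLogger(__name__)

__all__ = [
    "MetricParams",
    "REDCurve",
    "psnr",
    "ssim",
    "hu_to_red",
    "roi_red_stats",
    "artifact_index",
    "default_red_curve",
]


@dataclasses.dataclass(frozen=True)
class MetricParams:
    """PSNR/SSIM constants; defaults are the standard reference values."""

    max_value: float = 4000.0  # HU dynamic range -1000..3000
    k1: float = 0.01
    k2: float = 0.03
    window: int = 11
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.max_value <= 0:
            raise ValueError("max_value must be positive")
        if self.window % 2 != 1:
            raise ValueError("window must be odd")

    @property
    def c1(self) -> float:
        return (self.k1 * self.max_value) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.max_value) ** 2


def _as_array(img) -> np.ndarray:
    if isinstance(img, ImageVolume):
        return img.values
    return np.asarray(img, dtype=np.float64)


def _band_mask(ref: np.ndarray, band: tuple[float, float] | None) -> np.ndarray:
    if band is None:
        return np.ones_like(ref, dtype=bool)
    lo, hi = band
    return (ref >= lo) & (ref <= hi)


def psnr(a, b, params: MetricParams | None = None, band: tuple[float, float] | None = None) -> float:
    """Peak signal-to-noise ratio in dB over pixels whose reference HU lies in ``band``.

    ``a`` is the reference.  Identical selections return ``math.inf`` (the
    zero-RMSE sentinel) rather than raising.
    """
    params = params or MetricParams()
    av, bv = _as_array(a), _as_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"image shapes differ: {av.shape} vs {bv.shape}")
    sel = _band_mask(av, band)
    if not sel.any():
        raise ValueError(f"no reference pixels in band {band}")
    mse = float(np.mean((av[sel] - bv[sel]) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(params.max_value**2 / mse)


def _gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    half = window // 2
    g = np.exp(-np.arange(-half, half + 1) ** 2 / (2.0 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def ssim_map(a, b, params: MetricParams | None = None) -> np.ndarray:
    """The local SSIM map on the valid interior (no boundary padding)."""
    params = params or MetricParams()
    av, bv = _as_array(a), _as_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"image shapes differ: {av.shape} vs {bv.shape}")
    if av.ndim != 2:
        raise ValueError("ssim operates on 2-D slices")
    if min(av.shape) < params.window:
        raise ValueError(f"window {params.window} larger than image {av.shape}")
    kern = _gaussian_kernel(params.window, params.sigma)
    half = params.window // 2

    def w(img: np.ndarray) -> np.ndarray:
        return ndimage.correlate(img, kern, mode="constant")[half:-half, half:-half]

    mu1, mu2 = w(av), w(bv)
    s11 = w(av * av) - mu1 * mu1
    s22 = w(bv * bv) - mu2 * mu2
    s12 = w(av * bv) - mu1 * mu2
    c1, c2 = params.c1, params.c2
    return ((2 * mu1 * mu2 + c1) * (2 * s12 + c2)) / ((mu1**2 + mu2**2 + c1) * (s11 + s22 + c2))


def ssim(a, b, params: MetricParams | None = None, band: tuple[float, float] | None = None) -> float:
    """Mean structural similarity; band selection uses the reference image's
    HU at each window center."""
    params = params or MetricParams()
    smap = ssim_map(a, b, params)
    av = _as_array(a)
    half = params.window // 2
    sel = _band_mask(av[half:-half, half:-half], band)
    if not sel.any():
        raise ValueError(f"no reference pixels in band {band}")
    return float(np.mean(smap[sel]))


# ---------------------------------------------------------------------------
# CT number -> relative electron density
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class REDCurve:
    """Monotone piecewise-linear (HU, RED) calibration curve.

    Below the first knot RED floors at 0; above the last knot the curve
    extrapolates flat (and logs that it did).
    """

    hu: np.ndarray
    red: np.ndarray
    name: str = "red-curve"

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float64)
        self.red = np.asarray(self.red, dtype=np.float64)
        if self.hu.ndim != 1 or self.hu.shape != self.red.shape:
            raise ValueError("hu and red must be matching 1-D arrays")
        if not np.all(np.diff(self.hu) > 0):
            raise ValueError("curve HU knots must be strictly increasing")
        if not np.all(np.diff(self.red) >= 0):
            raise ValueError("curve RED values must be non-decreasing")

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "REDCurve":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(hu=data[:, 0], red=data[:, 1], name=name or str(path))

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu, dtype=np.float64)
        if np.any(hu > self.hu[-1]):
            logger.info("%s: flat extrapolation above last knot (%g HU)", self.name, self.hu[-1])
        return np.interp(hu, self.hu, self.red, left=0.0, right=self.red[-1])


def default_red_curve(modality: str) -> REDCurve:
    """The packaged synthetic calibration curve for ``"ct"`` or ``"mv"``."""
    mod = "ct" if modality in ("ct", "sct") else "mv"
    ref = importlib.resources.files("mvmar.data") / f"red_curve_{mod}.csv"
    with importlib.resources.as_file(ref) as path:
        return REDCurve.from_csv(path, name=f"default-{mod}")


def hu_to_red(vol: ImageVolume, curve: REDCurve) -> np.ndarray:
    """Convert an HU image to a relative-electron-density map."""
    return curve(vol.values)


def roi_red_stats(red_map: np.ndarray, mask: StructureMask, bin_edges: np.ndarray | None = None) -> dict:
    """Mean/std/histogram of RED inside an ROI.

    Default histogram: 0.004-wide bins over [0.9, 1.2], fine enough to
    resolve the soft-tissue band where streaks corrupt RED.
    """
    if mask.mask.shape != red_map.shape:
        raise ValueError("mask shape does not match RED map shape")
    vals = red_map[mask.mask]
    if vals.size == 0:
        raise ValueError(f"mask {mask.name!r} is empty")
    if bin_edges is None:
        bin_edges = np.arange(0.9, 1.2 + 1e-12, 0.004)
    hist, edges = np.histogram(vals, bins=bin_edges)
    return {
        "name": mask.name,
        "mean": float(vals.mean()),
        "std": float(vals.std()),
        "n": int(vals.size),
        "hist": hist,
        "bin_edges": edges,
    }


# ---------------------------------------------------------------------------
# Streak artifact index
# ---------------------------------------------------------------------------

def artifact_index(
    vol: ImageVolume,
    soft_tissue_mask: StructureMask,
    metal_mask: StructureMask | None = None,
    truth: ImageVolume | None = None,
    radius_mm: float = 30.0,
) -> float:
    """Robust streak severity: the 5-95 inter-percentile HU spread over
    soft tissue near metal, minus the same spread on the ground truth.

    When a metal mask with any pixels is given, the statistic is restricted
    to soft-tissue pixels within ``radius_mm`` of metal (where streaks
    concentrate); otherwise the whole soft-tissue mask is used.  Subtracting
    the truth's spread removes genuine anatomical contrast, so the index is
    ~0 for a perfect reconstruction and grows with streak amplitude.
    """
    soft = soft_tissue_mask.mask
    if not soft.any():
        raise ValueError("soft-tissue mask is empty")
    region = soft
    if metal_mask is not None and metal_mask.mask.any():
        spacing = vol.spacing[-1]
        dist = ndimage.distance_transform_edt(~metal_mask.mask, sampling=vol.spacing[-2:])
        region = soft & (dist <= radius_mm)
        if not region.any():
            region = soft
    vals = vol.values[region] if vol.values.ndim == 2 else vol.plane[region]
    lo, hi = np.percentile(vals, [5.0, 95.0])
    idx = float(hi - lo)
    if truth is not None:
        tvals = truth.values[region] if truth.values.ndim == 2 else truth.plane[region]
        tlo, thi = np.percentile(tvals, [5.0, 95.0])
        idx -= float(thi - tlo)
    return idx
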