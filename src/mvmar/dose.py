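"""Dose evaluation: toy dose engine, gamma analysis, DVH metrics.

The toy dose engine is a deliberately simple primary-beam model — a
configurable set of coplanar beams, each attenuating exponentially along
parallel rays through the relative-electron-density (RED) map — normalized
to the prescription at a reference point.  It contains just enough physics
for RED differences between two images to move dose metrics, while staying
verifiable against a closed form.

Gamma analysis implements the standard global criterion: a reference point
passes when some test point within the search radius satisfies
``sqrt((dr/DTA)^2 + (dD/(p * Dnorm))^2) <= 1`` with DTA the
distance-to-agreement (mm) and ``p`` the dose-difference fraction.  DVH
metrics (Dmean, Dx, Vx%, D0.1cc) are order statistics over ROI voxels.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .core import StructureMask

__all__ = [
    "DoseGrid",
    "BeamSpec",
    "GammaCriteria",
    "toy_dose",
    "gamma_pass_rate",
    "dvh_metrics",
    "dose_compare",
    "PAPER_METRIC_SET",
]

#: Per-ROI metric sets for the dose comparison report.
PAPER_METRIC_SET: dict[str, tuple[str, ...]] = {
    "ptv": ("Dmean", "D5", "D95", "V95%", "V100%", "V110%"),
    "mandible": ("D2", "Dmean"),
    "oral_cavity": ("D50", "Dmean"),
    "parotid": ("D50", "Dmean"),
    "spinal_cord": ("D0.1cc",),
}


@dataclasses.dataclass
class DoseGrid:
    """A non-negative dose raster (cGy) with spacing and prescription."""

    dose: np.ndarray
    spacing: tuple[float, ...]
    prescription: float = 6000.0
    origin: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative everywhere")
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)
        if not self.origin:
            self.origin = (0.0,) * self.dose.ndim

    @property
    def voxel_volume_cc(self) -> float:
        vol_mm3 = float(np.prod(self.spacing))
        if self.dose.ndim == 2:
            vol_mm3 *= 1.0  # unit slice thickness (1 mm) for 2-D grids
        return vol_mm3 / 1000.0


@dataclasses.dataclass
class BeamSpec:
    """Coplanar parallel beams entering from the given angles (degrees).

    0 enters from the top edge (rays travel down rows), 90 from the left
    edge, 180 from the bottom, 270 from the right.  Only multiples of 90
    are supported, keeping the engine exactly verifiable against the
    closed-form exponential.
    """

    angles: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    #: Linear attenuation per unit RED per mm of path.
    k: float = 0.005
    prescription: float = 6000.0
    #: Normalization point (voxel index); default: grid center.
    norm_point: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.angles) == 0:
            raise ValueError("at least one beam angle is required")
        for a in self.angles:
            if a % 90 != 0:
                raise ValueError("beam angles must be multiples of 90 degrees")


def _beam_dose(red: np.ndarray, spacing_mm: float, k: float, angle: float) -> np.ndarray:
    """Primary fluence of one parallel beam through the RED map.

    Attenuation to a voxel uses the path to the voxel *center*:
    path = spacing * (cumsum(red) - red/2) along the ray direction.
    """
    turns = int(angle // 90) % 4
    r = np.rot90(red, k=turns)  # beam now enters from the top, travels down rows
    path = spacing_mm * (np.cumsum(r, axis=0) - r / 2.0)
    d = np.exp(-k * path)
    return np.rot90(d, k=-turns)


def toy_dose(red: np.ndarray, beams: BeamSpec, spacing: tuple[float, ...] = (1.0, 1.0)) -> DoseGrid:
    """Deterministic toy dose: summed attenuated beams scaled to prescription.

    ``red`` is a 2-D relative-electron-density map.  Dose strictly
    decreases with depth along each ray wherever RED > 0.
    """
    red = np.asarray(red, dtype=np.float64)
    if red.ndim != 2:
        raise ValueError("toy_dose operates on 2-D RED maps")
    if np.any(red < 0):
        raise ValueError("RED must be non-negative")
    total = np.zeros_like(red)
    for ang in beams.angles:
        total += _beam_dose(red, spacing[-1], beams.k, ang)
    point = beams.norm_point or (red.shape[0] // 2, red.shape[1] // 2)
    ref = total[point]
    if ref <= 0:
        raise ValueError("zero dose at the normalization point")
    return DoseGrid(dose=total * (beams.prescription / ref), spacing=spacing, prescription=beams.prescription)


# ---------------------------------------------------------------------------
# Gamma analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class GammaCriteria:
    """dta in mm, dose_diff as a fraction (0.02 for 2%)."""

    dta: float = 2.0
    dose_diff: float = 0.02
    normalization: str = "global-max"  # or "prescription"
    low_dose_cutoff: float = 0.0  # fraction of Dnorm below which ref points are skipped

    def __post_init__(self) -> None:
        if self.dta <= 0 or self.dose_diff <= 0:
            raise ValueError("dta and dose_diff must be positive")
        if self.normalization not in ("global-max", "prescription"):
            raise ValueError("normalization must be 'global-max' or 'prescription'")


def gamma_pass_rate(
    ref: DoseGrid,
    test: DoseGrid,
    crit: GammaCriteria,
    refine: int = 1,
) -> tuple[float, np.ndarray]:
    """Global gamma pass rate (%) and the per-point gamma map.

    The test grid is searched exhaustively within a radius of 3 * dta of
    each evaluated reference point (any point farther away has a distance
    term > 3, so it cannot change pass/fail).  ``refine > 1`` linearly
    up-samples the test grid by that factor before the search; finer
    interpolation can only increase the pass rate.
    """
    if ref.dose.shape != test.dose.shape or ref.spacing != test.spacing:
        raise ValueError("gamma analysis requires grids on a common geometry")
    rd = ref.dose
    td = test.dose
    spacing = np.asarray(ref.spacing, dtype=float)
    if refine > 1:
        td = ndimage.zoom(td, refine, order=1, grid_mode=True, mode="nearest")
        spacing_t = spacing / refine
    else:
        spacing_t = spacing

    dnorm = float(rd.max()) if crit.normalization == "global-max" else ref.prescription
    if dnorm <= 0:
        raise ValueError("non-positive normalization dose")
    evaluable = rd >= crit.low_dose_cutoff * dnorm
    if not evaluable.any():
        raise ValueError("no evaluable reference points above the low-dose cutoff")

    # search offsets within 3*dta on the test grid
    radius = 3.0 * crit.dta
    half = [int(np.floor(radius / s)) for s in spacing_t]
    offsets = []
    for di in range(-half[0], half[0] + 1):
        for dj in range(-half[1], half[1] + 1):
            dist2 = (di * spacing_t[0]) ** 2 + (dj * spacing_t[1]) ** 2
            if dist2 <= radius**2:
                offsets.append((di, dj, dist2))

    scale = refine if refine > 1 else 1
    gamma2 = np.full(rd.shape, np.inf)
    nt0, nt1 = td.shape
    ii, jj = np.nonzero(evaluable)
    ref_vals = rd[ii, jj]
    for di, dj, dist2 in offsets:
        ti = ii * scale + di
        tj = jj * scale + dj
        ok = (ti >= 0) & (ti < nt0) & (tj >= 0) & (tj < nt1)
        if not ok.any():
            continue
        dd = np.full(ii.shape, np.inf)
        dd[ok] = td[ti[ok], tj[ok]] - ref_vals[ok]
        g2 = dist2 / crit.dta**2 + (dd / (crit.dose_diff * dnorm)) ** 2
        np.minimum.at(gamma2, (ii, jj), g2)

    gmap = np.sqrt(gamma2)
    passed = gmap[evaluable] <= 1.0
    rate = 100.0 * float(np.count_nonzero(passed)) / float(passed.size)
    return rate, gmap


# ---------------------------------------------------------------------------
# DVH metrics
# ---------------------------------------------------------------------------

def dvh_metrics(dose: DoseGrid, roi: StructureMask, prescription: float | None = None) -> dict[str, float]:
    """DVH report for one ROI.

    Dx: dose exceeded by exactly x% of the ROI volume (interpolated order
    statistic).  Vx%: percent of ROI volume receiving at least x% of the
    prescription.  D0.1cc: dose exceeded by the hottest 0.1 cm^3; if the
    ROI is smaller than 0.1 cc this falls back to Dmax with a warning.
    """
    if roi.mask.shape != dose.dose.shape:
        raise ValueError("ROI shape does not match dose grid")
    vals = dose.dose[roi.mask]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    rx = prescription or dose.prescription
    sorted_desc = np.sort(vals)[::-1]
    n = vals.size

    def dx(x: float) -> float:
        # dose exceeded by exactly x% of the volume; interpolate between voxels
        pos = x / 100.0 * n - 0.5
        pos = min(max(pos, 0.0), n - 1.0)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return float(sorted_desc[lo] * (1 - frac) + sorted_desc[hi] * frac)

    def vx(x: float) -> float:
        return 100.0 * float(np.count_nonzero(vals >= x / 100.0 * rx)) / n

    roi_cc = n * dose.voxel_volume_cc
    if roi_cc < 0.1:
        warnings.warn(f"ROI {roi.name!r} smaller than 0.1 cc; D0.1cc reported as Dmax")
        d01cc = float(vals.max())
    else:
        d01cc = dx(100.0 * 0.1 / roi_cc)

    return {
        "Dmean": float(vals.mean()),
        "D2": dx(2.0),
        "D5": dx(5.0),
        "D50": dx(50.0),
        "D95": dx(95.0),
        "D0.1cc": d01cc,
        "V95%": vx(95.0),
        "V100%": vx(100.0),
        "V110%": vx(110.0),
    }


def dose_compare(
    ref_dose: DoseGrid,
    test_dose: DoseGrid,
    rois: list[StructureMask],
    metric_set: dict[str, tuple[str, ...]] | None = None,
):
    """Per-ROI absolute differences of DVH metrics between two plans.

    Returns a pandas DataFrame with columns (roi, metric, ref, test,
    abs_diff).  ``metric_set`` maps ROI name to the metrics to report; ROIs
    in the set but absent from ``rois`` raise.
    """
    import pandas as pd

    metric_set = metric_set or PAPER_METRIC_SET
    by_name = {r.name: r for r in rois}
    missing = [name for name in metric_set if name not in by_name]
    if missing:
        raise ValueError(f"missing ROIs for dose comparison: {missing}")
    rows = []
    for name, metrics in metric_set.items():
        ref_rep = dvh_metrics(ref_dose, by_name[name])
        test_rep = dvh_metrics(test_dose, by_name[name])
        for m in metrics:
            rows.append(
                {
                    "roi": name,
                    "metric": m,
                    "ref": ref_rep[m],
                    "test": test_rep[m],
                    "abs_diff": abs(ref_rep[m] - test_rep[m]),
                }
            )
    return pd.DataFrame(rows, columns=["roi", "metric", "ref", "test", "abs_diff"])
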