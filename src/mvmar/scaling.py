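"""Tanh intensity scaling between HU and the (-1, 1) network domain.

Three preprocessing variants are used, each a shifted/divided tanh applied
per modality:

====== =========== ================= ===============
method modality    shift (HU)        divisor (HU)
====== =========== ================= ===============
P1     CT, MVCBCT  0                 400
P2     CT          0                 300
P2     MVCBCT      0                 150
P3     CT          1600              960
P3     MVCBCT      800               400
====== =========== ================= ===============

forward:  x = tanh((HU - shift) / divisor)
inverse:  HU = shift + divisor * atanh(x), then clamp to the modality range.

The shift/divisor pairs were chosen so each variant is most faithful in a
different HU band (P2 for soft tissue, P1 mid-range, P3 for bone/teeth),
which is what the downstream P4 fusion exploits.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core import ImageVolume, clamp_hu

logger = logging.getLogger(__name__)

__all__ = ["ScalingSpec", "forward_scale", "inverse_scale", "get_spec", "SCALING_TABLE"]

#: Clamp margin applied before atanh so saturated network outputs stay finite.
ATANH_EPS = 1e-7

#: (method, modality) -> (shift, divisor); "mv" covers MVCBCT, "ct" covers
#: both planning CT and synthetic CT.
SCALING_TABLE: dict[tuple[str, str], tuple[float, float]] = {
    ("P1", "ct"): (0.0, 400.0),
    ("P1", "mv"): (0.0, 400.0),
    ("P2", "ct"): (0.0, 300.0),
    ("P2", "mv"): (0.0, 150.0),
    ("P3", "ct"): (1600.0, 960.0),
    ("P3", "mv"): (800.0, 400.0),
}

METHODS = ("P1", "P2", "P3")


@dataclasses.dataclass(frozen=True)
class ScalingSpec:
    method: str
    modality: str
    shift: float
    divisor: float

    def __post_init__(self) -> None:
        if self.divisor <= 0:
            raise ValueError("divisor must be positive")


def get_spec(method: str, modality: str) -> ScalingSpec:
    """The canonical spec for a (method, modality) pair; sCT uses the CT side."""
    mod = "ct" if modality in ("ct", "sct") else "mv"
    key = (method, mod)
    if key not in SCALING_TABLE:
        raise KeyError(f"no scaling defined for method={method!r}, modality={modality!r}")
    shift, divisor = SCALING_TABLE[key]
    return ScalingSpec(method=method, modality=mod, shift=shift, divisor=divisor)


def forward_scale(vol: ImageVolume, spec: ScalingSpec) -> np.ndarray:
    """Map HU to (-1, 1): tanh((HU - shift) / divisor).

    The volume must already be clamped to its modality range and its modality
    must match the spec's.
    """
    mod = "ct" if vol.modality in ("ct", "sct") else "mv"
    if mod != spec.modality:
        raise ValueError(f"modality mismatch: image is {vol.modality!r}, spec is for {spec.modality!r}")
    return np.tanh((vol.values - spec.shift) / spec.divisor)


def inverse_scale(x: np.ndarray, spec: ScalingSpec, like: ImageVolume) -> ImageVolume:
    """Map scaled intensities back to HU: shift + divisor * atanh(x), clamped.

    Values at or beyond ±1 (possible for saturated network outputs) are
    clamped to ±(1 - 1e-7) and logged.
    """
    x = np.asarray(x, dtype=np.float64)
    saturated = np.abs(x) >= 1.0
    if saturated.any():
        logger.warning(
            "inverse_scale: clamping %d saturated value(s) to ±(1-%g)",
            int(saturated.sum()), ATANH_EPS,
        )
        x = np.where(saturated, np.sign(x) * (1.0 - ATANH_EPS), x)
    hu = spec.shift + spec.divisor * np.arctanh(x)
    modality = "ct" if spec.modality == "ct" else "mv"
    return clamp_hu(like.with_values(hu, modality=modality))
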