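"""HU-range fusion of translated candidates and metal copy-back.

The MAR post-processing has three pieces:

* **P4 fusion** — the three translated candidates are merged per pixel by
  HU range: below 400 HU the P2 candidate is used, in [400, 800) the P1
  candidate, and at or above 800 HU the P3 candidate.  Each variant is most
  accurate in its own band, so the fused image inherits the best of all
  three.  The band of a pixel is decided by a *selector* image (default:
  the P3 candidate, the variant most faithful at high HU; configurable).
* **Metal segmentation** — metal is the intersection of bright pixels in
  both modalities: HU > 2500 in the metal-containing CT and HU > 300 in the
  MV-CBCT.  The MV condition excludes bright CT streaks, which have no MV
  counterpart.
* **Copy-back** — metal pixels cannot be synthesized from MV (the scale
  saturates at 1400 HU), so their CT values are copied verbatim into the
  fused synthetic CT.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from . import constants as C
from .core import ImageVolume, StructureMask, _require_same_shape, clamp_hu
from .scaling import METHODS

__all__ = ["CandidateSet", "MetalMask", "fuse_p4", "segment_metal", "apply_mar"]


@dataclasses.dataclass
class CandidateSet:
    """The three sCT candidates plus the selector used to classify pixels."""

    p1: ImageVolume
    p2: ImageVolume
    p3: ImageVolume
    selector: ImageVolume | None = None

    def __post_init__(self) -> None:
        if self.selector is None:
            self.selector = self.p3
        for other in (self.p2, self.p3, self.selector):
            _require_same_shape(self.p1, other)


@dataclasses.dataclass
class MetalMask:
    mask: np.ndarray
    ct_threshold: float = C.CT_METAL_THRESHOLD
    mv_threshold: float = C.MV_METAL_THRESHOLD

    def as_structure(self) -> StructureMask:
        return StructureMask("metal", self.mask)


def fuse_p4(cands: CandidateSet) -> ImageVolume:
    """Merge candidates by the selector's HU band.

    selector < 400 -> P2; 400 <= selector < 800 -> P1; selector >= 800 -> P3.
    The bands partition the HU axis (half-open at both edges), so every
    output pixel equals exactly one candidate's pixel.
    """
    s = cands.selector.values
    out = np.where(
        s < C.FUSION_LOW_HU,
        cands.p2.values,
        np.where(s < C.FUSION_HIGH_HU, cands.p1.values, cands.p3.values),
    )
    return cands.p1.with_values(out, modality="sct")


def segment_metal(
    ct_m: ImageVolume,
    mv_m: ImageVolume,
    cleanup: bool = False,
    min_component_px: int = 3,
    ct_threshold: float = C.CT_METAL_THRESHOLD,
    mv_threshold: float = C.MV_METAL_THRESHOLD,
) -> MetalMask:
    """Dual-threshold metal segmentation: (CT > 2500) AND (MV > 300).

    ``cleanup`` optionally applies morphological closing and removes
    connected components smaller than ``min_component_px`` pixels (off by
    default: the base rule is pure thresholding).
    """
    _require_same_shape(ct_m, mv_m)
    mask = (ct_m.values > ct_threshold) & (mv_m.values > mv_threshold)
    if cleanup and mask.any():
        mask = ndimage.binary_closing(mask)
        labels, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        for lab, size in enumerate(sizes, start=1):
            if size < min_component_px:
                mask[labels == lab] = False
    return MetalMask(mask=mask, ct_threshold=ct_threshold, mv_threshold=mv_threshold)


def apply_mar(
    ct_m: ImageVolume,
    mv_m: ImageVolume,
    translator,
    selector: str = "P3",
    cleanup: bool = False,
) -> tuple[ImageVolume, MetalMask]:
    """Full MAR: translate, fuse, segment metal, copy metal pixels back.

    ``translator`` must expose ``translate(mv, method) -> ImageVolume`` (a
    :class:`~mvmar.translator.TranslatorBank` or
    :class:`~mvmar.translator.SurrogateTranslator`).  Inputs must be
    aligned.  Off-mask pixels equal the fused synthetic CT exactly; on-mask
    pixels equal ``ct_m`` exactly.
    """
    _require_same_shape(ct_m, mv_m)
    mv_clipped = clamp_hu(mv_m if mv_m.modality == "mv" else mv_m.with_values(mv_m.values, modality="mv"))
    cands = {m: translator.translate(mv_clipped, m) for m in METHODS}
    sel_map = {"P1": cands["P1"], "P2": cands["P2"], "P3": cands["P3"]}
    if selector == "median":
        sel_vol = cands["P1"].with_values(
            np.median(np.stack([c.values for c in cands.values()]), axis=0)
        )
    elif selector in sel_map:
        sel_vol = sel_map[selector]
    else:
        raise ValueError(f"selector must be one of P1/P2/P3/median, got {selector!r}")
    fused = fuse_p4(CandidateSet(p1=cands["P1"], p2=cands["P2"], p3=cands["P3"], selector=sel_vol))
    metal = segment_metal(ct_m, mv_m, cleanup=cleanup)
    out = fused.values.copy()
    out[metal.mask] = ct_m.values[metal.mask]
    return fused.with_values(out, modality="sct"), metal
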