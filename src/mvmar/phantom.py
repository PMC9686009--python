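"""Seeded simulation of paired kV-CT / MV-CBCT head slices with ground truth.

The generator stands in for clinical paired data: a stylized axial head
slice at the dental level (head outline, mandible arc, teeth, oral cavity,
parotids, spinal cord, optional metal dentures), imaged twice through a
desk-scale projection/reconstruction chain:

* kV-CT: polychromatic attenuation over a few spectrum bins (beam
  hardening), Poisson counting noise (photon starvation behind metal),
  ramp-filtered parallel-beam FBP.  Metal produces the familiar bright/dark
  streaks; without metal the reconstruction is faithful.
* MV-CBCT: monochromatic high-energy attenuation (no hardening, hence no
  streaks), stronger Poisson noise, compressed soft-tissue contrast, HU
  capped at 1400.

Because both images reconstruct the same ground-truth grid, every pair is
intrinsically registered: voxelwise comparisons need no alignment step.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage.transform import iradon, radon

from . import constants as C
from .core import ImageVolume, StructureMask, clamp_hu, write_volume

__all__ = [
    "PhantomSpec",
    "MetalInsert",
    "AcquisitionParams",
    "PhantomPair",
    "make_phantom",
    "mv_truth_from_ct",
    "simulate_kvct",
    "simulate_mvcbct",
    "make_pair",
    "make_dataset",
]


@dataclasses.dataclass(frozen=True)
class MetalInsert:
    """A circular metal denture insert: position in mm (row, col), radius mm."""

    position: tuple[float, float]
    radius: float
    material: str

    def __post_init__(self) -> None:
        if self.material not in C.METAL_HU:
            raise ValueError(
                f"unknown material {self.material!r}; expected one of {sorted(C.METAL_HU)}"
            )
        if self.radius <= 0:
            raise ValueError("insert radius must be positive")


@dataclasses.dataclass
class PhantomSpec:
    """Anatomy layout for one synthetic head slice.

    Geometry parameters are in mm on a grid of ``shape`` pixels at
    ``spacing`` mm.  ``jitter`` adds a seeded +-2 mm perturbation to organ
    centers so cases differ anatomically.
    """

    shape: tuple[int, int] = (128, 128)
    spacing: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    metal_inserts: tuple[MetalInsert, ...] = ()
    jitter: float = 2.0


@dataclasses.dataclass
class AcquisitionParams:
    """Projection/reconstruction settings shared by both simulators."""

    n_angles: int = 256
    kv_fluence: float = C.KV_FLUENCE
    mv_fluence: float = C.MV_FLUENCE
    kv_energies_kev: np.ndarray = dataclasses.field(
        default_factory=lambda: C.KV_ENERGIES_KEV.copy()
    )
    kv_weights: np.ndarray = dataclasses.field(default_factory=lambda: C.KV_WEIGHTS.copy())
    mu_water_kv: np.ndarray = dataclasses.field(default_factory=lambda: C.MU_WATER_KV.copy())
    #: Soft-tissue contrast slope of MV relative to kV (1 = no compression).
    mv_contrast: float = 0.6

    def __post_init__(self) -> None:
        self.kv_weights = np.asarray(self.kv_weights, dtype=float)
        if not np.isclose(self.kv_weights.sum(), 1.0):
            raise ValueError("spectrum weights must sum to 1")
        if self.kv_fluence <= 0 or self.mv_fluence <= 0:
            raise ValueError("fluence must be positive")


@dataclasses.dataclass
class PhantomPair:
    """A ground-truth slice with its simulated kV-CT and MV-CBCT images."""

    truth: ImageVolume
    ct: ImageVolume
    mv: ImageVolume
    masks: list[StructureMask]
    has_metal: bool
    mv_truth: ImageVolume  # ground truth on the MV HU scale
    seed: int = 0

    def mask(self, name: str) -> StructureMask:
        for m in self.masks:
            if m.name == name:
                return m
        raise KeyError(f"no mask named {name!r}")


# ---------------------------------------------------------------------------
# Ground-truth anatomy
# ---------------------------------------------------------------------------

def _ellipse(yy, xx, center, axes) -> np.ndarray:
    cy, cx = center
    ay, ax = axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, list[StructureMask]]:
    """Paint the ground-truth HU slice and its structure masks.

    HU assignments: air -1000, soft tissue ~0-80, mandible/skull 700-1500,
    teeth 1500, metal >= 3000 (per material).  Deterministic given the seed.
    Raises if a metal insert falls outside the head outline.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    sy, sx = spec.spacing
    yy, xx = np.mgrid[0:h, 0:w]
    yy = yy * sy
    xx = xx * sx

    def jit() -> float:
        return float(rng.uniform(-spec.jitter, spec.jitter))

    head_c = (70.0 + jit(), 64.0 + jit())
    head_ax = (54.0 + jit(), 46.0 + jit())
    head = _ellipse(yy, xx, head_c, head_ax)

    img = np.full((h, w), C.HU_AIR)
    img[head] = C.HU_SOFT_TISSUE + rng.uniform(-5, 5)

    # posterior cranium base: partial bone ring
    sk_out = _ellipse(yy, xx, head_c, (head_ax[0] - 4, head_ax[1] - 4))
    sk_in = _ellipse(yy, xx, head_c, (head_ax[0] - 10, head_ax[1] - 10))
    skull = sk_out & ~sk_in & (yy >= head_c[0] + 14)
    img[skull] = C.HU_SKULL + rng.uniform(-50, 50)

    # mandible: anterior U-shaped arc
    mand_c = (52.0 + jit(), 64.0 + jit())
    m_out = _ellipse(yy, xx, mand_c, (26.0, 30.0))
    m_in = _ellipse(yy, xx, mand_c, (19.0, 23.0))
    mandible = m_out & ~m_in & (yy <= mand_c[0] + 6)
    img[mandible] = C.HU_MANDIBLE + rng.uniform(-50, 50)

    # teeth: disks along the anterior dental arc
    teeth = np.zeros((h, w), dtype=bool)
    tooth_centers = []
    for ang_deg in (-60, -40, -20, 0, 20, 40, 60):
        ang = np.deg2rad(ang_deg)
        ty = mand_c[0] - 22.5 * np.cos(ang)
        tx = mand_c[1] + 26.5 * np.sin(ang)
        tooth_centers.append((ty, tx))
        teeth |= (yy - ty) ** 2 + (xx - tx) ** 2 <= 3.0**2
    img[teeth] = C.HU_TEETH + rng.uniform(-100, 100)

    oral_c = (mand_c[0] + 9, mand_c[1])
    oral = _ellipse(yy, xx, oral_c, (9.0, 13.0)) & ~teeth & ~mandible
    img[oral] = C.HU_ORAL_CAVITY + rng.uniform(-5, 5)

    parotid = np.zeros((h, w), dtype=bool)
    for px in (30.0 + jit(), 98.0 + jit()):
        parotid |= _ellipse(yy, xx, (84.0 + jit(), px), (10.0, 7.0))
    parotid &= head & ~skull
    img[parotid] = C.HU_PAROTID + rng.uniform(-5, 5)

    cord_c = (106.0 + jit(), 64.0 + jit())
    cord = (yy - cord_c[0]) ** 2 + (xx - cord_c[1]) ** 2 <= 4.0**2
    img[cord] = C.HU_CORD

    metal = np.zeros((h, w), dtype=bool)
    for ins in spec.metal_inserts:
        disk = (yy - ins.position[0]) ** 2 + (xx - ins.position[1]) ** 2 <= ins.radius**2
        if not np.all(head[disk]):
            raise ValueError(f"metal insert at {ins.position} extends outside the head outline")
        img[disk] = C.METAL_HU[ins.material]
        metal |= disk

    bone = (mandible | skull | teeth) & ~metal
    soft = head & ~bone & ~metal
    # soft tissue away from bone/air boundaries: partial-volume and edge
    # ringing pixels are excluded from artifact statistics
    from scipy import ndimage as _ndi

    not_soft = ~head | bone | metal
    soft_core = soft & ~_ndi.binary_dilation(not_soft, iterations=3)
    # small guaranteed-uniform soft-tissue disk for noise measurements
    noise_roi = ((yy - (mand_c[0] + 24.0)) ** 2 + (xx - mand_c[1]) ** 2 <= 5.0**2) & soft_core
    # planning target volume analog: region around the dental arc
    ptv = _ellipse(yy, xx, (mand_c[0] + 2, mand_c[1]), (20.0, 24.0))

    vol = ImageVolume(values=img, spacing=spec.spacing, modality="ct")
    masks = [
        StructureMask("head", head),
        StructureMask("soft_tissue", soft),
        StructureMask("soft_core", soft_core),
        StructureMask("noise_roi", noise_roi),
        StructureMask("mandible", mandible & ~metal),
        StructureMask("teeth", teeth & ~metal),
        StructureMask("oral_cavity", oral & ~metal),
        StructureMask("parotid", parotid),
        StructureMask("spinal_cord", cord),
        StructureMask("metal", metal),
        StructureMask("ptv", ptv),
    ]
    return vol, masks


def default_metal_inserts(rng: np.random.Generator, materials=("stainless_steel", "titanium_alloy")) -> tuple[MetalInsert, ...]:
    """One or two denture inserts placed on the dental arc."""
    n = int(rng.integers(1, 3))
    angles = rng.choice([-40, -20, 0, 20, 40], size=n, replace=False)
    inserts = []
    for ang_deg in angles:
        ang = np.deg2rad(float(ang_deg))
        ty = 52.0 - 22.5 * np.cos(ang)
        tx = 64.0 + 26.5 * np.sin(ang)
        mat = str(rng.choice(list(materials)))
        inserts.append(MetalInsert(position=(ty, tx), radius=3.0, material=mat))
    return tuple(inserts)


# ---------------------------------------------------------------------------
# Acquisition simulators
# ---------------------------------------------------------------------------

def mv_truth_from_ct(truth: ImageVolume, mv_contrast: float = 0.6) -> ImageVolume:
    """Ground truth on the MV HU scale: piecewise-linear contrast compression.

    Soft tissue slope is ``mv_contrast``; the map saturates toward 1400 HU
    and is strictly increasing (hence invertible by the surrogate
    translator).
    """
    kn_ct = C.MV_COMPRESSION_KNOTS_CT.copy()
    kn_mv = C.MV_COMPRESSION_KNOTS_MV.copy()
    # inner knots (+-100 HU) carry the soft-tissue slope
    kn_mv[1] = kn_ct[1] * mv_contrast  # at -100
    kn_mv[3] = kn_ct[3] * mv_contrast  # at +100
    out = np.interp(truth.values, kn_ct, kn_mv)
    return truth.with_values(out, modality="mv")


def _require_slice(vol: ImageVolume) -> np.ndarray:
    if vol.values.ndim == 3 and vol.values.shape[0] != 1:
        raise ValueError("simulators operate on single 2-D slices")
    return vol.plane


def _project_reconstruct(sino: np.ndarray, theta: np.ndarray, size: int) -> np.ndarray:
    return iradon(sino, theta=theta, circle=True, filter_name="ramp", output_size=size)


def simulate_kvct(truth: ImageVolume, acq: AcquisitionParams | None = None, seed: int = 0) -> ImageVolume:
    """Simulate a kV-CT acquisition of the ground-truth slice.

    Attenuation is decomposed into a water-like channel (scales with HU) and
    a hardening channel (the photoelectric excess of bone/metal, boosted at
    low energies), so only two projections are needed regardless of the
    number of spectrum bins.
    """
    acq = acq or AcquisitionParams()
    img = _require_slice(truth)
    rng = np.random.default_rng(seed)
    spacing = truth.spacing[-1]
    theta = np.linspace(0.0, 180.0, acq.n_angles, endpoint=False)

    hu = img
    metal_frac = np.clip((hu - 2500.0) / 1500.0, 0.0, 1.0)
    water = np.clip(1.0 + hu / 1000.0, 0.0, None) + C.METAL_DENSITY_EXCESS * metal_frac
    frac = np.clip((hu - C.HARDENING_ONSET_HU) / (C.HARDENING_FULL_HU - C.HARDENING_ONSET_HU), 0.0, 1.0)
    hard = np.clip(hu / 1000.0, 0.0, None) * frac

    sino_w = radon(water, theta=theta, circle=True)
    sino_h = radon(hard, theta=theta, circle=True)

    counts = np.zeros_like(sino_w)
    for e_kev, wgt, mu_w in zip(acq.kv_energies_kev, acq.kv_weights, acq.mu_water_kv):
        boost = (C.HARDENING_E_REF_KEV / e_kev) ** C.HARDENING_EXPONENT - 1.0
        t = mu_w * spacing * (sino_w + boost * sino_h)
        counts += rng.poisson(acq.kv_fluence * wgt * np.exp(-t))
    counts = np.maximum(counts.astype(float), 0.5)
    q = -np.log(counts / acq.kv_fluence)

    # Water linearization (the standard first-order beam-hardening
    # correction): map each measured polychromatic log-attenuation to the
    # water-equivalent path length, then back to an effective monochromatic
    # sinogram.  Removes cupping in water-like regions; bone/metal rays stay
    # inconsistent, which is exactly what produces the streaks.
    lgrid = np.linspace(0.0, C.WATER_LIN_LMAX_MM, 3001)
    q_water = -np.log(
        np.sum(acq.kv_weights[:, None] * np.exp(-acq.mu_water_kv[:, None] * lgrid[None, :]), axis=0)
    )
    sino_eff = np.interp(q, q_water, lgrid) * C.MU_WATER_KV_EFF

    mu_pix = _project_reconstruct(sino_eff, theta, img.shape[0])
    hu_rec = 1000.0 * (mu_pix / (C.MU_WATER_KV_EFF * spacing) - 1.0)
    out = truth.with_values(hu_rec, modality="ct")
    return clamp_hu(out)


def simulate_mvcbct(truth: ImageVolume, acq: AcquisitionParams | None = None, seed: int = 0) -> ImageVolume:
    """Simulate an MV-CBCT acquisition: monochromatic, noisy, HU-capped.

    High beam energy removes beam hardening and photon starvation, so metal
    produces no streaks; the price is higher Poisson noise and compressed
    soft-tissue contrast.
    """
    acq = acq or AcquisitionParams()
    _require_slice(truth)
    rng = np.random.default_rng(seed)
    spacing = truth.spacing[-1]
    theta = np.linspace(0.0, 180.0, acq.n_angles, endpoint=False)

    mv_truth = mv_truth_from_ct(truth, acq.mv_contrast)
    red = np.clip(1.0 + mv_truth.plane / 1000.0, 0.0, None)
    sino = radon(red, theta=theta, circle=True) * (C.MU_WATER_MV * spacing)
    counts = np.maximum(rng.poisson(acq.mv_fluence * np.exp(-sino)).astype(float), 0.5)
    sino_eff = -np.log(counts / acq.mv_fluence)
    mu_pix = _project_reconstruct(sino_eff, theta, mv_truth.plane.shape[0])
    hu_rec = 1000.0 * (mu_pix / (C.MU_WATER_MV * spacing) - 1.0)
    out = truth.with_values(hu_rec, modality="mv")
    return clamp_hu(out)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def make_pair(seed: int, with_metal: bool, shape=(128, 128), acq: AcquisitionParams | None = None) -> PhantomPair:
    """One intrinsically-registered truth/CT/MV triple for a given seed.

    The physical field of view is fixed at 128 mm regardless of the grid
    size, so smaller grids are coarser samplings of the same anatomy.
    """
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(seed)
    inserts = default_metal_inserts(rng) if with_metal else ()
    spacing = (128.0 / shape[0], 128.0 / shape[1])
    spec = PhantomSpec(shape=shape, spacing=spacing, seed=seed, metal_inserts=inserts)
    truth, masks = make_phantom(spec)
    ct = simulate_kvct(truth, acq, seed=seed + 1)
    mv = simulate_mvcbct(truth, acq, seed=seed + 2)
    return PhantomPair(
        truth=truth,
        ct=ct,
        mv=mv,
        masks=masks,
        has_metal=with_metal,
        mv_truth=mv_truth_from_ct(truth, acq.mv_contrast),
        seed=seed,
    )


def make_dataset(
    n_cases: int,
    metal_fraction: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    shape=(128, 128),
    acq: AcquisitionParams | None = None,
) -> tuple[list[PhantomPair], dict]:
    """Generate a seeded dataset of phantom pairs plus a manifest.

    The number of metal cases is ``round(metal_fraction * n_cases)``
    (banker's rounding avoided by flooring x+0.5); metal flags are assigned
    to a seeded shuffle of case indices.  The manifest is deterministic
    given the seed (two runs produce byte-identical JSON).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    n_metal = int(np.floor(metal_fraction * n_cases + 0.5))
    order = rng.permutation(n_cases)
    flags = np.zeros(n_cases, dtype=bool)
    flags[order[:n_metal]] = True
    case_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_cases)]

    pairs = []
    records = []
    out_path = Path(out_dir) if out_dir is not None else None
    for i in range(n_cases):
        pair = make_pair(case_seeds[i], bool(flags[i]), shape=shape, acq=acq)
        pairs.append(pair)
        rec = {"case": i, "seed": case_seeds[i], "has_metal": bool(flags[i])}
        if out_path is not None:
            case_dir = out_path / f"case_{i:03d}"
            case_dir.mkdir(parents=True, exist_ok=True)
            for tag, vol in (("truth", pair.truth), ("ct", pair.ct), ("mv", pair.mv)):
                write_volume(vol, case_dir / f"{tag}.nii.gz", format="nifti")
            rec["files"] = {t: f"case_{i:03d}/{t}.nii.gz" for t in ("truth", "ct", "mv")}
        records.append(rec)

    manifest = {
        "n_cases": n_cases,
        "metal_fraction": metal_fraction,
        "n_metal": n_metal,
        "rounding_rule": "n_metal = floor(metal_fraction * n_cases + 0.5)",
        "seed": seed,
        "cases": records,
    }
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return pairs, manifest
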