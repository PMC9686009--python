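"""Shared raster data model, HU conventions, resampling and image I/O.

The universal carrier is :class:`ImageVolume`: an HU grid plus spacing,
origin and a modality tag that fixes the representable HU range (kV-CT
[-1000, 3000], MV-CBCT [-1000, 1400]).  2-D slices are first-class: a slice
is simply a volume whose array has two axes (or a leading singleton axis).

Coordinate convention: voxel indices are 0-based and physical position =
origin + index * spacing (voxel-center convention), axis order matching the
array axes.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
from scipy import ndimage

from .constants import HU_RANGES

__all__ = [
    "ImageVolume",
    "StructureMask",
    "read_volume",
    "write_volume",
    "resample_crop",
    "clamp_hu",
]


@dataclasses.dataclass
class ImageVolume:
    """An HU-calibrated raster image.

    Parameters
    ----------
    values : ndarray
        HU grid, 2-D ``(H, W)`` or 3-D ``(D, H, W)``.
    spacing : tuple of float
        Physical voxel size in mm per axis, same length as ``values.ndim``.
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, ..., 0)``.
    modality : str
        One of ``"ct"`` (kV-CT), ``"mv"`` (MV-CBCT) or ``"sct"``.
    """

    values: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = ()
    modality: str = "ct"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"values must be 2-D or 3-D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.values.ndim:
            raise ValueError("spacing length must match values.ndim")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not self.origin:
            self.origin = (0.0,) * self.values.ndim
        else:
            self.origin = tuple(float(o) for o in self.origin)
        if self.modality not in HU_RANGES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {sorted(HU_RANGES)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def hu_range(self) -> tuple[float, float]:
        return HU_RANGES[self.modality]

    @property
    def plane(self) -> np.ndarray:
        """The 2-D slice data; raises for true 3-D volumes."""
        if self.values.ndim == 2:
            return self.values
        if self.values.shape[0] == 1:
            return self.values[0]
        raise ValueError("volume is not a single 2-D slice")

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "ImageVolume":
        """A copy carrying new values on the same grid."""
        return ImageVolume(
            values=np.asarray(values, dtype=np.float64),
            spacing=self.spacing,
            origin=self.origin,
            modality=modality or self.modality,
        )


@dataclasses.dataclass
class StructureMask:
    """A named boolean ROI aligned with an :class:`ImageVolume`."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            raise ValueError(f"mask for {self.name!r} must be boolean, got dtype {self.mask.dtype}")

    def check_alignment(self, vol: ImageVolume) -> None:
        if self.mask.shape != vol.shape:
            raise ValueError(
                f"mask {self.name!r} shape {self.mask.shape} does not match image shape {vol.shape}"
            )


def _require_same_shape(a: ImageVolume, b: ImageVolume) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_volume(vol: ImageVolume, path: str | os.PathLike, format: str | None = None) -> Path:
    """Write a volume to disk as NIfTI (int16 HU) or a DICOM series directory.

    NaNs are refused: they would silently corrupt the int16 encoding.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if np.any(~np.isfinite(vol.values)):
        raise ValueError("refusing to write volume containing NaN/inf values")
    if fmt == "nifti":
        import nibabel as nib

        arr = np.rint(vol.values).astype(np.int16)
        # nibabel is (x, y, z)-ordered; store transposed so read_volume restores.
        data = arr.T
        affine = np.eye(4)
        for i, s in enumerate(reversed(vol.spacing)):
            affine[i, i] = s
        for i, o in enumerate(reversed(vol.origin)):
            affine[i, 3] = o
        img = nib.Nifti1Image(data, affine)
        img.header.set_data_dtype(np.int16)
        img.header["descrip"] = vol.modality.encode()
        nib.save(img, str(path))
        return path
    if fmt == "dicom-series":
        _write_dicom_series(vol, path)
        return path
    raise ValueError(f"unsupported format {fmt!r}; expected 'nifti' or 'dicom-series'")


def read_volume(path: str | os.PathLike, format: str | None = None, modality: str = "ct") -> ImageVolume:
    """Read an HU-calibrated volume from NIfTI or a DICOM series directory.

    DICOM stored values are converted to HU via RescaleSlope/RescaleIntercept;
    missing rescale tags are an explicit error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).T.astype(np.float64)
        zooms = img.header.get_zooms()
        spacing = tuple(float(z) for z in reversed(zooms[: data.ndim]))
        origin = tuple(float(img.affine[i, 3]) for i in reversed(range(data.ndim)))
        descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="ignore")
        mod = descrip if descrip in HU_RANGES else modality
        return ImageVolume(values=data, spacing=spacing, origin=origin, modality=mod)
    if fmt == "dicom-series":
        return _read_dicom_series(path, modality)
    raise ValueError(f"unsupported format {fmt!r}")


def _infer_format(path: Path) -> str:
    name = path.name
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if path.is_dir():
        return "dicom-series"
    # default for new files without an extension hint
    return "nifti" if not path.exists() else "dicom-series"


def _read_dicom_series(path: Path, modality: str) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no DICOM slices found in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    orientations = {tuple(float(x) for x in getattr(ds, "ImageOrientationPatient", (1, 0, 0, 0, 1, 0))) for ds in slices}
    if len(orientations) > 1:
        raise ValueError("mixed-orientation DICOM series is not supported")
    for ds in slices:
        if "RescaleSlope" not in ds:
            raise ValueError("DICOM slice missing RescaleSlope tag (0028,1053)")
        if "RescaleIntercept" not in ds:
            raise ValueError("DICOM slice missing RescaleIntercept tag (0028,1052)")
    slices.sort(key=lambda ds: float(getattr(ds, "ImagePositionPatient", [0, 0, 0])[2]))
    planes = [
        ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        for ds in slices
    ]
    data = np.stack(planes, axis=0)
    first = slices[0]
    px = [float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0])]
    dz = float(getattr(first, "SliceThickness", 1.0))
    pos = [float(v) for v in getattr(first, "ImagePositionPatient", [0.0, 0.0, 0.0])]
    return ImageVolume(
        values=data,
        spacing=(dz, px[0], px[1]),
        origin=(pos[2], pos[1], pos[0]),
        modality=modality,
    )


def _write_dicom_series(vol: ImageVolume, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    path.mkdir(parents=True, exist_ok=True)
    data = vol.values if vol.values.ndim == 3 else vol.values[None]
    series_uid = generate_uid()
    dz = vol.spacing[0] if len(vol.spacing) == 3 else 1.0
    for k, plane in enumerate(data):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(path / f"slice_{k:04d}.dcm"), {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = plane.shape
        ds.PixelSpacing = [str(vol.spacing[-2]), str(vol.spacing[-1])]
        ds.SliceThickness = str(dz)
        ds.ImagePositionPatient = [str(vol.origin[-1]), str(vol.origin[-2]), str(vol.origin[0] + k * dz if len(vol.origin) == 3 else k * dz)]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "-1024"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        stored = np.rint(plane + 1024.0)
        if stored.min() < 0 or stored.max() > 65535:
            raise ValueError("HU values out of encodable range for 16-bit DICOM with intercept -1024")
        ds.PixelData = stored.astype(np.uint16).tobytes()
        ds.save_as(str(path / f"slice_{k:04d}.dcm"), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def resample_crop(
    vol: ImageVolume,
    target_spacing: float | tuple[float, ...],
    target_shape: tuple[int, ...],
    center: tuple[float, ...] | None = None,
    fill_value: float = -1000.0,
) -> ImageVolume:
    """Resample to ``target_spacing`` (mm) and crop/pad to ``target_shape``.

    HU images are linearly interpolated; out-of-field pixels are filled with
    -1000 HU (air).  ``center`` is the physical center (mm) of the output
    grid; by default the input field-of-view center.
    """
    ndim = vol.values.ndim
    if np.isscalar(target_spacing):
        target_spacing = (float(target_spacing),) * ndim
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target_spacing must be strictly positive")
    if len(target_shape) != ndim:
        raise ValueError("target_shape length must match image dimensionality")
    if center is None:
        center = tuple(
            vol.origin[i] + (vol.shape[i] - 1) * vol.spacing[i] / 2.0 for i in range(ndim)
        )
    new_origin = tuple(
        center[i] - (target_shape[i] - 1) * target_spacing[i] / 2.0 for i in range(ndim)
    )
    # Output voxel centers mapped into input index space.
    grids = np.meshgrid(
        *[
            (new_origin[i] + np.arange(target_shape[i]) * target_spacing[i] - vol.origin[i])
            / vol.spacing[i]
            for i in range(ndim)
        ],
        indexing="ij",
    )
    coords = np.stack([g.ravel() for g in grids])
    out = ndimage.map_coordinates(
        vol.values, coords, order=1, mode="constant", cval=fill_value
    ).reshape(target_shape)
    return ImageVolume(values=out, spacing=target_spacing, origin=new_origin, modality=vol.modality)


def resample_mask(
    mask: StructureMask,
    vol: ImageVolume,
    target_spacing: float | tuple[float, ...],
    target_shape: tuple[int, ...],
    center: tuple[float, ...] | None = None,
) -> StructureMask:
    """Resample a mask on ``vol``'s grid with nearest-neighbour interpolation."""
    mask.check_alignment(vol)
    carrier = ImageVolume(mask.mask.astype(np.float64), vol.spacing, vol.origin, vol.modality)
    res = resample_crop(carrier, target_spacing, target_shape, center, fill_value=0.0)
    return StructureMask(name=mask.name, mask=res.values > 0.5)


def clamp_hu(vol: ImageVolume) -> ImageVolume:
    """Clip values to the modality's HU range (idempotent, monotone)."""
    lo, hi = vol.hu_range
    return vol.with_values(np.clip(vol.values, lo, hi))
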