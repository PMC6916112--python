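"""CT volume and label-map IO.

Conventions used package-wide:

* canonical axis order ``(slice, row, col)``, 0-based indices;
* spacing stored as ``(dz, dx, dy)`` in mm, matching that axis order;
* Hounsfield units are the working intensity unit everywhere — DICOM stored
  values are rescaled at load time, never lazily;
* boxes are half-open on every axis.

DICOM support is limited to axis-aligned single-frame axial CT series (the
data this tool targets are plain axial stacks); oblique orientations are
rejected rather than resampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume", "RoiBox", "LabelMap", "DEFAULT_LABEL_NAMES",
    "read_dicom_series", "write_dicom_series", "read_nifti", "read_nifti_labels",
    "write_nifti", "clip_roi",
]

#: default tissue labels: background/air, extraocular muscle, intraorbital
#: fat, bone or hydroxyapatite prosthesis (both marked with the dense brush)
DEFAULT_LABEL_NAMES: dict[int, str] = {0: "background", 1: "muscle", 2: "fat", 3: "bone"}


@dataclass
class CTVolume:
    """A 3-D scalar field of Hounsfield units with voxel geometry.

    Parameters
    ----------
    data
        3-D float array in HU, axis order (slice, row, col).
    spacing
        Voxel spacing (dz, dx, dy) in mm, one entry per data axis.
    origin
        Position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"CT volume must be 3-D, got {self.data.ndim}-D")
        if min(self.data.shape) < 1:
            raise ValueError("every CT volume axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CT volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned half-open voxel box: ``lo`` inclusive, ``hi`` exclusive."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("RoiBox corners must be 3-tuples")
        if any(l < 0 for l in self.lo) or any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"invalid box lo={self.lo} hi={self.hi}: need 0 <= lo < hi")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


@dataclass
class LabelMap:
    """Integer tissue assignment aligned voxel-for-voxel with a CTVolume."""

    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must hold integers")
        self.labels = self.labels.astype(np.int32, copy=False)
        if self.labels.ndim != 3:
            raise ValueError(f"label map must be 3-D, got {self.labels.ndim}-D")
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.label_names)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from label_names {sorted(self.label_names)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label: int) -> np.ndarray:
        """Binary mask of one tissue."""
        return self.labels == int(label)


# ---------------------------------------------------------------------------
# DICOM

def _slice_position(ds) -> float:
    ipp = getattr(ds, "ImagePositionPatient", None)
    if ipp is not None:
        return float(ipp[2])
    return float(getattr(ds, "SliceLocation", getattr(ds, "InstanceNumber", 0)))


def read_dicom_series(directory: str | Path) -> CTVolume:
    """Read a single-frame CT DICOM series into a HU volume.

    Slices are sorted by spatial position along the slice axis, stored values
    are rescaled to HU via each file's RescaleSlope/RescaleIntercept, and
    spacing is taken from PixelSpacing plus the inter-slice distance.

    Raises
    ------
    ValueError
        On an empty directory, mixed series, non-axis-aligned orientation, or
        inter-slice spacing that varies by more than 1%.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ".ima", ""})
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed SeriesInstanceUID values in {directory}: {sorted(map(str, uids))}")

    for ds in datasets:
        iop = getattr(ds, "ImageOrientationPatient", None)
        if iop is not None:
            expected = [1, 0, 0, 0, 1, 0]
            if not np.allclose([float(v) for v in iop], expected, atol=1e-3):
                raise ValueError("non-axis-aligned DICOM orientation is not supported (axial stacks only)")

    datasets.sort(key=_slice_position)

    slices = []
    for ds in datasets:
        if "RescaleSlope" in ds and "RescaleIntercept" in ds:
            slope, intercept = float(ds.RescaleSlope), float(ds.RescaleIntercept)
        else:
            warnings.warn("missing RescaleSlope/Intercept; assuming slope 1, intercept 0", stacklevel=2)
            slope, intercept = 1.0, 0.0
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    data = np.stack(slices, axis=0)

    ps = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    dx, dy = float(ps[0]), float(ps[1])
    if len(datasets) > 1:
        zs = np.array([_slice_position(ds) for ds in datasets], dtype=float)
        gaps = np.diff(zs)
        dz = float(np.mean(gaps))
        if dz <= 0:
            raise ValueError("slice positions are not strictly increasing")
        if np.max(np.abs(gaps - dz)) > 0.01 * dz:
            raise ValueError(f"non-uniform inter-slice spacing (gaps {gaps.tolist()}) exceeds 1% tolerance")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    ipp = getattr(datasets[0], "ImagePositionPatient", [0.0, 0.0, 0.0])
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    return CTVolume(data=data, spacing=(dz, dx, dy), origin=origin)


def write_dicom_series(vol: CTVolume, directory: str | Path) -> list[Path]:
    """Write a CTVolume as a minimal single-frame CT DICOM series.

    HU values are rounded to int16 and stored with rescale slope 1 /
    intercept 0, so a round-trip through :func:`read_dicom_series` agrees
    with the source to within 0.5 HU.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    dz, dx, dy = vol.spacing
    z0, x0, y0 = vol.origin
    pixels = np.clip(np.round(vol.data), -32768, 32767).astype(np.int16)
    paths = []
    for i in range(vol.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, Dataset(), file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [y0, x0, z0 + i * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dx, dy]
        ds.SliceThickness = dz
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.Rows, ds.Columns = pixels.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = pixels[i].tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# NIfTI

def _nifti_geometry(path: Path):
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {img.ndim}-D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return img, zooms, origin


def read_nifti(path: str | Path) -> CTVolume:
    """Read a NIfTI volume written by :func:`write_nifti` (axes (slice,row,col))."""
    img, zooms, origin = _nifti_geometry(Path(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    return CTVolume(data=data, spacing=zooms, origin=origin)


def read_nifti_labels(path: str | Path, label_names: dict[int, str] | None = None) -> LabelMap:
    """Read an integer NIfTI label map."""
    img, _, _ = _nifti_geometry(Path(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise ValueError(f"{path}: expected integer labels")
        data = data.astype(np.int32)
    names = label_names
    if names is None:
        present = np.unique(data).tolist()
        names = {int(k): DEFAULT_LABEL_NAMES.get(int(k), f"label_{int(k)}") for k in present}
        names.update(DEFAULT_LABEL_NAMES)
    return LabelMap(labels=data, label_names=names)


def write_nifti(obj: CTVolume | LabelMap, path: str | Path,
                spacing: tuple[float, float, float] | None = None,
                origin: tuple[float, float, float] | None = None) -> None:
    """Write a CTVolume (float) or LabelMap (int) as NIfTI-1.

    The array is stored in canonical (slice, row, col) axis order with the
    spacing on the affine diagonal; HU volumes are stored as float32 for
    CT-range fidelity, label maps as int16.
    """
    path = Path(path)
    if isinstance(obj, CTVolume):
        arr = obj.data.astype(np.float32)
        spacing = obj.spacing
        origin = obj.origin
    elif isinstance(obj, LabelMap):
        arr = obj.labels.astype(np.int16)
        spacing = spacing or (1.0, 1.0, 1.0)
        origin = origin or (0.0, 0.0, 0.0)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = list(origin)[::-1]
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# ROI clipping

def clip_roi(vol: CTVolume, box: RoiBox) -> CTVolume:
    """Extract the unilateral orbital region of interest.

    Values are copied unchanged; the origin shifts by ``lo * spacing``.
    A box exceeding the volume bounds is rejected, never silently clamped.
    """
    if any(h > s for h, s in zip(box.hi, vol.shape)):
        raise ValueError(f"box hi={box.hi} exceeds volume shape {vol.shape}")
    data = vol.data[box.slices()].copy()
    origin = tuple(o + l * s for o, l, s in zip(vol.origin, box.lo, vol.spacing))
    return CTVolume(data=data, spacing=vol.spacing, origin=origin)
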