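"""DICOM input/output: geometry-aware containers and file round-trips.

All positions are expressed in the DICOM patient coordinate system (LPS,
millimetres) and refer to voxel/pixel *centers*, matching the DICOM
``ImagePositionPatient`` convention. Indices are 0-based throughout.

A note on orientation naming: ``ImageOrientationPatient`` stores first the
unit vector along which the *column* index increases and then the unit
vector along which the *row* index increases. The containers here name the
cosines by the index they advance — ``row_cosine`` moves pixel (i, j) to
(i+1, j) — so the tag maps to ``[col_cosine, row_cosine]`` on disk.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

__all__ = [
    "SliceHeader",
    "VolumeGrid",
    "load_volume_series",
    "load_reference_slice",
    "load_pixel_array",
    "export_resliced_dicom",
]

#: Geometry/identity tags that must be present on every input slice.
REQUIRED_TAGS = (
    "ImagePositionPatient",
    "ImageOrientationPatient",
    "PixelSpacing",
    "Rows",
    "Columns",
    "SeriesInstanceUID",
    "SOPInstanceUID",
    "StudyInstanceUID",
)

_ORTHO_TOL = 1e-4
_SPACING_RTOL = 1e-3


class DicomIOError(ValueError):
    """Raised for malformed or inconsistent DICOM input."""


@dataclass
class SliceHeader:
    """Geometry and identity of one single-frame DICOM slice.

    ``position`` is the patient-space center of pixel (0, 0) in mm.
    ``slice_thickness`` is ``None`` when the tag is absent (never defaulted).
    """

    position: np.ndarray
    row_cosine: np.ndarray
    col_cosine: np.ndarray
    pixel_spacing_row: float
    pixel_spacing_col: float
    rows: int
    cols: int
    slice_thickness: float | None
    series_uid: str
    sop_uid: str
    study_uid: str
    series_number: int | None = None
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.row_cosine = np.asarray(self.row_cosine, dtype=float)
        self.col_cosine = np.asarray(self.col_cosine, dtype=float)
        for name, v in (("row_cosine", self.row_cosine), ("col_cosine", self.col_cosine)):
            if abs(np.linalg.norm(v) - 1.0) > _ORTHO_TOL:
                raise DicomIOError(f"{name} is not a unit vector: {v}")
        if abs(float(np.dot(self.row_cosine, self.col_cosine))) > _ORTHO_TOL:
            raise DicomIOError("row_cosine and col_cosine are not orthogonal")
        if self.rows < 1 or self.cols < 1:
            raise DicomIOError("matrix size must be at least 1x1")
        if self.pixel_spacing_row <= 0 or self.pixel_spacing_col <= 0:
            raise DicomIOError("pixel spacing must be positive")


@dataclass
class VolumeGrid:
    """A 3D scalar field on a regular grid in patient space.

    ``values`` is indexed (i_row, j_col, k_slice); the patient-space center
    of voxel (i, j, k) is
    ``origin + i*spacing[0]*row_cosine + j*spacing[1]*col_cosine
    + k*spacing[2]*normal_cosine``.
    ``spacing[2]`` is the inter-slice distance along the acquisition
    direction (the through-plane z-resolution of the 3D data).
    """

    values: np.ndarray
    origin: np.ndarray
    row_cosine: np.ndarray
    col_cosine: np.ndarray
    normal_cosine: np.ndarray
    spacing: tuple[float, float, float]
    series_uid: str = ""
    series_number: int | None = None
    study_uid: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.row_cosine = np.asarray(self.row_cosine, dtype=float)
        self.col_cosine = np.asarray(self.col_cosine, dtype=float)
        self.normal_cosine = np.asarray(self.normal_cosine, dtype=float)
        if self.values.ndim != 3:
            raise DicomIOError("volume values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise DicomIOError("volume contains non-finite values")
        cos = np.stack([self.row_cosine, self.col_cosine, self.normal_cosine])
        if not np.allclose(cos @ cos.T, np.eye(3), atol=_ORTHO_TOL):
            raise DicomIOError("direction cosines are not mutually orthonormal")
        if any(s <= 0 for s in self.spacing):
            raise DicomIOError("spacings must be positive")


def _header_from_dataset(ds: Dataset, path: str = "<memory>") -> SliceHeader:
    missing = [t for t in REQUIRED_TAGS if getattr(ds, t, None) is None]
    if missing:
        raise DicomIOError(f"{path}: missing required DICOM tags: {', '.join(missing)}")
    iop = np.asarray([float(x) for x in ds.ImageOrientationPatient], dtype=float)
    thickness = getattr(ds, "SliceThickness", None)
    series_number = getattr(ds, "SeriesNumber", None)
    return SliceHeader(
        position=[float(x) for x in ds.ImagePositionPatient],
        row_cosine=iop[3:6],
        col_cosine=iop[0:3],
        pixel_spacing_row=float(ds.PixelSpacing[0]),
        pixel_spacing_col=float(ds.PixelSpacing[1]),
        rows=int(ds.Rows),
        cols=int(ds.Columns),
        slice_thickness=None if thickness is None else float(thickness),
        series_uid=str(ds.SeriesInstanceUID),
        sop_uid=str(ds.SOPInstanceUID),
        study_uid=str(ds.StudyInstanceUID),
        series_number=None if series_number is None else int(series_number),
        rescale_slope=float(getattr(ds, "RescaleSlope", 1.0)),
        rescale_intercept=float(getattr(ds, "RescaleIntercept", 0.0)),
    )


def load_reference_slice(path: str | os.PathLike) -> SliceHeader:
    """Parse the geometry of a single-frame 2D reference DICOM slice."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "NumberOfFrames", 1) not in (1, None, "1"):
        raise DicomIOError(f"{path}: multi-frame (enhanced) DICOM is not supported")
    return _header_from_dataset(ds, str(path))


def load_pixel_array(path: str | os.PathLike) -> np.ndarray:
    """Pixel values of one DICOM file with rescale slope/intercept applied."""
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def load_volume_series(paths: list[str | os.PathLike]) -> VolumeGrid:
    """Assemble a 3D volume from single-frame DICOM files of one series.

    Slices are sorted by the projection of their position onto the slice
    normal ``row_cosine x col_cosine``, so the result does not depend on the
    input file order. Rescale slope/intercept are applied to the stored
    values. The inter-slice spacing must be uniform within a relative
    tolerance of 1e-3.
    """
    if len(paths) < 2:
        raise DicomIOError(f"need at least 2 slices to build a volume, got {len(paths)}")
    headers: list[SliceHeader] = []
    arrays: list[np.ndarray] = []
    for p in paths:
        ds = pydicom.dcmread(p)
        if getattr(ds, "NumberOfFrames", 1) not in (1, None, "1"):
            raise DicomIOError(f"{p}: multi-frame (enhanced) DICOM is not supported")
        h = _header_from_dataset(ds, str(p))
        headers.append(h)
        arrays.append(ds.pixel_array.astype(float) * h.rescale_slope + h.rescale_intercept)

    ref = headers[0]
    for h, p in zip(headers, paths):
        if h.series_uid != ref.series_uid:
            raise DicomIOError(
                f"mixed series UIDs in input: {ref.series_uid} vs {h.series_uid} ({p})"
            )
        if (h.rows, h.cols) != (ref.rows, ref.cols):
            raise DicomIOError(f"inconsistent matrix size in series ({p})")
        if not (
            np.allclose(h.row_cosine, ref.row_cosine, atol=_ORTHO_TOL)
            and np.allclose(h.col_cosine, ref.col_cosine, atol=_ORTHO_TOL)
        ):
            raise DicomIOError(f"inconsistent orientation in series ({p})")
        if not np.allclose(
            [h.pixel_spacing_row, h.pixel_spacing_col],
            [ref.pixel_spacing_row, ref.pixel_spacing_col],
            rtol=_SPACING_RTOL,
        ):
            raise DicomIOError(f"inconsistent pixel spacing in series ({p})")

    normal = np.cross(ref.row_cosine, ref.col_cosine)
    normal /= np.linalg.norm(normal)
    proj = np.array([float(np.dot(h.position, normal)) for h in headers])
    order = np.argsort(proj)
    proj = proj[order]
    gaps = np.diff(proj)
    if np.any(gaps <= 0):
        raise DicomIOError("duplicate slice positions in series")
    mean_gap = float(np.mean(gaps))
    bad = np.flatnonzero(np.abs(gaps - mean_gap) > _SPACING_RTOL * mean_gap)
    if bad.size:
        k = int(bad[0])
        raise DicomIOError(
            f"non-uniform inter-slice spacing: gap between sorted slices "
            f"{k} and {k + 1} is {gaps[k]:.6g} mm (expected {mean_gap:.6g} mm)"
        )

    values = np.stack([arrays[k] for k in order], axis=2)
    first = headers[int(order[0])]
    return VolumeGrid(
        values=values,
        origin=first.position,
        row_cosine=ref.row_cosine,
        col_cosine=ref.col_cosine,
        normal_cosine=normal,
        spacing=(ref.pixel_spacing_row, ref.pixel_spacing_col, mean_gap),
        series_uid=ref.series_uid,
        series_number=ref.series_number,
        study_uid=ref.study_uid,
    )


def _ds_str(x: float) -> str:
    """Format a float for a DICOM DS element (max 16 characters)."""
    s = format(float(x), ".10g")
    assert len(s) <= 16
    return s


def _base_dataset(sop_uid: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "MR"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    return ds


def write_slice(
    path: str | os.PathLike,
    pixels: np.ndarray,
    *,
    position: np.ndarray,
    row_cosine: np.ndarray,
    col_cosine: np.ndarray,
    pixel_spacing: tuple[float, float],
    series_uid: str,
    study_uid: str,
    sop_uid: str | None = None,
    series_number: int | None = None,
    instance_number: int | None = None,
    slice_thickness: float | None = None,
    series_description: str | None = None,
    derivation_description: str | None = None,
) -> str:
    """Write one single-frame DICOM file (unsigned 16-bit, explicit VR LE).

    Values are rounded and clipped to [0, 65535]; rescale slope/intercept
    are written as 1/0 so the stored values are the physical ones.
    """
    pixels = np.asarray(pixels)
    stored = np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)
    ds = _base_dataset(sop_uid or generate_uid())
    ds.Rows, ds.Columns = stored.shape
    ds.ImagePositionPatient = [_ds_str(v) for v in np.asarray(position, float)]
    iop = list(np.asarray(col_cosine, float)) + list(np.asarray(row_cosine, float))
    ds.ImageOrientationPatient = [_ds_str(v) for v in iop]
    ds.PixelSpacing = [_ds_str(pixel_spacing[0]), _ds_str(pixel_spacing[1])]
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = study_uid
    if series_number is not None:
        ds.SeriesNumber = int(series_number)
    if instance_number is not None:
        ds.InstanceNumber = int(instance_number)
    if slice_thickness is not None:
        ds.SliceThickness = _ds_str(slice_thickness)
    if series_description is not None:
        ds.SeriesDescription = series_description[:64]
    if derivation_description is not None:
        ds.DerivationDescription = derivation_description[:1024]
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "0"
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return str(path)


def export_resliced_dicom(result, reference: SliceHeader, out_dir: str | os.PathLike,
                          series_number: int | None = None) -> str:
    """Export a reformatted image as a DICOM file next to its reference.

    The file copies the reference's geometry (position, orientation, pixel
    spacing, matrix size) and study UID, carries freshly generated series
    and SOP instance UIDs, and a new series number (default: 3000 plus the
    source series number). The slice-thickness tag records the reslicing
    thickness actually used, not the reference's own thickness.
    """
    if result.values.shape != (reference.rows, reference.cols):
        raise DicomIOError(
            f"result matrix {result.values.shape} does not match reference "
            f"matrix {(reference.rows, reference.cols)}"
        )
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    if series_number is None:
        series_number = 3000 + (result.source_series_number or 0)
    sop_uid = generate_uid()
    desc = (
        f"Resliced s{result.source_series_number} "
        f"{result.profile_name} {result.thickness_used:.2f}mm"
    )
    deriv = (
        f"Reformatted from 3D series {result.source_series} at reference "
        f"slice {result.reference_sop}; slice thickness "
        f"{result.thickness_used:.4g} mm, profile {result.profile_name}"
    )
    path = os.path.join(out_dir, f"reslice_{sop_uid}.dcm")
    return write_slice(
        path,
        result.values,
        position=reference.position,
        row_cosine=reference.row_cosine,
        col_cosine=reference.col_cosine,
        pixel_spacing=(reference.pixel_spacing_row, reference.pixel_spacing_col),
        series_uid=generate_uid(),
        study_uid=reference.study_uid,
        sop_uid=sop_uid,
        series_number=series_number,
        instance_number=1,
        slice_thickness=result.thickness_used,
        series_description=desc,
        derivation_description=deriv,
    )
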