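"""Reading and writing DICOM series and NIfTI volumes.

DICOM stores geometry in LPS world coordinates; NIfTI affines are RAS.  Both
are converted into the package-wide RAS convention (see
:mod:`rapidwashout.volume`) on read and converted back on write.  Slice order
of a DICOM series is resolved by spatial position (projection of
ImagePositionPatient onto the slice normal), never by file name.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .volume import GeometryError, RgbVolume, Volume

__all__ = [
    "DicomReadError",
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "write_rgb_dicom",
    "write_gray_dicom",
]

_RAS_LPS = np.diag([-1.0, -1.0, 1.0])

SECONDARY_CAPTURE_SOP = "1.2.840.10008.5.1.4.1.1.7"


class DicomReadError(ValueError):
    """Raised when a DICOM directory cannot be read as one consistent series."""


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def read_nifti(file: str | os.PathLike, on_nonorthonormal: str = "orthonormalize") -> Volume:
    """Read a NIfTI-1 volume.

    Parameters
    ----------
    file
        Path to a ``.nii`` or ``.nii.gz`` file.
    on_nonorthonormal
        Policy when the affine's rotation part is not orthonormal (i.e. the
        grid is sheared): ``"orthonormalize"`` replaces it with the nearest
        rotation (polar decomposition), ``"reject"`` raises.
    """
    try:
        img = nib.load(str(file))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise GeometryError(f"cannot read NIfTI file {file!r}: {exc}") from exc
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise GeometryError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    affine = img.affine
    R = affine[:3, :3]
    spacing = np.linalg.norm(R, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError("NIfTI affine has a zero-length axis")
    orientation = R / spacing
    if not np.allclose(orientation.T @ orientation, np.eye(3), atol=1e-4):
        if on_nonorthonormal == "reject":
            raise GeometryError("NIfTI affine is sheared (non-orthonormal directions)")
        u, _, vt = np.linalg.svd(orientation)
        orientation = u @ vt
    else:
        # clean up float noise so downstream orthonormality checks pass
        u, _, vt = np.linalg.svd(orientation)
        orientation = u @ vt
    return Volume(
        data=data,
        spacing=tuple(spacing),
        origin=tuple(affine[:3, 3]),
        orientation=orientation,
        meta={"source": str(file), "format": "nifti"},
    )


def write_nifti(vol: Volume, file: str | os.PathLike) -> Path:
    """Write a Volume as NIfTI-1 (RAS affine); lossless for data and geometry."""
    file = Path(file)
    img = nib.Nifti1Image(np.asanyarray(vol.data), vol.affine)
    img.header.set_zooms(vol.spacing)
    img.set_qform(vol.affine, code=1)
    img.set_sform(vol.affine, code=1)
    nib.save(img, str(file))
    return file


# ---------------------------------------------------------------------------
# DICOM reading
# ---------------------------------------------------------------------------


def _dicom_files(directory: str | os.PathLike) -> list[Path]:
    directory = Path(directory)
    if not directory.is_dir():
        raise DicomReadError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    out = []
    for p in files:
        try:
            pydicom.dcmread(str(p), stop_before_pixels=True)
        except Exception:
            continue
        out.append(p)
    if not out:
        raise DicomReadError(f"no readable DICOM files in {directory}")
    return out


def _rescale(ds: Dataset, arr: np.ndarray) -> np.ndarray:
    slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
    if slope != 1.0 or intercept != 0.0:
        return arr.astype(np.float64) * slope + intercept
    return arr


def _geometry_from_tags(ipp, iop, pixel_spacing):
    ipp = np.asarray([float(v) for v in ipp])
    iop = np.asarray([float(v) for v in iop])
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    # PixelSpacing is (row spacing, col spacing) = (dy, dx)
    dy, dx = (float(v) for v in pixel_spacing)
    return ipp, row_dir, col_dir, normal, dx, dy


def _volume_from_slices(slices, meta) -> Volume:
    """Assemble slices [(position_lps, row_dir, col_dir, dx, dy, pixel2d), ...]."""
    ipp0, row_dir, col_dir, normal, dx, dy = _geometry_from_tags(*slices[0][:3])
    positions = []
    for ipp, iop, ps, arr in slices:
        ippi, rdi, cdi, _, dxi, dyi = _geometry_from_tags(ipp, iop, ps)
        if not (np.allclose(rdi, row_dir, atol=1e-4) and np.allclose(cdi, col_dir, atol=1e-4)):
            raise DicomReadError("inconsistent slice orientation within series")
        positions.append((float(np.dot(ippi, normal)), ippi, arr))
    positions.sort(key=lambda t: t[0])
    locs = np.array([p[0] for p in positions])
    if len(positions) > 1:
        gaps = np.diff(locs)
        if np.any(gaps <= 0):
            raise DicomReadError("duplicate or non-monotonic slice positions")
        dz = float(np.mean(gaps))
        if np.max(np.abs(gaps - dz)) > 0.01 * dz:
            raise DicomReadError(
                f"inconsistent slice spacing beyond 1% tolerance: gaps {gaps.tolist()}"
            )
    else:
        dz = float(meta.get("slice_thickness") or 1.0)
    # pixel array arr[r, c]: r runs along col_dir (y-index), c along row_dir
    stack = np.stack([p[2] for p in positions], axis=-1)  # (rows, cols, nslices)
    data = np.transpose(stack, (1, 0, 2))  # -> (i=cols, j=rows, k=slices)
    origin_lps = positions[0][1]
    orient_lps = np.column_stack([row_dir, col_dir, normal])
    return Volume(
        data=data,
        spacing=(dx, dy, dz),
        origin=tuple(_RAS_LPS @ origin_lps),
        orientation=_RAS_LPS @ orient_lps,
        meta=meta,
    )


def _read_multiframe(ds: Dataset, meta) -> Volume:
    shared = ds.SharedFunctionalGroupsSequence[0]
    try:
        iop = shared.PlaneOrientationSequence[0].ImageOrientationPatient
    except Exception:
        iop = None
    try:
        ps = shared.PixelMeasuresSequence[0].PixelSpacing
    except Exception:
        ps = None
    frames = ds.pixel_array  # (nframes, rows, cols)
    if frames.ndim == 2:
        frames = frames[None]
    slices = []
    for frame, group in zip(frames, ds.PerFrameFunctionalGroupsSequence):
        ipp = group.PlanePositionSequence[0].ImagePositionPatient
        iop_f = iop
        if iop_f is None:
            iop_f = group.PlaneOrientationSequence[0].ImageOrientationPatient
        ps_f = ps
        if ps_f is None:
            ps_f = group.PixelMeasuresSequence[0].PixelSpacing
        slices.append((ipp, iop_f, ps_f, _rescale(ds, frame)))
    return _volume_from_slices(slices, meta)


def read_dicom_series(directory: str | os.PathLike) -> Volume:
    """Read one DICOM series (classic single-frame files or one multiframe file).

    Slice ordering is resolved by spatial position along the slice normal.
    Rescale slope/intercept are applied.  A directory containing more than one
    SeriesInstanceUID is rejected with a message listing all series found.
    """
    files = _dicom_files(directory)
    datasets = [pydicom.dcmread(str(p)) for p in files]
    uids = sorted({str(getattr(ds, "SeriesInstanceUID", "<missing>")) for ds in datasets})
    if len(uids) > 1:
        raise DicomReadError(
            f"directory {directory} mixes {len(uids)} series: {', '.join(uids)}"
        )
    ds0 = datasets[0]
    meta = {
        "format": "dicom",
        "source": str(directory),
        "series_uid": uids[0],
        "modality": str(getattr(ds0, "Modality", "")),
        "patient_id": str(getattr(ds0, "PatientID", "")),
        "series_time": str(getattr(ds0, "SeriesTime", "")),
        "slice_thickness": getattr(ds0, "SliceThickness", None),
    }
    if int(getattr(ds0, "NumberOfFrames", 1) or 1) > 1:
        if len(datasets) > 1:
            raise DicomReadError("multiframe series must be a single file")
        return _read_multiframe(ds0, meta)
    slices = []
    for ds in datasets:
        if not hasattr(ds, "ImagePositionPatient") or not hasattr(ds, "ImageOrientationPatient"):
            raise DicomReadError("missing spatial attributes (ImagePositionPatient/Orientation)")
        if not hasattr(ds, "PixelSpacing"):
            raise DicomReadError("missing PixelSpacing")
        slices.append(
            (ds.ImagePositionPatient, ds.ImageOrientationPatient, ds.PixelSpacing,
             _rescale(ds, ds.pixel_array))
        )
    return _volume_from_slices(slices, meta)


# ---------------------------------------------------------------------------
# DICOM writing (secondary-capture semantics)
# ---------------------------------------------------------------------------


def _base_dataset(reference: Volume, series_uid: str, instance: int, description: str) -> Dataset:
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SECONDARY_CAPTURE_SOP
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = SECONDARY_CAPTURE_SOP
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = str(reference.meta.get("study_uid") or generate_uid())
    ds.Modality = "OT"
    ds.SeriesDescription = description
    ds.PatientID = str(reference.meta.get("patient_id", ""))
    ds.PatientName = str(reference.meta.get("patient_name", ""))
    ds.InstanceNumber = instance
    return ds


def _set_slice_geometry(ds: Dataset, reference: Volume, k: int) -> None:
    orient_lps = _RAS_LPS @ reference.orientation
    origin_lps = _RAS_LPS @ (
        np.asarray(reference.origin)
        + reference.orientation @ (np.array([0.0, 0.0, k]) * reference.spacing)
    )
    row_dir, col_dir = orient_lps[:, 0], orient_lps[:, 1]
    ds.ImageOrientationPatient = [f"{v:.8f}" for v in np.concatenate([row_dir, col_dir])]
    ds.ImagePositionPatient = [f"{v:.8f}" for v in origin_lps]
    dx, dy, dz = reference.spacing
    ds.PixelSpacing = [f"{dy:.8f}", f"{dx:.8f}"]  # (row, col) spacing
    ds.SliceThickness = f"{dz:.8f}"
    ds.SpacingBetweenSlices = f"{dz:.8f}"
    ds.SliceLocation = f"{float(np.dot(origin_lps, orient_lps[:, 2])):.8f}"


def write_rgb_dicom(
    rgb: RgbVolume, reference: Volume, directory: str | os.PathLike,
    description: str = "rapid wash-out RGB map",
) -> list[Path]:
    """Write an RGB volume as a per-slice secondary-capture DICOM series.

    Spatial attributes are copied from ``reference`` so the color maps overlay
    the source anatomy on a PACS viewer.
    """
    if rgb.shape != reference.shape:
        raise GeometryError(
            f"RGB shape {rgb.shape} does not match reference {reference.shape}"
        )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for k in range(rgb.shape[2]):
        ds = _base_dataset(reference, series_uid, k + 1, description)
        ds.SamplesPerPixel = 3
        ds.PhotometricInterpretation = "RGB"
        ds.PlanarConfiguration = 0
        ds.Rows, ds.Columns = rgb.shape[1], rgb.shape[0]
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        _set_slice_geometry(ds, reference, k)
        # slice (i, j, 3) -> (rows=j, cols=i, 3)
        ds.PixelData = np.ascontiguousarray(
            np.transpose(rgb.data[:, :, k, :], (1, 0, 2))
        ).tobytes()
        path = directory / f"slice_{k + 1:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


def write_gray_dicom(
    vol: Volume, reference: Volume, directory: str | os.PathLike,
    description: str = "rapid wash-out gray map",
) -> list[Path]:
    """Write a grayscale volume (values in [0, 65535]) as a DICOM series.

    Same secondary-capture call path as :func:`write_rgb_dicom`.
    """
    if vol.shape != reference.shape:
        raise GeometryError(f"shape {vol.shape} does not match reference {reference.shape}")
    data = np.asarray(vol.data)
    if data.min() < 0 or data.max() > 65535:
        raise ValueError("grayscale DICOM output requires values in [0, 65535]")
    data = np.round(data).astype(np.uint16)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for k in range(vol.shape[2]):
        ds = _base_dataset(reference, series_uid, k + 1, description)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = vol.shape[1], vol.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        _set_slice_geometry(ds, reference, k)
        ds.PixelData = np.ascontiguousarray(data[:, :, k].T).tobytes()
        path = directory / f"slice_{k + 1:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths
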