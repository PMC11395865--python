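"""Synthetic DICOM fixtures written programmatically at test time."""

from pathlib import Path

import numpy as np
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.sequence import Sequence
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

ENHANCED_MR = "1.2.840.10008.5.1.4.1.1.4.1"


def write_classic_series(
    directory, data, spacing=(1.0, 1.0, 2.0), slope=1.0, intercept=0.0,
    series_uid=None, origin_lps=(0.0, 0.0, 0.0), filenames=None,
    slice_positions=None,
):
    """Write a classic per-slice MR series whose voxel values equal ``data``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    nx, ny, nz = data.shape
    paths = []
    for k in range(nz):
        fm = FileMetaDataset()
        fm.MediaStorageSOPClassUID = MRImageStorage
        fm.MediaStorageSOPInstanceUID = generate_uid()
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = fm
        ds.SOPClassUID = MRImageStorage
        ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "MR"
        ds.PatientID = "PHANTOM"
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelSpacing = [str(spacing[1]), str(spacing[0])]
        ds.SliceThickness = str(spacing[2])
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        z = slice_positions[k] if slice_positions is not None else k * spacing[2]
        ds.ImagePositionPatient = [origin_lps[0], origin_lps[1], origin_lps[2] + z]
        ds.InstanceNumber = k + 1
        if slope != 1.0 or intercept != 0.0:
            ds.RescaleSlope = str(slope)
            ds.RescaleIntercept = str(intercept)
        stored = np.round((data[:, :, k].T - intercept) / slope).astype(np.uint16)
        ds.PixelData = stored.tobytes()
        name = filenames[k] if filenames is not None else f"z{k:03d}.dcm"
        path = directory / name
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


def write_multiframe_file(path, data, spacing=(1.0, 1.0, 2.0)):
    """Write the same volume as one enhanced-MR multiframe file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = data.shape
    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = ENHANCED_MR
    fm.MediaStorageSOPInstanceUID = generate_uid()
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = fm
    ds.SOPClassUID = ENHANCED_MR
    ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.Modality = "MR"
    ds.NumberOfFrames = nz
    ds.Rows, ds.Columns = ny, nx
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"

    shared = Dataset()
    orient = Dataset()
    orient.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    shared.PlaneOrientationSequence = Sequence([orient])
    measures = Dataset()
    measures.PixelSpacing = [str(spacing[1]), str(spacing[0])]
    measures.SliceThickness = str(spacing[2])
    shared.PixelMeasuresSequence = Sequence([measures])
    ds.SharedFunctionalGroupsSequence = Sequence([shared])

    per_frame = []
    for k in range(nz):
        grp = Dataset()
        pos = Dataset()
        pos.ImagePositionPatient = [0.0, 0.0, k * spacing[2]]
        grp.PlanePositionSequence = Sequence([pos])
        per_frame.append(grp)
    ds.PerFrameFunctionalGroupsSequence = Sequence(per_frame)
    ds.PixelData = np.ascontiguousarray(
        np.transpose(data.astype(np.uint16), (2, 1, 0))
    ).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path
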