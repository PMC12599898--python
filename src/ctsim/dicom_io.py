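"""Read and write axial CT volumes as DICOM series or NIfTI files.

The loaders extract the geometric header fields everything downstream
depends on: per-slice z-positions in the patient coordinate frame (from
Image Position (Patient)), slice thickness, and in-plane spacing.
Slices are always returned sorted by ascending physical z regardless of
on-disk file order, and intensities are rescaled to HU at load time.

Gantry-tilted or oblique series are rejected rather than resampled: the
simulation geometry assumes axial patient-coordinate slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .volume import DUPLICATE_Z_TOL, AxialVolume

__all__ = ["load_dicom_series", "load_nifti", "save_volume", "SeriesMetadata"]

#: row/column direction cosines must be within this of the patient x/y axes
ORIENTATION_TOL = 1e-2


@dataclass
class SeriesMetadata:
    """Header fields extracted from a DICOM series."""

    series_uid: str
    modality: str
    rescale_slope: float
    rescale_intercept: float
    positions: list[tuple[float, float, float]]
    slice_thickness: float
    spacing_between_slices: float | None
    orientation: tuple[float, ...]


def _check_axial(orientation, source: str) -> None:
    cos = np.asarray(orientation, dtype=np.float64)
    if cos.size != 6:
        raise ValueError(f"{source}: Image Orientation (Patient) must have 6 cosines")
    row, col = cos[:3], cos[3:]
    if abs(abs(row[0]) - 1.0) > ORIENTATION_TOL or abs(abs(col[1]) - 1.0) > ORIENTATION_TOL:
        raise ValueError(
            f"{source}: non-axial orientation {cos.tolist()} — gantry-tilted or "
            "oblique series are not supported"
        )


def load_dicom_series(directory: str | Path) -> AxialVolume:
    """Load a single-frame axial CT DICOM series into an :class:`AxialVolume`.

    Slices are sorted by the z-component of Image Position (Patient);
    stored values are rescaled to HU with the slope/intercept tags.

    Raises
    ------
    ValueError
        On mixed series UIDs, non-axial orientation, duplicate z-positions
        (named with the offending files), or missing position tags.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for path in files:
        try:
            ds = pydicom.dcmread(path)
        except pydicom.errors.InvalidDicomError:
            continue
        datasets.append((path, ds))
    if len(datasets) < 2:
        raise ValueError(f"{directory}: need at least 2 DICOM files, found {len(datasets)}")

    uids = {ds.SeriesInstanceUID for _, ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"{directory}: mixed series UIDs {sorted(uids)}")

    entries = []
    for path, ds in datasets:
        if "ImagePositionPatient" not in ds:
            raise ValueError(f"{path.name}: missing Image Position (Patient) tag")
        _check_axial(ds.ImageOrientationPatient, path.name)
        z = float(ds.ImagePositionPatient[2])
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        entries.append((z, path, hu, ds))

    entries.sort(key=lambda e: e[0])
    for (z0, p0, _, _), (z1, p1, _, _) in zip(entries, entries[1:]):
        if z1 - z0 < DUPLICATE_Z_TOL:
            raise ValueError(
                f"duplicate slice position z={z0:g} mm in files {p0.name!r} and {p1.name!r}"
            )

    ref = entries[0][3]
    thickness = float(ref.SliceThickness)
    spacing = [float(v) for v in ref.PixelSpacing]
    return AxialVolume(
        voxels=np.stack([hu for _, _, hu, _ in entries]),
        positions=np.array([z for z, _, _, _ in entries]),
        thickness=thickness,
        in_plane_spacing=(spacing[0], spacing[1]),
    )


def load_nifti(path: str | Path, thickness: float) -> AxialVolume:
    """Load a 3D NIfTI volume.

    NIfTI stores voxel spacing, not slice thickness, so the thickness
    must be supplied by the caller.  Slice positions are derived from the
    affine (origin + k * spacing along the third axis); a negative z
    spacing is flipped so positions come out ascending, with the voxel
    data flipped consistently.
    """
    if not thickness > 0:
        raise ValueError(f"thickness must be > 0, got {thickness}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    aff = np.asarray(img.affine, dtype=np.float64)
    rot = aff[:3, :3]
    off_axis = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_axis)) > 1e-3 * max(np.max(np.abs(rot)), 1.0):
        raise ValueError(f"{path}: affine is not axis-aligned; resample before loading")
    dz = aff[2, 2]
    if dz == 0:
        raise ValueError(f"{path}: affine has zero slice spacing")
    n = data.shape[2]
    positions = aff[2, 3] + np.arange(n) * dz
    vox = np.transpose(data, (2, 1, 0))  # (x, y, z) -> (slice, row, col)
    if dz < 0:
        vox = vox[::-1]
        positions = positions[::-1]
    return AxialVolume(
        voxels=vox.copy(),
        positions=positions,
        thickness=float(thickness),
        in_plane_spacing=(abs(aff[1, 1]), abs(aff[0, 0])),
    )


def save_volume(
    vol: AxialVolume,
    path: str | Path,
    format: str = "nifti",
    interval: float | None = None,
) -> None:
    """Write a volume as NIfTI or as a stack of single-frame DICOM files.

    For ``dicom_like_stack`` the emitted headers carry the volume's
    thickness as Slice Thickness and the centre-to-centre interval as
    Spacing Between Slices (inferred from the positions when not given);
    pixel data is quantized to signed 16-bit HU.  For NIfTI the slice
    positions must be uniformly spaced, since the affine can only encode
    a uniform grid.
    """
    path = Path(path)
    if format == "nifti":
        _save_nifti(vol, path)
    elif format == "dicom_like_stack":
        _save_dicom_stack(vol, path, interval)
    else:
        raise ValueError(f"unknown format {format!r}; choose 'nifti' or 'dicom_like_stack'")


def _slice_interval(vol: AxialVolume) -> float:
    if vol.n_slices == 1:
        return vol.thickness
    diffs = np.diff(vol.positions)
    if not np.allclose(diffs, diffs[0], atol=1e-6):
        raise ValueError("slice positions are not uniformly spaced")
    return float(diffs[0])


def _save_nifti(vol: AxialVolume, path: Path) -> None:
    dz = _slice_interval(vol)
    aff = np.diag([vol.in_plane_spacing[1], vol.in_plane_spacing[0], dz, 1.0])
    aff[2, 3] = vol.positions[0]
    data = np.transpose(vol.voxels, (2, 1, 0)).astype(np.float32)
    img = nib.Nifti1Image(data, aff)
    img.header["pixdim"][4] = 0
    nib.save(img, str(path))


def _save_dicom_stack(vol: AxialVolume, directory: Path, interval: float | None) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    if interval is None:
        interval = _slice_interval(vol)
    series_uid = generate_uid()
    study_uid = generate_uid()
    stored = np.clip(np.round(vol.voxels), -32768, 32767).astype(np.int16)
    for k in range(vol.n_slices):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = CTImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(vol.positions[k])]
        ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
        ds.SliceThickness = float(vol.thickness)
        ds.SpacingBetweenSlices = float(interval)
        ds.PixelSpacing = [float(vol.in_plane_spacing[0]), float(vol.in_plane_spacing[1])]
        ds.Rows, ds.Columns = vol.rows, vol.cols
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = stored[k].tobytes()
        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)
    manifest = {
        "n_slices": vol.n_slices,
        "thickness_mm": vol.thickness,
        "spacing_between_slices_mm": interval,
        "series_uid": str(series_uid),
    }
    (directory / "series_manifest.json").write_text(json.dumps(manifest, indent=2))
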