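"""CT volume container and DICOM series I/O.

The geometric conventions used throughout the package are fixed here:

* voxel data is indexed ``(z, y, x)``, 0-based, with slice ``k`` the k-th
  axial image in ascending world-z order;
* ``spacing`` is ``(dx, dy, dz)`` in millimetres;
* the world coordinate of voxel ``(k, j, i)`` is
  ``origin + (i*dx, j*dy, k*dz)`` in the scanner patient frame, which is
  taken as given (axial acquisitions only — oblique series are rejected).

Voxel values are Hounsfield units (HU).  The inter-slice spacing ``dz`` is
always measured from the slice world positions rather than taken from the
nominal slice-thickness tag, because overlapping reconstructions make the
two differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

__all__ = ["CTVolume", "read_ct_series", "write_ct_series", "read_raw_volume", "write_raw_volume"]

# stored pixel representation used by write_ct_series
_STORED_DTYPE = np.int16
_RESCALE_INTERCEPT = -8192.0
_RESCALE_SLOPE = 1.0


@dataclass
class CTVolume:
    """A 3D scalar grid of Hounsfield units with axial-slice geometry.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU values, slice-major.
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel size in mm.
    origin : tuple of float
        World position (mm) of voxel ``(0, 0, 0)``.
    series_meta : dict
        Opaque carry-through of source metadata (series UID, description,
        derivation tag) used when re-writing a derived series.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    series_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D (z, y, x), got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite HU values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def voxel_to_world(self, k, j, i) -> np.ndarray:
        """World (x, y, z) mm of voxel centre(s) (k, j, i)."""
        dx, dy, dz = self.spacing
        ox, oy, oz = self.origin
        return np.stack(
            [ox + np.asarray(i) * dx, oy + np.asarray(j) * dy, oz + np.asarray(k) * dz],
            axis=-1,
        )

    def copy(self, *, data: np.ndarray | None = None, tag: str | None = None) -> "CTVolume":
        meta = dict(self.series_meta)
        if tag is not None:
            meta["derivation_tag"] = tag
        return CTVolume(
            data=self.data.copy() if data is None else data,
            spacing=self.spacing,
            origin=self.origin,
            series_meta=meta,
        )


def _slice_datasets(directory_path) -> list[Dataset]:
    paths = sorted(Path(directory_path).iterdir())
    datasets = []
    for p in paths:
        if p.is_dir():
            continue
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue  # non-DICOM clutter (e.g. DICOMDIR, logs) is ignored
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    return datasets


def read_ct_series(directory_path) -> CTVolume:
    """Read a single-frame axial DICOM series into a :class:`CTVolume`.

    Slices are ordered by world z (``ImagePositionPatient[2]``), never by
    file name; the rescale slope/intercept are applied so the returned data
    is in HU; ``dz`` is the measured inter-slice world spacing.

    Raises
    ------
    ValueError
        If the directory mixes series, the inter-slice spacing is
        non-uniform beyond 1 %, or pixel-spacing metadata is missing.
    """
    datasets = _slice_datasets(directory_path)
    if len(datasets) < 2:
        raise ValueError(f"need at least 2 DICOM slices in {directory_path}, found {len(datasets)}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(uids) > 1:
        raise ValueError("directory mixes DICOM series: " + ", ".join(sorted(uids)))

    for ds in datasets:
        if "PixelSpacing" not in ds:
            raise ValueError("slice is missing PixelSpacing metadata")
        if "ImagePositionPatient" not in ds:
            raise ValueError("slice is missing ImagePositionPatient metadata")
        iop = getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
        if not np.allclose([float(v) for v in iop], [1, 0, 0, 0, 1, 0], atol=1e-4):
            raise ValueError("non-axial (oblique) acquisition is not supported")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    dzs = np.diff(zs)
    if np.any(dzs <= 0):
        raise ValueError("slice world-z positions are not strictly increasing")
    dz = float(np.mean(dzs))
    if np.max(np.abs(dzs - dz)) > 0.01 * dz:
        raise ValueError(
            f"non-uniform inter-slice spacing: range [{dzs.min():.4f}, {dzs.max():.4f}] mm"
        )

    first = datasets[0]
    # PixelSpacing is (row spacing, column spacing) = (dy, dx)
    dy, dx = (float(v) for v in first.PixelSpacing)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    data = np.stack(slices, axis=0)
    if len({s.shape for s in slices}) > 1:
        raise ValueError("slice pixel array shapes differ within the series")

    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[2]),
    )
    meta = {
        "series_uid": str(first.SeriesInstanceUID),
        "series_description": str(getattr(first, "SeriesDescription", "")),
        "derivation_tag": str(getattr(first, "ImageComments", "")) or None,
    }
    return CTVolume(data=data, spacing=(dx, dy, dz), origin=origin, series_meta=meta)


def write_ct_series(volume: CTVolume, directory_path, derivation_tag: str = "") -> list[Path]:
    """Write a :class:`CTVolume` as one single-frame DICOM file per slice.

    ``derivation_tag`` is recorded in ``ImageComments`` (and the series
    description) so that derived series — ``"crust-template"``,
    ``"virtually-cleaned"`` — are distinguishable from originals.

    Raises
    ------
    ValueError
        If the HU range does not fit the stored 16-bit representation
        after inverse rescale (never silently clipped).
    """
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)

    stored = (volume.data - _RESCALE_INTERCEPT) / _RESCALE_SLOPE
    info = np.iinfo(_STORED_DTYPE)
    if stored.min() < info.min or stored.max() > info.max:
        raise ValueError(
            f"HU range [{volume.data.min():.1f}, {volume.data.max():.1f}] exceeds the "
            f"representable stored range for int16 with intercept {_RESCALE_INTERCEPT}"
        )
    stored = np.rint(stored).astype(_STORED_DTYPE)

    series_uid = generate_uid()
    dx, dy, dz = volume.spacing
    ox, oy, oz = volume.origin
    paths = []
    for k in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = volume.series_meta.get("study_uid", "1.2.826.0.1.3680043.8.498.1")
        ds.SeriesDescription = (derivation_tag or "original")[:64]
        ds.ImageComments = derivation_tag
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [ox, oy, oz + k * dz]
        ds.SliceThickness = dz
        ds.PixelSpacing = [dy, dx]
        ds.Rows, ds.Columns = volume.data.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = _RESCALE_SLOPE
        ds.RescaleIntercept = _RESCALE_INTERCEPT
        ds.PixelData = stored[k].tobytes()

        path = directory_path / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_raw_volume(volume: CTVolume, basename) -> tuple[Path, Path]:
    """Fallback format: ``<basename>.ctmeta`` (JSON header) + ``<basename>.raw``.

    The raw file holds little-endian float32 scalars in (z, y, x) C order.
    Intended for tests and intermediates that must not depend on DICOM
    plumbing.
    """
    basename = Path(basename)
    meta_path = basename.with_suffix(".ctmeta")
    raw_path = basename.with_suffix(".raw")
    header = {
        "shape": list(volume.shape),
        "spacing": list(volume.spacing),
        "origin": list(volume.origin),
        "dtype": "<f4",
        "series_meta": volume.series_meta,
    }
    meta_path.write_text(json.dumps(header, indent=1))
    volume.data.astype("<f4").tofile(raw_path)
    return meta_path, raw_path


def read_raw_volume(basename) -> CTVolume:
    basename = Path(basename)
    header = json.loads(basename.with_suffix(".ctmeta").read_text())
    data = np.fromfile(basename.with_suffix(".raw"), dtype=header["dtype"])
    data = data.reshape(header["shape"]).astype(np.float64)
    return CTVolume(
        data=data,
        spacing=tuple(header["spacing"]),
        origin=tuple(header["origin"]),
        series_meta=header.get("series_meta", {}),
    )
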