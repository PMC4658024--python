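"""File I/O: 32-bit float TIFF + JSON sidecars for images and sinograms,
plus a minimal DICOM path (secondary-capture export and HU slice import)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .simulate import Geometry, ReconImage, Sinogram

__all__ = [
    "save_image", "load_image", "save_sinogram", "load_sinogram",
    "write_dicom", "read_dicom_image",
]

_ARM_TAG = 0x00990010  # private tag carrying the arm label


def save_image(image: ReconImage, stem: str | Path) -> None:
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tiff"), image.hu.astype(np.float32))
    stem.with_suffix(".json").write_text(json.dumps({
        "pixel_size_cm": image.pixel_size,
        "arm_label": image.arm_label,
        "energy_meta": image.energy_meta,
    }, indent=1))


def load_image(stem: str | Path) -> ReconImage:
    stem = Path(stem)
    hu = tifffile.imread(stem.with_suffix(".tiff")).astype(float)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return ReconImage(hu=hu, pixel_size=meta["pixel_size_cm"],
                      arm_label=meta["arm_label"], energy_meta=meta["energy_meta"])


def save_sinogram(sino: Sinogram, stem: str | Path) -> None:
    stem = Path(stem)
    tifffile.imwrite(stem.with_suffix(".tiff"), sino.values.astype(np.float32))
    geo = sino.geometry
    stem.with_suffix(".json").write_text(json.dumps({
        "kvp_label": sino.kvp_label,
        "effective_kev": sino.effective_kev,
        "noise_meta": sino.noise_meta,
        "geometry": {"n_angles": geo.n_angles, "n_detectors": geo.n_detectors,
                     "detector_spacing": geo.detector_spacing,
                     "grid_size": geo.grid_size},
    }, indent=1))


def load_sinogram(stem: str | Path) -> Sinogram:
    stem = Path(stem)
    values = tifffile.imread(stem.with_suffix(".tiff")).astype(float)
    meta = json.loads(stem.with_suffix(".json").read_text())
    geo = Geometry(**meta["geometry"])
    return Sinogram(values=values, geometry=geo, kvp_label=meta["kvp_label"],
                    effective_kev=meta["effective_kev"], noise_meta=meta["noise_meta"])


def write_dicom(image: ReconImage, path: str | Path) -> None:
    """Export an HU image as a minimal secondary-capture DICOM slice."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = image.hu.shape
    ds.PixelSpacing = [image.pixel_size * 10.0, image.pixel_size * 10.0]  # mm
    ds.RescaleSlope, ds.RescaleIntercept = 1.0, -1024.0
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    stored = np.clip(np.round(image.hu + 1024.0), 0, 65535).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    block = ds.private_block(0x0099, "ctmar", create=True)
    block.add_new(0x10, "LO", image.arm_label)
    pydicom.dcmwrite(str(path), ds)


def read_dicom_image(path: str | Path, arm_label: str = "dicom") -> ReconImage:
    """Read a DICOM slice into a calibrated HU image (slope/intercept applied)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    hu = ds.pixel_array.astype(float) * float(getattr(ds, "RescaleSlope", 1.0)) \
        + float(getattr(ds, "RescaleIntercept", 0.0))
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    try:
        block = ds.private_block(0x0099, "ctmar")
        arm_label = str(block[0x10].value)
    except (KeyError, AttributeError):
        pass
    return ReconImage(hu=hu, pixel_size=float(spacing[0]) / 10.0,
                      arm_label=arm_label, energy_meta={})
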