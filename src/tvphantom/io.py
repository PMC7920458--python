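"""Reading and writing 2-D grayscale images.

Supported formats: a lossless portable array container (NumPy .npz with
pixel pitch and provenance), NIfTI-1 (pixel pitch in the header zooms),
single-frame grayscale DICOM, and 8/16-bit PNG (intensity-scaled, for
inspection). Round-tripping through the portable container is bitwise
lossless; PNG and DICOM quantize to integers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError
from .image import Image

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return "dicom"
    if suffix == ".png":
        return "png"
    if suffix == ".npz":
        return "npz"
    raise FormatError(
        f"cannot infer format from {path.name!r}; expected .npz, .nii[.gz], "
        ".dcm or .png (or pass format explicitly)"
    )


def load_image(path, format: str | None = None, slice_index: int | None = None) -> Image:
    """Load a 2-D grayscale image.

    Multi-slice (3-D) NIfTI inputs require an explicit ``slice_index``
    (axial index into the last axis). Color images are rejected.
    """
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as data:
            return Image(values=data["values"],
                         pixel_mm=float(data["pixel_mm"]),
                         provenance=str(data["provenance"]))
    if fmt == "nifti":
        import nibabel as nib

        nii = nib.load(str(path))
        arr = np.asarray(nii.get_fdata(), dtype=np.float64)
        zooms = nii.header.get_zooms()
        if arr.ndim == 3:
            if arr.shape[2] == 1:
                arr = arr[:, :, 0]
            elif slice_index is None:
                raise FormatError(
                    f"{path.name} has {arr.shape[2]} slices; pass slice_index "
                    "to select one"
                )
            else:
                arr = arr[:, :, slice_index]
        elif arr.ndim != 2:
            raise FormatError(f"unsupported NIfTI dimensionality {arr.ndim}")
        return Image(values=arr, pixel_mm=float(zooms[0]),
                     provenance=f"nifti:{path.name}")
    if fmt == "dicom":
        import pydicom

        try:
            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array
        except Exception as exc:  # unreadable or unsupported transfer syntax
            raise FormatError(f"cannot decode DICOM {path.name}: {exc}") from exc
        if getattr(ds, "SamplesPerPixel", 1) != 1:
            raise FormatError("only single-sample (grayscale) DICOM is supported")
        photometric = getattr(ds, "PhotometricInterpretation", "MONOCHROME2")
        if not str(photometric).startswith("MONOCHROME"):
            raise FormatError(f"unsupported photometric interpretation {photometric}")
        if arr.ndim != 2:
            raise FormatError("only single-frame DICOM is supported")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        values = arr.astype(np.float64) * slope + intercept
        spacing = getattr(ds, "PixelSpacing", None)
        pixel_mm = float(spacing[0]) if spacing is not None else 1.0
        return Image(values=values, pixel_mm=pixel_mm, provenance=f"dicom:{path.name}")
    if fmt == "png":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim != 2:
            raise FormatError("color PNG images are not supported; provide grayscale")
        peak = float(np.iinfo(arr.dtype).max) if arr.dtype.kind == "u" else 1.0
        return Image(values=arr.astype(np.float64) / peak, pixel_mm=1.0,
                     provenance=f"png:{path.name}")
    raise FormatError(f"unknown format {fmt!r}")


def save_image(img: Image, path, format: str | None = None) -> Path:
    """Write an image; the format follows the file suffix unless given."""
    path = Path(path)
    fmt = format or _detect_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "npz":
        np.savez(path, values=img.values, pixel_mm=img.pixel_mm,
                 provenance=img.provenance)
        return path
    if fmt == "nifti":
        import nibabel as nib

        nii = nib.Nifti1Image(img.values.astype(np.float64), affine=np.diag(
            [img.pixel_mm, img.pixel_mm, 1.0, 1.0]))
        nii.header.set_zooms((img.pixel_mm, img.pixel_mm))
        nib.save(nii, str(path))
        return path
    if fmt == "png":
        import imageio.v3 as iio

        lo, hi = float(img.values.min()), float(img.values.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 0.0
        arr = np.round((img.values - lo) * scale).astype(np.uint16)
        iio.imwrite(path, arr)
        return path
    if fmt == "dicom":
        _save_dicom(img, path)
        return path
    raise FormatError(f"unknown format {fmt!r}")


def _save_dicom(img: Image, path: Path) -> None:
    """Write a minimal single-frame MONOCHROME2 secondary-capture file."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    lo, hi = float(img.values.min()), float(img.values.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    pixels = np.round((img.values - lo) / slope).astype(np.uint16) if hi > lo \
        else np.zeros(img.shape, dtype=np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = img.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = lo
    ds.PixelSpacing = [img.pixel_mm, img.pixel_mm]
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
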