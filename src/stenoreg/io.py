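"""File format helpers: grayscale images, CTA containers, CSV/PLY exports.

A CTA volume travels either as a DICOM series (rescale slope/intercept and
spacing read from the headers) or as a documented NPZ container with keys
``raw`` (int16, (nz, ny, nx)), ``slope``, ``intercept`` and ``spacing``
(dz, dy, dx in mm).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .phantom import CTAVolume

__all__ = [
    "read_gray",
    "write_png",
    "save_volume",
    "load_volume",
    "read_dicom_series",
    "write_keypoints_csv",
    "write_ply",
]


def read_gray(path, frame: int | None = None) -> np.ndarray:
    """Read a grayscale image (PNG/BMP; RGB converted by luminance).

    For a DICOM cine file, ``frame`` selects the frame index.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim == 3 and frame is not None:
            arr = arr[frame]
        elif arr.ndim == 3:
            arr = arr[0]
        return np.asarray(arr, dtype=float)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    return np.asarray(arr, dtype=float)


def write_png(path, img) -> None:
    import imageio.v3 as iio

    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def save_volume(path, vol: CTAVolume) -> None:
    np.savez_compressed(
        Path(path),
        raw=vol.raw.astype(np.int16),
        slope=vol.slope,
        intercept=vol.intercept,
        spacing=np.asarray(vol.spacing, dtype=float),
    )


def load_volume(path) -> CTAVolume:
    with np.load(Path(path)) as data:
        return CTAVolume(
            raw=data["raw"],
            slope=float(data["slope"]),
            intercept=float(data["intercept"]),
            spacing=tuple(data["spacing"]),
        )


def read_dicom_series(directory) -> CTAVolume:
    """Load a directory of DICOM slices, sorted along the patient z axis."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]

    def _zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=_zpos)
    first = slices[0]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    dy, dx = (float(v) for v in getattr(first, "PixelSpacing", (1.0, 1.0)))
    if len(slices) > 1:
        dz = abs(_zpos(slices[1]) - _zpos(slices[0])) or 1.0
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    raw = np.stack([ds.pixel_array for ds in slices]).astype(np.int16)
    return CTAVolume(raw=raw, slope=slope, intercept=intercept, spacing=(dz, dy, dx))


def write_keypoints_csv(path, rows) -> None:
    """Write keypoint rows ``(label, role, z, row, col)`` as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "role", "z", "row", "col"])
        writer.writerows(rows)


def write_ply(path, voxels_xyz, spacing=(1.0, 1.0, 1.0)) -> None:
    """ASCII PLY point cloud of (x, y, z) voxel coordinates (scaled to mm)."""
    dz, dy, dx = spacing
    pts = np.atleast_2d(np.asarray(voxels_xyz, dtype=float)) * [dx, dy, dz]
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in pts:
            fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")
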