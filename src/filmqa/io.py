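"""Reading and writing film scans and dose planes.

Two on-disk dose formats are supported: a self-describing ``ascii_grid``
text format (used for TPS exports and fixtures) and DICOM RT Dose (one
coronal slice).  Film scans are TIFF: 8/12/16-bit grayscale, or RGB in
which case the red channel is taken (the red channel carries most of the
dose signal for EBT-family film on flatbed scanners).
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import tifffile

from .model import DosePlane, FilmScan

__all__ = [
    "read_film_tiff",
    "write_film_tiff",
    "read_dose_grid",
    "write_ascii_grid",
    "roi_mean_pixel",
]

ASCII_GRID_MAGIC = "filmqa-dose-grid"
ASCII_GRID_VERSION = 1


# --------------------------------------------------------------------------
# Film TIFF
# --------------------------------------------------------------------------

def read_film_tiff(
    path,
    roi: tuple[int, int, int, int] | None = None,
    *,
    default_dpi: float = 75.0,
    sdd: float = 56.8,
) -> FilmScan:
    """Read a scanned film image into a :class:`FilmScan`.

    Parameters
    ----------
    path : path-like
        Single-channel or RGB TIFF.  For RGB the red channel is taken.
    roi : (row0, row1, col0, col1), optional
        Half-open crop in pixel indices, applied after channel selection.
    default_dpi : float
        Used when the file carries no resolution tag.  75 dpi matches the
        scanning protocol this package targets.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            dpi = _page_dpi(page) or float(default_dpi)
    except (OSError, ValueError, IndexError) as exc:
        raise IOError(f"cannot read film TIFF {path}: {exc}") from exc

    if arr.ndim == 3:
        if arr.shape[-1] < 3:
            raise ValueError(
                f"{path}: unsupported sample format (shape {arr.shape})"
            )
        arr = arr[..., 0]  # red channel
    elif arr.ndim != 2:
        raise ValueError(f"{path}: unsupported sample format (ndim {arr.ndim})")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: unsupported sample format (dtype {arr.dtype})")

    if roi is not None:
        r0, r1, c0, c1 = roi
        if not (0 <= r0 < r1 <= arr.shape[0] and 0 <= c0 < c1 <= arr.shape[1]):
            raise ValueError(f"{path}: ROI {roi} outside image {arr.shape} or empty")
        arr = arr[r0:r1, c0:c1]

    # 12-bit data commonly travels in a 16-bit container; infer the
    # effective depth from the data, never exceeding the container.
    container_bits = arr.dtype.itemsize * 8
    vmax = int(arr.max(initial=0))
    bit_depth = 12 if (container_bits == 16 and vmax < 4096) else container_bits

    return FilmScan(
        pixels=np.ascontiguousarray(arr),
        bit_depth=bit_depth,
        dpi=dpi,
        roi=roi,
        sdd=sdd,
        label=path.name,
    )


def _page_dpi(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if den == 0 or num == 0:
        return None
    res = num / den
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    unit = getattr(unit, "value", unit)
    if unit == 1:  # RESUNIT.NONE: aspect ratio only, no physical scale
        return None
    if unit == 3:  # centimetre
        res *= 2.54
    return float(res)


def write_film_tiff(path, scan: FilmScan) -> None:
    """Write a FilmScan as a 16-bit grayscale TIFF with its dpi tag."""
    tifffile.imwrite(
        Path(path),
        scan.pixels.astype(np.uint16),
        resolution=(scan.dpi, scan.dpi),
        resolutionunit="INCH",
    )


# --------------------------------------------------------------------------
# Dose grids
# --------------------------------------------------------------------------

def read_dose_grid(path, format: str = "ascii_grid") -> DosePlane:
    """Read a TPS dose plane from disk.

    ``ascii_grid`` is this package's self-describing text format (header
    of key=value lines, then ny rows of nx doses in cGy); ``dicom_rt_dose``
    reads a standard RT Dose object, converting Gy to cGy via
    DoseGridScaling.
    """
    if format == "ascii_grid":
        return _read_ascii_grid(Path(path))
    if format == "dicom_rt_dose":
        return _read_dicom_rt_dose(Path(path))
    raise ValueError(f"unknown dose-grid format {format!r}")


def _read_ascii_grid(path: Path) -> DosePlane:
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read dose grid {path}: {exc}") from exc
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(f"# {ASCII_GRID_MAGIC}"):
        raise ValueError(f"{path}: not a {ASCII_GRID_MAGIC} file")
    header: dict[str, str] = {}
    body_start = 1
    for i, ln in enumerate(lines[1:], start=1):
        if ln.startswith("#"):
            key, _, val = ln.lstrip("# ").partition("=")
            header[key.strip()] = val.strip()
        else:
            body_start = i
            break
    required = ("nx", "ny", "spacing_mm", "origin_mm", "sdd_cm", "unit")
    missing = [k for k in required if k not in header]
    if missing:
        raise ValueError(f"{path}: header missing {missing}")
    if header["unit"] != "cGy":
        raise ValueError(f"{path}: unsupported dose unit {header['unit']!r}")
    nx, ny = int(header["nx"]), int(header["ny"])
    sp = tuple(float(v) for v in header["spacing_mm"].split(","))
    org = tuple(float(v) for v in header["origin_mm"].split(","))
    values = np.array(
        [[float(v) for v in ln.split()] for ln in lines[body_start:]], dtype=float
    )
    if values.shape != (ny, nx):
        raise ValueError(
            f"{path}: body shape {values.shape} does not match header (ny={ny}, nx={nx})"
        )
    return DosePlane(values, sp, org, float(header["sdd_cm"]), label=path.name)


def write_ascii_grid(path, plane: DosePlane) -> None:
    ny, nx = plane.shape
    with open(path, "w") as fh:
        fh.write(f"# {ASCII_GRID_MAGIC} v{ASCII_GRID_VERSION}\n")
        fh.write(f"# nx = {nx}\n# ny = {ny}\n")
        fh.write(f"# spacing_mm = {plane.spacing[0]:.10g},{plane.spacing[1]:.10g}\n")
        fh.write(f"# origin_mm = {plane.origin[0]:.10g},{plane.origin[1]:.10g}\n")
        fh.write(f"# sdd_cm = {plane.sdd:.10g}\n# unit = cGy\n")
        np.savetxt(fh, plane.values, fmt="%.6g")


def _read_dicom_rt_dose(path: Path) -> DosePlane:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several exception types
        raise IOError(f"cannot read DICOM {path}: {exc}") from exc
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValueError(f"{path}: not an RT Dose object")
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise ValueError(f"{path}: missing DoseGridScaling")
    arr = ds.pixel_array
    if arr.ndim == 3:
        if arr.shape[0] != 1:
            raise ValueError(
                f"{path}: multi-frame dose ({arr.shape[0]} frames); select one slice"
            )
        arr = arr[0]
    orient = getattr(ds, "ImageOrientationPatient", None)
    if orient is not None:
        o = np.asarray([float(v) for v in orient])
        # coronal: row axis along patient x, column axis along patient z
        if not (abs(abs(o[0]) - 1) < 1e-3 and abs(abs(o[5]) - 1) < 1e-3):
            raise ValueError(f"{path}: dose slice is not coronal")
    unit = getattr(ds, "DoseUnits", "GY").upper()
    factor = float(scaling) * (100.0 if unit == "GY" else 1.0)
    values = arr.astype(float) * factor
    sp = getattr(ds, "PixelSpacing", [1.0, 1.0])
    spacing = (float(sp[0]), float(sp[1]))
    pos = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    origin = (float(pos[2]), float(pos[0]))  # (inplane, crossplane) in mm
    return DosePlane(values, spacing, origin, sdd=100.0, label=path.name)


# --------------------------------------------------------------------------
# Pixel statistics
# --------------------------------------------------------------------------

def roi_mean_pixel(
    scan: FilmScan, patch: tuple[int, int, int, int]
) -> tuple[float, float]:
    """Mean and standard deviation of pixel values in a rectangular patch.

    ``patch`` is (row0, row1, col0, col1), half-open, in the scan's own
    pixel indices.  This is the statistic used to reduce a calibration
    exposure to a single pixel value.
    """
    r0, r1, c0, c1 = patch
    h, w = scan.pixels.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"patch {patch} empty or outside scan {scan.pixels.shape}")
    block = scan.pixels[r0:r1, c0:c1].astype(float)
    return float(block.mean()), float(block.std(ddof=0))
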