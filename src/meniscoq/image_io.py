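"""Reading and writing of relaxometry image series, ROI masks and reports.

The pipeline works on per-slice 2D magnitude frames. A :class:`ImageSeries`
holds the frames of one sagittal slice acquired at several weighting times
(spin-lock times for T1rho, echo times for T2), in milliseconds. ROI masks
are binary rasters labelled by meniscal side (lateral ``LM`` / medial
``MM``), segment (anterior horn ``AH``, body ``BD``, posterior horn ``PH``),
observer and session.

Coordinates are 0-based ``(row, col)``, row-major; masks and frames share
one grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Modality(str, Enum):
    T1RHO = "T1RHO"
    T2 = "T2"


class Side(str, Enum):
    LM = "LM"
    MM = "MM"


class Segment(str, Enum):
    AH = "AH"
    BD = "BD"
    PH = "PH"


class FormatError(ValueError):
    """Raised when an input file violates the series/mask contracts."""


@dataclass
class ImageSeries:
    """A stack of 2D magnitude frames of one slice, ordered by weighting time.

    Parameters
    ----------
    frames:
        Array of shape ``(n_times, rows, cols)`` with nonnegative intensities.
    weight_times:
        Strictly increasing times in ms (TSL for T1rho, TE for T2), one per
        frame.
    modality:
        Which relaxation parameter the series encodes.
    pixel_spacing:
        (row, col) spacing in mm.
    slice_index:
        Index of the sagittal slice this series belongs to.
    """

    frames: np.ndarray
    weight_times: np.ndarray
    modality: Modality
    pixel_spacing: tuple[float, float] = (0.27, 0.27)
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.weight_times = np.asarray(self.weight_times, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (n_times, rows, cols) stack")
        if self.frames.shape[0] != self.weight_times.shape[0]:
            raise FormatError("one weighting time is required per frame")
        if self.frames.shape[0] < 2:
            raise FormatError("a relaxometry series needs at least 2 frames")
        if np.any(self.weight_times <= 0):
            raise FormatError("weighting times must be positive")
        if np.any(np.diff(self.weight_times) == 0):
            raise FormatError("duplicated weighting times")
        if np.any(np.diff(self.weight_times) < 0):
            raise FormatError("weighting times must be strictly increasing")
        self.modality = Modality(self.modality)
        if int(self.slice_index) < 0:
            raise FormatError("slice_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def sorted_by_time(self) -> "ImageSeries":
        order = np.argsort(self.weight_times, kind="stable")
        return ImageSeries(
            frames=self.frames[order],
            weight_times=self.weight_times[order],
            modality=self.modality,
            pixel_spacing=self.pixel_spacing,
            slice_index=self.slice_index,
        )


@dataclass
class RoiMask:
    """Binary meniscus ROI for one slice, with study labels."""

    mask: np.ndarray
    side: Side
    segment: Segment
    observer: str = "R1"
    session: str = "S1"
    slice_index: int = 0
    empty: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise FormatError("mask must be a 2D raster")
        self.side = Side(self.side)
        self.segment = Segment(self.segment)
        self.empty = not bool(self.mask.any())
        if self.empty:
            warnings.warn(
                f"empty ROI mask ({self.side.value}{self.segment.value}, "
                f"observer={self.observer}, session={self.session})",
                stacklevel=2,
            )

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# series I/O


def _series_from_sorted(frames, times, modality, spacing, slice_index) -> ImageSeries:
    series = ImageSeries(
        frames=np.stack(frames),
        weight_times=np.asarray(times, dtype=float),
        modality=modality,
        pixel_spacing=spacing,
        slice_index=slice_index,
    )
    return series


def read_series(
    path: str | Path,
    modality: Modality | str,
    weight_times: Sequence[float] | None = None,
    sidecar: str | Path | None = None,
    slice_index: int = 0,
) -> ImageSeries:
    """Read a multi-weighting-time magnitude series.

    ``path`` is either a DICOM directory (one file per frame) or a NIfTI
    file whose third axis indexes the frames. Weighting times come from
    per-frame DICOM metadata (EchoTime) when available; otherwise they must
    be supplied via ``weight_times`` or a YAML sidecar with keys
    ``weight_times_ms`` and optionally ``pixel_spacing_mm``. Times are never
    inferred. Frames are returned sorted by ascending weighting time.
    """
    path = Path(path)
    modality = Modality(modality)
    spacing = (0.27, 0.27)
    spacing_from_meta = False

    if sidecar is not None:
        import yaml

        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        if weight_times is None:
            weight_times = meta.get("weight_times_ms")
        if "pixel_spacing_mm" in meta:
            spacing = tuple(float(v) for v in meta["pixel_spacing_mm"])
            spacing_from_meta = True

    if path.is_dir():
        frames, times = _read_dicom_dir(path, weight_times)
    else:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError("NIfTI series must be 3D (rows, cols, frames)")
        frames = [data[:, :, k].astype(float) for k in range(data.shape[2])]
        if weight_times is None:
            raise FormatError(
                "weighting times must be supplied for NIfTI input "
                "(weight_times argument or sidecar)"
            )
        times = [float(t) for t in weight_times]
        zooms = img.header.get_zooms()
        if not spacing_from_meta and len(zooms) >= 2 and zooms[0] > 0:
            spacing = (float(zooms[0]), float(zooms[1]))

    if len(times) != len(frames):
        raise FormatError("number of weighting times does not match frames")
    if len(set(times)) != len(times):
        raise FormatError("duplicated weighting times")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError("mismatched frame shapes")

    order = np.argsort(times, kind="stable")
    frames = [frames[k] for k in order]
    times = [times[k] for k in order]
    return _series_from_sorted(frames, times, modality, spacing, slice_index)


def _read_dicom_dir(path: Path, weight_times):
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    frames, times = [], []
    for k, f in enumerate(files):
        ds = pydicom.dcmread(str(f))
        frames.append(ds.pixel_array.astype(float))
        if weight_times is not None:
            times.append(float(weight_times[k]))
        elif hasattr(ds, "EchoTime") and ds.EchoTime is not None:
            times.append(float(ds.EchoTime))
        else:
            raise FormatError(
                f"{f.name}: no per-frame weighting time in metadata and "
                "no sidecar list supplied"
            )
    return frames, times


def write_series_nifti(series: ImageSeries, path: str | Path) -> None:
    """Write a series as a 3D NIfTI with frames along the third axis."""
    import nibabel as nib

    data = np.moveaxis(series.frames, 0, 2)
    affine = np.diag([series.pixel_spacing[0], series.pixel_spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# mask I/O


def polygon_to_mask(vertices: Sequence[tuple[float, float]], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon: a pixel is inside iff its center is inside
    under the even-odd rule. Vertices are (row, col), 0-based."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    py, px = rows.ravel().astype(float), cols.ravel().astype(float)
    inside = np.zeros(py.shape, dtype=bool)
    n = verts.shape[0]
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        # edge crossing test in the col (x) direction against a ray along +row
        cond = (c1 > px) != (c2 > px)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_at = (r2 - r1) * (px - c1) / (c2 - c1) + r1
        crosses = cond & (py < r_at)
        inside ^= crosses
    # points exactly on a boundary edge count as inside
    on_edge = np.zeros(py.shape, dtype=bool)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        d = np.abs((r2 - r1) * (px - c1) - (c2 - c1) * (py - r1))
        seglen2 = (r2 - r1) ** 2 + (c2 - c1) ** 2
        if seglen2 == 0:
            continue
        t = ((py - r1) * (r2 - r1) + (px - c1) * (c2 - c1)) / seglen2
        on_edge |= (d < 1e-9 * max(1.0, np.sqrt(seglen2))) & (t >= 0) & (t <= 1)
    return (inside | on_edge).reshape(shape)


def read_mask(
    path: str | Path,
    side: Side | str,
    segment: Segment | str,
    observer: str = "R1",
    session: str = "S1",
    slice_index: int = 0,
    expected_shape: tuple[int, int] | None = None,
) -> RoiMask:
    """Read an ROI mask from a PNG/NIfTI label image or a JSON polygon file.

    JSON polygon files carry ``{"shape": [rows, cols], "vertices": [[r, c], ...]}``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            spec = json.load(fh)
        mask = polygon_to_mask(spec["vertices"], tuple(spec["shape"]))
    elif path.suffix.lower() in {".nii", ".gz"}:
        import nibabel as nib

        mask = np.asanyarray(nib.load(str(path)).dataobj) > 0
        if mask.ndim == 3:
            mask = mask[:, :, 0]
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
        mask = arr > 0
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise FormatError(
            f"mask shape {mask.shape} does not match series shape {expected_shape}"
        )
    return RoiMask(
        mask=mask,
        side=side,
        segment=segment,
        observer=observer,
        session=session,
        slice_index=slice_index,
    )


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# reports


def _sig6(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.6g}"


def write_report(rows: Iterable[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write summary rows to CSV with a deterministic column order and
    numbers at 6 significant digits."""
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    df = pd.DataFrame(rows, columns=list(columns))
    formatted = df.copy()
    for col in formatted.columns:
        formatted[col] = [
            _sig6(v) if isinstance(v, (float, np.floating, int, np.integer)) else v
            for v in formatted[col]
        ]
    formatted.to_csv(path, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
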