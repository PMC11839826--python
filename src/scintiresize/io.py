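"""Readers and writers: 16-bit PNG, CSV matrices, minimal planar DICOM, curves.

Count images are stored as 16-bit unsigned grayscale (PNG or DICOM pixel
data) — ample headroom, since even a 550 kcnts full-count image spread over a
64x64 grid stays far below 65,535 counts per pixel; an overflow raises
rather than truncating.  Real-valued intermediates go to CSV at full
precision.  Pixel spacing travels in the DICOM Pixel Spacing tag or in a
JSON sidecar next to PNG/CSV files.

Array convention in every writer: row-major, origin top-left, 0-based
indices; row ``i`` of the array is row ``i`` of the stored image.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .images import CountImage, RealImage
from .experiments import SimilarityCurve
from .phantom import DynamicSeries

__all__ = [
    "read_image",
    "write_image",
    "write_series",
    "read_series",
    "write_series_dicom",
    "read_series_dicom",
    "write_curve",
    "write_curves",
    "read_curve",
    "RunConfig",
]

_MAX_U16 = 65_535

CURVE_COLUMNS = [
    "level_frames",
    "nominal_kcnts",
    "metric",
    "mean",
    "ci_low",
    "ci_high",
    "n_perm",
]


# ---------------------------------------------------------------------------
# single images


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, img) -> None:
    meta = {
        "pixel_spacing_mm": img.pixel_spacing_mm,
        "view_label": img.view_label,
        "kind": "count" if isinstance(img, CountImage) else "real",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {}


def _check_u16(pixels: np.ndarray) -> np.ndarray:
    if pixels.max(initial=0) > _MAX_U16:
        raise OverflowError(
            f"pixel count {pixels.max()} exceeds the 16-bit storage limit {_MAX_U16}"
        )
    return pixels.astype(np.uint16)


def write_image(img: Union[CountImage, RealImage], path) -> None:
    """Write an image as 16-bit PNG (counts), CSV, or single-frame DICOM.

    The format follows the suffix (.png / .csv / .dcm).  PNG and CSV get a
    JSON sidecar carrying pixel spacing and view; DICOM carries them in tags.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        if not isinstance(img, CountImage):
            raise ValueError("PNG storage is for integer count images; use CSV")
        from PIL import Image

        Image.fromarray(_check_u16(img.pixels)).save(path)
        _write_sidecar(path, img)
    elif suffix == ".csv":
        data = img.pixels if isinstance(img, CountImage) else img.values
        fmt = "%d" if isinstance(img, CountImage) else "%.17g"
        np.savetxt(path, data, delimiter=",", fmt=fmt)
        _write_sidecar(path, img)
    elif suffix == ".dcm":
        if not isinstance(img, CountImage):
            raise ValueError("DICOM storage is for integer count images; use CSV")
        _write_dicom(path, img.pixels[np.newaxis], img.pixel_spacing_mm, img.view_label)
    else:
        raise ValueError(f"unsupported image format {suffix!r}")


def read_image(path, format: Optional[str] = None) -> Union[CountImage, RealImage]:
    """Read a DICOM, 16-bit PNG, or CSV image.

    Integer pixel data yields a :class:`CountImage`; real-valued CSV yields a
    :class:`RealImage`.  Spacing comes from the DICOM Pixel Spacing tag or
    the JSON sidecar; when absent, 1 mm is assumed with a warning.
    """
    import warnings

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("dcm", "dicom"):
        stack, spacing, view = _read_dicom(path)
        if stack.shape[0] != 1:
            raise ValueError("multi-frame DICOM: use read_series_dicom")
        return CountImage(stack[0], spacing, view)
    if fmt == "png":
        from PIL import Image

        arr = np.asarray(Image.open(path), dtype=np.int64)
    elif fmt == "csv":
        arr = np.atleast_2d(np.loadtxt(path, delimiter=","))
    else:
        raise ValueError(f"unsupported image format {fmt!r}")
    meta = _read_sidecar(path)
    spacing = meta.get("pixel_spacing_mm")
    if spacing is None:
        warnings.warn(f"no pixel spacing recorded for {path.name}; assuming 1 mm")
        spacing = 1.0
    view = meta.get("view_label")
    kind = meta.get("kind")
    is_integral = np.issubdtype(arr.dtype, np.integer) or np.all(arr == np.floor(arr))
    if kind == "real" or not is_integral:
        return RealImage(np.asarray(arr, dtype=np.float64), spacing, view)
    if arr.min() < 0:
        raise ValueError(f"{path.name}: negative values in a count image")
    return CountImage(arr.astype(np.int64), spacing, view)


# ---------------------------------------------------------------------------
# dynamic series


def write_series(series: DynamicSeries, out_dir) -> None:
    """Write a dynamic series as a directory of 16-bit PNG frames + sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from PIL import Image

    width = max(3, len(str(series.n_frames - 1)))
    for i in range(series.n_frames):
        frame = _check_u16(series.stack[i])
        Image.fromarray(frame).save(out_dir / f"frame_{i:0{width}d}.png")
    meta = {
        "pixel_spacing_mm": series.pixel_spacing_mm,
        "view_label": series.view_label,
        "frame_duration_s": series.frame_duration_s,
        "n_frames": series.n_frames,
    }
    (out_dir / "series.json").write_text(json.dumps(meta, indent=1))


def read_series(in_dir) -> DynamicSeries:
    """Read a dynamic series written by :func:`write_series`."""
    from PIL import Image

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "series.json").read_text())
    paths = sorted(in_dir.glob("frame_*.png"))
    if len(paths) != meta["n_frames"]:
        raise ValueError(
            f"expected {meta['n_frames']} frames, found {len(paths)} in {in_dir}"
        )
    stack = np.stack([np.asarray(Image.open(p), dtype=np.int64) for p in paths])
    return DynamicSeries(
        stack,
        meta["pixel_spacing_mm"],
        meta.get("view_label"),
        meta.get("frame_duration_s", 1.0),
    )


def _write_dicom(path: Path, stack: np.ndarray, spacing: float, view) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    stack = np.ascontiguousarray(stack)
    u16 = _check_u16(stack)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.20")  # NM
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.SeriesDescription = view or ""
    ds.Rows, ds.Columns = u16.shape[1:]
    ds.NumberOfFrames = u16.shape[0]
    ds.PixelSpacing = [f"{spacing:.6g}", f"{spacing:.6g}"]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = u16.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path: Path) -> tuple[np.ndarray, float, Optional[str]]:
    import warnings

    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    spacing_tag = getattr(ds, "PixelSpacing", None)
    if spacing_tag is None:
        warnings.warn(f"{path.name}: no Pixel Spacing tag; assuming 1 mm")
        spacing = 1.0
    else:
        spacing = float(spacing_tag[0])
    view = getattr(ds, "SeriesDescription", "") or None
    return arr.astype(np.int64), spacing, view


def write_series_dicom(series: DynamicSeries, path) -> None:
    """Write a dynamic series as one multi-frame planar NM DICOM object."""
    _write_dicom(Path(path), series.stack, series.pixel_spacing_mm, series.view_label)


def read_series_dicom(path) -> DynamicSeries:
    """Read a multi-frame planar NM DICOM object as a dynamic series."""
    stack, spacing, view = _read_dicom(Path(path))
    return DynamicSeries(stack, spacing, view)


# ---------------------------------------------------------------------------
# similarity curves


def write_curve(curve: SimilarityCurve, path) -> None:
    """Write a similarity curve as CSV (lossless float round trip)."""
    df = pd.DataFrame(
        {
            "level_frames": curve.levels.astype(int),
            "nominal_kcnts": curve.nominal_kcnts,
            "metric": curve.metric,
            "mean": curve.mean,
            "ci_low": curve.ci_low,
            "ci_high": curve.ci_high,
            "n_perm": curve.n_perm,
        },
        columns=CURVE_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_curves(curves: dict[str, SimilarityCurve], path) -> None:
    """Write several metrics' curves into one CSV (one block per metric)."""
    frames = []
    for m in sorted(curves):
        c = curves[m]
        frames.append(
            pd.DataFrame(
                {
                    "level_frames": c.levels.astype(int),
                    "nominal_kcnts": c.nominal_kcnts,
                    "metric": c.metric,
                    "mean": c.mean,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "n_perm": c.n_perm,
                },
                columns=CURVE_COLUMNS,
            )
        )
    out = pd.concat(frames) if frames else pd.DataFrame(columns=CURVE_COLUMNS)
    out.to_csv(path, index=False)


def read_curve(path, metric: Optional[str] = None) -> SimilarityCurve:
    """Read a similarity curve CSV written by :func:`write_curve`.

    If the file holds several metrics, ``metric`` selects one.
    """
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed curve CSV: missing columns {missing}")
    if len(df) == 0:
        return SimilarityCurve(metric or "", [], [], [], [], [], 0)
    if metric is not None:
        df = df[df["metric"] == metric]
        if len(df) == 0:
            raise ValueError(f"no rows for metric {metric!r}")
    metrics = df["metric"].unique()
    if len(metrics) != 1:
        raise ValueError(f"curve CSV holds several metrics {list(metrics)}; pick one")
    n_perm = df["n_perm"].unique()
    if len(n_perm) != 1:
        raise ValueError("inconsistent n_perm in curve CSV")
    return SimilarityCurve(
        metric=str(metrics[0]),
        levels=df["level_frames"].to_numpy(float),
        nominal_kcnts=df["nominal_kcnts"].to_numpy(float),
        mean=df["mean"].to_numpy(float),
        ci_low=df["ci_low"].to_numpy(float),
        ci_high=df["ci_high"].to_numpy(float),
        n_perm=int(n_perm[0]),
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of a simulation/experiment run.

    Round-trips losslessly through TOML; every field has a valid default.
    """

    seed: int = 0
    views: tuple[str, ...] = ("ANT",)
    grids: tuple[int, ...] = (64, 128, 256)
    levels: tuple[int, ...] = (1, 2, 5, 10, 20, 35, 50)
    n_perm: int = 1000
    metrics: tuple[str, ...] = ("ssim", "log_mse")
    frame_kcnts: float = 11.0
    n_frames: int = 100
    out_dir: str = "."
    verbosity: int = 1

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                items = ", ".join(json.dumps(x) for x in v)
                lines.append(f"{f.name} = [{items}]")
            else:
                lines.append(f"{f.name} = {json.dumps(v)}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_toml())

    @classmethod
    def load(cls, path) -> "RunConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)
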