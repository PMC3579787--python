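"""Image, scale-table and measurement I/O plus run configuration.

Images are held as plain 2-D ``uint8`` numpy arrays wrapped in
:class:`IntensityImage` with an optional physical scale (µm per pixel).
Coordinates are (row, col) with the origin at the top-left pixel center.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "IntensityImage",
    "ScaleTable",
    "MeasurementRecord",
    "RunConfig",
    "load_image",
    "save_image",
    "scale_for_zoom",
    "read_scale_table",
    "write_measurements",
    "read_measurements",
    "render_overlay",
    "CONTOUR_COLOR",
    "SKELETON_COLOR",
    "RADII_COLOR",
]

_SUPPORTED_SUFFIXES = {".tif", ".tiff", ".png", ".bmp", ".jpg", ".jpeg"}

# Overlay palette: contour yellow, skeleton blue, sampled radii cyan.
CONTOUR_COLOR = (255, 255, 0)
SKELETON_COLOR = (0, 0, 255)
RADII_COLOR = (0, 255, 255)

# ITU-R BT.601 luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class IntensityImage:
    """8-bit grayscale image with an optional µm/px scale."""

    pixels: np.ndarray
    scale: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("IntensityImage requires a 2-D pixel grid")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie within [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape


def load_image(path) -> IntensityImage:
    """Load a TIFF/PNG/BMP/JPEG image as 8-bit grayscale.

    Multi-channel images are converted by BT.601 luminance weighting and
    rounding; images deeper than 8 bits are rescaled to [0, 255] by min-max
    mapping.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise IOError(f"unsupported image format: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise IOError(f"cannot read image {path}: {exc}") from exc

    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = np.rint(arr[:, :, :3].astype(float) @ _LUMA)
    arr = arr.astype(float)
    if arr.max() > 255:
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(arr)
    return IntensityImage(np.rint(arr).astype(np.uint8))


def save_image(image, path) -> None:
    """Write an 8-bit grayscale (2-D) or RGB (3-D) array losslessly.

    JPEG is deliberately refused: it is accepted on read but never written.
    """
    path = Path(path)
    if path.suffix.lower() in (".jpg", ".jpeg"):
        raise IOError("refusing to write lossy JPEG; use PNG/TIFF/BMP")
    arr = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.uint8))
    else:
        Image.fromarray(arr.astype(np.uint8)).save(path)


@dataclass
class ScaleTable:
    """Map of microscope zoom level → recorded µm-per-pixel scale."""

    entries: dict

    def __post_init__(self):
        if not self.entries:
            raise ValueError("scale table must contain at least one entry")
        if any(v <= 0 for v in self.entries.values()):
            raise ValueError("all scales must be > 0 µm/px")


def scale_for_zoom(table: ScaleTable, zoom: float) -> float:
    """Scale at a zoom level; linear interpolation between recorded zooms.

    Zooms outside the recorded range raise (no extrapolation).
    """
    zooms = np.array(sorted(table.entries))
    scales = np.array([table.entries[z] for z in zooms])
    if zoom < zooms[0] or zoom > zooms[-1]:
        raise ValueError(
            f"zoom {zoom} outside recorded range [{zooms[0]}, {zooms[-1]}]")
    return float(np.interp(zoom, zooms, scales))


def read_scale_table(path) -> ScaleTable:
    """Read a ``zoom,um_per_px`` CSV into a :class:`ScaleTable`."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "zoom" not in cols or "um_per_px" not in cols:
        raise IOError(f"scale table {path} needs columns zoom,um_per_px")
    return ScaleTable(dict(zip(df[cols["zoom"]].astype(float),
                               df[cols["um_per_px"]].astype(float))))


@dataclass
class RunConfig:
    """Parameters of the image-processing pipeline, echoed into outputs."""

    ball_radius_px: int = 50
    light_background: bool = True
    threshold_algorithm: str = "minimum"
    area_min_px2: float = 100.0
    area_max_px2: float = 1e6
    prune_ratio_min: float = 0.8
    interval_px: float = 10.0
    extension_window_px: int = 5

    def __post_init__(self):
        if self.interval_px < 1:
            raise ValueError("interval_px must be >= 1")
        if not 0 <= self.prune_ratio_min <= 1:
            raise ValueError("prune_ratio_min must lie in [0, 1]")
        if not self.area_min_px2 < self.area_max_px2:
            raise ValueError("area_min_px2 must be < area_max_px2")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MeasurementRecord:
    """One measured worm, in absolute units, with the settings echoed."""

    image_file: str
    worm_id: str
    pass_flag: bool
    length_um: float
    avg_width_um: float
    mid_width_um: float
    volume_pl: float
    cylinder_volume_pl: float
    scale_um_per_px: float
    settings_echo: str = ""


_CSV_COLUMNS = [f.name for f in dataclasses.fields(MeasurementRecord)]


def write_measurements(records, path) -> None:
    """Write measurement records to CSV (RFC 4180, UTF-8, '.' decimal).

    Floats are written with ``repr`` precision so a read-back reproduces
    the in-memory values exactly.  Zero records produce a header-only file.
    """
    rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in records]
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_measurements(path) -> list[MeasurementRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["settings_echo"] = "" if pd.isna(d.get("settings_echo")) else str(d["settings_echo"])
        out.append(MeasurementRecord(**d))
    return out


def render_overlay(image, worm) -> np.ndarray:
    """Paint a worm's contour (yellow), skeleton (blue) and radius chords
    (cyan) over the grayscale image; returns an RGB uint8 array."""
    import warnings

    from skimage.draw import line as sk_line

    gray = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    rgb = np.stack([gray] * 3, axis=-1).astype(np.uint8)
    h, w = gray.shape

    def paint(rows, cols, color):
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        rgb[rows[ok], cols[ok]] = color

    contour = getattr(worm, "contour", None)
    if contour is not None and len(contour):
        c = np.rint(np.asarray(contour)).astype(int)
        paint(c[:, 0], c[:, 1], CONTOUR_COLOR)

    profile = getattr(worm, "radius_profile", None)
    if profile is not None and getattr(profile, "chords", None) is not None:
        for (r0, c0), (r1, c1) in profile.chords:
            rr, cc = sk_line(int(round(r0)), int(round(c0)),
                             int(round(r1)), int(round(c1)))
            paint(rr, cc, RADII_COLOR)

    path = getattr(worm, "skeleton_path", None)
    if path is not None and len(getattr(path, "points", [])):
        p = np.rint(np.asarray(path.points)).astype(int)
        paint(p[:, 0], p[:, 1], SKELETON_COLOR)
    else:
        warnings.warn("worm has no skeleton; overlay shows contour only",
                      stacklevel=2)
    return rgb
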