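"""Image/tabular I/O, pattern geometry, masks and results serialization.

Physical units are micrometres, seconds and pascals everywhere inside the
package; conversions happen only at the I/O boundary.  See
:mod:`bbbq.angles` for the coordinate and angle conventions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImageStack",
    "PatternGeometry",
    "RoiMask",
    "load_stack",
    "save_stack",
    "pattern_mask",
    "write_results",
    "read_results",
    "load_config",
    "save_config",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: Default microscope calibration, micrometres per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.645


@dataclass
class ImageStack:
    """A grayscale image stack with physical calibration.

    Parameters
    ----------
    pixels
        Array of shape (frames, rows, cols); single frames are stored with a
        leading axis of length 1.  Stored as float64.
    pixel_size
        Micrometres per pixel, > 0.
    frame_interval
        Seconds between frames; 0 for a single frame.
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = 0.0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = px[None]
        if px.ndim != 3:
            raise ValueError(f"pixels must be 2D or 3D, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval < 0:
            raise ValueError("frame_interval must be >= 0")
        self.pixels = px

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def frame(self, i: int = 0) -> np.ndarray:
        return self.pixels[i]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class PatternGeometry:
    """Ring or line micropattern defining the reference direction field.

    ``center`` is (x, y) in micrometres: the ring centre, or a point on the
    line axis.  ``axis_angle`` follows the screen-CCW convention and is
    normalized to [0, 180).
    """

    kind: Literal["ring", "line"]
    center: tuple[float, float]
    diameter: float = 0.0
    band_width: float = 0.0
    axis_angle: float = 0.0

    def __post_init__(self):
        if self.kind not in ("ring", "line"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.band_width <= 0:
            raise ValueError("band_width must be > 0")
        if self.kind == "ring":
            if self.diameter <= 0:
                raise ValueError("ring diameter must be > 0")
            if self.band_width > self.diameter / 2:
                raise ValueError("band_width exceeds ring radius")
        self.axis_angle = float(np.mod(self.axis_angle, 180.0))

    @property
    def outer_radius(self) -> float:
        return self.diameter / 2.0

    @property
    def inner_radius(self) -> float:
        return self.diameter / 2.0 - self.band_width


@dataclass
class RoiMask:
    """Boolean mask aligned to an image frame."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2D")
        if not m.any():
            raise ValueError("mask is empty")
        self.mask = m

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def load_stack(path, pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
               frame_interval: float = 0.0) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Integer pixels (8/16-bit) are promoted to float; frame order is as
    stored in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    try:
        px = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several types on junk input
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc
    px = np.asarray(px)
    if px.ndim not in (2, 3):
        raise ValueError(f"expected grayscale 2D/3D TIFF, got shape {px.shape}")
    return ImageStack(px.astype(float), pixel_size=pixel_size,
                      frame_interval=frame_interval)


def save_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as a multi-page float32 TIFF."""
    tifffile.imwrite(Path(path), stack.pixels.astype(np.float32))


def pattern_mask(geometry: PatternGeometry, shape: tuple[int, int],
                 pixel_size: float) -> RoiMask:
    """Rasterize a pattern geometry into a boolean ROI on an image frame.

    Ring: annulus with outer diameter ``geometry.diameter`` and radial
    thickness ``geometry.band_width``.  Line: band of width ``band_width``
    around the axis through ``center`` at ``axis_angle``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    x = cols * pixel_size
    y = rows * pixel_size
    cx, cy = geometry.center
    if geometry.kind == "ring":
        if cx - geometry.outer_radius < -pixel_size or cy - geometry.outer_radius < -pixel_size \
                or cx + geometry.outer_radius > shape[1] * pixel_size + pixel_size \
                or cy + geometry.outer_radius > shape[0] * pixel_size + pixel_size:
            raise ValueError("ring geometry extends outside the image")
        r = np.hypot(x - cx, y - cy)
        mask = (r <= geometry.outer_radius) & (r >= geometry.inner_radius)
        label = f"ring_d{geometry.diameter:g}"
    else:
        # signed distance from the axis line, in the screen-CCW frame
        theta = np.radians(geometry.axis_angle)
        # axis direction (d_col, d_row) = (cos t, -sin t); normal = (sin t, cos t)
        dist = np.abs((x - cx) * np.sin(theta) + (y - cy) * np.cos(theta))
        mask = dist <= geometry.band_width / 2.0
        label = f"line_a{geometry.axis_angle:g}"
    if not mask.any():
        raise ValueError("pattern mask is empty on this image")
    return RoiMask(mask, label=label)


def _records_to_frame(records: Sequence) -> pd.DataFrame:
    rows = []
    for r in records:
        if dataclasses.is_dataclass(r) and not isinstance(r, type):
            rows.append(dataclasses.asdict(r))
        elif isinstance(r, dict):
            rows.append(dict(r))
        else:
            raise TypeError(f"cannot serialize record of type {type(r)!r}")
    return pd.DataFrame(rows)


def write_results(records: Sequence, path, format: str | None = None,
                  columns: Sequence[str] | None = None) -> Path:
    """Write homogeneous records (dicts or dataclasses) to CSV or JSON.

    The format is inferred from the suffix when not given.  CSV gets one
    record per row with a header; JSON is a list of objects.  Round-trips
    through :func:`read_results` losslessly for scalar fields.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported results format {fmt!r}")
    df = _records_to_frame(records)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        df.to_csv(path, index=False)
    else:
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1,
                                   default=float) + "\n")
    return path


def read_results(path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"unsupported results format {fmt!r}")


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
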