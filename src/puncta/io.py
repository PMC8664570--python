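"""Image stacks, maximum projection, and polygonal ROI handling.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col) = (y, x)``; polygon vertices
  live in the same frame and are given in pixel-center coordinates.
* Normalized stacks have axes ``(z, channel, y, x)``.
* The pixel size (``μm/pixel``) is supplied by the caller/config; TIFF tags
  are not trusted for physical calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from skimage.measure import grid_points_in_poly

__all__ = [
    "ImageScene",
    "ROIMask",
    "read_stack",
    "write_stack",
    "max_project",
    "rasterize_roi",
    "roi_area_um2",
    "read_scene",
    "write_scene",
    "read_rois",
    "write_rois",
]


@dataclass
class ImageScene:
    """A two-dimensional multi-channel image plus physical calibration.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D intensity array.  All channels must share
        a shape; intensities must be finite and non-negative.
    pixel_size
        Physical pixel size in μm/pixel (square pixels assumed).
    provenance
        Free-form metadata (source path, projection flag, ...).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageScene requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels must share a shape, got {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2-D, got shape {shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            )
        return self.channels[name]


@dataclass
class ROIMask:
    """A named polygonal region of interest.

    ``polygon`` is an ``(N, 2)`` sequence of ``(y, x)`` vertices in
    pixel-center coordinates; the polygon must be simple (non
    self-intersecting) with at least three vertices.
    """

    label: str
    polygon: np.ndarray

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError(
                f"ROI {self.label!r}: polygon needs >= 3 (y, x) vertices"
            )
        if not np.all(np.isfinite(poly)):
            raise ValueError(f"ROI {self.label!r}: non-finite vertex")
        self.polygon = poly


def read_stack(path: str | Path) -> np.ndarray:
    """Read a TIFF and normalize axes to ``(z, channel, y, x)``.

    Axis tags from shaped/OME/ImageJ metadata are honored; sample axes
    (``S``) are treated as channels.  A stack of more than two dimensions
    without an interpretable axis tag is rejected rather than guessed.
    Dtype is preserved.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            axes = series.axes.upper()
            data = series.asarray()
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc
    if data.ndim == 2:
        return data[None, None]
    if data.ndim > 4:
        raise ValueError(f"{path}: more than 4 dimensions (axes {axes!r})")
    axes = axes.replace("S", "C")
    if not axes.endswith("YX") or not set(axes) <= set("ZCYX"):
        raise ValueError(
            f"{path}: ambiguous axis order {axes!r}; expected a combination "
            "of 'ZCYX' axis tags (write the file with e.g. "
            "metadata={'axes': 'ZCYX'})"
        )
    for ax in "CZ":
        if ax not in axes:
            data = data[None]
            axes = ax + axes
    perm = [axes.index(ax) for ax in "ZCYX"]
    return np.transpose(data, perm)


def write_stack(
    path: str | Path,
    stack: np.ndarray,
    axes: str = "ZCYX",
    extra_metadata: dict | None = None,
) -> None:
    """Write an array as TIFF with an explicit axes tag."""
    stack = np.asarray(stack)
    if stack.ndim != len(axes):
        raise ValueError(f"array ndim {stack.ndim} does not match axes {axes!r}")
    metadata = {"axes": axes}
    if extra_metadata:
        metadata.update(extra_metadata)
    tifffile.imwrite(
        Path(path), stack, metadata=metadata, photometric="minisblack"
    )


def max_project(
    stack: np.ndarray | ImageScene,
    channel_names: Sequence[str] | None = None,
    pixel_size: float = 1.0,
    provenance: dict | None = None,
) -> ImageScene:
    """Maximum-intensity projection of a ``(z, c, y, x)`` stack.

    Passing an :class:`ImageScene` (already 2-D) returns it unchanged, which
    makes projection idempotent.
    """
    if isinstance(stack, ImageScene):
        return stack
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise ValueError("expected a normalized (z, channel, y, x) stack")
    proj = stack.max(axis=0)
    n_chan = proj.shape[0]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_chan)]
    if len(channel_names) != n_chan:
        raise ValueError(
            f"{len(channel_names)} channel names for {n_chan} channels"
        )
    prov = dict(provenance or {})
    prov["projection"] = "max"
    channels = {name: proj[i] for i, name in enumerate(channel_names)}
    return ImageScene(channels=channels, pixel_size=pixel_size, provenance=prov)


def rasterize_roi(roi: ROIMask, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the ROI polygon.

    Inclusion follows the even-odd rule evaluated at integer pixel centers.
    The polygon must lie within the image bounds (vertices may touch the
    outer pixel edges at ``-0.5`` / ``dim - 0.5``).
    """
    h, w = shape
    poly = roi.polygon
    eps = 1e-9
    if (
        poly[:, 0].min() < -0.5 - eps
        or poly[:, 1].min() < -0.5 - eps
        or poly[:, 0].max() > h - 0.5 + eps
        or poly[:, 1].max() > w - 0.5 + eps
    ):
        raise ValueError(f"ROI {roi.label!r}: polygon outside image bounds")
    mask = grid_points_in_poly((h, w), poly)
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r}: zero-area cell")
    return mask


def roi_area_um2(roi: ROIMask, shape: tuple[int, int], pixel_size: float) -> float:
    """ROI area in μm², from the rasterized pixel count."""
    return float(rasterize_roi(roi, shape).sum()) * pixel_size**2


def write_scene(scene: ImageScene, path: str | Path) -> None:
    """Write a scene as a single multi-channel TIFF (axes ``CYX``)."""
    stack = np.stack([scene.channels[name] for name in scene.channel_names])
    write_stack(
        path,
        stack,
        axes="CYX",
        extra_metadata={
            "channel_names": scene.channel_names,
            "pixel_size_um": scene.pixel_size,
        },
    )


def read_scene(path: str | Path, pixel_size: float | None = None) -> ImageScene:
    """Read a scene TIFF written by :func:`write_scene` (or any tagged TIFF).

    ``pixel_size`` overrides any calibration stored in the file; when neither
    is available the pixel size defaults to 1 μm.
    """
    path = Path(path)
    stack = read_stack(path)
    names = None
    stored_px = None
    with tifffile.TiffFile(path) as tf:
        meta = tf.shaped_metadata
        if meta:
            names = meta[0].get("channel_names")
            stored_px = meta[0].get("pixel_size_um")
    scene = max_project(
        stack,
        channel_names=names,
        pixel_size=pixel_size or stored_px or 1.0,
        provenance={"source": str(path)},
    )
    return scene


def write_rois(rois: Sequence[ROIMask], path: str | Path) -> None:
    """Write ROIs as a JSON list of ``{"label", "vertices"}`` records."""
    records = [
        {"label": roi.label, "vertices": np.asarray(roi.polygon).tolist()}
        for roi in rois
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_rois(path: str | Path) -> list[ROIMask]:
    records = json.loads(Path(path).read_text())
    return [
        ROIMask(label=str(rec["label"]), polygon=np.asarray(rec["vertices"], float))
        for rec in records
    ]
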