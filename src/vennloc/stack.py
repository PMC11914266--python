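"""Multichannel image container and TIFF I/O.

A :class:`ChannelStack` holds one registered grayscale plane per named channel,
an optional region-of-interest (ROI) mask, and the physical pixel size.  Stacks
round-trip through multi-page TIFF files (one page per channel, channel name
and pixel size recorded in the page description as JSON) so simulated cells can
be analyzed through exactly the same file-based path as real micrographs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import ParameterError, StackIOError

__all__ = ["ChannelStack", "load_stack", "write_stack", "load_roi"]


@dataclass
class ChannelStack:
    """Registered grayscale planes, one per named channel.

    Parameters
    ----------
    channels
        Ordered mapping of channel name to 2D float/integer plane.  All planes
        must share one shape.
    roi
        Boolean mask of the same shape, or None for the whole frame.
    pixel_size
        Physical pixel size in nm/pixel, or None if unknown.
    """

    channels: dict[str, np.ndarray]
    roi: np.ndarray | None = None
    pixel_size: float | None = None
    cell_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ParameterError("channels: at least one channel plane is required")
        names = list(self.channels)
        if len(set(names)) != len(names):
            raise ParameterError("channels: channel names must be unique")
        shapes = {name: np.asarray(plane).shape for name, plane in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise ParameterError("channels: every plane must be 2D")
        for name, s in shapes.items():
            if s != first:
                raise ParameterError(
                    f"channels: plane {name!r} has shape {s}, expected {first}"
                )
        self.channels = {n: np.asarray(p) for n, p in self.channels.items()}
        if self.roi is not None:
            self.roi = np.asarray(self.roi).astype(bool)
            if self.roi.shape != first:
                raise ParameterError(
                    f"roi: shape {self.roi.shape} does not match planes {first}"
                )
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ParameterError("pixel_size: must be > 0 nm/pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def roi_mask(self) -> np.ndarray:
        """The effective ROI: the stored mask, or an all-True frame."""
        if self.roi is None:
            return np.ones(self.shape, dtype=bool)
        return self.roi


def write_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF, one page per channel.

    Each page's description is a JSON object with the channel name and, when
    known, the pixel size in nm so :func:`load_stack` can restore both.
    """
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, plane in stack.channels.items():
            desc = {"channel": name}
            if stack.pixel_size is not None:
                desc["pixel_size_nm"] = stack.pixel_size
            tif.write(
                np.asarray(plane, dtype=np.float32),
                description=json.dumps(desc),
                contiguous=False,
            )


def load_roi(roi_path: str | Path, expected_shape: tuple[int, int]) -> np.ndarray:
    """Load an ROI mask (TIFF/PNG, nonzero = inside) and check its shape."""
    roi_path = Path(roi_path)
    if not roi_path.exists():
        raise StackIOError(f"ROI file not found: {roi_path}")
    if roi_path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(roi_path)
    else:
        from imageio.v3 import imread

        arr = imread(roi_path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) to a single plane
        arr = arr.max(axis=-1)
    if arr.shape != expected_shape:
        raise StackIOError(
            f"ROI {roi_path} has shape {arr.shape}, expected {expected_shape}"
        )
    return arr != 0


def load_stack(
    path: str | Path,
    channel_names: Sequence[str],
    roi_path: str | Path | None = None,
) -> ChannelStack:
    """Load a multi-page TIFF into a named :class:`ChannelStack`.

    Pages are mapped to ``channel_names`` in order; the file must contain at
    least ``len(channel_names)`` planes of identical shape.  Pixel size is
    restored from the page description when present, else left unknown.
    """
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        planes = [page.asarray() for page in tif.pages]
        descriptions = [page.description for page in tif.pages]
    if len(planes) == 1 and planes[0].ndim == 3:
        # single-page multichannel image: split leading axis into planes
        descriptions = [descriptions[0]] * planes[0].shape[0]
        planes = list(planes[0])
    if len(planes) < len(channel_names):
        raise StackIOError(
            f"{path}: expected >= {len(channel_names)} planes for channels "
            f"{list(channel_names)}, found {len(planes)}"
        )
    planes = planes[: len(channel_names)]
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise StackIOError(f"{path}: planes have mismatched shapes {sorted(shapes)}")

    pixel_size = None
    for desc in descriptions:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            continue
        if isinstance(meta, dict) and "pixel_size_nm" in meta:
            pixel_size = float(meta["pixel_size_nm"])
            break

    roi = load_roi(roi_path, planes[0].shape) if roi_path is not None else None
    channels = dict(zip(channel_names, planes))
    return ChannelStack(channels=channels, roi=roi, pixel_size=pixel_size)
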