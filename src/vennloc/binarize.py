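"""Channel binarization within a region of interest.

Converts each grayscale channel to a boolean mask by thresholding; the
threshold is always computed from pixels *inside* the ROI only, and pixels
outside the ROI are always False.  Three methods are exposed:

``otsu``
    Otsu's between-class-variance threshold (the reproducible default when no
    threshold is dictated by the acquisition).
``fixed``
    A user-supplied absolute intensity threshold per channel.
``quantile``
    Threshold at a given intensity quantile of the ROI pixels per channel,
    i.e. keep approximately the brightest (1 - q) fraction.

In every case the mask is ``plane > threshold``, and the threshold actually
used is recorded on the mask for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateThresholdError, ParameterError
from .stack import ChannelStack

__all__ = ["BinaryMask", "binarize"]

_METHODS = ("otsu", "fixed", "quantile")


@dataclass
class BinaryMask:
    """One channel's boolean mask plus the provenance of its threshold."""

    mask: np.ndarray
    channel: str
    threshold_used: float
    method: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ParameterError("mask: must be 2D")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def _channel_param(params: Mapping | float | None, channel: str, method: str) -> float:
    if params is None:
        raise ParameterError(f"params: method {method!r} requires a per-channel value")
    if isinstance(params, Mapping):
        if channel not in params:
            raise ParameterError(f"params: no {method} value for channel {channel!r}")
        return float(params[channel])
    return float(params)


def binarize(
    stack: ChannelStack,
    method: str = "otsu",
    params: Mapping[str, float] | float | None = None,
) -> list[BinaryMask]:
    """Threshold every channel of ``stack`` into a :class:`BinaryMask`.

    Parameters
    ----------
    stack
        The multichannel image; its ROI (or the whole frame) delimits both
        the threshold computation and the resulting mask.
    method
        ``"otsu"``, ``"fixed"`` or ``"quantile"``.
    params
        For ``fixed``: absolute threshold, scalar or per-channel mapping.
        For ``quantile``: quantile level in [0, 1], scalar or mapping.
        Ignored for ``otsu``.

    Returns
    -------
    list of BinaryMask, in the stack's channel order.
    """
    if method not in _METHODS:
        raise ParameterError(f"method: {method!r} not one of {_METHODS}")
    roi = stack.roi_mask()
    if not roi.any():
        raise ParameterError("roi: the region of interest contains no pixels")

    masks = []
    for channel, plane in stack.channels.items():
        values = np.asarray(plane, dtype=np.float64)[roi]
        if method == "otsu":
            if np.ptp(values) == 0:
                raise DegenerateThresholdError(
                    f"channel {channel!r}: constant intensity inside ROI; Otsu is "
                    "undefined — use method='fixed' with an explicit threshold"
                )
            threshold = float(threshold_otsu(values))
            label = "otsu"
        elif method == "fixed":
            threshold = _channel_param(params, channel, method)
            label = "fixed"
        else:
            q = _channel_param(params, channel, method)
            if not 0.0 <= q <= 1.0:
                raise ParameterError(f"params[{channel}]: quantile {q} outside [0, 1]")
            threshold = float(np.quantile(values, q))
            label = f"quantile:{q:g}"
        mask = (np.asarray(plane, dtype=np.float64) > threshold) & roi
        masks.append(
            BinaryMask(mask=mask, channel=channel, threshold_used=threshold, method=label)
        )
    return masks
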