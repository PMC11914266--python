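"""Venn-area partition and Colocalization Factors.

The core statistic of the package.  Given k binary channel masks and an ROI,
the ROI pixels are partitioned into the 2^k - 1 *exclusive* Venn regions (one
per non-empty membership pattern); areas are exact integer pixel counts, so
the partition conserves both the union area and every channel's marginal area
exactly.

Under the random-placement null — every channel's pixels independently and
uniformly located — the expected fraction of the ROI occupied by a region
"all of ``include``, none of ``exclude``" is

    prod_{i in include} p_i  *  prod_{j in exclude} (1 - p_j)

where p_i is channel i's area fraction.  The **Colocalization Factor** (CF)
of a region is its observed area fraction divided by that expectation: CF = 1
means no association, CF > 1 enrichment.  Two expectation conventions are
supported: ``exclusion_aware`` (above, the default — the exact independence
null for an exclusive region) and ``paper_literal`` (product over included
channels only, i.e. the excluded channels' (1 - p) factors are dropped); they
coincide whenever ``exclude`` is empty, in particular for the all-channel
overlap region.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binarize import BinaryMask
from .errors import ParameterError, RegionError

__all__ = [
    "RegionSpec",
    "VennPartition",
    "CFRecord",
    "partition_areas",
    "region_area",
    "expected_fraction",
    "colocalization_factor",
    "venn_summary",
    "default_regions",
]

CONVENTIONS = ("exclusion_aware", "paper_literal")


@dataclass(frozen=True)
class RegionSpec:
    """A Venn region: pixels in every ``include`` channel and no ``exclude`` one.

    Channels named in neither set are unconstrained, so e.g.
    ``RegionSpec({"A"})`` is channel A's whole mask while
    ``RegionSpec({"A", "B"}, {"C"})`` is "A and B but not C".
    """

    include: frozenset[str]
    exclude: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "include", frozenset(self.include))
        object.__setattr__(self, "exclude", frozenset(self.exclude))
        if not self.include:
            raise RegionError("include: must name at least one channel")
        if self.include & self.exclude:
            raise RegionError(
                f"include/exclude overlap: {sorted(self.include & self.exclude)}"
            )

    def validate_channels(self, channels) -> None:
        unknown = (self.include | self.exclude) - set(channels)
        if unknown:
            raise RegionError(
                f"unknown channel(s) {sorted(unknown)}; available: {list(channels)}"
            )

    @property
    def label(self) -> str:
        inc = "&".join(sorted(self.include))
        if not self.exclude:
            return inc
        return inc + "~" + "~".join(sorted(self.exclude))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class VennPartition:
    """Exact pixel-count partition of the ROI by channel membership.

    ``exclusive_region_areas`` maps each non-empty membership pattern (a
    frozenset of channel names) to the number of ROI pixels with exactly that
    membership; ``channel_fractions[i]`` is mask_i's area over the ROI area.
    """

    channels: tuple[str, ...]
    roi_area: int
    exclusive_region_areas: dict[frozenset[str], int]
    channel_fractions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.roi_area <= 0:
            raise ParameterError("roi_area: must be positive")
        self.channel_fractions = {
            c: self.channel_area(c) / self.roi_area for c in self.channels
        }

    def channel_area(self, channel: str) -> int:
        """Channel's total mask area: sum of exclusive patterns containing it."""
        if channel not in self.channels:
            raise RegionError(f"unknown channel {channel!r}")
        return sum(
            area
            for pattern, area in self.exclusive_region_areas.items()
            if channel in pattern
        )

    @property
    def union_area(self) -> int:
        return sum(self.exclusive_region_areas.values())


def partition_areas(masks: list[BinaryMask], roi: np.ndarray | None = None) -> VennPartition:
    """Exact Venn partition of >= 2 binary masks within an ROI.

    Each ROI pixel is assigned a membership bit-code over the channels; areas
    are integer counts of each non-zero code.  Raises on shape mismatch,
    naming the offending channel.
    """
    if len(masks) < 2:
        raise ParameterError("masks: need at least 2 channels to partition")
    names = [m.channel for m in masks]
    if len(set(names)) != len(names):
        raise ParameterError(f"masks: duplicate channel names in {names}")
    shape = masks[0].mask.shape
    for m in masks[1:]:
        if m.mask.shape != shape:
            raise ParameterError(
                f"channel {m.channel!r}: mask shape {m.mask.shape} != {shape}"
            )
    if roi is None:
        roi = np.ones(shape, dtype=bool)
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != shape:
            raise ParameterError(f"roi: shape {roi.shape} != masks {shape}")

    codes = np.zeros(shape, dtype=np.int64)
    for bit, m in enumerate(masks):
        codes |= (m.mask & roi).astype(np.int64) << bit
    counts = np.bincount(codes[roi].ravel(), minlength=2 ** len(masks))

    areas: dict[frozenset[str], int] = {}
    for code in range(1, 2 ** len(masks)):
        pattern = frozenset(names[b] for b in range(len(masks)) if code >> b & 1)
        areas[pattern] = int(counts[code])
    return VennPartition(
        channels=tuple(names),
        roi_area=int(roi.sum()),
        exclusive_region_areas=areas,
    )


def region_area(partition: VennPartition, region: RegionSpec) -> int:
    """Pixel area of a region: sum of the exclusive patterns it covers.

    A pattern P contributes iff ``include`` is a subset of P and P is disjoint
    from ``exclude``; with ``include={i}, exclude={}`` this recovers channel
    i's full mask area.
    """
    region.validate_channels(partition.channels)
    return sum(
        area
        for pattern, area in partition.exclusive_region_areas.items()
        if region.include <= pattern and not (region.exclude & pattern)
    )


def expected_fraction(
    p: dict[str, float], region: RegionSpec, convention: str = "exclusion_aware"
) -> float:
    """Expected ROI fraction of ``region`` under independent random placement.

    ``exclusion_aware``: prod p_i over included times prod (1 - p_j) over
    excluded channels.  ``paper_literal``: the included product only.  The two
    agree when ``exclude`` is empty.
    """
    if convention not in CONVENTIONS:
        raise ParameterError(f"convention: {convention!r} not one of {CONVENTIONS}")
    region.validate_channels(p)
    for c, pi in p.items():
        if not 0.0 <= pi <= 1.0:
            raise ParameterError(f"p[{c}]: fraction {pi} outside [0, 1]")
    value = math.prod(p[c] for c in region.include)
    if convention == "exclusion_aware":
        value *= math.prod(1.0 - p[c] for c in region.exclude)
    return value


@dataclass
class CFRecord:
    """One region's Colocalization Factor in one cell.

    ``cf`` is ``actual_fraction / expected_fraction``; when both are zero the
    record is flagged ``undefined`` and ``cf`` is NaN (never an exception, and
    never silently dropped — cohort statistics count the exclusions).
    """

    region: RegionSpec
    actual_fraction: float
    expected_fraction: float
    cf: float
    convention: str
    cell_id: str = ""

    @property
    def undefined(self) -> bool:
        return self.expected_fraction == 0.0


def colocalization_factor(
    partition: VennPartition,
    region: RegionSpec,
    convention: str = "exclusion_aware",
    cell_id: str = "",
) -> CFRecord:
    """CF of one region: observed area fraction over its null expectation."""
    actual = region_area(partition, region) / partition.roi_area
    expected = expected_fraction(partition.channel_fractions, region, convention)
    if expected == 0.0:
        # an included channel has p_i = 0, hence the region itself is empty
        assert actual == 0.0, "empty expectation with non-empty region is impossible"
        cf = math.nan
    else:
        cf = actual / expected
    return CFRecord(
        region=region,
        actual_fraction=actual,
        expected_fraction=expected,
        cf=cf,
        convention=convention,
        cell_id=cell_id,
    )


def venn_summary(partition: VennPartition) -> pd.DataFrame:
    """All 2^k - 1 exclusive regions as percentages of the ROI.

    One row per membership pattern, ordered by (pattern size, name); the
    ``percent`` column sums to the union's percentage of the ROI.
    """
    rows = []
    for pattern in sorted(
        partition.exclusive_region_areas, key=lambda s: (len(s), tuple(sorted(s)))
    ):
        area = partition.exclusive_region_areas[pattern]
        only = "&".join(sorted(pattern))
        without = sorted(set(partition.channels) - pattern)
        rows.append(
            {
                "pattern": only + ("~" + "~".join(without) if without else ""),
                "channels": "&".join(sorted(pattern)),
                "area_px": area,
                "percent": 100.0 * area / partition.roi_area,
            }
        )
    return pd.DataFrame(rows)


def default_regions(channels) -> list[RegionSpec]:
    """The all-channel overlap plus every exclusive-pair region.

    For three channels this is the region set of the scaffold analysis: the
    triple overlap and the three pairwise-without-the-third regions.
    """
    channels = list(channels)
    regions = [RegionSpec(frozenset(channels))]
    for pair in itertools.combinations(sorted(channels), 2):
        rest = frozenset(channels) - set(pair)
        regions.append(RegionSpec(frozenset(pair), rest))
    return regions
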