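import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vennloc import BinaryMask, RegionSpec

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_mask(array, channel, threshold=0.5, method="fixed"):
    """Wrap a boolean array as a BinaryMask for direct Venn-level tests."""
    return BinaryMask(
        mask=np.asarray(array, dtype=bool),
        channel=channel,
        threshold_used=threshold,
        method=method,
    )


def brute_force_region_area(masks, roi, include, exclude):
    """Pixel-by-pixel loop oracle for region areas, independent of the bincount path."""
    by_name = {m.channel: m.mask for m in masks}
    rows, cols = roi.shape
    count = 0
    for r in range(rows):
        for c in range(cols):
            if not roi[r, c]:
                continue
            if all(by_name[ch][r, c] for ch in include) and not any(
                by_name[ch][r, c] for ch in exclude
            ):
                count += 1
    return count


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_mask_triple(rng):
    """Three random 8x8 masks plus a random ROI, for oracle comparisons."""
    masks = [make_mask(rng.random((8, 8)) < 0.4, ch) for ch in "ABC"]
    roi = rng.random((8, 8)) < 0.9
    return masks, roi


@pytest.fixture(scope="session")
def triple_regions():
    """Triple region and the three exclusive-pair regions over channels A, B, C."""
    return [
        RegionSpec(frozenset("ABC")),
        RegionSpec(frozenset("AB"), frozenset("C")),
        RegionSpec(frozenset("AC"), frozenset("B")),
        RegionSpec(frozenset("BC"), frozenset("A")),
    ]
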