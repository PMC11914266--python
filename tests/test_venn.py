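"""Venn partition, expected fractions and Colocalization Factors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vennloc import (
    RegionError,
    RegionSpec,
    colocalization_factor,
    default_regions,
    expected_fraction,
    partition_areas,
    region_area,
    venn_summary,
)

from .conftest import brute_force_region_area, make_mask


def square_mask(shape, r0, c0, size, channel):
    arr = np.zeros(shape, dtype=bool)
    arr[r0 : r0 + size, c0 : c0 + size] = True
    return make_mask(arr, channel)


class TestPartition:
    def test_identical_masks_concentrate_in_triple_pattern(self):
        masks = [square_mask((10, 10), 2, 2, 4, ch) for ch in "ABC"]
        part = partition_areas(masks)
        nonzero = {p: a for p, a in part.exclusive_region_areas.items() if a}
        assert nonzero == {frozenset("ABC"): 16}

    def test_disjoint_masks_concentrate_in_singletons(self):
        masks = [
            square_mask((12, 12), 0, 0, 2, "A"),
            square_mask((12, 12), 5, 5, 3, "B"),
            square_mask((12, 12), 9, 9, 3, "C"),
        ]
        part = partition_areas(masks)
        nonzero = {p: a for p, a in part.exclusive_region_areas.items() if a}
        assert nonzero == {
            frozenset("A"): 4,
            frozenset("B"): 9,
            frozenset("C"): 9,
        }

    def test_matches_pixel_loop_oracle(self, random_mask_triple):
        masks, roi = random_mask_triple
        part = partition_areas(masks, roi)
        for pattern, area in part.exclusive_region_areas.items():
            include = set(pattern)
            exclude = {"A", "B", "C"} - include
            assert area == brute_force_region_area(masks, roi, include, exclude)

    def test_shape_mismatch_names_channel(self):
        masks = [
            make_mask(np.zeros((4, 4), bool), "A"),
            make_mask(np.zeros((5, 5), bool), "B"),
        ]
        with pytest.raises(Exception, match="'B'"):
            partition_areas(masks)

    @given(
        a=arrays(bool, (6, 7), elements=st.booleans()),
        b=arrays(bool, (6, 7), elements=st.booleans()),
        c=arrays(bool, (6, 7), elements=st.booleans()),
    )
    def test_conservation_invariants(self, a, b, c):
        """Exclusive areas sum to the union and reconstruct every marginal exactly."""
        masks = [make_mask(m, ch) for m, ch in [(a, "A"), (b, "B"), (c, "C")]]
        part = partition_areas(masks)
        union = int((a | b | c).sum())
        assert part.union_area == union
        for m in masks:
            assert part.channel_area(m.channel) == int(m.mask.sum())
            assert part.channel_fractions[m.channel] == pytest.approx(
                m.mask.mean(), abs=0
            )


class TestRegionArea:
    def test_single_channel_region_is_marginal_area(self, random_mask_triple):
        masks, roi = random_mask_triple
        part = partition_areas(masks, roi)
        for m in masks:
            got = region_area(part, RegionSpec(frozenset({m.channel})))
            assert got == int((m.mask & roi).sum())

    def test_identical_masks_exclusive_pair_empty(self):
        masks = [square_mask((10, 10), 1, 1, 5, ch) for ch in "ABC"]
        part = partition_areas(masks)
        assert region_area(part, RegionSpec(frozenset("ABC"))) == 25
        assert region_area(part, RegionSpec(frozenset("AB"), frozenset("C"))) == 0

    def test_matches_oracle_on_random_masks(self, random_mask_triple, triple_regions):
        masks, roi = random_mask_triple
        part = partition_areas(masks, roi)
        for region in triple_regions:
            assert region_area(part, region) == brute_force_region_area(
                masks, roi, region.include, region.exclude
            )

    def test_unknown_channel_rejected(self, random_mask_triple):
        masks, roi = random_mask_triple
        part = partition_areas(masks, roi)
        with pytest.raises(RegionError):
            region_area(part, RegionSpec(frozenset({"Z"})))


class TestExpectedFraction:
    p = {"A": 0.5, "B": 0.5, "C": 0.5}

    def test_triple_region_same_under_both_conventions(self):
        region = RegionSpec(frozenset("ABC"))
        assert expected_fraction(self.p, region, "exclusion_aware") == 0.125
        assert expected_fraction(self.p, region, "paper_literal") == 0.125

    def test_exclusive_pair_conventions_differ(self):
        region = RegionSpec(frozenset("AB"), frozenset("C"))
        assert expected_fraction(self.p, region, "exclusion_aware") == 0.125
        assert expected_fraction(self.p, region, "paper_literal") == 0.25

    def test_zero_included_fraction_gives_zero(self):
        region = RegionSpec(frozenset("AB"))
        assert expected_fraction({"A": 0.0, "B": 0.7, "C": 0.1}, region) == 0.0

    def test_invalid_region_spec(self):
        with pytest.raises(RegionError):
            RegionSpec(frozenset(), frozenset("A"))
        with pytest.raises(RegionError):
            RegionSpec(frozenset("A"), frozenset("A"))


class TestColocalizationFactor:
    def test_identical_masks_closed_form(self):
        """k identical masks of fraction p give all-overlap CF = p^(1-k)."""
        shape = (10, 10)
        masks = [square_mask(shape, 1, 1, 5, ch) for ch in "ABC"]  # p = 0.25
        part = partition_areas(masks)
        rec = colocalization_factor(part, RegionSpec(frozenset("ABC")))
        assert rec.actual_fraction == 0.25
        assert rec.expected_fraction == pytest.approx(0.25**3, rel=1e-15)
        assert rec.cf == pytest.approx(0.25 ** (1 - 3), rel=1e-12)

    def test_disjoint_masks_zero_cf(self):
        masks = [
            square_mask((12, 12), 0, 0, 3, "A"),
            square_mask((12, 12), 4, 4, 3, "B"),
            square_mask((12, 12), 8, 8, 3, "C"),
        ]
        part = partition_areas(masks)
        rec = colocalization_factor(part, RegionSpec(frozenset("ABC")))
        assert rec.actual_fraction == 0.0
        assert rec.cf == 0.0 and not rec.undefined

    def test_empty_channel_flags_undefined_not_raises(self):
        masks = [
            make_mask(np.zeros((8, 8), bool), "A"),
            square_mask((8, 8), 0, 0, 4, "B"),
            square_mask((8, 8), 2, 2, 4, "C"),
        ]
        part = partition_areas(masks)
        rec = colocalization_factor(part, RegionSpec(frozenset("AB")))
        assert rec.undefined and math.isnan(rec.cf)

    def test_translation_and_relabel_symmetry(self, rng, triple_regions):
        """CF is invariant to a joint toroidal shift and equivariant to relabeling."""
        arrays_ = {ch: rng.random((16, 16)) < 0.3 for ch in "ABC"}
        part = partition_areas([make_mask(arrays_[ch], ch) for ch in "ABC"])
        shifted = {
            ch: np.roll(arr, shift=(5, -3), axis=(0, 1)) for ch, arr in arrays_.items()
        }
        part_shift = partition_areas([make_mask(shifted[ch], ch) for ch in "ABC"])
        relabel = {"A": "B", "B": "C", "C": "A"}
        part_relab = partition_areas(
            [make_mask(arrays_[ch], relabel[ch]) for ch in "ABC"]
        )
        for region in triple_regions:
            rec = colocalization_factor(part, region)
            assert colocalization_factor(part_shift, region).cf == rec.cf
            mapped = RegionSpec(
                frozenset(relabel[c] for c in region.include),
                frozenset(relabel[c] for c in region.exclude),
            )
            assert colocalization_factor(part_relab, mapped).cf == rec.cf


class TestVennSummary:
    def test_identical_masks_single_row(self):
        masks = [square_mask((10, 10), 1, 1, 5, ch) for ch in "ABC"]  # 25% cover
        table = venn_summary(partition_areas(masks))
        nonzero = table[table.percent > 0]
        assert len(nonzero) == 1
        assert nonzero.iloc[0]["percent"] == 25.0

    def test_disjoint_masks_three_rows(self):
        masks = [
            square_mask((10, 10), 0, 0, 2, "A"),
            square_mask((10, 10), 3, 3, 3, "B"),
            square_mask((10, 10), 7, 7, 3, "C"),
        ]
        table = venn_summary(partition_areas(masks))
        nonzero = table[table.percent > 0]
        assert sorted(nonzero["percent"]) == [4.0, 9.0, 9.0]

    def test_rows_match_oracle_and_sum_to_union(self, random_mask_triple):
        masks, roi = random_mask_triple
        part = partition_areas(masks, roi)
        table = venn_summary(part)
        assert len(table) == 7
        assert table["area_px"].sum() == part.union_area
        assert table["percent"].sum() == pytest.approx(
            100.0 * part.union_area / part.roi_area
        )


def test_default_regions_triple_plus_pairs():
    regions = default_regions(["ACC1", "COP1", "KIF12"])
    labels = {r.label for r in regions}
    assert labels == {
        "ACC1&COP1&KIF12",
        "ACC1&COP1~KIF12",
        "ACC1&KIF12~COP1",
        "COP1&KIF12~ACC1",
    }
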