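"""Bone area/density, bone–implant contact, field placement, aggregation."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from periomorph import morphometry, synthdata, zonegeom
from periomorph.morphometry import (aggregate_disc, bone_area, bone_density,
                                    compute_bic, place_fields,
                                    section_morphometry)

from conftest import brute_bic, random_mask_triple


class TestBoneArea:
    def test_empty_bone_is_zero(self):
        assert bone_area(np.zeros((10, 10), bool), np.ones((10, 10), bool),
                         17.43) == 0.0

    def test_thousand_pixels_at_default_calibration(self):
        bone = np.zeros((40, 40), bool)
        bone.ravel()[:1000] = True
        assert bone_area(bone, np.ones((40, 40), bool), 17.43) == pytest.approx(
            0.01743)

    def test_bone_equal_region_gives_region_area(self):
        region = np.zeros((20, 20), bool)
        region[5:15, 5:15] = True
        assert bone_area(region, region, 100.0) == pytest.approx(
            region.sum() * 100.0 * 1e-6)


class TestBoneDensity:
    def test_full_region_is_100(self):
        region = np.ones((8, 8), bool)
        assert bone_density(region, region) == 100.0

    def test_empty_bone_is_0(self):
        assert bone_density(np.zeros((8, 8), bool), np.ones((8, 8), bool)) == 0.0

    def test_half_filled_region_is_50(self):
        region = np.ones((10, 10), bool)
        bone = np.zeros((10, 10), bool)
        bone[:5, :] = True
        assert bone_density(bone, region) == 50.0

    def test_empty_region_is_missing(self):
        assert math.isnan(bone_density(np.ones((5, 5), bool),
                                       np.zeros((5, 5), bool)))


class TestBIC:
    def _square(self):
        implant = np.zeros((30, 30), bool)
        implant[10:20, 10:20] = True
        return implant

    def test_full_coverage_is_100(self):
        implant = self._square()
        bone = ~implant
        assert compute_bic(implant, bone, np.ones_like(implant)) == 100.0

    def test_no_bone_is_0(self):
        implant = self._square()
        assert compute_bic(implant, np.zeros_like(implant),
                           np.ones_like(implant)) == 0.0

    def test_empty_surface_band_is_missing(self):
        implant = self._square()
        defect = np.zeros_like(implant)  # clip removes the whole band
        assert math.isnan(compute_bic(implant, np.zeros_like(implant), defect))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        implant, bone, defect = random_mask_triple(rng)
        got = compute_bic(implant, bone, defect)
        want = brute_bic(implant, bone, defect)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want)

    def test_monotone_under_added_bone(self):
        rng = np.random.default_rng(3)
        implant, bone, defect = random_mask_triple(rng)
        more = bone | (rng.random(bone.shape) < 0.2) & ~implant
        assert np.nan_to_num(compute_bic(implant, more, defect)) >= \
            np.nan_to_num(compute_bic(implant, bone, defect))

    def test_unclipped_variant_uses_full_perimeter(self):
        implant = self._square()
        defect = np.zeros_like(implant)
        defect[:, :15] = True  # clips half the band
        bone = ~implant
        clipped = compute_bic(implant, bone, defect)
        unclipped = compute_bic(implant, bone, defect, clip_to_defect=False)
        assert clipped == 100.0 and unclipped == 100.0
        bone_half = bone & defect
        assert compute_bic(implant, bone_half, defect) == 100.0
        assert compute_bic(implant, bone_half, defect, clip_to_defect=False) < 100.0


class TestSectionMorphometry:
    def test_zone_bf_sums_to_band_bf(self, small_section):
        masks, _ = small_section
        df = section_morphometry(masks.bone, masks.implant, masks.defect,
                                 masks.pixel_area_um2)
        zones = df[(df.metric == "BF") & df.region.str.startswith("zone-")]
        band = zonegeom.build_band(masks.implant, masks.defect,
                                   masks.pixel_area_um2)
        band_bf = bone_area(masks.bone, band, masks.pixel_area_um2)
        assert zones["value"].sum() == pytest.approx(band_bf, abs=1e-12)

    def test_whole_defect_density_excludes_implant(self, small_section):
        masks, _ = small_section
        df = section_morphometry(masks.bone, masks.implant, masks.defect,
                                 masks.pixel_area_um2)
        got = df[(df.region == "whole-defect") & (df.metric == "BD")].value.iloc[0]
        want = bone_density(masks.bone, masks.defect & ~masks.implant)
        assert got == pytest.approx(want)

    def test_matches_generator_ground_truth(self, small_section):
        masks, truth = small_section
        df = section_morphometry(masks.bone, masks.implant, masks.defect,
                                 masks.pixel_area_um2)
        bic = df[(df.metric == "BIC")].value.iloc[0]
        assert bic == pytest.approx(truth.true_bic_percent)
        zones = df[(df.metric == "BD") & df.region.str.startswith("zone-")]
        for rid, frac in truth.true_zone_bone_fraction.items():
            got = zones[zones.region == f"zone-{rid:02d}"].value.iloc[0]
            assert got == pytest.approx(100 * frac)


class TestPlaceFields:
    def test_thirteen_fields_on_standard_section(self, standard_geometry):
        boxes = place_fields(standard_geometry.implant,
                             standard_geometry.pixel_area_um2)
        assert len(boxes) == 13
        assert sum(b.side == "upper" for b in boxes) == 7
        assert sum(b.side == "lower" for b in boxes) == 6

    def test_fields_touch_the_implant_surface(self, standard_geometry):
        implant = standard_geometry.implant
        for b in place_fields(implant, standard_geometry.pixel_area_um2):
            if b.side == "upper":
                # implant surface at the field's implant-facing border
                assert implant[b.row1, b.col0:b.col1].any()
                assert not implant[b.row1 - 1, b.col0:b.col1].any()
            else:
                assert implant[b.row0 - 1, b.col0:b.col1].any()
                assert not implant[b.row0, b.col0:b.col1].any()

    def test_zero_requested_fields_gives_empty_list(self, standard_geometry):
        assert place_fields(standard_geometry.implant,
                            standard_geometry.pixel_area_um2,
                            n_upper=0, n_lower=0) == []

    def test_overwide_request_preserves_count_with_warning(self, caplog):
        implant = np.zeros((120, 120), bool)
        implant[50:60, 10:110] = True
        with caplog.at_level(logging.WARNING, logger="periomorph.morphometry"):
            boxes = place_fields(implant, 17.43 * 16, field_um=(725, 543),
                                 n_upper=7, n_lower=6)
        assert len(boxes) == 13
        assert any("overlap" in r.message for r in caplog.records)

    def test_edge_shorter_than_field_emits_single_clipped_box(self, caplog):
        implant = np.zeros((60, 60), bool)
        implant[28:32, 20:40] = True  # 20 px edge << field width
        with caplog.at_level(logging.WARNING, logger="periomorph.morphometry"):
            boxes = place_fields(implant, 17.43, n_upper=7, n_lower=6)
        assert len(boxes) == 2
        assert any("shorter" in r.message for r in caplog.records)


class TestAggregateDisc:
    def _records(self, values, region="whole-defect", metric="BD"):
        return pd.DataFrame({
            "cross_section": range(1, len(values) + 1),
            "region": region, "metric": metric, "value": values,
        })

    def test_identical_sections_mean_is_value(self):
        out = aggregate_disc(self._records([7.0, 7.0, 7.0]))
        assert out["value"].iloc[0] == 7.0
        assert out["n_sections"].iloc[0] == 3

    def test_mean_of_1_2_3_is_2(self):
        assert aggregate_disc(self._records([1.0, 2.0, 3.0]))["value"].iloc[0] == 2.0

    def test_missing_values_excluded_pairwise(self):
        out = aggregate_disc(self._records([4.0, float("nan"), 6.0]))
        assert out["value"].iloc[0] == 5.0
        assert out["n_sections"].iloc[0] == 2

    def test_two_sections_warns_low_count(self, caplog):
        with caplog.at_level(logging.WARNING, logger="periomorph.morphometry"):
            aggregate_disc(self._records([1.0, 2.0]))
        assert any("only 2" in r.message for r in caplog.records)

    def test_zero_records_raises(self):
        with pytest.raises(ValueError):
            aggregate_disc(self._records([]))
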