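"""Synthetic section growth, rendering, fluorescence, release, and study tables."""

import numpy as np
import pytest

from periomorph import synthdata, zonegeom
from periomorph.synthdata import (MaskSet, SectionSpec, StudyDesign,
                                  gen_fluorescence, gen_release_series,
                                  gen_study, grow_bone, planned_disc_count,
                                  render_stain, surviving_disc_count)
from periomorph.zonegeom import GeometryError


def layer_fraction(masks, layer):
    part = zonegeom.partition_zones(masks.implant, masks.defect,
                                    masks.pixel_area_um2)
    sel = part.layer_mask(layer)
    return (sel & masks.bone).sum() / sel.sum()


class TestSpecValidation:
    def test_defaults_are_valid(self):
        spec = SectionSpec()
        assert spec.pixel_edge_um == pytest.approx(4.1749, abs=1e-3)

    @pytest.mark.parametrize("kw", [
        {"pixel_area_um2": 0}, {"growth_steps": -1}, {"conduction_bias": 0.5},
        {"noise_level": 1.5}, {"implant_length_mm": -1},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SectionSpec(**kw)

    def test_implant_too_large_for_image_raises(self):
        spec = SectionSpec(image_width_px=100, image_height_px=100)
        with pytest.raises(GeometryError):
            synthdata.section_geometry(spec)

    def test_spec_yaml_roundtrip(self, tmp_path, small_spec):
        p = tmp_path / "spec.yaml"
        small_spec.to_yaml(p)
        assert SectionSpec.from_yaml(p) == small_spec


class TestGrowBone:
    def test_zero_steps_gives_empty_bone(self, small_spec):
        series = grow_bone(small_spec.scaled(growth_steps=0))
        assert len(series) == 1 and not series[0].bone.any()

    def test_growth_is_monotone_and_avoids_implant(self, small_spec):
        series = grow_bone(small_spec.scaled(growth_steps=12, seed=5))
        for prev, cur in zip(series, series[1:]):
            assert not (prev.bone & ~cur.bone).any()       # bone_t ⊆ bone_{t+1}
            assert not (cur.bone & cur.implant).any()
            assert not (cur.bone & ~cur.defect).any()      # confined to defect

    def test_bone_seeds_only_at_defect_walls(self, small_spec):
        series = grow_bone(small_spec.scaled(growth_steps=1, seed=5))
        first = series[1]
        seeds = synthdata._wall_seed(series[0])
        assert first.bone.any()
        assert not (first.bone & ~seeds).any()

    def test_unbiased_growth_is_isotropic_across_layers(self, small_spec):
        # many steps without conduction bias: the front reaches the implant
        # isotropically, so immediate and remote layers fill alike
        masks = grow_bone(small_spec.scaled(conduction_bias=1.0, growth_steps=90,
                                            seed=2), keep_series=False)[-1]
        f_imm = layer_fraction(masks, "immediate")
        f_rem = layer_fraction(masks, "remote")
        assert abs(f_imm - f_rem) <= 0.05

    def test_conduction_bias_enriches_immediate_layer(self, small_spec):
        masks = grow_bone(small_spec.scaled(conduction_bias=4.0, growth_steps=35,
                                            seed=2), keep_series=False)[-1]
        assert layer_fraction(masks, "immediate") > layer_fraction(masks, "remote")

    def test_seeded_growth_is_reproducible(self, small_spec):
        a = grow_bone(small_spec.scaled(seed=9), keep_series=False)[-1]
        b = grow_bone(small_spec.scaled(seed=9), keep_series=False)[-1]
        assert np.array_equal(a.bone, b.bone)

    def test_maskset_rejects_bone_on_implant(self, small_section):
        masks, _ = small_section
        bad = masks.bone | masks.implant
        with pytest.raises(ValueError):
            MaskSet(masks.implant, masks.defect, bad, masks.pixel_area_um2)


class TestRenderStain:
    def test_seeded_render_is_reproducible(self, small_section):
        masks, _ = small_section
        a = render_stain(masks, noise_level=0.2, seed=21)
        b = render_stain(masks, noise_level=0.2, seed=21)
        assert np.array_equal(a.data, b.data)

    def test_render_carries_calibration(self, small_section):
        masks, _ = small_section
        img = render_stain(masks)
        assert img.pixel_area_um2 == masks.pixel_area_um2
        assert img.shape == masks.bone.shape


class TestFluorescence:
    def test_zero_blobs_give_zero_truth(self):
        _, truth = gen_fluorescence(n_blobs=0, seed=1)
        assert truth.true_cd31_area_um2 == 0.0

    def test_nonoverlapping_blob_areas_sum(self):
        _, truth = gen_fluorescence(n_blobs=10, blob_area_um2=500.0, seed=4)
        assert truth.true_cd31_area_um2 == pytest.approx(5000.0, rel=0.05)

    def test_seeded_field_is_reproducible(self):
        a, _ = gen_fluorescence(seed=6)
        b, _ = gen_fluorescence(seed=6)
        assert np.array_equal(a.data, b.data)

    def test_blobs_concentrate_near_lower_border(self):
        img, _ = gen_fluorescence(n_blobs=12, blob_area_um2=1500.0, seed=3)
        red = img.data[..., 0] >= 0.5
        rows = np.nonzero(red)[0]
        assert rows.mean() > img.shape[0] / 2  # lower half of the field

    def test_oversized_blob_area_rejected(self):
        with pytest.raises(ValueError):
            gen_fluorescence(n_blobs=1, blob_area_um2=1e9)


class TestReleaseGeneration:
    def test_zero_total_gives_all_zero_intervals(self):
        s = gen_release_series(0.0, 0.3, 0.2)
        assert all(m == 0 for m in s.interval_ug)

    def test_delay_beyond_window_gives_zero_cumulative(self):
        s = gen_release_series(2.59, 0.3, 0.2, delay_days=30.0)
        assert s.cumulative_ug_per_cm2[-1] == 0.0

    def test_cumulative_matches_closed_form(self):
        s = gen_release_series(2.59, 0.3, 0.2, delay_days=0.0)
        expect = 2.59 * (0.3 + 0.7 * (1 - np.exp(-0.2 * 21)))
        assert s.cumulative_ug_per_cm2[-1] == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cumulative_nondecreasing_under_noise(self, seed):
        s = gen_release_series(2.0, 0.4, 0.3, noise_sd=0.5, seed=seed)
        assert (np.diff(s.cumulative_ug) >= 0).all()

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_release_series(-1.0, 0.3, 0.2)
        with pytest.raises(ValueError):
            gen_release_series(1.0, 1.3, 0.2)


class TestStudyGeneration:
    def test_disc_accounting(self):
        assert planned_disc_count(14, 12) == 168
        assert surviving_disc_count(14, 12, 1) == 167
        assert planned_disc_count(10, 12) * 2 == 240  # both healing intervals

    def test_full_design_produces_240_discs(self, small_spec):
        spec = small_spec.scaled(growth_steps=0)  # counting only
        records, discs = gen_study(StudyDesign(), spec, seed=1, n_sections=(3, 4))
        assert len(discs) == 240
        assert not discs["lost"].any()
        assert discs["n_sections"].between(3, 4).all()
        assert records.groupby("disc")["cross_section"].nunique().between(3, 4).all()

    def test_lost_disc_flags_block_incomplete(self, small_spec):
        spec = small_spec.scaled(growth_steps=0)
        design = StudyDesign(lost_discs=((3, "PLL-HEP20/VEGF", 13),))
        records, discs = gen_study(design, spec, seed=1)
        assert (~discs["lost"]).sum() == 239
        block = discs[(discs.animal == 3) & (discs.timepoint_weeks == 13)]
        assert block["block_incomplete"].all()
        other = discs[(discs.animal == 3) & (discs.timepoint_weeks == 4)]
        assert not other["block_incomplete"].any()
        assert "A03-W13-PLL-HEP20/VEGF" not in set(records["disc"])

    def test_planted_effect_shifts_immediate_layer(self, small_spec):
        design = StudyDesign(conditions=("Ti", "A"), n_animals=4, timepoints=(13,),
                             planted_effects={("A", 13, "immediate"): 0.30})
        # fewer growth steps leave headroom in the immediate layer for the shift
        records, _ = gen_study(design, small_spec.scaled(growth_steps=18),
                               seed=8, n_sections=(1, 1))
        sel = records[(records.metric == "BD")
                      & (records.region == "layer-immediate")]
        means = sel.groupby("condition")["value"].mean()
        assert means["A"] - means["Ti"] > 20  # +0.30 fraction ≈ +30 BD points

    def test_design_validation(self):
        with pytest.raises(ValueError):
            StudyDesign(conditions=())
        with pytest.raises(ValueError):
            StudyDesign(conditions=("a", "a"))
        with pytest.raises(ValueError):
            StudyDesign(n_animals=1)
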