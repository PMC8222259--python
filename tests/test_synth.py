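import dataclasses

import numpy as np
import pytest

from aortomorph.aortometry import NomogramModel
from aortomorph.stats import mann_whitney
from aortomorph.synth import (
    CohortSpec,
    FieldSpec,
    InfeasibleSpecError,
    RingSpec,
    generate_cohort,
    generate_ring_image,
    generate_stain_field,
)


class TestFieldSpecValidation:
    def test_fraction_sum_over_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            FieldSpec(target_fractions={"cytoplasm": 0.7, "collagen": 0.5})

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            FieldSpec(lamella_thickness=-1.0)

    def test_bad_fragmentation_prob(self):
        with pytest.raises(ValueError):
            FieldSpec(fragmentation_prob=1.5)

    def test_unknown_component(self):
        with pytest.raises(ValueError, match="unknown"):
            FieldSpec(target_fractions={"keratin": 0.2})


class TestGenerateStainField:
    def test_noiseless_preserves_lamella_count(self, movat_spec):
        _, truth = generate_stain_field(movat_spec)
        assert truth.n_lamellae == 8

    def test_realized_fractions_near_targets(self, movat_spec):
        _, truth = generate_stain_field(movat_spec)
        targets = {"elastin": 0.25, "cytoplasm": 0.30, "collagen": 0.30, "gag": 0.15}
        for comp, target in targets.items():
            assert truth.realized_fractions[comp] == pytest.approx(
                target, abs=0.02
            ), comp

    def test_same_seed_bit_identical(self, movat_spec):
        spec = dataclasses.replace(movat_spec, color_jitter_sd=6.0,
                                   nuclei_density=400.0)
        img1, t1 = generate_stain_field(spec)
        img2, t2 = generate_stain_field(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert t1 == t2

    def test_different_seed_differs(self, movat_spec):
        spec = dataclasses.replace(movat_spec, color_jitter_sd=6.0)
        img1, _ = generate_stain_field(spec)
        img2, _ = generate_stain_field(dataclasses.replace(spec, seed=99))
        assert not np.array_equal(img1.pixels, img2.pixels)

    def test_truth_is_pre_noise(self, movat_spec):
        _, clean = generate_stain_field(movat_spec)
        _, noisy = generate_stain_field(
            dataclasses.replace(movat_spec, color_jitter_sd=10.0)
        )
        assert clean.realized_fractions == noisy.realized_fractions

    def test_truth_fractions_sum_le_one(self, movat_spec):
        _, truth = generate_stain_field(movat_spec)
        assert sum(truth.realized_fractions.values()) <= 1.0 + 1e-9

    def test_infeasible_fractions_raise(self):
        # 12 x 10 µm bands in 150 µm = 80% elastin; 30% more does not fit
        spec = FieldSpec(
            image_size=(150, 200), pixel_size=1.0, n_lamellae=12,
            lamella_thickness=10.0, interlamellar_distance=1.5,
            target_fractions={"cytoplasm": 0.30},
        )
        with pytest.raises(InfeasibleSpecError, match="remain"):
            generate_stain_field(spec)

    def test_too_small_image_raises(self):
        spec = FieldSpec(image_size=(40, 100), pixel_size=1.0, n_lamellae=8,
                         lamella_thickness=6.0, interlamellar_distance=14.0,
                         target_fractions={})
        with pytest.raises(InfeasibleSpecError, match="too small"):
            generate_stain_field(spec)

    @pytest.mark.parametrize("p_lo,p_hi", [(0.0, 0.3), (0.2, 0.5), (0.5, 0.9)])
    def test_monotone_fragmentation(self, vvg_spec, p_lo, p_hi):
        # coupled sampling: more fragmentation never adds elastin pixels
        lo = dataclasses.replace(vvg_spec, fragmentation_prob=p_lo)
        hi = dataclasses.replace(vvg_spec, fragmentation_prob=p_hi)
        _, t_lo = generate_stain_field(lo)
        _, t_hi = generate_stain_field(hi)
        assert (
            t_hi.realized_fractions["elastin"]
            <= t_lo.realized_fractions["elastin"] + 1e-12
        )

    def test_nuclei_count_recorded(self, he_spec):
        _, truth = generate_stain_field(he_spec)
        assert truth.nuclei_count == 60  # 500/mm² x 0.12 mm²
        assert truth.field_area == pytest.approx(0.12)


class TestGenerateRingImage:
    def test_media_band_width_along_radius(self):
        # 1200 µm media at 2 µm/px -> 600 samples of media on a radial ray
        spec = RingSpec(external_diameter=0.42, intima_thickness=40.0,
                        media_thickness=1200.0, adventitia_thickness=120.0,
                        pixel_size=2.0)
        img, truth = generate_ring_image(spec)
        side = img.shape[0]
        row = img.pixels[side // 2, :, :]
        # count media-colored pixels on the horizontal midline, one side
        media_rgb = np.array([40, 32, 45], dtype=np.uint8)
        media_px = (row == media_rgb).all(axis=1)
        half = media_px[: side // 2]
        assert abs(int(half.sum()) - 600) <= 2

    def test_media_annulus_area_within_1pct(self):
        spec = RingSpec(external_diameter=3.0, intima_thickness=100.0,
                        media_thickness=1200.0, adventitia_thickness=500.0,
                        pixel_size=10.0)
        _, truth = generate_ring_image(spec)
        closed = np.pi * (truth.media_outer_radius**2 - truth.media_inner_radius**2)
        pixel = truth.media_area_px * spec.pixel_size**2
        assert abs(pixel - closed) / closed < 0.01

    def test_zero_adventitia_ok(self, ring_spec):
        spec = dataclasses.replace(ring_spec, adventitia_thickness=0.0)
        img, truth = generate_ring_image(spec)
        assert truth.media_outer_radius == truth.external_radius
        adv_rgb = np.array([200, 45, 55], dtype=np.uint8)
        assert not (img.pixels == adv_rgb).all(axis=2).any()

    def test_subpixel_layer_rejected(self):
        with pytest.raises(ValueError, match="below one pixel"):
            RingSpec(external_diameter=0.5, intima_thickness=2.0,
                     media_thickness=300.0, adventitia_thickness=100.0,
                     pixel_size=4.0)

    def test_wall_thicker_than_radius_rejected(self):
        with pytest.raises(ValueError, match="external radius"):
            RingSpec(external_diameter=0.1, intima_thickness=100.0,
                     media_thickness=300.0, adventitia_thickness=200.0,
                     pixel_size=2.0)

    def test_deterministic(self, ring_spec):
        img1, _ = generate_ring_image(ring_spec)
        img2, _ = generate_ring_image(ring_spec)
        assert np.array_equal(img1.pixels, img2.pixels)


class TestGenerateCohort:
    def test_row_counts_match_spec(self):
        subjects, truth = generate_cohort(
            CohortSpec(n_per_group={"nondilated": 17, "aneurysm": 18})
        )
        assert len(subjects) == 35
        assert len(truth) == 35
        assert (subjects["group"] == "nondilated").sum() == 17
        assert (subjects["group"] == "aneurysm").sum() == 18

    def test_deterministic(self):
        spec = CohortSpec(seed=7)
        s1, t1 = generate_cohort(spec)
        s2, t2 = generate_cohort(spec)
        assert s1.equals(s2) and t1.equals(t2)

    def test_group_delta_applied_exactly_without_noise(self):
        spec = CohortSpec(
            group_effects={"media_thickness": -400.0}, seed=3
        )
        _, truth = generate_cohort(spec)
        by = truth.groupby("group")["media_thickness"].mean()
        assert by["nondilated"] == pytest.approx(1500.0)
        assert by["aneurysm"] == pytest.approx(1100.0)

    def test_diameter_fold_effect(self):
        spec = CohortSpec(group_effects={"diameter_fold": 1.6}, seed=3)
        _, truth = generate_cohort(spec)
        ratio = truth["observed_diameter"] / truth["expected_diameter"]
        assert np.allclose(ratio[truth.group == "aneurysm"], 1.6)
        assert np.allclose(ratio[truth.group == "nondilated"], 1.0)

    def test_invalid_group_size(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_group={"nondilated": 0})

    def test_unknown_effect_metric(self):
        with pytest.raises(ValueError, match="unknown"):
            CohortSpec(group_effects={"not_a_metric": 1.0})

    def test_scores_ordinal(self):
        subjects, _ = generate_cohort(CohortSpec(seed=5))
        for r in (1, 2, 3):
            assert subjects[f"score_rater{r}"].isin([1, 2, 3]).all()

    def test_null_effect_type_i_calibration(self):
        # with no group effect, Mann-Whitney on a noisy metric should
        # reject at ~alpha; 400 seeded replicates, band 0.05 +/- 0.02
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            spec = CohortSpec(
                n_per_group={"nondilated": 20, "aneurysm": 20},
                metric_noise_sd={"elastin_fraction": 0.04},
                seed=seed,
            )
            _, truth = generate_cohort(spec)
            x = truth.loc[truth.group == "nondilated", "elastin_fraction"]
            y = truth.loc[truth.group == "aneurysm", "elastin_fraction"]
            if mann_whitney(x, y).p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) <= 0.02

    def test_power_against_configured_effect(self):
        # elastin delta -0.07 at noise SD 0.04, n = 17/18: detected in the
        # majority of 200 seeds
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = CohortSpec(
                group_effects={"elastin_fraction": -0.07},
                metric_noise_sd={"elastin_fraction": 0.04},
                seed=seed,
            )
            _, truth = generate_cohort(spec)
            x = truth.loc[truth.group == "nondilated", "elastin_fraction"]
            y = truth.loc[truth.group == "aneurysm", "elastin_fraction"]
            if mann_whitney(x, y).p_value < 0.05:
                hits += 1
        assert hits > n_rep / 2

    def test_nomogram_threading(self):
        model = NomogramModel(intercept=3.0, coef_age=0.0, coef_sex=0.0,
                              coef_bsa=0.0, residual_sd=0.2)
        _, truth = generate_cohort(CohortSpec(nomogram=model, seed=1))
        assert np.allclose(truth["expected_diameter"], 3.0)
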