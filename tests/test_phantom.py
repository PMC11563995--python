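"""Phantom generator: geometry, generator arithmetic, cohort randomization."""

import numpy as np
import pytest

from perfterr.errors import ValidationError
from perfterr.phantom import (
    DEFAULT_TRUTH_MEANS,
    CohortConfig,
    ExperimentAssignment,
    PhantomConfig,
    TerritoryTruth,
    _territory_weights,
    build_specimen_phantom,
    clipped_normal_mean,
    draw_cohort_truths,
    generate_cohort,
    region_masks,
)
from perfterr.regions import BONE_SUBREGION_CELLS, FULL, MUSCLE, REGIONS, SUBREGIONS


class TestRegionMasks:
    def test_bone_regions_pairwise_disjoint(self, small_masks):
        for i, a in enumerate(REGIONS):
            for b in REGIONS[i + 1 :]:
                assert not (small_masks.mask(a) & small_masks.mask(b)).any()
        assert not (small_masks.mask(FULL) & small_masks.muscle_mask()).any()

    def test_anterior_posterior_partition_each_region(self, small_masks):
        for region in REGIONS:
            whole = small_masks.mask(region)
            ant = small_masks.mask(region, "anterior")
            post = small_masks.mask(region, "posterior")
            assert not (ant & post).any()
            assert ((ant | post) == whole).all()
            # equal halves: the bone band has an even anterior-posterior extent
            assert ant.sum() == post.sum() > 0

    def test_exactly_four_bone_regions_plus_muscle(self, small_masks):
        regions_present = {
            reg for lab, (reg, _) in small_masks.label_map.items()
            if np.any(small_masks.labels == lab)
        }
        assert regions_present == set(REGIONS) | {MUSCLE}

    def test_grid_below_minimum_rejected(self):
        with pytest.raises(ValidationError):
            PhantomConfig(grid_shape=(6, 16, 32))

    def test_minimum_grid_hosts_all_regions(self):
        masks = region_masks(PhantomConfig(grid_shape=(8, 8, 8)))
        masks.validate()


class TestSpecimenPhantom:
    def test_full_mfca_territory_makes_single_equal_dual_infusion(self, noise_free_config):
        truth = TerritoryTruth.uniform(1.0)
        spec = build_specimen_phantom(
            noise_free_config, truth, ExperimentAssignment("left", "MFCA"), seed=0
        )
        d_exp = spec.post_experimental.data - spec.pre_experimental.data
        d_ctrl = spec.post_control.data - spec.pre_control.data
        bone = spec.masks_experimental.mask(FULL)
        np.testing.assert_allclose(d_exp[bone], d_ctrl[bone], atol=1e-12)

    def test_uniform_fraction_gives_exact_roi_ratio(self, noise_free_specimen):
        # direct voxel arithmetic, independent of the enhancement module
        spec = noise_free_specimen
        d_exp = spec.post_experimental.data - spec.pre_experimental.data
        d_ctrl = spec.post_control.data - spec.pre_control.data
        for region in REGIONS + (FULL,):
            m = spec.masks_experimental.mask(region)
            assert d_exp[m].mean() / d_ctrl[m].mean() == pytest.approx(0.7, abs=1e-12)

    def test_muscle_never_enhances(self, noise_free_specimen):
        spec = noise_free_specimen
        muscle = spec.masks_experimental.muscle_mask()
        np.testing.assert_array_equal(
            spec.post_experimental.data[muscle], spec.pre_experimental.data[muscle]
        )
        np.testing.assert_array_equal(
            spec.post_control.data[muscle], spec.pre_control.data[muscle]
        )

    def test_dual_infusion_is_sum_of_single_infusions(self, noise_free_config):
        """Control-hip enhancement equals the sum of the two single-artery
        enhancements the same territory field would produce."""
        truth = TerritoryTruth({c: 0.3 + 0.05 * i for i, c in enumerate(BONE_SUBREGION_CELLS)})
        by_artery = {}
        for artery in ("MFCA", "LFCA"):
            spec = build_specimen_phantom(
                noise_free_config, truth, ExperimentAssignment("left", artery), seed=5
            )
            by_artery[artery] = spec.post_experimental.data - spec.pre_experimental.data
            d_ctrl = spec.post_control.data - spec.pre_control.data
        np.testing.assert_allclose(
            by_artery["MFCA"] + by_artery["LFCA"], d_ctrl, atol=1e-10
        )

    def test_territory_weights_clipped_under_heavy_jitter(self, small_masks, rng):
        truth = TerritoryTruth.uniform(0.9, jitter_sd=0.8)
        w = _territory_weights(small_masks, truth, rng)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_rician_noise_yields_nonnegative_magnitudes(self, small_config):
        config = PhantomConfig(
            grid_shape=small_config.grid_shape, noise_sd=20.0, noise_model="rician"
        )
        spec = build_specimen_phantom(
            config, TerritoryTruth.uniform(0.5), ExperimentAssignment(), seed=3
        )
        assert (spec.pre_experimental.data >= 0).all()


class TestCohort:
    def test_balanced_allocation_splits_arteries_evenly(self, small_cohort_config):
        dataset, _ = generate_cohort(small_cohort_config, seed=42)
        arteries = [s.infused_artery for s in dataset]
        assert arteries.count("MFCA") == arteries.count("LFCA") == 5

    def test_same_seed_bitwise_identical(self, small_cohort_config):
        d1, t1 = generate_cohort(small_cohort_config, seed=7)
        d2, t2 = generate_cohort(small_cohort_config, seed=7)
        for s1, s2 in zip(d1, d2):
            np.testing.assert_array_equal(
                s1.post_experimental.data, s2.post_experimental.data
            )
            assert s1.infused_artery == s2.infused_artery
        assert t1.equals(t2)

    def test_default_truth_means_match_study_region_means(self):
        """Region-level defaults: full trochanteric 0.685, GT 0.525."""
        means = DEFAULT_TRUTH_MEANS
        full = np.mean(list(means.values()))
        gt = np.mean([means[("GT", s)] for s in SUBREGIONS])
        assert full == pytest.approx(0.685, abs=1e-3)
        assert gt == pytest.approx(0.525, abs=1e-3)

    def test_truth_draws_match_clipped_normal_mean(self, small_config):
        """Sample mean of n=500 clipped-normal draws agrees with the closed-form
        clipped mean within 3*SD/sqrt(n) for every subregion."""
        cohort = CohortConfig(n_specimens=500, phantom=small_config)
        truths = draw_cohort_truths(cohort, seed=123)
        for cell in BONE_SUBREGION_CELLS:
            vals = np.array([t.mfca_fraction[cell] for t in truths])
            expected = clipped_normal_mean(
                cohort.truth_means[cell], cohort.truth_sds[cell]
            )
            tol = 3.0 * cohort.truth_sds[cell] / np.sqrt(len(vals))
            assert abs(vals.mean() - expected) < tol, cell

    def test_clipped_normal_mean_against_monte_carlo(self):
        rng = np.random.default_rng(99)
        draws = np.clip(rng.normal(0.808, 0.212, size=200_000), 0, 1)
        analytic = clipped_normal_mean(0.808, 0.212)
        assert draws.mean() == pytest.approx(analytic, abs=3 * 0.212 / np.sqrt(200_000))

    def test_negative_truth_sd_rejected(self, small_config):
        sds = {c: -0.1 for c in BONE_SUBREGION_CELLS}
        with pytest.raises(ValidationError):
            CohortConfig(truth_sds=sds, phantom=small_config)

    def test_truth_fraction_outside_unit_interval_rejected(self):
        fracs = {c: 0.5 for c in BONE_SUBREGION_CELLS}
        fracs[("GT", "anterior")] = 1.2
        with pytest.raises(ValidationError):
            TerritoryTruth(fracs)
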