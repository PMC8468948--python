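"""Bruise segmentation: circularity, damage PCA fitting, region filtering."""

import numpy as np
import pytest

from kakispec.damageseg import (
    DamagePCAConfig,
    RegionFilter,
    circularity,
    fit_damage_pca,
    region_perimeter,
    segment_damage,
)
from kakispec.errors import ContractError, InsufficientDataError
from kakispec.hypercube import HyperCube
from kakispec.pipeline import detect_cube
from kakispec.synthetic import (
    SceneDistribution,
    SceneSpec,
    generate_cube,
    iterate_dataset,
    make_templates,
)


def oracle_perimeter(mask):
    """Outer-boundary length recomputed per 2x2 marching-squares cell.

    Each mixed cell contributes a segment: one inside corner (or three) gives
    a diagonal cut of length sqrt(0.5), two adjacent inside corners give a
    straight cut of length 1, two diagonal corners give two diagonal cuts.
    No contour tracing involved.
    """
    from scipy import ndimage

    m = np.pad(ndimage.binary_fill_holes(np.asarray(mask, bool)), 1)
    diag = np.sqrt(0.5)
    total = 0.0
    for r in range(m.shape[0] - 1):
        for c in range(m.shape[1] - 1):
            corners = int(m[r, c]) + int(m[r, c + 1]) \
                + int(m[r + 1, c]) + int(m[r + 1, c + 1])
            if corners in (1, 3):
                total += diag
            elif corners == 2:
                if m[r, c] == m[r + 1, c + 1]:   # diagonal pair
                    total += 2 * diag
                else:
                    total += 1.0
    return total


class TestCircularity:
    def test_disk_is_nearly_circular(self):
        from skimage.morphology import disk

        assert circularity(disk(15).astype(bool)) >= 0.85

    def test_thin_line_scores_low(self):
        line = np.zeros((5, 40), dtype=bool)
        line[2, 5:35] = True
        assert circularity(line) < 0.25

    def test_single_pixel_caps_at_one(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        assert circularity(m) == 1.0

    def test_empty_region_rejected(self):
        with pytest.raises(ContractError):
            circularity(np.zeros((3, 3), dtype=bool))

    def test_perimeter_matches_cellwise_oracle(self):
        from skimage.morphology import disk

        rng = np.random.default_rng(0)
        shapes = [disk(7).astype(bool), disk(3).astype(bool)]
        for _ in range(10):
            blob = rng.random((15, 15)) < 0.45
            from scipy import ndimage

            lab, n = ndimage.label(blob)
            if n:
                shapes.append(lab == 1)
        for m in shapes:
            assert abs(region_perimeter(m) - oracle_perimeter(m)) < 1e-9


class TestFitDamagePCA:
    def _training(self, noise_sd=0.01, n_per_day=2, seed=100):
        base = SceneSpec(noise_sd=noise_sd)
        dist = SceneDistribution(base=base)
        from kakispec.fruitseg import segment_fruit

        pairs = []
        for _, state, cube, masks in iterate_dataset(n_per_day, dist=dist,
                                                     seed=seed):
            if state == "intact":
                continue
            pairs.append((cube, segment_fruit(cube)))
        return pairs

    def test_deterministic_given_inputs(self):
        pairs = self._training()
        cfg = DamagePCAConfig(selected_pc=2)
        m1 = fit_damage_pca(pairs, cfg)
        m2 = fit_damage_pca(pairs, cfg)
        assert np.array_equal(m1.loadings, m2.loadings)
        assert np.array_equal(m1.mean, m2.mean)

    def test_invariant_to_dataset_duplication(self):
        pairs = self._training()
        cfg = DamagePCAConfig(selected_pc=2)
        m1 = fit_damage_pca(pairs, cfg)
        m2 = fit_damage_pca(pairs + pairs, cfg)
        assert np.max(np.abs(m1.loadings - m2.loadings)) < 1e-10

    def test_noiseless_spectra_are_low_rank(self):
        pairs = self._training(noise_sd=0.0)
        model = fit_damage_pca(pairs, DamagePCAConfig(selected_pc=2))
        assert np.all(np.diff(model.evr) <= 1e-12)
        assert np.cumsum(model.evr)[-1] >= 0.999

    def test_too_few_pixels_rejected(self):
        cube, masks = generate_cube(SceneSpec(seed=1), make_templates(), 2)
        tiny = np.zeros_like(masks["fruit"])
        tiny[60:63, 60:63] = True
        with pytest.raises(InsufficientDataError):
            fit_damage_pca([(cube, tiny)], DamagePCAConfig())


class TestSegmentDamage:
    def test_intact_cube_verdict_intact(self, damage_model, synth_config,
                                        templates):
        from kakispec.fruitseg import segment_fruit

        cube, _ = generate_cube(SceneSpec(seed=21), templates, "intact")
        result = segment_damage(cube, segment_fruit(cube), damage_model,
                                synth_config.damage_pca,
                                synth_config.region_filter)
        assert result.verdict == "intact"
        assert not result.damage_mask.any()
        assert result.mean_damage_spectrum is None

    def test_day3_bruise_found_with_good_overlap(self, damage_model,
                                                 synth_config, templates):
        from kakispec.fruitseg import segment_fruit

        cube, masks = generate_cube(SceneSpec(seed=22), templates, 3)
        result = segment_damage(cube, segment_fruit(cube), damage_model,
                                synth_config.damage_pca,
                                synth_config.region_filter)
        assert result.verdict == "damaged"
        gt = masks["bruise"]
        iou = (result.damage_mask & gt).sum() / (result.damage_mask | gt).sum()
        assert iou >= 0.5
        assert result.mean_damage_spectrum.shape == (60,)

    def test_damage_mask_inside_fruit_mask(self, damage_model, synth_config,
                                           templates):
        from kakispec.fruitseg import segment_fruit

        cube, _ = generate_cube(SceneSpec(seed=23), templates, 1)
        fruit = segment_fruit(cube)
        result = segment_damage(cube, fruit, damage_model,
                                synth_config.damage_pca,
                                synth_config.region_filter)
        assert not (result.damage_mask & ~fruit).any()

    def test_spectrally_flat_fruit_is_degenerate_intact(self, damage_model,
                                                        synth_config,
                                                        templates):
        cube, masks = generate_cube(SceneSpec(noise_sd=0.0,
                                              vignette_strength=0.0, seed=24),
                                    templates, "intact")
        result = segment_damage(cube, masks["fruit"], damage_model,
                                synth_config.damage_pca,
                                synth_config.region_filter)
        assert result.verdict == "intact"
        assert result.degenerate

    def test_empty_fruit_mask_rejected(self, damage_model, synth_config,
                                       templates):
        cube, _ = generate_cube(SceneSpec(seed=25), templates, 2)
        with pytest.raises(ContractError):
            segment_damage(cube, np.zeros(cube.shape[:2], bool), damage_model,
                           synth_config.damage_pca,
                           synth_config.region_filter)

    def test_detection_rate_monotone_in_bruise_contrast(self, damage_model,
                                                        synth_config):
        rates = []
        for contrast in (0.1, 0.4, 1.0):
            templates_c = make_templates(contrast)
            hits = n = 0
            for _, state, cube, _ in iterate_dataset(6,
                                                     templates=templates_c,
                                                     seed=11):
                if state != "2":
                    continue
                n += 1
                verdict = detect_cube(cube, damage_model, synth_config).verdict
                hits += verdict == "damaged"
            rates.append(hits / n)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 1.0

    def test_mean_spectrum_is_raw_reflectance(self, damage_model,
                                              synth_config, templates):
        """The spectrum handed to the aging model is un-normalised
        reflectance averaged over the damage pixels (not SNV'd scores)."""
        from kakispec.fruitseg import segment_fruit

        cube, _ = generate_cube(SceneSpec(seed=26), templates, 3)
        fruit = segment_fruit(cube)
        result = segment_damage(cube, fruit, damage_model,
                                synth_config.damage_pca,
                                synth_config.region_filter)
        expected = cube.data[result.damage_mask].mean(axis=0)
        assert np.allclose(result.mean_damage_spectrum, expected)
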