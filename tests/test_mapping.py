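import numpy as np
import pytest
from scipy import stats

from deti import mapping, synthdata
from deti.exceptions import ArgumentError, DegenerateInputError
from deti.mapping import (
    DETIMap,
    RegressionMaps,
    SignificanceMask,
    _bh_r2_thresholds,
    _bh_significant_from_r2,
    behavioral_encoder_map,
    bh_correct,
    monotonicity_statistic,
    permutation_null,
    pixelwise_regression,
    significance_mask,
    tag_image_general,
    tag_image_specific,
    tuning_curves,
)


class TestPixelwiseRegression:
    def test_perfect_fit_r2_one(self, tiny_space):
        y = tiny_space.values[3, :, 17].copy()
        maps = pixelwise_regression(tiny_space, y)
        assert maps.r2[3, 17] == pytest.approx(1.0, abs=1e-10)
        assert maps.p[3, 17] < 1e-12

    def test_constant_predictor_convention(self, tiny_space):
        space_vals = tiny_space.values.copy()
        space = type(tiny_space)(
            values=space_vals,
            bank=tiny_space.bank,
            pixel_index=tiny_space.pixel_index,
            floor=tiny_space.floor,
            mask=tiny_space.mask,
            degrees_per_pixel=tiny_space.degrees_per_pixel,
        )
        space.values[0, :, 5] = -3.0  # floored-constant pixel
        rng = np.random.default_rng(0)
        maps = pixelwise_regression(space, rng.standard_normal(space.n_images))
        assert maps.r2[0, 5] == 0.0
        assert maps.p[0, 5] == 1.0

    def test_matches_closed_form_oracle(self, tiny_space):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(tiny_space.n_images)
        maps = pixelwise_regression(tiny_space, y)
        n = y.size
        for k, p in [(0, 3), (4, 100), (6, 250)]:
            x = tiny_space.values[k, :, p]
            r, _ = stats.pearsonr(x, y)
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p_expect = 2 * stats.t.sf(abs(t), n - 2)
            slope, intercept, *_ = stats.linregress(x, y)
            assert maps.r2[k, p] == pytest.approx(r**2, abs=1e-10)
            assert maps.p[k, p] == pytest.approx(p_expect, rel=1e-8)
            assert maps.slope[k, p] == pytest.approx(slope, rel=1e-10)
            assert maps.intercept[k, p] == pytest.approx(intercept, rel=1e-10)

    def test_constant_loadings_rejected(self, tiny_space):
        with pytest.raises(DegenerateInputError):
            pixelwise_regression(tiny_space, np.ones(tiny_space.n_images))

    def test_too_few_images_rejected(self, tiny_space):
        with pytest.raises(ArgumentError):
            pixelwise_regression(tiny_space, np.array([1.0, 2.0, 3.0]))


class TestBHCorrect:
    def test_hand_evaluated_step_up(self):
        p = np.array([0.001] * 10 + [0.9] * 10)
        rejected = bh_correct(p, 0.05)
        assert rejected.sum() == 10
        assert rejected[:10].all() and not rejected[10:].any()

    def test_all_ones_rejects_nothing(self):
        assert not bh_correct(np.ones(50), 0.05).any()

    def test_empty_input(self):
        assert bh_correct(np.array([]), 0.05).size == 0

    def test_null_monte_carlo_rejection_rate(self):
        rng = np.random.default_rng(2)
        fractions = [
            bh_correct(rng.uniform(size=10_000), 0.05).mean() for _ in range(200)
        ]
        assert np.mean(fractions) < 0.005

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.uniform(size=500) ** 2
            ours = bh_correct(p, 0.05)
            theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(ours, theirs)

    def test_r2_rank_fast_path_equivalent(self):
        # the permutation-null inner loop must match the p-value route
        rng = np.random.default_rng(4)
        n_images, m = 30, 400
        r = np.tanh(rng.standard_normal(m) * 0.6)
        r2 = r**2
        t = np.sqrt(r2 * (n_images - 2) / (1 - r2))
        p = 2 * stats.t.sf(t, n_images - 2)
        for q in (0.05, 0.10):
            via_p = bh_correct(p, q)
            via_r2 = _bh_significant_from_r2(r2, _bh_r2_thresholds(n_images, m, q))
            np.testing.assert_array_equal(via_p, via_r2)


def _toy_maps(r2, p=None, slope=None, intercept=None):
    r2 = np.asarray(r2, dtype=float)
    return RegressionMaps(
        r2=r2,
        slope=np.zeros_like(r2) if slope is None else np.asarray(slope, float),
        intercept=np.zeros_like(r2) if intercept is None else np.asarray(intercept, float),
        p=np.full_like(r2, 0.01) if p is None else np.asarray(p, float),
        n_images=10,
    )


class TestTagging:
    def test_single_significant_encoder_wins(self):
        maps = _toy_maps([[0.2], [0.9], [0.5]])
        mask = SignificanceMask(np.array([[False], [True], [False]]), 0.05)
        assert tag_image_general(maps, mask).tags[0] == 2

    def test_no_significant_encoder_untagged(self):
        maps = _toy_maps([[0.2], [0.9]])
        mask = SignificanceMask(np.zeros((2, 1), dtype=bool), 0.05)
        assert tag_image_general(maps, mask).tags[0] == 0

    def test_tie_breaks_to_lower_index(self):
        maps = _toy_maps([[0.7], [0.7], [0.7]])
        mask = SignificanceMask(np.ones((3, 1), dtype=bool), 0.05)
        assert tag_image_general(maps, mask).tags[0] == 1

    def test_tagged_subset_of_significant(self, tiny_space):
        rng = np.random.default_rng(5)
        maps = pixelwise_regression(tiny_space, rng.standard_normal(tiny_space.n_images))
        sig = significance_mask(maps, 0.10)
        tags = tag_image_general(maps, sig).tags
        for p in np.flatnonzero(tags):
            assert sig.mask[tags[p] - 1, p]


class TestTagImageSpecific:
    def test_image_on_regression_line(self, tiny_space):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(tiny_space.n_images)
        maps = pixelwise_regression(tiny_space, y)
        # force image 2 exactly onto encoder 1's line at every pixel
        maps.intercept[1] = y[2] - maps.slope[1] * tiny_space.values[1, 2, :]
        mask = SignificanceMask(np.ones_like(maps.r2, dtype=bool), 0.10)
        tags = tag_image_specific(maps, mask, tiny_space, y, 2).tags
        assert (tags == 2).all()

    def test_equal_residuals_tie_to_lowest(self, tiny_space):
        y = np.zeros(tiny_space.n_images)
        y[0] = 1.0
        maps = _toy_maps(
            np.full((7, tiny_space.n_visible), 0.5),
            slope=np.zeros((7, tiny_space.n_visible)),
            intercept=np.zeros((7, tiny_space.n_visible)),
        )
        mask = SignificanceMask(np.ones_like(maps.r2, dtype=bool), 0.10)
        tags = tag_image_specific(maps, mask, tiny_space, y, 0).tags
        assert (tags == 1).all()

    def test_matches_bruteforce_enumeration(self, tiny_space):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(tiny_space.n_images)
        maps = pixelwise_regression(tiny_space, y)
        sig = significance_mask(maps, 0.10)
        image_index = 4
        tags = tag_image_specific(maps, sig, tiny_space, y, image_index).tags
        for p in rng.choice(tiny_space.n_visible, 25, replace=False):
            best, best_resid = 0, np.inf
            for k in range(7):
                if not sig.mask[k, p]:
                    continue
                pred = maps.intercept[k, p] + maps.slope[k, p] * tiny_space.values[
                    k, image_index, p
                ]
                resid = abs(y[image_index] - pred)
                if resid < best_resid:
                    best, best_resid = k + 1, resid
            assert tags[p] == best

    def test_invalid_image_index(self, tiny_space):
        maps = _toy_maps(np.zeros((7, tiny_space.n_visible)))
        mask = SignificanceMask(np.ones_like(maps.r2, dtype=bool), 0.10)
        with pytest.raises(ArgumentError):
            tag_image_specific(maps, mask, tiny_space, np.zeros(8), 99)


class TestSignAndNesting:
    def test_end_to_end_sign_invariance(self, recovery_run):
        space = recovery_run["space"]
        y = recovery_run["series"].loadings[0, 4]
        for q in (0.05, 0.10):
            a = tag_image_general(
                *(lambda m: (m, significance_mask(m, q)))(pixelwise_regression(space, y))
            ).tags
            b = tag_image_general(
                *(lambda m: (m, significance_mask(m, q)))(
                    pixelwise_regression(space, -y)
                )
            ).tags
            np.testing.assert_array_equal(a, b)

    def test_q_nesting(self, recovery_run):
        space = recovery_run["space"]
        y = recovery_run["series"].loadings[1, 6]
        maps = pixelwise_regression(space, y)
        tags05 = tag_image_general(maps, significance_mask(maps, 0.05)).tags
        tags10 = tag_image_general(maps, significance_mask(maps, 0.10)).tags
        assert ((tags05 > 0) <= (tags10 > 0)).all()


class TestPermutationNull:
    def test_identity_permutation_reproduces_unshuffled(self, recovery_run):
        space = recovery_run["space"]
        veps = recovery_run["veps"]
        series = recovery_run["series"]
        n_i = space.n_images
        res = permutation_null(
            veps, space, q=0.05, permutations=[np.arange(n_i)]
        )
        # recompute unshuffled tagged fractions directly
        n_e, n_s, _ = series.loadings.shape
        for e in range(n_e):
            for s in range(0, n_s, 3):
                maps = pixelwise_regression(space, series.loadings[e, s])
                sig = significance_mask(maps, 0.05)
                frac = tag_image_general(maps, sig).tagged_fraction
                assert res.fractions[0, e, s] == pytest.approx(frac, abs=1e-12)


class TestTuningCurves:
    def test_single_pixel_curve(self):
        r2 = np.array([[0.1], [0.5], [0.3]])
        maps = _toy_maps(r2)
        dmap = DETIMap(np.array([2]), 3)
        curves = tuning_curves(dmap, maps)
        np.testing.assert_allclose(curves[2]["mean"], r2[:, 0])
        assert curves[2]["n_pixels"] == 1

    def test_monotonicity_statistic(self):
        assert monotonicity_statistic(np.array([0.1, 0.3, 0.9, 0.4, 0.2])) == 1.0
        assert monotonicity_statistic(np.array([0.9, 0.1, 0.5])) == 0.5

    def test_shuffled_labels_lose_tuning(self, recovery_run, recovery_tags):
        space = recovery_run["space"]
        series = recovery_run["series"]
        e, s = 0, 4
        maps = pixelwise_regression(space, series.loadings[e, s])
        dmap = DETIMap(recovery_tags[e, s].copy(), 7)
        curves = tuning_curves(dmap, maps)
        observed = np.mean([c["monotonicity"] for c in curves.values()])
        rng = np.random.default_rng(8)
        shuffled_stats = []
        for _ in range(20):
            perm_r2 = maps.r2[:, rng.permutation(space.n_visible)]
            sh = tuning_curves(dmap, _toy_maps(perm_r2))
            shuffled_stats.append(np.mean([c["monotonicity"] for c in sh.values()]))
        assert observed >= np.mean(shuffled_stats)


class TestBehavioral:
    def test_scores_equal_loadings_identity(self, recovery_run):
        space = recovery_run["space"]
        y = recovery_run["series"].loadings[2, 5]
        maps, dmap = behavioral_encoder_map(y, space, q=0.05)
        ref = pixelwise_regression(space, y)
        expected = tag_image_general(ref, significance_mask(ref, 0.05)).tags
        np.testing.assert_array_equal(dmap.tags, expected)

    def test_constant_scores_rejected(self, tiny_space):
        with pytest.raises(DegenerateInputError):
            behavioral_encoder_map(np.ones(8), tiny_space)

    def test_random_scores_mostly_untagged(self, recovery_run):
        space = recovery_run["space"]
        rng = np.random.default_rng(9)
        fractions = []
        for _ in range(10):
            _, dmap = behavioral_encoder_map(
                rng.standard_normal(space.n_images), space, q=0.05
            )
            fractions.append(dmap.tagged_fraction)
        assert np.median(fractions) <= 0.02


class TestRecoveryProperties:
    def test_zero_noise_recovery(self, recovery_run, recovery_tags):
        truth = recovery_run["truth"]
        score = synthdata.recovery_score(
            recovery_tags, np.transpose(truth.preferred_encoder, (0, 2, 1)), 7
        )
        assert score["agreement"] is not None and score["agreement"] >= 0.9

    def test_noise_sweep_monotone(self, recovery_cfg):
        import dataclasses

        from deti import encoders
        from deti import veps as veps_mod

        agreements = []
        for sigma in (0.0, 1.0, 4.0):
            cfg = dataclasses.replace(recovery_cfg, noise_sigma=sigma)
            stim = synthdata.synth_images(cfg)
            space = encoders.encode_images(stim)
            truth = synthdata.synth_ground_truth(cfg, space.n_visible, space.pixel_index)
            _, veps = synthdata.synth_veps(space, truth, cfg)
            series = veps_mod.timeresolved_pc1(veps)
            tags = []
            for e in range(cfg.n_electrodes):
                maps = pixelwise_regression(space, series.loadings[e, 4])
                sig = significance_mask(maps, 0.05)
                tags.append(tag_image_general(maps, sig).tags)
            score = synthdata.recovery_score(
                np.stack(tags), truth.preferred_encoder[:, :, 4], 7
            )
            agreements.append(score["agreement"] if score["agreement"] is not None else 0.0)
        assert agreements[0] >= agreements[1] >= agreements[2] - 1e-9
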