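"""Texton dictionary learning, histograms, chi-square 1-NN staging."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from cirrtex import (PipelineConfig, RoiImage, STAGES, StageModelSet,
                     TextonHistogram, assign_textons, chi2_distance,
                     classify_roi, generate_texture, learn_textons,
                     texton_histogram, train_models)
from cirrtex.synthetic_textures import DEFAULT_PRESETS


def random_histograms(rng, n, k):
    X = rng.random((n, k))
    return X / X.sum(axis=1, keepdims=True)


class TestLearnTextons:
    def test_dictionary_size_is_c_times_k(self, rng):
        pools = {s: rng.normal(size=(50, 15)) for s in STAGES}
        d = learn_textons(pools, K=10, seed=0)
        assert d.textons.shape == (30, 15)
        assert d.C == 3 and d.size == 30

    def test_k_equal_one_gives_stage_means(self, rng):
        pools = {s: rng.normal(size=(40, 15)) for s in STAGES}
        d = learn_textons(pools, K=1, seed=0)
        for c, s in enumerate(d.stage_order):
            np.testing.assert_allclose(d.textons[c], pools[s].mean(axis=0),
                                       atol=1e-8)

    @pytest.mark.parametrize("K", [2, 5, 10])
    def test_planted_cluster_recovery(self, K, rng):
        """K well-separated point clouds per stage: K-means must recover
        the planted centers to within 0.1 * separation under optimal
        matching."""
        separation, spread = 20.0, 0.5
        pools, truth = {}, {}
        for s in STAGES:
            centers = rng.normal(size=(K, 15))
            centers = centers / np.linalg.norm(centers, axis=1,
                                               keepdims=True) * separation
            centers += rng.normal(scale=separation, size=(1, 15))
            pts = np.vstack([c + rng.normal(scale=spread, size=(60, 15))
                             for c in centers])
            pools[s], truth[s] = pts, centers
        d = learn_textons(pools, K=K, seed=3)
        for s in STAGES:
            block = d.stage_block(s)
            cost = cdist(block, truth[s])
            rows, cols = linear_sum_assignment(cost)
            assert cost[rows, cols].max() < 0.1 * separation

    def test_stage_blocks_originate_from_their_pool(self, rng):
        """Dictionary block c must lie in stage c's region when the
        per-stage pools occupy disjoint regions of feature space."""
        pools = {s: rng.normal(size=(80, 15)) + 100.0 * i
                 for i, s in enumerate(STAGES)}
        d = learn_textons(pools, K=5, seed=1)
        for i, s in enumerate(d.stage_order):
            block = d.stage_block(s)
            np.testing.assert_allclose(block.mean(), 100.0 * i, atol=5.0)

    def test_pool_smaller_than_k_names_the_stage(self, rng):
        pools = {s: rng.normal(size=(50, 15)) for s in STAGES}
        pools["early"] = pools["early"][:3]
        with pytest.raises(ValueError, match="early"):
            learn_textons(pools, K=10, seed=0)


class TestAssignTextons:
    def test_feature_equal_to_texton_gets_its_index(self, rng):
        pools = {s: rng.normal(size=(30, 15)) for s in STAGES}
        d = learn_textons(pools, K=3, seed=0)
        idx = assign_textons(d.textons[[7]], d)
        assert idx[0] == 7

    def test_equidistant_tie_goes_to_lowest_index(self):
        from cirrtex.texton_model import TextonDictionary
        textons = np.zeros((6, 2))
        textons[2] = [1.0, 0.0]
        textons[5] = [-1.0, 0.0]
        textons[0] = [0.0, 9.0]
        textons[1] = [0.0, 8.0]
        textons[3] = [0.0, 7.0]
        textons[4] = [0.0, 6.0]
        d = TextonDictionary(textons=textons, K=2,
                             stage_order=("a", "b", "c"))
        assert assign_textons(np.array([[0.0, 0.0]]), d)[0] == 2

    def test_matches_exhaustive_pairwise_scan(self, rng):
        X = rng.normal(size=(100, 15))
        from cirrtex.texton_model import TextonDictionary
        d = TextonDictionary(textons=rng.normal(size=(30, 15)), K=10,
                             stage_order=STAGES)
        got = assign_textons(X, d)
        for l in range(100):
            dists = [np.sqrt(np.sum((X[l] - t) ** 2)) for t in d.textons]
            assert got[l] == int(np.argmin(dists))

    def test_dimension_mismatch_rejected(self, rng):
        from cirrtex.texton_model import TextonDictionary
        d = TextonDictionary(textons=rng.normal(size=(30, 15)), K=10,
                             stage_order=STAGES)
        with pytest.raises(ValueError):
            assign_textons(np.zeros((4, 14)), d)


class TestTextonHistogram:
    def test_direct_count(self):
        h = texton_histogram([0, 0, 1], dict_size=2)
        np.testing.assert_allclose(h.bins, [2 / 3, 1 / 3])

    def test_all_same_index_gives_one_hot(self):
        h = texton_histogram([4] * 20, dict_size=6)
        expected = np.zeros(6)
        expected[4] = 1.0
        np.testing.assert_allclose(h.bins, expected)

    def test_matches_brute_force_tally(self, rng):
        idx = rng.integers(0, 30, size=676)
        h = texton_histogram(idx, dict_size=30)
        tally = np.array([np.sum(idx == k) for k in range(30)]) / 676
        np.testing.assert_allclose(h.bins, tally)
        assert abs(h.bins.sum() - 1.0) < 1e-9

    def test_empty_indices_rejected(self):
        with pytest.raises(ValueError):
            texton_histogram([], dict_size=5)


class TestChi2Distance:
    def test_identical_histograms_have_zero_distance(self, rng):
        h = random_histograms(rng, 1, 30)[0]
        assert chi2_distance(h, h) == 0.0

    def test_disjoint_one_hot_histograms_at_distance_one(self):
        assert chi2_distance(np.array([1.0, 0.0]),
                             np.array([0.0, 1.0])) == pytest.approx(1.0)

    def test_matches_term_by_term_oracle_and_symmetry(self, rng):
        a, b = random_histograms(rng, 2, 30)
        expected = 0.0
        for k in range(30):
            if a[k] + b[k] > 0:
                expected += (a[k] - b[k]) ** 2 / (a[k] + b[k])
        expected *= 0.5
        assert chi2_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert chi2_distance(a, b) == pytest.approx(chi2_distance(b, a))

    def test_metric_axioms_on_1000_random_pairs(self, rng):
        A = random_histograms(rng, 1000, 30)
        B = random_histograms(rng, 1000, 30)
        for a, b in zip(A, B):
            d = chi2_distance(a, b)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(chi2_distance(b, a))
        assert chi2_distance(A[0], A[0]) == 0.0

    def test_zero_denominator_bins_contribute_nothing(self):
        a = np.array([0.5, 0.5, 0.0])
        b = np.array([0.5, 0.5, 0.0])
        assert chi2_distance(a, b) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi2_distance(np.ones(3) / 3, np.ones(4) / 4)


def _training_rois(n_per_stage=2, size=30, seed0=0):
    rois = []
    for i, stage in enumerate(STAGES):
        for j in range(n_per_stage):
            img = generate_texture(DEFAULT_PRESETS[stage], size, size,
                                   seed=seed0 + 100 * i + j)
            rois.append((RoiImage(pixels=img), stage))
    return rois


class TestTrainModels:
    def test_bookkeeping_two_rois_per_stage(self):
        cfg = PipelineConfig(K=5)
        _, models, _ = train_models(_training_rois(2), cfg)
        for s in STAGES:
            assert len(models.models[s]) == 2

    def test_same_seed_gives_identical_model_histograms(self):
        cfg = PipelineConfig(K=5)
        _, m1, _ = train_models(_training_rois(2), cfg)
        _, m2, _ = train_models(_training_rois(2), cfg)
        for s in STAGES:
            for h1, h2 in zip(m1.models[s], m2.models[s]):
                np.testing.assert_array_equal(h1.bins, h2.bins)

    def test_missing_stage_rejected(self):
        rois = [(r, s) for r, s in _training_rois(2) if s != "early"]
        with pytest.raises(ValueError, match="early"):
            train_models(rois, PipelineConfig(K=5))

    def test_within_stage_distances_smaller_than_between(self):
        """Separation statistic: on well-separated presets, the mean
        within-stage chi2 distance of training histograms must fall
        below the mean between-stage distance."""
        _, models, _ = train_models(_training_rois(4), PipelineConfig(K=5))
        within, between = [], []
        for si in STAGES:
            for sj in STAGES:
                for hi in models.models[si]:
                    for hj in models.models[sj]:
                        if hi is hj:
                            continue
                        (within if si == sj else between).append(
                            chi2_distance(hi, hj))
        assert np.mean(within) < np.mean(between)


class TestClassifyRoi:
    def _models(self, rng):
        return StageModelSet(
            models={s: [TextonHistogram(bins=h)
                        for h in random_histograms(rng, 3, 30)]
                    for s in STAGES},
            stage_order=STAGES)

    def test_exact_training_histogram_match(self, rng):
        models = self._models(rng)
        h = models.models["early"][1]
        stage, d = classify_roi(h, models)
        assert stage == "early" and d == 0.0

    def test_argmin_over_stage_distances(self):
        models = StageModelSet(
            models={
                "normal": [TextonHistogram(bins=np.array([1.0, 0.0, 0.0]))],
                "early": [TextonHistogram(bins=np.array([0.0, 1.0, 0.0]))],
                "mid_advanced": [TextonHistogram(bins=np.array([0.0, 0.0, 1.0]))],
            },
            stage_order=STAGES)
        h = TextonHistogram(bins=np.array([0.1, 0.8, 0.1]))
        stage, _ = classify_roi(h, models)
        assert stage == "early"

    def test_matches_brute_force_one_nn_scan(self, rng):
        models = self._models(rng)
        tests = random_histograms(rng, 30, 30)
        for t in tests:
            h = TextonHistogram(bins=t)
            got_stage, got_d = classify_roi(h, models)
            best = min(
                ((s, chi2_distance(t, m.bins))
                 for s in STAGES for m in models.models[s]),
                key=lambda sd: sd[1])
            assert got_d == pytest.approx(best[1])
            assert got_stage == best[0]


def test_roi_accuracy_does_not_collapse_as_k_grows(small_cohort, small_config):
    """Regression guard: on the separable synthetic cohort, growing the
    dictionary from K=1 to K=10 must not cost more than 10 percentage
    points of mean ROI accuracy."""
    import dataclasses

    from cirrtex.pipeline import run_cctcrf

    accs = {}
    for K in (1, 2, 5, 10):
        cfg = dataclasses.replace(small_config, K=K)
        table = run_cctcrf(cfg, cohort=small_cohort)
        accs[K] = table["roi_accuracy"].mean()
    assert accs[10] >= accs[1] - 10.0
    assert min(accs.values()) >= accs[1] - 10.0
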