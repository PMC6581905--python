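"""Training-set assembly, information gain, forest training and evaluation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from pathcna.catalog import default_catalog
from pathcna.graphfeat import FeatureVector, featurize
from pathcna.mlcore import (ForestConfig, PredictionRecord, TrainingSet,
                            assemble_training_set, auto_m_try, compute_metrics,
                            evaluate, info_gain_rank, information_gain,
                            load_feature_table, predict, rank_against_random,
                            rank_auc, roc_points, save_feature_table,
                            sensitivity_analysis, top_features, train_forest,
                            training_set_from_vectors)


def _gaussian_training(n=100, d=5, separation=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x_pos = rng.normal(separation, 1.0, size=(n, d))
    x_neg = rng.normal(0.0, 1.0, size=(n, d))
    x = np.vstack([x_pos, x_neg])
    y = np.array([1] * n + [0] * n)
    names = tuple(f"f{i}" for i in range(d))
    ids = tuple(f"i{i}" for i in range(2 * n))
    return TrainingSet(x, y, ids, names, tuple(["positive_collection"] * n
                                               + ["negative_collection"] * n))


def _vectors(x, names, prefix="v"):
    return [FeatureVector(f"{prefix}{i}", row, np.zeros(len(row), dtype=bool), names)
            for i, row in enumerate(x)]


class TestComputeMetrics:
    def test_reconstructs_published_confusion_rates(self):
        """TP=155/FN=14/FP=41/TN=129 must give the printed per-class rates."""
        report = compute_metrics(155, 14, 41, 129)
        pos = report.per_class["positive"]
        assert pos["tpr"] == pytest.approx(0.917, abs=5e-4)
        assert pos["fpr"] == pytest.approx(0.241, abs=5e-4)
        assert pos["precision"] == pytest.approx(0.791, abs=5e-4)
        assert pos["f_measure"] == pytest.approx(0.849, abs=5e-4)
        neg = report.per_class["negative"]
        assert neg["tpr"] == pytest.approx(0.759, abs=5e-4)
        assert neg["fpr"] == pytest.approx(0.083, abs=5e-4)
        assert neg["precision"] == pytest.approx(0.902, abs=5e-4)
        assert neg["f_measure"] == pytest.approx(0.824, abs=5e-4)
        weighted = report.weighted
        assert weighted["tpr"] == pytest.approx(0.838, abs=5e-4)
        assert weighted["fpr"] == pytest.approx(0.162, abs=5e-4)
        assert weighted["precision"] == pytest.approx(0.847, abs=5e-4)
        assert report.accuracy == pytest.approx((155 + 129) / 339)

    def test_perfect_classifier(self):
        report = compute_metrics(10, 0, 0, 10, scores=[1.0] * 10 + [0.0] * 10,
                                 labels=[1] * 10 + [0] * 10)
        assert report.per_class["positive"]["tpr"] == 1.0
        assert report.per_class["positive"]["fpr"] == 0.0
        assert report.auc == pytest.approx(1.0)

    def test_weighted_average_between_class_values(self):
        report = compute_metrics(50, 10, 20, 40)
        for key in ("tpr", "precision", "f_measure"):
            lo = min(report.per_class["positive"][key], report.per_class["negative"][key])
            hi = max(report.per_class["positive"][key], report.per_class["negative"][key])
            assert lo <= report.weighted[key] <= hi

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 5, 5)


class TestAUC:
    def test_brute_force_pairs(self):
        scores = [0.9, 0.8, 0.7, 0.1]
        labels = [1, 1, 0, 0]
        assert rank_auc(scores, labels) == pytest.approx(1.0)

    def test_matches_sklearn_and_trapezoid(self):
        rng = np.random.default_rng(2)
        scores = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        auc = rank_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        pts = roc_points(scores, labels)
        trapezoid = float(np.trapezoid([tpr for _, tpr in pts],
                                       [fpr for fpr, _ in pts]))
        assert auc == pytest.approx(trapezoid, abs=1e-9)

    def test_ties_count_half(self):
        assert rank_auc([0.5, 0.5], [1, 0]) == pytest.approx(0.5)


class TestAutoMTry:
    def test_matches_printed_nine_at_444_features(self):
        assert auto_m_try(444) == 9

    def test_small_dimensions(self):
        assert auto_m_try(20) == 5
        assert auto_m_try(1) == 1


class TestInformationGain:
    def test_perfect_binary_predictor(self):
        y = np.array([1] * 10 + [0] * 10)
        assert information_gain(y.astype(float), y) == pytest.approx(1.0)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 50 + [0] * 50)
        x = rng.normal(size=100)
        assert information_gain(x, y) == pytest.approx(0.0, abs=1e-9)

    def test_hand_entropy_for_binary_feature(self):
        # class-conditional counts pos: 8/2, neg: 2/8 -> 1 - H(0.8)
        x = np.array([0.0] * 8 + [1.0] * 2 + [0.0] * 2 + [1.0] * 8)
        y = np.array([1] * 10 + [0] * 10)
        expected = 1.0 - (-(0.8 * np.log2(0.8) + 0.2 * np.log2(0.2)))
        assert information_gain(x, y) == pytest.approx(expected, abs=1e-9)

    def test_mdl_accepts_informative_continuous_split(self):
        rng = np.random.default_rng(8)
        y = np.array([1] * 60 + [0] * 60)
        x = np.where(y == 1, rng.normal(3, 0.5, 120), rng.normal(0, 0.5, 120))
        assert information_gain(x, y) > 0.5

    def test_ranking_sorted_with_catalog_tie_break(self):
        training = _gaussian_training(seed=1)
        ranked = info_gain_rank(training)
        gains = [g for _, g in ranked]
        assert gains == sorted(gains, reverse=True)
        assert set(top_features(ranked, 3)) <= set(training.feature_names)

    def test_single_class_rejected(self):
        x = np.zeros((4, 2))
        ts = TrainingSet(x, np.ones(4, dtype=int), ("a", "b", "c", "d"),
                         ("f0", "f1"), ("positive_collection",) * 4)
        with pytest.raises(ValueError):
            info_gain_rank(ts)


class TestAssembleTrainingSet:
    def _fake_vectors(self, n, names, prefix):
        rng = np.random.default_rng(hash(prefix) % (1 << 31))
        return _vectors(rng.normal(size=(n, len(names))), names, prefix)

    def test_ceil_rule_and_provenance(self, small_networks, small_common, catalog,
                                      small_caches):
        names = tuple(f"{spec.name}__{net.season_label}"
                      for net in small_networks for spec in catalog)
        positives = self._fake_vectors(10, names, "pos")
        candidates = self._fake_vectors(20, names, "cand")
        ts = assemble_training_set(positives, candidates, small_common,
                                   small_networks, catalog, seed=5,
                                   size_max=min(18, len(small_common)),
                                   caches=small_caches)
        assert ts.n_positive == 10
        assert ts.n_negative == 10  # 5 sampled + 5 random sets
        assert ts.provenance.count("negative_collection") == 5
        assert ts.provenance.count("random") == 5

    def test_deterministic_under_seed(self, small_networks, small_common, catalog,
                                      small_caches):
        names = tuple(f"{spec.name}__{net.season_label}"
                      for net in small_networks for spec in catalog)
        positives = self._fake_vectors(6, names, "pos")
        candidates = self._fake_vectors(8, names, "cand")
        kwargs = dict(common=small_common, networks=small_networks, catalog=catalog,
                      seed=9, size_max=min(18, len(small_common)), caches=small_caches)
        a = assemble_training_set(positives, candidates, **kwargs)
        b = assemble_training_set(positives, candidates, **kwargs)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.x, b.x)

    def test_insufficient_candidates_rejected(self, small_networks, small_common,
                                              catalog):
        names = ("f0",)
        with pytest.raises(ValueError):
            assemble_training_set(_vectors(np.zeros((10, 1)), names), [],
                                  small_common, small_networks, catalog)


class TestTrainForest:
    def test_separable_gaussians_low_oob(self):
        training = _gaussian_training(n=100, separation=5.0, seed=0)
        _, oob = train_forest(training, ForestConfig(seed=0))
        assert oob <= 0.05

    def test_constant_features_vote_near_prior(self):
        # trees on uninformative input vote their bootstrap majority, so the
        # vote fraction tracks the (balanced) class prior
        x = np.ones((60, 3))
        y = np.array([1] * 30 + [0] * 30)
        ts = TrainingSet(x, y, tuple(f"i{i}" for i in range(60)),
                         ("a", "b", "c"), ("random",) * 60)
        model, _ = train_forest(ts, ForestConfig(seed=0))
        votes = model.vote_fraction(np.ones((1, 3)))
        assert votes[0] == pytest.approx(0.5, abs=0.15)

    def test_m_try_out_of_range_rejected(self):
        training = _gaussian_training(n=20, d=3)
        with pytest.raises(ValueError):
            train_forest(training, ForestConfig(m_try=10))


class TestEvaluate:
    def test_loocv_separable_is_perfect(self):
        training = _gaussian_training(n=12, d=3, separation=6.0, seed=3)
        report = evaluate(training, ForestConfig(seed=0), scheme="loocv")
        assert report.accuracy == pytest.approx(1.0)

    def test_stratified_fold_sizes_at_study_scale(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([1] * 169 + [0] * 170)
        folds = [len(test) for _, test in
                 StratifiedKFold(10, shuffle=True, random_state=0).split(y[:, None], y)]
        assert sorted(folds) == [33] + [34] * 9
        for _, test in StratifiedKFold(10, shuffle=True, random_state=0).split(y[:, None], y):
            n_pos = int(y[test].sum())
            assert abs(n_pos - 169 / 10) <= 1

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(6)
        aucs = []
        for seed in range(3):
            x = rng.normal(size=(200, 5))
            y = np.array([1] * 100 + [0] * 100)
            ts = TrainingSet(x, y, tuple(f"i{i}" for i in range(200)),
                             tuple(f"f{i}" for i in range(5)), ("random",) * 200)
            aucs.append(evaluate(ts, ForestConfig(seed=seed), k=10).auc)
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1

    def test_k_exceeding_n_rejected(self):
        training = _gaussian_training(n=4, d=2)
        with pytest.raises(ValueError):
            evaluate(training, scheme="kfold", k=100)


class TestPredict:
    def test_threshold_inclusive_at_half(self):
        rec = PredictionRecord("p", 0.50, 1)
        assert rec.predicted_class == 1
        training = _gaussian_training(n=30, d=3, seed=2)
        model, _ = train_forest(training, ForestConfig(seed=0))
        vecs = _vectors(np.vstack([training.x[0], training.x[-1]]),
                        training.feature_names)
        records = predict(model, vecs)
        for rec in records:
            assert (rec.predicted_class == 1) == (rec.prediction_value >= 0.5)

    def test_empty_input(self):
        training = _gaussian_training(n=10, d=2)
        model, _ = train_forest(training, ForestConfig(seed=0))
        assert predict(model, []) == []

    def test_manifest_mismatch_rejected(self):
        training = _gaussian_training(n=10, d=2)
        model, _ = train_forest(training, ForestConfig(seed=0))
        bad = _vectors(np.zeros((1, 2)), ("other0", "other1"))
        with pytest.raises(ValueError):
            predict(model, bad)


class TestSensitivity:
    @pytest.mark.parametrize("original,mean,expected", [
        (0.89, 0.631, True),
        (0.58, 0.481, False),
    ])
    def test_conform_contract(self, original, mean, expected):
        rec = PredictionRecord("p", original, int(original >= 0.5),
                               sensitivity_mean=mean, sensitivity_variance=0.02)
        assert rec.conform is expected

    def test_deterministic_means(self):
        training = _gaussian_training(n=20, d=3, seed=5)
        test = _vectors(training.x[:4], training.feature_names, "t")
        kwargs = dict(config=ForestConfig(n_trees=20, seed=1), iterations=5,
                      fraction=0.8, seed=7)
        a = sensitivity_analysis(training, test, **kwargs)
        b = sensitivity_analysis(training, test, **kwargs)
        assert [r.sensitivity_mean for r in a] == [r.sensitivity_mean for r in b]
        assert all(r.sensitivity_variance >= 0 for r in a)

    def test_validation(self):
        training = _gaussian_training(n=10, d=2)
        with pytest.raises(ValueError):
            sensitivity_analysis(training, [], iterations=1)
        with pytest.raises(ValueError):
            sensitivity_analysis(training, [], fraction=1.5)


class TestRankAgainstRandom:
    def test_planted_pathway_outranks_random_sets(self, small_panel, small_networks,
                                                  small_common, catalog, small_caches):
        from pathcna.pathmap import map_pathway

        _, truth = small_panel
        instances = [map_pathway(pw, small_networks, small_common)
                     for pw in truth.positive_pathways + truth.negative_pathways]
        vectors = {i.instance_id: featurize(i, small_networks, catalog, small_caches)
                   for i in instances if i.eligible}
        labels = truth.labels
        pos = [v for k, v in vectors.items() if labels[k] == 1]
        neg = [v for k, v in vectors.items() if labels[k] == 0]
        training = training_set_from_vectors(pos, neg)
        model, _ = train_forest(training, ForestConfig(seed=0))
        percentiles = rank_against_random(
            model, pos[:3], small_networks, catalog, small_common,
            n_random=100, seed=0, size_max=min(18, len(small_common)),
            caches=small_caches)
        assert all(p <= 0.05 for p in percentiles.values())

    def test_minimum_sample_size(self, small_networks, small_common, catalog):
        training = _gaussian_training(n=10, d=2)
        model, _ = train_forest(training, ForestConfig(seed=0))
        with pytest.raises(ValueError):
            rank_against_random(model, [], small_networks, catalog, small_common,
                                n_random=10)


class TestFeatureTableIO:
    def test_round_trip(self, tmp_path):
        names = ("f0", "f1", "f2")
        vecs = _vectors(np.random.default_rng(0).normal(size=(4, 3)), names)
        path = tmp_path / "features.tsv"
        save_feature_table(vecs, path)
        back = load_feature_table(path)
        assert [v.instance_id for v in back] == [v.instance_id for v in vecs]
        np.testing.assert_allclose(np.vstack([v.values for v in back]),
                                   np.vstack([v.values for v in vecs]))
        assert back[0].names == names
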