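import numpy as np
import pytest
from scipy.special import expit

from pulseqc import (
    FeatureRanking,
    LabeledCorpus,
    TrainingConfig,
    TrainingError,
    UndefinedMetricError,
    ValidationError,
    compute_metrics,
    cross_validate,
    evaluate_model,
    fit_logistic_l2,
    reference_model,
    rfe_rank,
    split_corpus_by_record,
    sweep_feature_count,
    sweep_standard_length,
)
from pulseqc.standardize import SegmentSource, StandardizedSegment
from pulseqc.synthetic import (
    SyntheticConfig,
    gen_abnormal_segment,
    gen_labeled_corpus,
    gen_normal_segment,
)


def corpus_from_matrix(X, y, record_ids=None):
    segs = [
        StandardizedSegment(
            values=row,
            standard_length=X.shape[1],
            source=SegmentSource(
                record_ids[i] if record_ids is not None else "sim", 0, 1, None
            ),
        )
        for i, row in enumerate(X)
    ]
    labels = ["normal" if yi else "abnormal" for yi in y]
    return LabeledCorpus(segments=segs, labels=labels)


def threshold_corpus(n=200, L=15, seed=0):
    """Labels are a deterministic threshold on one feature, with a margin."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, L))
    col = min(4, L - 1)
    u = X[:, col]
    X[:, col] = np.where(u > 0.5, 0.6 + 0.8 * (u - 0.5), 0.8 * u)
    y = u > 0.5
    return corpus_from_matrix(X, y)


class TestComputeMetrics:
    def test_perfect_agreement(self):
        n, a = "normal", "abnormal"
        assert compute_metrics([n, n, a, a], [n, n, a, a]) == (1.0, 1.0, 1.0)

    def test_enumerated_confusion(self):
        n, a = "normal", "abnormal"
        assert compute_metrics([n, a, a, a], [n, n, a, a]) == (0.75, 0.5, 1.0)

    def test_single_class_truth_is_undefined(self):
        n = "normal"
        with pytest.raises(UndefinedMetricError):
            compute_metrics([n, n], [n, n])

    def test_accuracy_identity_on_random_confusions(self, rng):
        """accuracy == (sens*n_normal + spec*n_abnormal) / n."""
        n, a = "normal", "abnormal"
        for _ in range(50):
            truth = list(rng.choice([n, a], size=40))
            pred = list(rng.choice([n, a], size=40))
            if n not in truth or a not in truth:
                continue
            acc, sens, spec = compute_metrics(pred, truth)
            n_n = truth.count(n)
            n_a = truth.count(a)
            assert acc == pytest.approx((sens * n_n + spec * n_a) / 40)


class TestFitLogistic:
    def test_separable_toy_corpus_is_fit_perfectly(self):
        rng = np.random.default_rng(1)
        X = np.zeros((60, 15))
        y = np.arange(60) < 30
        X[:, 0] = np.where(y, 0.9, 0.1) + rng.normal(0, 0.01, 60)
        X[:, 1] = rng.uniform(size=60)
        corpus = corpus_from_matrix(X, y)
        model = fit_logistic_l2(corpus, [1, 2], l2_strength=0.01)
        probs = expit(
            model.intercept
            + model.weights[1] * X[:, 0]
            + model.weights[2] * X[:, 1]
        )
        assert np.array_equal(probs >= 0.5, y)

    def test_recovers_published_coefficients_from_simulated_labels(self):
        """Bernoulli labels from the published model are inverted by MLE."""
        ref = reference_model()
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(20_000, 15))
        z = ref.intercept + sum(ref.weights[k] * X[:, k - 1] for k in ref.weights)
        y = rng.uniform(size=20_000) < expit(z)
        fit = fit_logistic_l2(corpus_from_matrix(X, y), [1, 3, 4, 14], 1e-4)
        for k, w in ref.weights.items():
            assert np.sign(fit.weights[k]) == np.sign(w)
            assert abs(fit.weights[k] - w) / abs(w) < 0.15

    def test_empty_feature_indices(self):
        with pytest.raises(ValidationError):
            fit_logistic_l2(threshold_corpus(), [], 1.0)

    def test_single_class_corpus(self):
        X = np.random.default_rng(0).uniform(size=(30, 15))
        corpus = corpus_from_matrix(X, np.ones(30, dtype=bool))
        with pytest.raises(TrainingError):
            fit_logistic_l2(corpus, [1], 1.0)


class TestCrossValidate:
    def test_separable_corpus_has_perfect_fold_metrics(self):
        corpus = threshold_corpus(n=300)
        metrics, _ = cross_validate(
            corpus, TrainingConfig(folds=10, rng_seed=1, l2_strength=1e-3)
        )
        assert metrics.accuracy_mean == 1.0 and metrics.accuracy_sd == 0.0

    def test_deterministic_given_seed(self):
        corpus = threshold_corpus(n=120, seed=3)
        cfg = TrainingConfig(algorithm="knn", knn_neighbor_grid=(1, 3, 5),
                             folds=5, rng_seed=11)
        assert cross_validate(corpus, cfg) == cross_validate(corpus, cfg)

    def test_too_small_corpus_for_stratification(self):
        X = np.random.default_rng(0).uniform(size=(10, 15))
        corpus = corpus_from_matrix(X, np.arange(10) < 5)
        with pytest.raises(ValidationError):
            cross_validate(corpus, TrainingConfig(algorithm="knn", folds=10))

    def test_svm_grid_reports_selected_hyperparameters(self):
        corpus = threshold_corpus(n=150, seed=5)
        cfg = TrainingConfig(
            algorithm="svm_rbf", svm_cost_grid=(1.0, 10.0),
            svm_gamma_grid=(0.1, 1.0), folds=5, rng_seed=0,
        )
        metrics, params = cross_validate(corpus, cfg)
        assert set(params) == {"cost", "gamma"}
        assert 0.5 < metrics.accuracy_mean <= 1.0


class TestRFE:
    def test_single_informative_feature_ranks_first(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            X = rng.uniform(size=(300, 3))
            y = rng.uniform(size=300) < expit(6.0 * (X[:, 1] - 0.5))
            if y.all() or not y.any():
                continue
            ranking = rfe_rank(corpus_from_matrix(X, y), l2_strength=1.0)
            hits += ranking.order[0] == 2
        assert hits >= 95

    def test_two_features_give_a_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(50, 2))
        corpus = corpus_from_matrix(X, X[:, 0] > 0.5)
        ranking = rfe_rank(corpus)
        assert sorted(ranking.order) == [1, 2]

    def test_reference_model_features_occupy_top_four(self):
        ref = reference_model()
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            X = rng.uniform(size=(2000, 15))
            X[:, 0] = rng.uniform(0, 0.4, 2000)
            X[:, 13] = rng.uniform(0, 0.4, 2000)
            X[:, 2] = rng.uniform(0.5, 1, 2000)
            X[:, 3] = rng.uniform(0.5, 1, 2000)
            z = ref.intercept + sum(ref.weights[k] * X[:, k - 1] for k in ref.weights)
            y = rng.uniform(size=2000) < expit(z)
            ranking = rfe_rank(corpus_from_matrix(X, y), l2_strength=1.0)
            hits += set(ranking.order[:4]) == {1, 3, 4, 14}
        assert hits >= 18

    def test_invalid_ranking_rejected(self):
        with pytest.raises(ValidationError):
            FeatureRanking(order=(1, 1, 3))


@pytest.fixture(scope="module")
def raw_labeled():
    cfg = SyntheticConfig(rng_seed=21)
    rng = np.random.default_rng(21)
    segs, labels = [], []
    for _ in range(70):
        s, l = gen_normal_segment(cfg, rng)
        segs.append(s)
        labels.append(l)
    for _ in range(50):
        kind = rng.choice(list(cfg.anomaly_mix))
        s, l = gen_abnormal_segment(str(kind), cfg, rng)
        segs.append(s)
        labels.append(l)
    return segs, labels


class TestSweeps:
    def test_single_length_row_matches_cross_validate(self, raw_labeled):
        from pulseqc import standardize

        segs, labels = raw_labeled
        cfg = TrainingConfig(folds=5, rng_seed=2)
        table = sweep_standard_length(segs, labels, [15], cfg)
        corpus = LabeledCorpus([standardize(s, 15) for s in segs], list(labels))
        metrics, _ = cross_validate(corpus, cfg)
        assert table.loc[0, "accuracy_mean"] == metrics.accuracy_mean

    def test_very_short_length_loses_information(self, raw_labeled):
        segs, labels = raw_labeled
        cfg = TrainingConfig(folds=5, rng_seed=2)
        table = sweep_standard_length(segs, labels, [3, 15], cfg).set_index(
            "standard_length"
        )
        assert table.loc[3, "accuracy_mean"] < table.loc[15, "accuracy_mean"]

    def test_length_outside_range_rejected(self, raw_labeled):
        segs, labels = raw_labeled
        with pytest.raises(ValidationError):
            sweep_standard_length(segs, labels, [2], TrainingConfig())

    def test_full_feature_count_matches_cross_validate(self):
        corpus = threshold_corpus(n=200, L=6, seed=8)
        cfg = TrainingConfig(folds=5, rng_seed=3)
        ranking = rfe_rank(corpus)
        table = sweep_feature_count(corpus, ranking, cfg, ks=[6])
        metrics, _ = cross_validate(corpus, cfg)
        assert table.loc[0, "accuracy_mean"] == metrics.accuracy_mean

    def test_zero_features_rejected(self):
        corpus = threshold_corpus(n=60, L=3)
        ranking = rfe_rank(corpus)
        with pytest.raises(ValidationError):
            sweep_feature_count(corpus, ranking, TrainingConfig(folds=3), ks=[0])


class TestEvaluateAndSplit:
    def test_reference_model_separates_default_corpus(self, default_corpus, ref_model):
        metrics = evaluate_model(default_corpus, ref_model)
        assert metrics["accuracy"] > 0.9
        assert 0.9 < metrics["auc"] <= 1.0

    def test_record_level_split_never_straddles(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(100, 5))
        ids = [f"rec{i % 10}" for i in range(100)]
        corpus = corpus_from_matrix(X, X[:, 0] > 0.5, record_ids=ids)
        train, test = split_corpus_by_record(corpus, 0.2, rng_seed=1)
        train_ids = {s.source.record_id for s in train.segments}
        test_ids = {s.source.record_id for s in test.segments}
        assert train_ids.isdisjoint(test_ids)
        assert len(train) + len(test) == 100
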