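"""Bagged-tree training, prediction, CV mechanics and channel selection."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from fecgsqa import (
    CVScheme,
    EnsembleParams,
    classification_metrics,
    cross_validate,
    load_model,
    predict,
    save_model,
    select_channels,
    train,
)
from conftest import separable_table


class TestMetrics:
    def test_hand_computed_counts(self):
        m = classification_metrics(tp=8, fp=2, tn=7, fn=1)
        assert m["Acc"] == pytest.approx(15 / 18)
        assert m["TPR"] == pytest.approx(8 / 9)
        assert m["TNR"] == pytest.approx(7 / 9)
        assert m["PPV"] == pytest.approx(0.8)

    def test_perfect_classifier(self):
        m = classification_metrics(tp=5, fp=0, tn=5, fn=0)
        assert all(v == 1.0 for v in m.values())

    def test_undefined_ppv_is_nan(self):
        m = classification_metrics(tp=0, fp=0, tn=10, fn=2)
        assert np.isnan(m["PPV"])
        assert m["TNR"] == 1.0


class TestTrainPredict:
    def test_separable_data_training_accuracy(self):
        table = separable_table(n=300, seed=1)
        model = train(table, EnsembleParams(seed=2))
        labels, scores = predict(model, table.features)
        assert np.mean(labels == table.labels) == 1.0

    def test_unanimous_votes_give_extreme_scores(self):
        table = separable_table(n=300, seed=1, shift=20.0)
        model = train(table, EnsembleParams(seed=2, features_per_split="all"))
        _, scores = predict(model, table.features)
        assert set(np.round(scores, 6)) <= {0.0, 1.0}

    def test_determinism(self):
        table = separable_table(n=200, seed=3)
        m1 = train(table, EnsembleParams(seed=5))
        m2 = train(table, EnsembleParams(seed=5))
        _, s1 = predict(m1, table.features)
        _, s2 = predict(m2, table.features)
        assert np.array_equal(s1, s2)

    def test_degenerate_rows_forced_non_informative(self):
        table = separable_table(n=200, seed=3)
        model = train(table, EnsembleParams(seed=5))
        degenerate = np.zeros(len(table), bool)
        degenerate[:10] = True
        labels, scores = predict(model, table.features, degenerate)
        assert not labels[:10].any()
        assert np.all(scores[:10] == 0.0)

    def test_missing_feature_rejected(self):
        table = separable_table(n=100, seed=0)
        model = train(table, EnsembleParams(seed=1))
        with pytest.raises(ValueError):
            predict(model, table.features.drop(columns=["pband2"]))

    def test_feature_subset_restricts_model(self):
        table = separable_table(n=200, seed=4)
        model = train(table, EnsembleParams(seed=1),
                      feature_subset=["pband2", "seSQI", "pband4"])
        assert model.feature_names == ["pband2", "seSQI", "pband4"]
        labels, _ = predict(model, table.features)
        assert labels.shape == (200,)

    def test_empty_table_rejected(self):
        table = separable_table(n=100, seed=0)
        empty = table.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            train(empty)

    def test_model_round_trip(self, tmp_path):
        table = separable_table(n=150, seed=6)
        model = train(table, EnsembleParams(seed=7))
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        _, s1 = predict(model, table.features)
        _, s2 = predict(back, table.features)
        assert np.array_equal(s1, s2)


class TestCrossValidation:
    def test_stratified_folds_balanced(self):
        y = np.r_[np.ones(73, int), np.zeros(127, int)]
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        sizes = []
        for _, test_idx in skf.split(np.zeros((200, 1)), y):
            sizes.append(len(test_idx))
            ratio = y[test_idx].sum()
            assert abs(ratio - 7.3) <= 1.0  # within one item of global ratio
        assert max(sizes) - min(sizes) <= 1

    def test_cv_deterministic(self):
        table = separable_table(n=120, seed=8)
        scheme = CVScheme(n_folds=5, n_repeats=2, seed=9)
        r1 = cross_validate(table, EnsembleParams(seed=1, n_learners=20), scheme)
        r2 = cross_validate(table, EnsembleParams(seed=1, n_learners=20), scheme)
        assert r1.partitions.equals(r2.partitions)

    def test_too_few_rows_per_class_rejected(self):
        table = separable_table(n=12, seed=0)
        with pytest.raises(ValueError):
            cross_validate(table, scheme=CVScheme(n_folds=10))

    def test_separable_cv_is_near_perfect(self):
        table = separable_table(n=300, seed=10)
        res = cross_validate(
            table, EnsembleParams(seed=2, n_learners=30),
            CVScheme(n_folds=5, n_repeats=2, seed=3),
        )
        assert res.median("Acc") >= 0.99
        assert set(res.partitions.columns) >= {"Acc", "TPR", "TNR", "PPV", "F1"}
        assert len(res.partitions) == 10


@pytest.fixture(scope="module")
def trained_model():
    from fecgsqa import build_training_table

    table = build_training_table(3, seed=55, duration=20.0)
    return train(table, EnsembleParams(seed=1))


class TestChannelSelection:
    def test_graded_recording_selection(self, trained_model, small_recording):
        rec, gt = small_recording
        sel = select_channels(trained_model, rec)
        snr = gt.true_fetal_snr_per_channel
        strong = {i for i in range(4) if snr[i] > 10}
        hopeless = {i for i in range(4) if snr[i] < -5}
        assert strong <= set(sel.selected)
        assert not (hopeless & set(sel.selected))

    def test_vote_fraction_monotone_in_snr(self, trained_model):
        from fecgsqa import generate_recording, study_config
        from scipy.stats import spearmanr

        cfg = study_config(77, duration=30.0)
        rec, gt = generate_recording(cfg)
        sel = select_channels(trained_model, rec)
        votes = [sel.vote_fraction[ch] for ch in rec.abdominal_indices]
        rho = spearmanr(votes, gt.true_fetal_snr_per_channel).statistic
        assert rho > 0.8

    def test_short_recording_rejected(self, trained_model):
        from fecgsqa import MultichannelRecording

        rec = MultichannelRecording(np.zeros((2, 1000)), 500.0,
                                    ["abdominal", "reference"])
        with pytest.raises(ValueError):
            select_channels(trained_model, rec)

    def test_all_zero_channels_select_nothing(self, trained_model):
        from fecgsqa import MultichannelRecording

        rec = MultichannelRecording(np.zeros((3, 5000)), 500.0,
                                    ["abdominal", "abdominal", "reference"])
        sel = select_channels(trained_model, rec)
        assert sel.selected == []
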