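"""Fold construction, PCA hygiene, metric closed forms, and the CV driver."""

from __future__ import annotations

import numpy as np
import pytest

from eegcurate.classifier import TrainConfig
from eegcurate.curation import AugmentSpec
from eegcurate.evaluation import (
    PipelineConfig,
    ci95,
    fit_pca,
    make_folds,
    paired_t,
    precision_recall_f1,
    run_cv,
)
from eegcurate.labels import get_scheme
from eegcurate.synthetic import GenParams, generate_corpus


@pytest.fixture(scope="module")
def corpus20():
    return generate_corpus(
        GenParams(n_participants=20, clips_per_emotion=1, neutral_clips=1,
                  n_channels=2, trial_duration_s=2.0, seed=9)
    )


@pytest.fixture(scope="module")
def small_corpus():
    return generate_corpus(
        GenParams(n_participants=10, clips_per_emotion=3, neutral_clips=2,
                  n_channels=8, seed=77)
    )


class TestFolds:
    def test_subject_mode_balances_participants(self, corpus20):
        plan = make_folds(corpus20, mode="subject", seed=0)
        sizes = [len(plan.test_participants(f)) for f in range(5)]
        assert sizes == [4, 4, 4, 4, 4]

    def test_every_trial_tested_exactly_once(self, corpus20):
        plan = make_folds(corpus20, mode="subject", seed=1)
        real = [t for t in corpus20.trials if not t.is_synthetic]
        assert sorted(plan.assignment) == sorted((t.participant_id, t.clip_id) for t in real)
        assert set(plan.assignment.values()) == {0, 1, 2, 3, 4}

    def test_subject_mode_keeps_participants_together(self, corpus20):
        plan = make_folds(corpus20, mode="subject", seed=2)
        for (pid, _), fold in plan.assignment.items():
            assert plan.participant_folds[pid] == fold

    def test_trial_mode_balances_sizes(self, corpus20):
        plan = make_folds(corpus20, mode="trial", seed=3)
        counts = np.bincount(list(plan.assignment.values()), minlength=5)
        assert counts.max() - counts.min() <= 1

    def test_same_seed_same_plan(self, corpus20):
        a = make_folds(corpus20, mode="subject", seed=5)
        b = make_folds(corpus20, mode="subject", seed=5)
        assert a == b

    def test_too_few_participants_rejected(self, tiny_corpus):
        small = generate_corpus(
            GenParams(n_participants=4, clips_per_emotion=1, neutral_clips=1,
                      n_channels=2, trial_duration_s=2.0, seed=1)
        )
        with pytest.raises(ValueError, match="participants"):
            make_folds(small, mode="subject")


class TestPCA:
    def test_rank_bound(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 20))
        data = rng.standard_normal((50, 2)) @ basis  # exact rank 2
        pca = fit_pca(data, 0.99)
        assert pca.n_components_ <= 2

    def test_training_mean_maps_to_origin(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((30, 8)) + 5.0
        pca = fit_pca(data, 0.99)
        z = pca.transform(data.mean(axis=0, keepdims=True))
        assert np.allclose(z, 0.0, atol=1e-9)

    def test_full_variance_reconstructs(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((20, 6))
        pca = fit_pca(data, 1.0)
        recon = pca.inverse_transform(pca.transform(data))
        assert np.max(np.abs(recon - data)) <= 1e-8

    def test_invalid_keep_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((5, 3)), 0.0)


class TestMetrics:
    def test_hand_computed_binary_case(self):
        # TP=2, FP=1, FN=1 -> precision = recall = f1 = 2/3
        y_true = ["HA", "HA", "HA", "LA", "LA"]
        y_pred = ["HA", "HA", "LA", "HA", "LA"]
        m = precision_recall_f1(y_true, y_pred, get_scheme("binary"))
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(3 / 5)

    def test_perfect_predictions(self):
        y = ["happy", "sad", "anger", "neutral"]
        m = precision_recall_f1(y, y, get_scheme("seven"))
        assert m.accuracy == 1.0

    def test_absent_class_f1_is_zero(self):
        y_true = ["HAHV", "HAHV"]
        y_pred = ["HAHV", "HAHV"]
        m = precision_recall_f1(y_true, y_pred, get_scheme("quadrant"))
        assert m.per_class["LALV"]["f1"] == 0.0

    def test_matches_sklearn_on_random_vectors(self):
        # independent oracle: sklearn's classification metrics
        from sklearn.metrics import accuracy_score, f1_score

        rng = np.random.default_rng(3)
        scheme = get_scheme("quadrant")
        for _ in range(20):
            y_true = rng.choice(scheme.classes, size=30).tolist()
            y_pred = rng.choice(scheme.classes, size=30).tolist()
            m = precision_recall_f1(y_true, y_pred, scheme)
            assert m.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
            assert m.f1 == pytest.approx(
                f1_score(y_true, y_pred, labels=list(scheme.classes),
                         average="macro", zero_division=0)
            )

    def test_binary_matches_sklearn_positive_class(self):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(4)
        scheme = get_scheme("binary")
        y_true = rng.choice(["HA", "LA"], size=50, p=[0.75, 0.25]).tolist()
        y_pred = rng.choice(["HA", "LA"], size=50, p=[0.75, 0.25]).tolist()
        m = precision_recall_f1(y_true, y_pred, scheme)
        assert m.f1 == pytest.approx(f1_score(y_true, y_pred, pos_label="HA"))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1([], [], get_scheme("binary"))


class TestIntervalAndTTest:
    def test_ci95_hand_computed(self):
        # SD = 2.6, n = 5 -> 1.96 * 2.6 / sqrt(5) = 2.2790
        values = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
        values = values + np.array([-2.6, -1.3, 0.0, 1.3, 2.6]) / np.std(
            [-2.6, -1.3, 0.0, 1.3, 2.6], ddof=1
        ) * 2.6
        assert np.std(values, ddof=1) == pytest.approx(2.6)
        assert ci95(values) == pytest.approx(1.96 * 2.6 / np.sqrt(5), abs=1e-4)

    def test_zero_spread_gives_zero_width(self):
        assert ci95([0.5, 0.5, 0.5]) == 0.0

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            ci95([1.0])

    def test_paired_t_hand_computed(self):
        # differences (1..5): t = 3 / (1.5811 / sqrt(5)) = 4.2426
        b = np.zeros(5)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, p, degenerate = paired_t(a, b)
        assert not degenerate
        assert t == pytest.approx(3.0 / (np.std(a, ddof=1) / np.sqrt(5)), abs=1e-4)
        assert t == pytest.approx(4.2426, abs=1e-3)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(4.2426, df=4), abs=1e-4)

    def test_identical_vectors_flagged(self):
        t, p, degenerate = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert degenerate and p == 1.0 and t == 0.0

    def test_constant_nonzero_difference_flagged(self):
        t, p, degenerate = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert degenerate and p == 1.0


class TestRunCV:
    def _config(self, **kw):
        base = dict(
            task="binary",
            augment=AugmentSpec(kind="none"),
            cleaning_ratio=None,
            model_variant=1,
            seed=5,
            train=TrainConfig(epochs=5),
        )
        base.update(kw)
        return PipelineConfig(**base)

    def test_contract_five_folds_metrics_in_range(self, small_corpus):
        result = run_cv(small_corpus, self._config())
        assert len(result.per_fold) == 5
        for fold in result.per_fold:
            assert 0.0 <= fold["accuracy"] <= 1.0
            assert 0.0 <= fold["f1"] <= 1.0
        assert result.ci95_acc == pytest.approx(
            1.96 * result.sd_acc / np.sqrt(5), abs=1e-12
        )

    def test_gaussian_doubles_every_training_fold(self, small_corpus):
        result = run_cv(small_corpus, self._config(augment=AugmentSpec(kind="gaussian")))
        plan_sizes = [sum(f["n_test"] for f in result.per_fold)]
        n_real = len(small_corpus.trials)
        for fold, n_train in zip(result.per_fold, result.n_train_after_curation):
            assert n_train == 2 * (n_real - fold["n_test"])

    def test_subject_mode_train_test_participants_disjoint(self, small_corpus):
        # structural leakage check across all augmentation kinds
        for kind in ("none", "average", "gaussian", "time"):
            result = run_cv(small_corpus, self._config(augment=AugmentSpec(kind=kind)))
            assert len(result.per_fold) == 5  # completing without LeakageError

    def test_cleaning_shrinks_training_sets(self, small_corpus):
        full = run_cv(small_corpus, self._config())
        cleaned = run_cv(small_corpus, self._config(cleaning_ratio=0.6))
        for a, b in zip(cleaned.n_train_after_curation, full.n_train_after_curation):
            assert a < b

    def test_pca_reduces_dimensionality(self, small_corpus):
        result = run_cv(small_corpus, self._config(pca=True))
        for n in result.n_components:
            assert n < small_corpus.n_features

    def test_result_serializes(self, small_corpus, tmp_path):
        import json

        result = run_cv(small_corpus, self._config())
        path = tmp_path / "report.json"
        result.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["config"]["task"] == "binary"
        assert len(payload["per_fold"]) == 5
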