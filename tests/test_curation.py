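"""Cleaning rule and the three augmentation operators."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegcurate.core_data import Corpus, Emotion, Trial
from eegcurate.curation import (
    AugmentSpec,
    LeakageError,
    apply_curation,
    augment_average,
    augment_gaussian,
    augment_time,
    clean_by_score,
)
from eegcurate.spectral import extract_de_features


def _trial(pid=1, cid=1, emotion=Emotion.HAPPY, score=0.5, features=(0.0, 0.0)):
    return Trial(
        participant_id=pid, clip_id=cid, emotion=emotion, score=score,
        features=np.asarray(features, dtype=float),
    )


class TestCleaning:
    def test_threshold_is_strict(self):
        trials = [_trial(pid=i + 1, score=s) for i, s in enumerate((0.0, 0.2, 0.21, 0.9))]
        kept = clean_by_score(trials, 0.2)
        assert [t.score for t in kept] == [0.21, 0.9]

    def test_none_disables_filtering(self):
        trials = [_trial(pid=i + 1, score=s) for i, s in enumerate((0.0, 0.1))]
        assert clean_by_score(trials, None) == trials

    def test_high_threshold_keeps_strongest_only(self):
        trials = [_trial(pid=i + 1, score=s) for i, s in enumerate((0.96, 0.5, 0.94))]
        assert len(clean_by_score(trials, 0.95)) == 1

    def test_zero_threshold_drops_exact_zero_scores(self):
        trials = [_trial(pid=1, score=0.0), _trial(pid=2, score=0.01)]
        assert len(clean_by_score(trials, 0.0)) == 1

    def test_out_of_range_tau_rejected(self):
        with pytest.raises(ValueError, match="cleaning ratio"):
            clean_by_score([], 1.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        taus=st.tuples(st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)),
    )
    def test_monotone_in_tau(self, scores, taus):
        trials = [_trial(pid=i + 1, score=s) for i, s in enumerate(scores)]
        lo, hi = min(taus), max(taus)
        kept_lo = {t.participant_id for t in clean_by_score(trials, lo)}
        kept_hi = {t.participant_id for t in clean_by_score(trials, hi)}
        assert kept_hi <= kept_lo


class TestAverageAugmentation:
    def test_pairwise_mean(self):
        rng = np.random.default_rng(0)
        trials = [
            _trial(pid=1, score=0.4, features=(0.0, 2.0)),
            _trial(pid=2, score=0.8, features=(2.0, 0.0)),
        ]
        out = augment_average(trials, k=2, rng=rng)
        assert len(out) == 3
        syn = out[-1]
        assert syn.is_synthetic
        assert np.allclose(syn.features, (1.0, 1.0))
        assert syn.score == pytest.approx(0.6)
        assert syn.source_participants == frozenset({1, 2})

    def test_mean_of_identical_trials_is_identity(self):
        rng = np.random.default_rng(1)
        trials = [_trial(pid=i + 1, features=(3.0, -1.0)) for i in range(5)]
        out = augment_average(trials, k=5, rng=rng)
        assert np.allclose(out[-1].features, (3.0, -1.0))

    def test_window_count(self):
        rng = np.random.default_rng(2)
        trials = [_trial(pid=i + 1) for i in range(6)]
        out = augment_average(trials, k=5, rng=rng)
        assert sum(t.is_synthetic for t in out) == 6 - 5 + 1

    def test_small_classes_contribute_nothing(self):
        rng = np.random.default_rng(3)
        trials = [_trial(pid=1), _trial(pid=2, cid=2, emotion=Emotion.SAD)]
        out = augment_average(trials, k=2, rng=rng)
        assert sum(t.is_synthetic for t in out) == 0  # each class has 1 trial

    def test_labels_preserved(self):
        rng = np.random.default_rng(4)
        trials = [_trial(pid=i + 1, emotion=Emotion.FEAR) for i in range(4)]
        out = augment_average(trials, k=3, rng=rng)
        assert all(t.emotion is Emotion.FEAR for t in out)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            augment_average([], k=1, rng=np.random.default_rng(0))


class TestGaussianAugmentation:
    def test_doubles_the_set_and_preserves_labels(self):
        rng = np.random.default_rng(0)
        trials = [_trial(pid=i + 1, score=0.3 + 0.1 * i) for i in range(7)]
        out = augment_gaussian(trials, 15.0, (0.5, 1.5), rng)
        assert len(out) == 14
        for orig, copy in zip(out[:7], out[7:]):
            assert copy.is_synthetic
            assert copy.emotion is orig.emotion
            assert copy.score == orig.score
            assert copy.source_participants == orig.source_participants

    def test_monte_carlo_noise_variance(self):
        # unit-power features at 15 dB: nominal variance 10**-1.5 ~ 0.031623;
        # the uniform 0.5-1.5x modulation has mean 1, so the mean injected
        # variance over many copies approaches the nominal value.
        rng = np.random.default_rng(42)
        n_feat = 310
        base = _trial(features=np.ones(n_feat))
        trials = [base] * 10_000
        out = augment_gaussian(trials, 15.0, (0.5, 1.5), rng)
        noise = np.stack([t.features - 1.0 for t in out[10_000:]])
        per_copy_var = (noise**2).mean(axis=1)
        sigma0_sq = 10.0 ** (-1.5)
        assert per_copy_var.mean() == pytest.approx(sigma0_sq, rel=0.05)
        # per-copy variance is m * sigma0^2 * chi2_310/310 with m in [0.5, 1.5];
        # allow 4 sd of chi-square spread (sd ~ sqrt(2/310) ~ 8%) at the extremes
        assert per_copy_var.min() > 0.5 * 0.68 * sigma0_sq
        assert per_copy_var.max() < 1.5 * 1.32 * sigma0_sq

    def test_bad_modulation_rejected(self):
        with pytest.raises(ValueError):
            augment_gaussian([_trial()], 15.0, (0.0, 1.5), np.random.default_rng(0))


@pytest.fixture(scope="module")
def raw_corpus(tiny_corpus):
    return tiny_corpus


class TestTimeAugmentation:
    def test_identical_signals_average_to_identity(self, raw_corpus):
        t1 = raw_corpus.trials[0]
        pairs = [(t1.clip_id, 1, 2)]
        # graft participant 2's slot with participant 1's raw signal
        trials = []
        for t in raw_corpus.trials:
            if t.participant_id == 2 and t.clip_id == t1.clip_id:
                trials.append(
                    Trial(
                        participant_id=2, clip_id=t.clip_id, emotion=t.emotion,
                        score=t.score, features=t1.features, raw=t1.raw,
                    )
                )
            else:
                trials.append(t)
        doctored = Corpus(
            trials=trials, n_participants=raw_corpus.n_participants,
            clip_emotion_map=raw_corpus.clip_emotion_map,
            sampling_rate_hz=raw_corpus.sampling_rate_hz,
            band_spec=raw_corpus.band_spec, n_channels=raw_corpus.n_channels,
        )
        out = augment_time(doctored, {1, 2}, AugmentSpec(kind="time"), pairs=pairs)
        syn = [t for t in out if t.is_synthetic]
        assert len(syn) == 1
        assert np.allclose(syn[0].features, t1.features, atol=1e-9)

    def test_score_is_mean_of_pair(self, raw_corpus):
        cid = raw_corpus.trials[0].clip_id
        out = augment_time(raw_corpus, {1, 2}, AugmentSpec(kind="time"), pairs=[(cid, 1, 2)])
        syn = [t for t in out if t.is_synthetic][0]
        scores = {
            t.participant_id: t.score
            for t in raw_corpus.trials
            if t.clip_id == cid and t.participant_id in (1, 2)
        }
        assert syn.score == pytest.approx(0.5 * (scores[1] + scores[2]))
        assert syn.source_participants == frozenset({1, 2})

    def test_test_participant_in_pair_raises(self, raw_corpus):
        cid = raw_corpus.trials[0].clip_id
        with pytest.raises(LeakageError):
            augment_time(raw_corpus, {1, 2}, AugmentSpec(kind="time"), pairs=[(cid, 1, 6)])

    def test_matching_pair_count(self, raw_corpus):
        train = {1, 2, 3, 4, 5}
        out = augment_time(raw_corpus, train, AugmentSpec(kind="time", seed=3))
        n_clips = len(raw_corpus.clip_emotion_map)
        assert sum(t.is_synthetic for t in out) == n_clips * (len(train) // 2)
        touched = frozenset().union(*(t.source_participants for t in out))
        assert touched <= train

    def test_de_of_mean_differs_from_mean_of_de(self, raw_corpus):
        # averaging independent signals halves the variance, so the operator
        # is distinct from feature-space averaging
        cid = raw_corpus.trials[0].clip_id
        out = augment_time(raw_corpus, {1, 2}, AugmentSpec(kind="time"), pairs=[(cid, 1, 2)])
        syn = [t for t in out if t.is_synthetic][0]
        originals = {
            t.participant_id: t.features
            for t in raw_corpus.trials
            if t.clip_id == cid and t.participant_id in (1, 2)
        }
        feature_mean = 0.5 * (originals[1] + originals[2])
        assert not np.allclose(syn.features, feature_mean, atol=0.05)
        # independent equal-variance signals: DE drops by about ln(2)/2
        assert np.mean(feature_mean - syn.features) == pytest.approx(np.log(2) / 2, abs=0.1)


class TestApplyCuration:
    def test_identity_when_disabled(self, tiny_corpus):
        train = [t for t in tiny_corpus.trials if t.participant_id <= 4]
        out = apply_curation(train, tiny_corpus, AugmentSpec(kind="none"), None, {1, 2, 3, 4})
        assert out == train

    def test_gaussian_doubles(self, tiny_corpus):
        train = [t for t in tiny_corpus.trials if t.participant_id <= 4]
        out = apply_curation(train, tiny_corpus, AugmentSpec(kind="gaussian"), None, {1, 2, 3, 4})
        assert len(out) == 2 * len(train)

    def test_cleaning_runs_after_augmentation(self):
        # all member scores below tau: the synthetic mean is filtered out too
        trials = [_trial(pid=i + 1, score=0.1, features=(1.0, 1.0)) for i in range(5)]
        corpus_stub = None  # average path never touches the corpus
        out = apply_curation(
            trials, corpus_stub, AugmentSpec(kind="average", k=5), 0.2, {1, 2, 3, 4, 5}
        )
        assert out == []

    def test_foreign_trial_rejected(self, tiny_corpus):
        train = [t for t in tiny_corpus.trials if t.participant_id <= 4]
        with pytest.raises(LeakageError):
            apply_curation(train, tiny_corpus, AugmentSpec(kind="none"), None, {1, 2, 3})

    def test_label_preservation_all_operators(self, tiny_corpus):
        train = [t for t in tiny_corpus.trials if t.participant_id <= 4]
        by_key = {(t.participant_id, t.clip_id): t.emotion for t in train}
        for kind in ("average", "gaussian", "time"):
            out = apply_curation(
                train, tiny_corpus, AugmentSpec(kind=kind), None, {1, 2, 3, 4}
            )
            for t in out:
                assert t.emotion is tiny_corpus.clip_emotion_map[t.clip_id]
                if not t.is_synthetic:
                    assert t.emotion is by_key[(t.participant_id, t.clip_id)]
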