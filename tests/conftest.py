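"""Shared fixtures: small synthetic corpora sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from eegcurate.core_data import Corpus, DEFAULT_BANDS, Emotion, Trial
from eegcurate.synthetic import GenParams, generate_corpus

#: Reduced-scale generator settings for unit tests: full band structure and
#: generative model, but fewer participants/clips/channels.
TINY = GenParams(
    n_participants=6,
    clips_per_emotion=2,
    neutral_clips=2,
    n_channels=8,
    seed=123,
)


@pytest.fixture(scope="session")
def full_default_corpus() -> Corpus:
    """Full-scale default corpus (20 x 80 trials, 62 channels), features only.

    Shared between the structural checks and the recovery experiment
    (its seed is the first recovery seed).
    """
    return generate_corpus(GenParams(seed=101, keep_raw=False))


@pytest.fixture(scope="session")
def tiny_corpus() -> Corpus:
    """6 participants x 14 clips, 8 channels, raw signals kept."""
    return generate_corpus(TINY)


@pytest.fixture(scope="session")
def tiny_clean_corpus() -> Corpus:
    """Same shape as tiny_corpus but with no corrupted subpopulation."""
    return generate_corpus(
        GenParams(
            n_participants=6,
            clips_per_emotion=2,
            neutral_clips=2,
            n_channels=8,
            corrupt_frac=0.0,
            seed=321,
        )
    )


def make_manual_corpus(scores=(0.9, 0.8, 0.7, 0.6), n_channels=2) -> Corpus:
    """A hand-built 2-participant x 2-clip corpus with explicit features."""
    n_feat = n_channels * DEFAULT_BANDS.n_bands
    clip_map = {1: Emotion.HAPPY, 2: Emotion.SAD}
    trials = []
    rng = np.random.default_rng(7)
    i = 0
    for pid in (1, 2):
        for cid in (1, 2):
            trials.append(
                Trial(
                    participant_id=pid,
                    clip_id=cid,
                    emotion=clip_map[cid],
                    score=scores[i],
                    features=rng.standard_normal(n_feat),
                )
            )
            i += 1
    return Corpus(
        trials=trials,
        n_participants=2,
        clip_emotion_map=clip_map,
        sampling_rate_hz=200.0,
        n_channels=n_channels,
    )
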