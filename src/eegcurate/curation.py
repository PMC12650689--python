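"""Data curation: score-guided cleaning and label-preserving augmentation.

The data-centric core of the pipeline.  Training data is first augmented by
exactly one of three operators, then filtered by the participant's
self-report score (the *cleaning ratio* tau removes every sample with
score <= tau).  The stage order matters: synthetic samples carry scores and
are subject to cleaning like any original.

Operators (never combined within one pipeline):

* ``average`` — element-wise mean of ``k`` same-class feature vectors
  (default k=5, a sliding window over a seeded shuffle of each class);
* ``gaussian`` — zero-mean Gaussian noise at a nominal 15 dB SNR, scaled to
  each sample's signal power and randomly modulated within 0.5-1.5x,
  doubling the training set;
* ``time`` — sample-wise averaging of two training participants' raw
  responses to the same clip, followed by DE re-extraction; the synthetic
  score is the mean of the two self-reports.

All operators preserve the emotion label, are pure (inputs never mutated),
and flag their products ``is_synthetic`` with full participant provenance so
leakage checks stay enforceable downstream.  Time augmentation refuses any
pair that touches a participant outside the training set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np

from .core_data import Corpus, Trial
from .spectral import extract_de_features_batch

__all__ = [
    "AugmentSpec",
    "LeakageError",
    "clean_by_score",
    "augment_average",
    "augment_gaussian",
    "augment_time",
    "apply_curation",
]

_KINDS = ("none", "average", "gaussian", "time")


class LeakageError(RuntimeError):
    """Raised when test-participant data would enter a training pipeline."""


@dataclass(frozen=True)
class AugmentSpec:
    """Exactly one augmentation operator and its knobs."""

    kind: str = "none"
    k: int = 5
    snr_db: float = 15.0
    modulation: tuple[float, float] = (0.5, 1.5)
    pairing: str = "matching"  # or "all_pairs" (time augmentation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown augmentation kind {self.kind!r}; expected one of {_KINDS}")
        if self.k < 2:
            raise ValueError("averaging group size k must be >= 2")
        if self.modulation[0] <= 0 or self.modulation[1] < self.modulation[0]:
            raise ValueError("modulation must satisfy 0 < low <= high")
        if self.pairing not in ("matching", "all_pairs"):
            raise ValueError("pairing must be 'matching' or 'all_pairs'")


def _check_tau(tau: float | None) -> None:
    if tau is not None and not (0.0 <= tau <= 1.0):
        raise ValueError(f"cleaning ratio must lie in [0, 1] or be None, got {tau}")


def clean_by_score(trials: list[Trial], tau: float | None) -> list[Trial]:
    """Retain trials with score strictly above *tau*, preserving order.

    ``tau=None`` disables filtering entirely (distinct from ``tau=0``,
    which still drops exact-zero scores).
    """
    _check_tau(tau)
    if tau is None:
        return list(trials)
    return [t for t in trials if t.score > tau]


def augment_average(trials: list[Trial], k: int, rng: np.random.Generator) -> list[Trial]:
    """Same-class sliding-window averaging; returns originals + synthetics.

    Each class's trials are ordered by a seeded shuffle; a width-``k``
    window slides with stride 1 and each window yields one synthetic trial
    whose features and score are the member means.  Classes with fewer than
    ``k`` trials contribute no synthetics.
    """
    if k < 2:
        raise ValueError("averaging group size k must be >= 2")
    by_class: dict[object, list[Trial]] = defaultdict(list)
    for t in trials:
        by_class[t.emotion].append(t)

    synthetics: list[Trial] = []
    for emotion in sorted(by_class, key=lambda e: e.value):
        members = by_class[emotion]
        if len(members) < k:
            continue
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        for start in range(len(shuffled) - k + 1):
            group = shuffled[start : start + k]
            feats = np.mean([g.features for g in group], axis=0)
            score = float(np.mean([g.score for g in group]))
            sources = frozenset().union(*(g.source_participants for g in group))
            anchor = group[0]
            synthetics.append(
                Trial(
                    participant_id=anchor.participant_id,
                    clip_id=anchor.clip_id,
                    emotion=emotion,
                    score=score,
                    features=feats,
                    is_synthetic=True,
                    source_participants=sources,
                )
            )
    return list(trials) + synthetics


def augment_gaussian(
    trials: list[Trial],
    snr_db: float,
    modulation: tuple[float, float],
    rng: np.random.Generator,
) -> list[Trial]:
    """Add power-scaled Gaussian noise to each feature vector; doubles the set.

    Per trial, signal power ``P`` is the mean squared feature value; the
    nominal noise variance is ``P / 10**(snr_db/10)`` and is modulated by a
    uniform draw in ``modulation`` before sampling i.i.d. noise.  The copy
    keeps the original's label, score and provenance.
    """
    if not trials:
        raise ValueError("augment_gaussian requires a non-empty trial list")
    if modulation[0] <= 0:
        raise ValueError("modulation low bound must be > 0")
    copies: list[Trial] = []
    for t in trials:
        power = float(np.mean(t.features**2))
        sigma0_sq = power / (10.0 ** (snr_db / 10.0))
        m = rng.uniform(modulation[0], modulation[1])
        noise = rng.normal(0.0, np.sqrt(m * sigma0_sq), size=t.features.shape)
        copies.append(
            replace(
                t,
                features=t.features + noise,
                raw=None,
                is_synthetic=True,
                source_participants=t.source_participants,
            )
        )
    return list(trials) + copies


def _matching_pairs(
    participants: list[int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    order = rng.permutation(len(participants))
    shuffled = [participants[i] for i in order]
    return [
        (shuffled[i], shuffled[i + 1]) for i in range(0, len(shuffled) - 1, 2)
    ]


def augment_time(
    corpus: Corpus,
    train_participants: set[int],
    spec: AugmentSpec,
    fs: float | None = None,
    bands=None,
    pairs: list[tuple[int, int, int]] | None = None,
) -> list[Trial]:
    """Cross-participant raw-signal averaging; returns originals + synthetics.

    For each clip, pairs of distinct training participants who viewed it are
    formed (default: one seeded random perfect matching per clip;
    ``all_pairs`` enumerates every unordered pair).  Both raw signals are
    truncated to the shorter length (frame-level alignment), averaged
    sample-wise, and DE features re-extracted from the average.  The
    synthetic score is the mean of the two self-reports.

    An explicit ``pairs`` list of ``(clip_id, pid_a, pid_b)`` overrides the
    pairing; any member outside *train_participants* raises
    :class:`LeakageError` (hard failure, never a silent skip).
    """
    fs = corpus.sampling_rate_hz if fs is None else fs
    bands = corpus.band_spec if bands is None else bands
    rng = np.random.default_rng(spec.seed)

    by_clip: dict[int, dict[int, Trial]] = defaultdict(dict)
    originals: list[Trial] = []
    for t in corpus.trials:
        if t.is_synthetic:
            continue
        if t.participant_id in train_participants:
            originals.append(t)
            by_clip[t.clip_id][t.participant_id] = t

    if pairs is None:
        pairs = []
        for cid in sorted(by_clip):
            viewers = sorted(by_clip[cid])
            if spec.pairing == "matching":
                pairs.extend((cid, a, b) for a, b in _matching_pairs(viewers, rng))
            else:
                pairs.extend(
                    (cid, viewers[i], viewers[j])
                    for i in range(len(viewers))
                    for j in range(i + 1, len(viewers))
                )
    else:
        for cid, a, b in pairs:
            for pid in (a, b):
                if pid not in train_participants:
                    raise LeakageError(
                        f"time augmentation pair (clip {cid}: {a}, {b}) includes "
                        f"participant {pid}, who is not in the training set"
                    )

    jobs: list[tuple[Trial, Trial]] = []
    for cid, a, b in pairs:
        if a == b:
            raise ValueError("time augmentation pairs must consist of distinct participants")
        try:
            ta, tb = by_clip[cid][a], by_clip[cid][b]
        except KeyError as exc:
            raise ValueError(f"participant {exc} has no trial for clip {cid}") from None
        if ta.raw is None or tb.raw is None:
            raise ValueError("time augmentation requires raw signals in the corpus")
        jobs.append((ta, tb))

    # batch DE extraction over equal-length averaged signals
    synthetics: list[Trial] = []
    by_len: dict[int, list[tuple[Trial, Trial, np.ndarray]]] = defaultdict(list)
    for ta, tb in jobs:
        n = min(ta.raw.shape[1], tb.raw.shape[1])
        avg = 0.5 * (ta.raw[:, :n] + tb.raw[:, :n])
        by_len[n].append((ta, tb, avg))
    for n, group in sorted(by_len.items()):
        feats = extract_de_features_batch(
            np.stack([avg for _, _, avg in group]), fs, bands
        )
        for (ta, tb, avg), f in zip(group, feats):
            synthetics.append(
                Trial(
                    participant_id=ta.participant_id,
                    clip_id=ta.clip_id,
                    emotion=ta.emotion,
                    score=0.5 * (ta.score + tb.score),
                    features=f,
                    raw=avg,
                    is_synthetic=True,
                    source_participants=frozenset(
                        {ta.participant_id, tb.participant_id}
                    ),
                )
            )
    return originals + synthetics


def apply_curation(
    train_trials: list[Trial],
    corpus: Corpus,
    spec: AugmentSpec,
    tau: float | None,
    train_participants: set[int],
) -> list[Trial]:
    """Run one augmentation operator, then score cleaning, on training data.

    Returns the curated training set (originals + surviving synthetics).
    Cleaning applies *after* augmentation, so synthetics whose scores fall
    at or below tau are filtered out too.
    """
    _check_tau(tau)
    for t in train_trials:
        if t.participant_id not in train_participants:
            raise LeakageError(
                f"training trial from participant {t.participant_id} outside the "
                "declared training participants"
            )
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "none":
        augmented = list(train_trials)
    elif spec.kind == "average":
        augmented = augment_average(train_trials, spec.k, rng)
    elif spec.kind == "gaussian":
        augmented = augment_gaussian(train_trials, spec.snr_db, spec.modulation, rng)
    elif spec.kind == "time":
        augmented = augment_time(corpus, train_participants, spec)
    else:  # pragma: no cover - AugmentSpec validates kinds
        raise ValueError(f"unknown augmentation kind {spec.kind!r}")

    leaked = frozenset().union(*(t.source_participants for t in augmented)) - set(
        train_participants
    ) if augmented else frozenset()
    if leaked:
        raise LeakageError(f"curated training set draws on non-training participants {sorted(leaked)}")
    return clean_by_score(augmented, tau)
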