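"""Label schemes: seven discrete emotions, binary arousal, Russell quadrants.

The binary scheme splits on arousal: happy, disgust, fear, surprise and
anger are high-arousal (HA); sad and neutral low-arousal (LA).  The
four-quadrant scheme refines this along valence: HAHV = {happy, surprise},
HALV = {disgust, anger, fear}, LALV = {sad}, LAHV = {neutral}.  Class label
order is fixed alphabetically within each scheme so confusion matrices and
one-hot encodings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .core_data import Corpus, Emotion

__all__ = ["TaskScheme", "to_binary", "to_quadrant", "class_distribution", "get_scheme"]

_BINARY = {
    Emotion.HAPPY: "HA",
    Emotion.DISGUST: "HA",
    Emotion.FEAR: "HA",
    Emotion.SURPRISE: "HA",
    Emotion.ANGER: "HA",
    Emotion.SAD: "LA",
    Emotion.NEUTRAL: "LA",
}

_QUADRANT = {
    Emotion.HAPPY: "HAHV",
    Emotion.SURPRISE: "HAHV",
    Emotion.DISGUST: "HALV",
    Emotion.ANGER: "HALV",
    Emotion.FEAR: "HALV",
    Emotion.SAD: "LALV",
    Emotion.NEUTRAL: "LAHV",
}


def to_binary(emotion: Emotion) -> str:
    """Arousal half of the Russell plane: 'HA' or 'LA'."""
    return _BINARY[emotion]


def to_quadrant(emotion: Emotion) -> str:
    """Russell quadrant: 'HAHV', 'HALV', 'LALV' or 'LAHV'."""
    return _QUADRANT[emotion]


@dataclass(frozen=True)
class TaskScheme:
    """A named classification target with a total Emotion -> class map."""

    name: str
    classes: tuple[str, ...]
    map: Mapping[Emotion, str]

    def __post_init__(self) -> None:
        if set(self.map) != set(Emotion):
            raise ValueError("scheme map must be total over the 7 emotions")
        if set(self.map.values()) != set(self.classes):
            raise ValueError("scheme classes must equal the map's range")

    def labels_for(self, corpus_or_emotions) -> list[str]:
        emotions = (
            [t.emotion for t in corpus_or_emotions.trials]
            if isinstance(corpus_or_emotions, Corpus)
            else list(corpus_or_emotions)
        )
        return [self.map[e] for e in emotions]

    def encode(self, labels: list[str]) -> list[int]:
        index = {c: i for i, c in enumerate(self.classes)}
        return [index[lab] for lab in labels]


_SCHEMES = {
    "seven": TaskScheme(
        name="seven",
        classes=tuple(sorted(e.value for e in Emotion)),
        map={e: e.value for e in Emotion},
    ),
    "binary": TaskScheme(name="binary", classes=("HA", "LA"), map=dict(_BINARY)),
    "quadrant": TaskScheme(
        name="quadrant", classes=("HAHV", "HALV", "LAHV", "LALV"), map=dict(_QUADRANT)
    ),
}


def get_scheme(name: str) -> TaskScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown scheme {name!r}; expected one of {sorted(_SCHEMES)}"
        ) from None


def class_distribution(corpus: Corpus, scheme: TaskScheme) -> dict[str, float]:
    """Proportion of trials per class; proportions sum to 1."""
    if not corpus.trials:
        raise ValueError("cannot compute a class distribution of an empty corpus")
    counts = {c: 0 for c in scheme.classes}
    for t in corpus.trials:
        counts[scheme.map[t.emotion]] += 1
    n = len(corpus.trials)
    return {c: counts[c] / n for c in scheme.classes}
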