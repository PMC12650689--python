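"""Core domain types and canonical corpus I/O.

A *corpus* is a collection of trials: one trial per (participant, clip)
viewing event, carrying the emotion label of the clip, the participant's
self-reported emotion-intensity score in [0, 1], a differential-entropy
feature vector (``n_channels × n_bands`` values, channel-major: channel 1's
bands in ascending frequency order, then channel 2, ...), and optionally the
raw multichannel signal.

Two canonical on-disk formats are defined here:

* a CSV *table* (features + metadata, no raw signal), and
* an HDF5 *container* (raw signals + features + metadata).

An adapter for the registration-gated SEED-VII distribution is provided but
never required: all pipeline stages run on synthetic corpora.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Emotion",
    "BandSpec",
    "Trial",
    "Corpus",
    "CorpusParseError",
    "read_corpus",
    "write_corpus",
    "load_seedvii",
    "DEFAULT_BANDS",
]


class CorpusParseError(ValueError):
    """Raised when an on-disk corpus violates the canonical schema.

    The message names the offending row/field so malformed files are
    diagnosable without a debugger.
    """


class Emotion(enum.Enum):
    """The seven admissible affective states (six emotions + neutral)."""

    HAPPY = "happy"
    SAD = "sad"
    DISGUST = "disgust"
    FEAR = "fear"
    SURPRISE = "surprise"
    ANGER = "anger"
    NEUTRAL = "neutral"

    @classmethod
    def parse(cls, text: str) -> "Emotion":
        try:
            return cls(text.strip().lower())
        except ValueError:
            valid = ", ".join(e.value for e in cls)
            raise CorpusParseError(
                f"unknown emotion {text!r}; expected one of: {valid}"
            ) from None


@dataclass(frozen=True)
class BandSpec:
    """Ordered frequency bands (name, low_hz, high_hz), ascending, disjoint."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = 0.0
        prev_low = -math.inf
        for name, lo, hi in self.bands:
            if not (0.0 < lo < hi):
                raise ValueError(f"band {name!r}: need 0 < low < high, got ({lo}, {hi})")
            if lo < prev_low:
                raise ValueError("bands must be listed in ascending low_hz order")
            if lo < prev_high:
                raise ValueError(f"band {name!r} overlaps its predecessor")
            prev_low, prev_high = lo, hi

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    def edges(self) -> np.ndarray:
        return np.array([[lo, hi] for _, lo, hi in self.bands], dtype=float)


#: The SEED-family five-band convention (Hz).
DEFAULT_BANDS = BandSpec(
    bands=(
        ("delta", 1.0, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 14.0),
        ("beta", 14.0, 31.0),
        ("gamma", 31.0, 50.0),
    )
)


@dataclass(frozen=True)
class Trial:
    """One viewing event (or one synthetic augmentation product).

    ``source_participants`` records provenance: for a real trial it is
    exactly ``{participant_id}``; for a synthetic trial it is the set of
    participants whose data contributed, which downstream leakage checks
    intersect with test-fold participants.
    """

    participant_id: int
    clip_id: int
    emotion: Emotion
    score: float
    features: np.ndarray
    raw: np.ndarray | None = None
    is_synthetic: bool = False
    source_participants: frozenset[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.participant_id < 1:
            raise ValueError(f"participant_id must be >= 1, got {self.participant_id}")
        if self.clip_id < 1:
            raise ValueError(f"clip_id must be >= 1, got {self.clip_id}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(
                f"score must lie in [0, 1], got {self.score} "
                f"(participant {self.participant_id}, clip {self.clip_id})"
            )
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        object.__setattr__(self, "features", feats)
        if self.raw is not None:
            raw = np.asarray(self.raw, dtype=float)
            if raw.ndim != 2 or raw.shape[1] < 1:
                raise ValueError("raw must be a (n_channels, n_samples>=1) matrix")
            object.__setattr__(self, "raw", raw)
        if self.source_participants is None:
            object.__setattr__(
                self, "source_participants", frozenset({self.participant_id})
            )
        else:
            object.__setattr__(
                self, "source_participants", frozenset(self.source_participants)
            )
        if not self.is_synthetic and self.source_participants != frozenset(
            {self.participant_id}
        ):
            raise ValueError(
                "a non-synthetic trial's source_participants must equal "
                "{participant_id}"
            )

    def with_features(self, features: np.ndarray) -> "Trial":
        return replace(self, features=features)

    def __eq__(self, other: object) -> bool:  # array-aware equality
        if not isinstance(other, Trial):
            return NotImplemented
        same_raw = (self.raw is None) == (other.raw is None) and (
            self.raw is None or np.array_equal(self.raw, other.raw)
        )
        return (
            self.participant_id == other.participant_id
            and self.clip_id == other.clip_id
            and self.emotion is other.emotion
            and self.score == other.score
            and np.array_equal(self.features, other.features)
            and same_raw
            and self.is_synthetic == other.is_synthetic
            and self.source_participants == other.source_participants
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass
class Corpus:
    """Trials plus corpus-level metadata.

    Invariants enforced at construction: unique (participant, clip) pairs
    among non-synthetic trials; every trial's emotion matches the clip map;
    non-synthetic participant ids within ``1..n_participants``; feature
    lengths equal ``n_channels × n_bands``.
    """

    trials: list[Trial]
    n_participants: int
    clip_emotion_map: dict[int, Emotion]
    sampling_rate_hz: float
    band_spec: BandSpec = DEFAULT_BANDS
    n_channels: int = 62
    provenance: object | None = None  # generator bookkeeping; never serialized

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        expected = self.n_channels * self.band_spec.n_bands
        seen: set[tuple[int, int]] = set()
        for t in self.trials:
            if t.features.shape[0] != expected:
                raise ValueError(
                    f"trial (p{t.participant_id}, c{t.clip_id}): feature length "
                    f"{t.features.shape[0]} != n_channels×n_bands = {expected}"
                )
            if t.raw is not None and t.raw.shape[0] != self.n_channels:
                raise ValueError(
                    f"trial (p{t.participant_id}, c{t.clip_id}): raw has "
                    f"{t.raw.shape[0]} channels, corpus declares {self.n_channels}"
                )
            if t.clip_id not in self.clip_emotion_map:
                raise ValueError(f"clip {t.clip_id} missing from clip_emotion_map")
            if t.emotion is not self.clip_emotion_map[t.clip_id]:
                raise ValueError(
                    f"trial (p{t.participant_id}, c{t.clip_id}) labelled "
                    f"{t.emotion.value} but clip map says "
                    f"{self.clip_emotion_map[t.clip_id].value}"
                )
            if not t.is_synthetic:
                key = (t.participant_id, t.clip_id)
                if key in seen:
                    raise ValueError(f"duplicate non-synthetic trial {key}")
                seen.add(key)
                if not (1 <= t.participant_id <= self.n_participants):
                    raise ValueError(
                        f"participant {t.participant_id} outside 1..{self.n_participants}"
                    )

    @property
    def n_features(self) -> int:
        return self.n_channels * self.band_spec.n_bands

    def feature_matrix(self) -> np.ndarray:
        return np.stack([t.features for t in self.trials]) if self.trials else np.empty(
            (0, self.n_features)
        )

    def participants(self) -> list[int]:
        return sorted({t.participant_id for t in self.trials if not t.is_synthetic})

    def __eq__(self, other: object) -> bool:
        """Equality over serializable content (provenance excluded)."""
        if not isinstance(other, Corpus):
            return NotImplemented
        key = lambda t: (t.participant_id, t.clip_id, t.is_synthetic)
        return (
            sorted(self.trials, key=key) == sorted(other.trials, key=key)
            and self.n_participants == other.n_participants
            and self.clip_emotion_map == other.clip_emotion_map
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.band_spec == other.band_spec
            and self.n_channels == other.n_channels
        )


# ---------------------------------------------------------------------------
# canonical table (CSV) format
# ---------------------------------------------------------------------------

def _sorted_trials(corpus: Corpus) -> list[Trial]:
    return sorted(corpus.trials, key=lambda t: (t.participant_id, t.clip_id, t.is_synthetic))


def _write_table(corpus: Corpus, path: Path) -> None:
    width = corpus.n_features
    header = ["participant_id", "clip_id", "emotion", "score"] + [
        f"f_{i + 1:04d}" for i in range(width)
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for t in _sorted_trials(corpus):
            writer.writerow(
                [t.participant_id, t.clip_id, t.emotion.value, repr(t.score)]
                + [repr(float(v)) for v in t.features]
            )


def _meta_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_table_meta(corpus: Corpus, path: Path) -> None:
    import json

    meta = {
        "n_participants": corpus.n_participants,
        "n_channels": corpus.n_channels,
        "sampling_rate_hz": corpus.sampling_rate_hz,
        "bands": [[n, lo, hi] for n, lo, hi in corpus.band_spec.bands],
        "clip_emotion_map": {str(c): e.value for c, e in sorted(corpus.clip_emotion_map.items())},
    }
    _meta_sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def _read_table(path: Path) -> Corpus:
    import json

    meta_path = _meta_sidecar(path)
    if not meta_path.exists():
        raise CorpusParseError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    band_spec = BandSpec(tuple((n, float(lo), float(hi)) for n, lo, hi in meta["bands"]))
    clip_map = {int(c): Emotion.parse(e) for c, e in meta["clip_emotion_map"].items()}
    n_channels = int(meta["n_channels"])
    width = n_channels * band_spec.n_bands

    trials: list[Trial] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CorpusParseError(f"{path}: empty file, expected a header row") from None
        expected_header = ["participant_id", "clip_id", "emotion", "score"] + [
            f"f_{i + 1:04d}" for i in range(width)
        ]
        if header != expected_header:
            raise CorpusParseError(
                f"{path}: malformed header (expected {len(expected_header)} canonical "
                f"columns, got {len(header)})"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(expected_header):
                raise CorpusParseError(f"{path}:{lineno}: expected {len(expected_header)} fields")
            try:
                pid, cid = int(row[0]), int(row[1])
                emotion = Emotion.parse(row[2])
                score = float(row[3])
                feats = np.array([float(v) for v in row[4:]], dtype=float)
                trials.append(
                    Trial(participant_id=pid, clip_id=cid, emotion=emotion, score=score, features=feats)
                )
            except (ValueError, CorpusParseError) as exc:
                raise CorpusParseError(f"{path}:{lineno}: {exc}") from None
    return Corpus(
        trials=trials,
        n_participants=int(meta["n_participants"]),
        clip_emotion_map=clip_map,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        band_spec=band_spec,
        n_channels=n_channels,
    )


# ---------------------------------------------------------------------------
# canonical container (HDF5) format
# ---------------------------------------------------------------------------

def _write_container(corpus: Corpus, path: Path) -> None:
    import h5py

    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["sampling_rate_hz"] = corpus.sampling_rate_hz
        f.attrs["n_participants"] = corpus.n_participants
        f.attrs["n_channels"] = corpus.n_channels
        f.attrs["band_names"] = [n for n, _, _ in corpus.band_spec.bands]
        f.attrs["band_edges"] = corpus.band_spec.edges()
        clips = sorted(corpus.clip_emotion_map)
        f.attrs["clip_ids"] = clips
        f.attrs["clip_emotions"] = [corpus.clip_emotion_map[c].value for c in clips]
        grp = f.create_group("trials")
        for i, t in enumerate(_sorted_trials(corpus)):
            g = grp.create_group(f"t{i:06d}")
            g.attrs["participant_id"] = t.participant_id
            g.attrs["clip_id"] = t.clip_id
            g.attrs["emotion"] = t.emotion.value
            g.attrs["score"] = t.score
            g.attrs["is_synthetic"] = t.is_synthetic
            g.attrs["source_participants"] = sorted(t.source_participants)
            g.create_dataset("features", data=t.features, track_times=False)
            if t.raw is not None:
                g.create_dataset("raw", data=t.raw, track_times=False)


def _read_container(path: Path) -> Corpus:
    import h5py

    with h5py.File(path, "r") as f:
        band_spec = BandSpec(
            tuple(
                (str(n), float(lo), float(hi))
                for n, (lo, hi) in zip(f.attrs["band_names"], f.attrs["band_edges"])
            )
        )
        clip_map = {
            int(c): Emotion.parse(str(e))
            for c, e in zip(f.attrs["clip_ids"], f.attrs["clip_emotions"])
        }
        trials = []
        for key in sorted(f["trials"]):
            g = f["trials"][key]
            trials.append(
                Trial(
                    participant_id=int(g.attrs["participant_id"]),
                    clip_id=int(g.attrs["clip_id"]),
                    emotion=Emotion.parse(str(g.attrs["emotion"])),
                    score=float(g.attrs["score"]),
                    features=g["features"][()],
                    raw=g["raw"][()] if "raw" in g else None,
                    is_synthetic=bool(g.attrs["is_synthetic"]),
                    source_participants=frozenset(
                        int(p) for p in g.attrs["source_participants"]
                    ),
                )
            )
        return Corpus(
            trials=trials,
            n_participants=int(f.attrs["n_participants"]),
            clip_emotion_map=clip_map,
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            band_spec=band_spec,
            n_channels=int(f.attrs["n_channels"]),
        )


def write_corpus(corpus: Corpus, path: str | Path, format: str = "table") -> None:
    """Write *corpus* to *path* in the canonical ``table`` or ``container`` format.

    Rows/groups are emitted sorted by (participant_id, clip_id) so repeated
    writes of the same corpus are byte-identical (table format).
    """
    path = Path(path)
    if format == "table":
        _write_table(corpus, path)
        _write_table_meta(corpus, path)
    elif format == "container":
        _write_container(corpus, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'table' or 'container'")


def read_corpus(path: str | Path, format: str = "table") -> Corpus:
    """Read a corpus written by :func:`write_corpus` (loss-free round trip)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "table":
        return _read_table(path)
    if format == "container":
        return _read_container(path)
    raise ValueError(f"unknown format {format!r}; expected 'table' or 'container'")


# ---------------------------------------------------------------------------
# SEED-VII adapter (optional; the real dataset is registration-gated)
# ---------------------------------------------------------------------------

def load_seedvii(directory: str | Path) -> Corpus:
    """Read a locally supplied SEED-VII-style distribution.

    Expected layout (one plausible arrangement of the gated distribution;
    validate against your download):

    * ``<dir>/EEG_features/<participant>.mat`` — MAT files whose variables
      ``de_<clip>`` hold differential-entropy arrays shaped
      ``(62, n_windows, 5)``; features are averaged over the time axis.
    * ``<dir>/scores.csv`` — columns ``participant_id, clip_id, emotion, score``.

    The dataset itself is registration-gated and never required: every
    pipeline stage runs on synthetic corpora.
    """
    from scipy.io import loadmat

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(
            f"{directory} not found. The SEED-VII dataset is registration-gated "
            "(https://bcmi.sjtu.edu.cn/~seed/seed-vii.html) and optional; this "
            "loader only reads a copy you have already obtained."
        )
    feat_dir = directory / "EEG_features"
    scores_path = directory / "scores.csv"
    if not feat_dir.is_dir() or not scores_path.exists():
        raise FileNotFoundError(
            f"{directory} lacks EEG_features/ or scores.csv; see load_seedvii "
            "docstring for the expected layout."
        )

    scores: dict[tuple[int, int], tuple[Emotion, float]] = {}
    with open(scores_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (int(row["participant_id"]), int(row["clip_id"]))
            scores[key] = (Emotion.parse(row["emotion"]), float(row["score"]))

    trials: list[Trial] = []
    clip_map: dict[int, Emotion] = {}
    for mat_path in sorted(feat_dir.glob("*.mat")):
        pid = int(mat_path.stem)
        data = loadmat(mat_path)
        for key in sorted(k for k in data if k.startswith("de_")):
            cid = int(key[3:])
            arr = np.asarray(data[key], dtype=float)  # (channels, windows, bands)
            if arr.ndim != 3:
                raise CorpusParseError(f"{mat_path}:{key}: expected a 3-D DE array")
            feats = arr.mean(axis=1).reshape(-1)  # average over time, channel-major
            emotion, score = scores[(pid, cid)]
            clip_map[cid] = emotion
            trials.append(
                Trial(participant_id=pid, clip_id=cid, emotion=emotion, score=score, features=feats)
            )
    if not trials:
        raise CorpusParseError(f"no feature files found under {feat_dir}")
    n_bands = 5
    n_channels = trials[0].features.shape[0] // n_bands
    return Corpus(
        trials=trials,
        n_participants=max(t.participant_id for t in trials),
        clip_emotion_map=clip_map,
        sampling_rate_hz=200.0,
        band_spec=DEFAULT_BANDS,
        n_channels=n_channels,
    )
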