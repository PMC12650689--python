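"""Leakage-safe five-fold cross-validation and the reporting statistics.

The default split is *subject-level*: participants (not trials) are
partitioned into five folds, so no individual contributes to both training
and testing and cross-participant augmentation provenance can be checked by
set intersection.  A trial-level mode ("randomly divided into five folds of
equal size") is also provided; the two disagree for shared-stimulus corpora
and neither is hidden behind the other.

Per fold: the training folds are curated (augment, then clean), an optional
PCA (99% variance retention, fit on curated training features only) and a
per-feature z-score (training statistics) are applied, a CNN variant is
trained, and the *raw* test fold — never augmented, never cleaned, never
used for fitting the PCA or the scaler — is evaluated.

Statistics: accuracy; precision/recall/F1 with the high-arousal class
positive in the binary task and macro-averaged one-vs-rest F1 otherwise;
a 95% CI half-width ``1.96 * SD / sqrt(n)`` (normal approximation, sample
SD with the n-1 denominator); and two-sided paired t-tests across folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as _stats

from .classifier import ModelSpec, TrainConfig, build_model, predict as _predict, train as _train
from .core_data import Corpus, Trial
from .curation import AugmentSpec, LeakageError, apply_curation
from .labels import TaskScheme, get_scheme

__all__ = [
    "FoldPlan",
    "Metrics",
    "PipelineConfig",
    "RunResult",
    "make_folds",
    "fit_pca",
    "precision_recall_f1",
    "ci95",
    "paired_t",
    "run_cv",
]

N_FOLDS = 5


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    mode: str  # "subject" | "trial"
    assignment: dict[tuple[int, int], int]  # (participant, clip) -> fold 0..4
    participant_folds: dict[int, int] | None = None

    def test_participants(self, fold: int) -> set[int]:
        if self.participant_folds is None:
            raise ValueError("participant folds exist only in subject mode")
        return {p for p, f in self.participant_folds.items() if f == fold}


def make_folds(corpus: Corpus, mode: str = "subject", seed: int = 0) -> FoldPlan:
    """Seeded, reproducible five-fold plan over the corpus's real trials."""
    rng = np.random.default_rng(seed)
    real = [t for t in corpus.trials if not t.is_synthetic]
    if mode == "subject":
        participants = corpus.participants()
        if len(participants) < N_FOLDS:
            raise ValueError(
                f"subject-level folds need >= {N_FOLDS} participants, got {len(participants)}"
            )
        order = rng.permutation(len(participants))
        chunks = np.array_split(order, N_FOLDS)
        pfolds = {
            participants[i]: fold for fold, chunk in enumerate(chunks) for i in chunk
        }
        assignment = {(t.participant_id, t.clip_id): pfolds[t.participant_id] for t in real}
        return FoldPlan(mode="subject", assignment=assignment, participant_folds=pfolds)
    if mode == "trial":
        order = rng.permutation(len(real))
        chunks = np.array_split(order, N_FOLDS)
        assignment = {}
        for fold, chunk in enumerate(chunks):
            for i in chunk:
                t = real[i]
                assignment[(t.participant_id, t.clip_id)] = fold
        return FoldPlan(mode="trial", assignment=assignment)
    raise ValueError(f"unknown fold mode {mode!r}; expected 'subject' or 'trial'")


# ---------------------------------------------------------------------------
# PCA front-end
# ---------------------------------------------------------------------------

def fit_pca(train_features: np.ndarray, variance_keep: float = 0.99):
    """PCA retaining the smallest component count reaching *variance_keep*.

    Fit on training data only; the returned transform is then applied
    unchanged to test data.
    """
    if not (0.0 < variance_keep <= 1.0):
        raise ValueError("variance_keep must lie in (0, 1]")
    train_features = np.asarray(train_features, dtype=float)
    if train_features.shape[0] < 2:
        raise ValueError("PCA needs at least 2 training rows")
    from sklearn.decomposition import PCA

    if variance_keep == 1.0:
        pca = PCA(svd_solver="full")
    else:
        pca = PCA(n_components=variance_keep, svd_solver="full")
    pca.fit(train_features)
    return pca


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)


def _binary_counts(y_true, y_pred, positive):
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    return tp, fp, fn


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def precision_recall_f1(y_true, y_pred, scheme: TaskScheme) -> Metrics:
    """Accuracy plus precision/recall/F1 under *scheme*.

    Binary: the high-arousal class is positive.  Multiclass: one-vs-rest per
    class, with the headline F1 the macro average; a class with neither true
    nor predicted members has F1 defined as 0.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if not y_true:
        raise ValueError("cannot score empty label vectors")
    for lab in set(y_true) | set(y_pred):
        if lab not in scheme.classes:
            raise ValueError(f"label {lab!r} outside scheme {scheme.name!r}")
    accuracy = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)

    per_class: dict[str, dict[str, float]] = {}
    for cls in scheme.classes:
        tp, fp, fn = _binary_counts(y_true, y_pred, cls)
        precision, recall, f1 = _prf(tp, fp, fn)
        per_class[cls] = {
            "TP": tp, "FP": fp, "FN": fn,
            "precision": precision, "recall": recall, "f1": f1,
        }
    if scheme.name == "binary":
        stats = per_class["HA"]
        return Metrics(accuracy, stats["precision"], stats["recall"], stats["f1"], per_class)
    macro_p = float(np.mean([per_class[c]["precision"] for c in scheme.classes]))
    macro_r = float(np.mean([per_class[c]["recall"] for c in scheme.classes]))
    macro_f1 = float(np.mean([per_class[c]["f1"] for c in scheme.classes]))
    return Metrics(accuracy, macro_p, macro_r, macro_f1, per_class)


def ci95(values) -> float:
    """95% CI half-width, normal approximation: ``1.96 * SD / sqrt(n)``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("ci95 needs at least 2 values")
    return float(1.96 * values.std(ddof=1) / np.sqrt(values.size))


def paired_t(a, b) -> tuple[float, float, bool]:
    """Two-sided paired t-test; returns ``(t, p, degenerate)``.

    When every paired difference is identical the statistic is undefined;
    ``(0 or inf)`` cases are collapsed to ``(nan, 1.0, True)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_t needs two equal-length vectors of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return (0.0 if np.allclose(d, 0.0) else float("nan")), 1.0, True
    t, p = _stats.ttest_rel(a, b)
    return float(t), float(p), False


# ---------------------------------------------------------------------------
# the cross-validation driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """One cell of the experimental grid."""

    task: str = "binary"  # binary | quadrant | seven
    augment: AugmentSpec = AugmentSpec()
    cleaning_ratio: float | None = None
    pca: bool = False
    variance_keep: float = 0.99
    model_variant: int = 1
    fold_mode: str = "subject"
    seed: int = 0
    train: TrainConfig = TrainConfig()


@dataclass
class RunResult:
    per_fold: list[dict[str, float]]
    mean_acc: float
    sd_acc: float
    mean_f1: float
    sd_f1: float
    ci95_acc: float
    ci95_f1: float
    n_train_after_curation: list[int]
    n_components: list[int]
    config: PipelineConfig
    seeds: dict[str, int]

    @property
    def fold_accuracies(self) -> list[float]:
        return [f["accuracy"] for f in self.per_fold]

    @property
    def fold_f1s(self) -> list[float]:
        return [f["f1"] for f in self.per_fold]

    def to_json(self, path=None) -> str:
        payload = {
            "per_fold": self.per_fold,
            "mean_acc": self.mean_acc,
            "sd_acc": self.sd_acc,
            "mean_f1": self.mean_f1,
            "sd_f1": self.sd_f1,
            "ci95_acc": self.ci95_acc,
            "ci95_f1": self.ci95_f1,
            "n_train_after_curation": self.n_train_after_curation,
            "n_components": self.n_components,
            "seeds": self.seeds,
            "config": {
                "task": self.config.task,
                "augment": asdict(self.config.augment),
                "cleaning_ratio": self.config.cleaning_ratio,
                "pca": self.config.pca,
                "variance_keep": self.config.variance_keep,
                "model_variant": self.config.model_variant,
                "fold_mode": self.config.fold_mode,
                "seed": self.config.seed,
                "train": asdict(self.config.train),
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _encode_labels(trials: list[Trial], scheme: TaskScheme) -> np.ndarray:
    if scheme.name == "binary":
        # HA is the positive class, encoded 1
        return np.array([1 if scheme.map[t.emotion] == "HA" else 0 for t in trials])
    index = {c: i for i, c in enumerate(scheme.classes)}
    return np.array([index[scheme.map[t.emotion]] for t in trials])


def _decode_labels(indices: np.ndarray, scheme: TaskScheme) -> list[str]:
    if scheme.name == "binary":
        return ["HA" if i == 1 else "LA" for i in indices]
    return [scheme.classes[i] for i in indices]


def run_cv(corpus: Corpus, config: PipelineConfig) -> RunResult:
    """Five-fold cross-validation of one pipeline configuration.

    Raises :class:`~eegcurate.curation.LeakageError` if any curated training
    trial draws on a test participant (subject mode).
    """
    scheme = get_scheme(config.task)
    ss = np.random.SeedSequence(config.seed)
    fold_seed, curation_seed, model_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    plan = make_folds(corpus, mode=config.fold_mode, seed=fold_seed)
    real = [t for t in corpus.trials if not t.is_synthetic]

    per_fold: list[dict[str, float]] = []
    n_train_after: list[int] = []
    n_components: list[int] = []
    for fold in range(N_FOLDS):
        test_trials = [t for t in real if plan.assignment[(t.participant_id, t.clip_id)] == fold]
        train_trials = [t for t in real if plan.assignment[(t.participant_id, t.clip_id)] != fold]
        if config.fold_mode == "subject":
            train_participants = {p for p, f in plan.participant_folds.items() if f != fold}
            test_participants = plan.test_participants(fold)
        else:
            train_participants = {t.participant_id for t in train_trials}
            test_participants = set()

        aug = AugmentSpec(
            kind=config.augment.kind,
            k=config.augment.k,
            snr_db=config.augment.snr_db,
            modulation=config.augment.modulation,
            pairing=config.augment.pairing,
            seed=curation_seed + fold,
        )
        curated = apply_curation(
            train_trials, corpus, aug, config.cleaning_ratio, train_participants
        )
        if config.fold_mode == "subject":
            touched = frozenset().union(
                *(t.source_participants for t in curated)
            ) if curated else frozenset()
            if touched & test_participants:
                raise LeakageError(
                    f"fold {fold}: curated training set touches test participants "
                    f"{sorted(touched & test_participants)}"
                )
        if not curated:
            raise ValueError(
                f"fold {fold}: cleaning ratio {config.cleaning_ratio} removed every training trial"
            )

        X_train = np.stack([t.features for t in curated])
        y_train = _encode_labels(curated, scheme)
        X_test = np.stack([t.features for t in test_trials])
        y_test_labels = [scheme.map[t.emotion] for t in test_trials]

        if config.pca:
            pca = fit_pca(X_train, config.variance_keep)
            X_train = pca.transform(X_train)
            X_test = pca.transform(X_test)
            n_components.append(int(pca.n_components_))
        else:
            n_components.append(X_train.shape[1])

        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd

        spec = ModelSpec(
            variant=config.model_variant,
            n_classes=len(scheme.classes),
            input_dim=X_train.shape[1],
        )
        model = build_model(spec, seed=model_seed + fold)
        cfg = TrainConfig(
            epochs=config.train.epochs,
            learning_rate=config.train.learning_rate,
            batch_size=config.train.batch_size,
            seed=model_seed + 1000 + fold,
        )
        _train(model, X_train, y_train, cfg)
        pred_idx, _ = _predict(model, X_test)
        metrics = precision_recall_f1(y_test_labels, _decode_labels(pred_idx, scheme), scheme)
        per_fold.append(
            {
                "fold": fold,
                "accuracy": metrics.accuracy,
                "f1": metrics.f1,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "n_test": len(test_trials),
            }
        )
        n_train_after.append(len(curated))

    accs = np.array([f["accuracy"] for f in per_fold])
    f1s = np.array([f["f1"] for f in per_fold])
    return RunResult(
        per_fold=per_fold,
        mean_acc=float(accs.mean()),
        sd_acc=float(accs.std(ddof=1)),
        mean_f1=float(f1s.mean()),
        sd_f1=float(f1s.std(ddof=1)),
        ci95_acc=ci95(accs),
        ci95_f1=ci95(f1s),
        n_train_after_curation=n_train_after,
        n_components=n_components,
        config=config,
        seeds={"fold": fold_seed, "curation": curation_seed, "model": model_seed},
    )
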