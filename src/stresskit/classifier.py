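"""Two-feature linear stress classifier trained by stochastic gradient descent.

Minute blocks are labeled non-stress (baseline) or stress (speech task;
optionally also the arithmetic task for held-out evaluation), split
75:25 stratified by label at block level, standardized on training
statistics, and fit with an SGD linear model (hinge loss, L2 penalty,
'optimal' learning-rate schedule). The model's bias term can be shifted
after training to trade hit rate against false-alarm rate.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import SGDClassifier

from .pulse import FeatureVector
from .session import Phase

__all__ = [
    "LabeledSample",
    "LinearStressModel",
    "SplitSpec",
    "CVResult",
    "label_blocks",
    "split_dataset",
    "train_sgd",
    "cross_validate",
    "predict",
    "decision_scores",
    "adjust_bias",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

NON_STRESS = 0
STRESS = 1


@dataclass(frozen=True)
class LabeledSample:
    """One minute block's features with its phase-derived class label."""

    dhr: float
    deda: float
    label: int
    participant_id: str
    phase: Phase

    def __post_init__(self) -> None:
        if self.label not in (NON_STRESS, STRESS):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class LinearStressModel:
    """Linear decision rule on standardized (dhr, deda) features.

    The decision score is ``w_hr * x1 + w_eda * x2 + bias`` where
    ``x_i = (raw_i - center_i) / scale_i``; label 1 (stress) iff the
    score is strictly positive.
    """

    w_hr: float
    w_eda: float
    bias: float
    center: tuple[float, float]
    scale: tuple[float, float]
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale[0] <= 0 or self.scale[1] <= 0:
            raise ValueError(f"feature scales must be positive, got {self.scale}")


@dataclass(frozen=True)
class SplitSpec:
    """Train fraction, fold count, and seed for dataset partitioning."""

    train_fraction: float = 0.75
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction <= 1:
            raise ValueError(f"train_fraction must be in (0, 1], got {self.train_fraction}")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float


def label_blocks(
    features: Sequence[FeatureVector], include_tsst_a: bool = False
) -> list[LabeledSample]:
    """Assign class labels by phase.

    Baseline -> non-stress (0); speech task -> stress (1); arithmetic
    task -> stress only when ``include_tsst_a`` (evaluation use);
    anticipation minutes are always excluded.
    """
    out: list[LabeledSample] = []
    for f in features:
        if f.phase is Phase.BASELINE:
            label = NON_STRESS
        elif f.phase is Phase.TSST_S:
            label = STRESS
        elif f.phase is Phase.TSST_A and include_tsst_a:
            label = STRESS
        else:
            continue
        out.append(LabeledSample(f.dhr, f.deda, label, f.participant_id, f.phase))
    return out


def split_dataset(
    samples: Sequence[LabeledSample], spec: SplitSpec
) -> tuple[list[LabeledSample], list[LabeledSample]]:
    """Seeded stratified-by-label random split at block level."""
    samples = list(samples)
    if spec.train_fraction == 1.0:
        return samples, []
    labels = {s.label for s in samples}
    if labels != {NON_STRESS, STRESS}:
        raise ValueError(f"both classes required for a split, got labels {sorted(labels)}")
    rng = np.random.default_rng(spec.seed)
    train: list[LabeledSample] = []
    test: list[LabeledSample] = []
    for label in (NON_STRESS, STRESS):
        idx = [i for i, s in enumerate(samples) if s.label == label]
        if len(idx) < 2:
            raise ValueError(f"need >= 2 samples of class {label} to split")
        perm = rng.permutation(len(idx))
        n_train = int(round(spec.train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        chosen = [idx[j] for j in perm]
        train.extend(samples[i] for i in sorted(chosen[:n_train]))
        test.extend(samples[i] for i in sorted(chosen[n_train:]))
    return train, test


def _design_matrix(samples: Sequence[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[s.dhr, s.deda] for s in samples], dtype=float)
    y = np.array([s.label for s in samples], dtype=int)
    return X, y


def train_sgd(
    train: Sequence[LabeledSample],
    seed: int = 0,
    epochs: int = 1000,
    l2: float = 1e-4,
    loss: str = "hinge",
) -> LinearStressModel:
    """Fit the linear model: standardize on training statistics, then SGD.

    Defaults follow a standard SGD linear classifier: hinge loss, L2
    penalty 1e-4, 'optimal' learning-rate schedule, per-epoch shuffling
    seeded for bit-reproducible refits. ``loss`` may be ``"hinge"`` or
    ``"log_loss"``.
    """
    if loss not in ("hinge", "log_loss"):
        raise ValueError(f"unsupported loss {loss!r}")
    X, y = _design_matrix(train)
    if X.shape[0] == 0 or len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.any(scale <= 0):
        feat = ["dhr", "deda"][int(np.argmin(scale))]
        raise ValueError(f"zero-variance training feature {feat!r}")
    Xs = (X - center) / scale
    clf = SGDClassifier(
        loss=loss,
        penalty="l2",
        alpha=l2,
        max_iter=epochs,
        tol=None,
        learning_rate="optimal",
        shuffle=True,
        random_state=seed,
        fit_intercept=True,
    )
    clf.fit(Xs, y)
    return LinearStressModel(
        w_hr=float(clf.coef_[0, 0]),
        w_eda=float(clf.coef_[0, 1]),
        bias=float(clf.intercept_[0]),
        center=(float(center[0]), float(center[1])),
        scale=(float(scale[0]), float(scale[1])),
        hyperparams={"loss": loss, "l2": l2, "epochs": epochs, "seed": seed},
    )


def decision_scores(model: LinearStressModel, X: np.ndarray) -> np.ndarray:
    """Decision scores for raw-feature rows ``[dhr, deda]``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    Xs = (X - np.asarray(model.center)) / np.asarray(model.scale)
    return Xs @ np.array([model.w_hr, model.w_eda]) + model.bias


def predict(
    model: LinearStressModel, features: tuple[float, float]
) -> tuple[int, float]:
    """Classify one (dhr, deda) pair; score 0 ties break to non-stress."""
    score = float(decision_scores(model, np.asarray(features))[0])
    return (STRESS if score > 0 else NON_STRESS), score


def predict_samples(
    model: LinearStressModel, samples: Sequence[LabeledSample]
) -> np.ndarray:
    X, _ = _design_matrix(samples)
    return (decision_scores(model, X) > 0).astype(int)


def _accuracy(model: LinearStressModel, samples: Sequence[LabeledSample]) -> float:
    _, y = _design_matrix(samples)
    return float(np.mean(predict_samples(model, samples) == y))


def cross_validate(
    train: Sequence[LabeledSample],
    n_folds: int = 5,
    seed: int = 0,
    epochs: int = 1000,
    l2: float = 1e-4,
    loss: str = "hinge",
) -> CVResult:
    """Seeded shuffled k-fold cross-validation at block level.

    Each of the near-equal folds is held out once; fold accuracy is the
    fraction correct on the held-out fold under a model trained on the
    complement. Raises when a training complement lacks both classes.
    """
    samples = list(train)
    if len(samples) < n_folds:
        raise ValueError(f"need >= {n_folds} samples for {n_folds}-fold CV, got {len(samples)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    folds = np.array_split(order, n_folds)
    accuracies = []
    for k, held in enumerate(folds):
        held_set = set(held.tolist())
        fit = [samples[i] for i in range(len(samples)) if i not in held_set]
        if len({s.label for s in fit}) < 2:
            raise ValueError(f"fold {k}: training complement lacks both classes")
        model = train_sgd(fit, seed=seed, epochs=epochs, l2=l2, loss=loss)
        accuracies.append(_accuracy(model, [samples[i] for i in held]))
    return CVResult(tuple(accuracies), float(np.mean(accuracies)))


def adjust_bias(model: LinearStressModel, delta: float) -> LinearStressModel:
    """Copy of the model with the decision bias shifted by ``delta``."""
    return dataclasses.replace(model, bias=model.bias + delta)


def save_model(model: LinearStressModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "w_hr": model.w_hr,
        "w_eda": model.w_eda,
        "bias": model.bias,
        "center": list(model.center),
        "scale": list(model.scale),
        "hyperparams": model.hyperparams,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path) -> LinearStressModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return LinearStressModel(
        w_hr=float(payload["w_hr"]),
        w_eda=float(payload["w_eda"]),
        bias=float(payload["bias"]),
        center=tuple(payload["center"]),
        scale=tuple(payload["scale"]),
        hyperparams=dict(payload.get("hyperparams", {})),
    )
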