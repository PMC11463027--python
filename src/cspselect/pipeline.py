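"""The classification pipeline: band-pass -> channel subset -> per-split
CSP + linear discriminant -> mean cross-validated accuracy.

The same stratified splits (fixed by the CV seed and the session's labels)
are reused for every channel subset and variant, so accuracy comparisons
between subsets share folds. The discriminant is a two-class Fisher
discriminant with pooled covariance and equal priors; a trial exactly on
the decision boundary is assigned the first class in label-sorted order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .csp import CSPModel, apply_csp, class_covariances, fit_csp
from .exceptions import ValidationError
from .io import ChannelSubset, EpochSet, Montage16, subset_channels
from .preprocess import FilterSpec, bandpass

__all__ = [
    "CVConfig",
    "AccuracyResult",
    "crossval_accuracy",
    "baseline_bfull",
    "baseline_b16",
    "transfer_accuracy",
    "percentage_change",
]


@dataclass(frozen=True)
class CVConfig:
    """Stratified k-fold configuration; splits are a pure function of
    (labels, n_splits, seed)."""

    n_splits: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValidationError("n_splits must be >= 2")
        if not self.stratified:
            raise ValidationError("only stratified splitting is supported")

    def splits(self, labels: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        labels = np.asarray(labels).astype(str)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < self.n_splits:
            raise ValidationError(
                f"smallest class has {counts.min()} trials; cannot build "
                f"{self.n_splits} stratified folds"
            )
        skf = StratifiedKFold(
            n_splits=self.n_splits, shuffle=True, random_state=self.seed
        )
        out = []
        for train, test in skf.split(np.zeros(labels.size), labels):
            if min(np.unique(labels[train], return_counts=True)[1]) < 2:
                raise ValidationError("a training fold has < 2 trials in a class")
            out.append((train, test))
        return out


@dataclass(frozen=True)
class AccuracyResult:
    """Cross-validated accuracy of one channel subset on one session.

    `correct`/`total` are pooled over folds and feed the beta-binomial
    evaluation; `per_trial_correct` is ordered by original trial index.
    """

    subset: ChannelSubset
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    correct: int
    total: int
    per_trial_correct: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.mean_accuracy <= 1 or self.correct > self.total:
            raise ValidationError("inconsistent accuracy bookkeeping")


class FisherLDA:
    """Two-class Fisher discriminant, pooled covariance, equal priors."""

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "FisherLDA":
        labels = np.asarray(labels).astype(str)
        self.classes_ = np.unique(labels)
        if self.classes_.size != 2:
            raise ValidationError("FisherLDA requires exactly two classes")
        x0 = features[labels == self.classes_[0]]
        x1 = features[labels == self.classes_[1]]
        if len(x0) < 2 or len(x1) < 2:
            raise ValidationError("each class needs >= 2 training trials")
        mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
        s0 = (x0 - mu0).T @ (x0 - mu0)
        s1 = (x1 - mu1).T @ (x1 - mu1)
        pooled = (s0 + s1) / (len(x0) + len(x1) - 2)
        ridge = 1e-10 * (np.trace(pooled) / pooled.shape[0] + 1.0)
        pooled = pooled + ridge * np.eye(pooled.shape[0])
        self.weights_ = np.linalg.solve(pooled, mu1 - mu0)
        self.threshold_ = float(self.weights_ @ (mu0 + mu1) / 2)
        return self

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        return features @ self.weights_ - self.threshold_

    def predict(self, features: np.ndarray) -> np.ndarray:
        # strictly positive -> second class; boundary ties -> first class
        return np.where(
            self.decision_function(features) > 0, self.classes_[1], self.classes_[0]
        )


def _fit_fold(
    train: EpochSet, n_components: int, shrinkage: float
) -> tuple[CSPModel, FisherLDA]:
    covs = class_covariances(train, shrinkage=shrinkage)
    model = fit_csp(covs, n_components=n_components)
    lda = FisherLDA().fit(apply_csp(model, train), train.labels)
    return model, lda


def crossval_accuracy(
    epochs: EpochSet,
    subset: ChannelSubset | None = None,
    cv: CVConfig = CVConfig(),
    filter_spec: FilterSpec | None = FilterSpec(),
    n_components: int = 8,
    shrinkage: float = 0.0,
) -> AccuracyResult:
    """Mean cross-validated accuracy of CSP + Fisher LDA on `subset`.

    `subset=None` means all channels. `filter_spec=None` skips filtering
    (for callers that band-pass a session once up front; filtering is
    per-channel, so it commutes with channel subsetting). Deterministic
    given (epochs, subset, cv.seed).
    """
    work = subset_channels(epochs, subset) if subset is not None else epochs
    if subset is None:
        subset = ChannelSubset(work.ch_names)
    if n_components > work.n_channels:
        raise ValidationError(
            f"n_components={n_components} exceeds subset size {work.n_channels}"
        )
    if filter_spec is not None:
        work = bandpass(work, filter_spec)

    per_trial = np.zeros(work.n_trials, dtype=bool)
    fold_accs = []
    for train_idx, test_idx in cv.splits(work.labels):
        model, lda = _fit_fold(work.select_trials(train_idx), n_components, shrinkage)
        feats = apply_csp(model, work.select_trials(test_idx))
        pred = lda.predict(feats)
        ok = pred == work.labels[test_idx].astype(str)
        per_trial[test_idx] = ok
        fold_accs.append(float(np.mean(ok)))
    return AccuracyResult(
        subset=subset,
        fold_accuracies=tuple(fold_accs),
        mean_accuracy=float(np.mean(fold_accs)),
        correct=int(per_trial.sum()),
        total=int(per_trial.size),
        per_trial_correct=tuple(bool(b) for b in per_trial),
    )


def baseline_bfull(
    epochs: EpochSet,
    cv: CVConfig = CVConfig(),
    filter_spec: FilterSpec | None = FilterSpec(),
    n_components: int = 8,
    shrinkage: float = 0.0,
) -> AccuracyResult:
    """Baseline over all electrodes of the session (BFull)."""
    return crossval_accuracy(
        epochs, None, cv, filter_spec, n_components, shrinkage
    )


def baseline_b16(
    epochs: EpochSet,
    montage: Montage16 = Montage16(),
    cv: CVConfig = CVConfig(),
    filter_spec: FilterSpec | None = FilterSpec(),
    n_components: int = 8,
    shrinkage: float = 0.0,
) -> AccuracyResult:
    """Baseline restricted to a fixed 16-electrode montage (B16)."""
    return crossval_accuracy(
        epochs, montage.as_subset(), cv, filter_spec, n_components, shrinkage
    )


def transfer_accuracy(
    train: EpochSet,
    test: EpochSet,
    subset: ChannelSubset | None = None,
    filter_spec: FilterSpec | None = FilterSpec(),
    n_components: int = 8,
    shrinkage: float = 0.0,
) -> AccuracyResult:
    """Fit on one whole session, score another (cross-session transfer).

    Used to ask whether a combination selected on one session still helps
    on a later session of the same subject.
    """
    tr = subset_channels(train, subset) if subset is not None else train
    te = subset_channels(test, subset) if subset is not None else test
    if subset is None:
        if tr.ch_names != te.ch_names:
            raise ValidationError("train/test channel sets differ")
        subset = ChannelSubset(tr.ch_names)
    if filter_spec is not None:
        tr, te = bandpass(tr, filter_spec), bandpass(te, filter_spec)
    model, lda = _fit_fold(tr, n_components, shrinkage)
    pred = lda.predict(apply_csp(model, te))
    ok = pred == te.labels.astype(str)
    acc = float(np.mean(ok))
    return AccuracyResult(
        subset=subset,
        fold_accuracies=(acc,),
        mean_accuracy=acc,
        correct=int(ok.sum()),
        total=int(ok.size),
        per_trial_correct=tuple(bool(b) for b in ok),
    )


def percentage_change(acc: float, base: float) -> float:
    """Per-subject effect measure: 100 * (acc - base) / base."""
    if base <= 0:
        raise ValidationError(f"baseline accuracy must be positive, got {base}")
    return 100.0 * (acc - base) / base
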