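"""Pattern-threshold electrode extraction from fitted CSP models.

The selection rule inspects the CSP *patterns* (mixing-matrix rows): an
electrode e is kept for a pattern p when

    |e_p - mean(p)| > theta * sigma(p),

with theta = 1.5 by default and sigma the standard deviation over all
electrode values of the pattern (population convention by default; the
n-1 convention is a config switch). The per-component selections over the
first 8 patterns are unioned into one combination.

Applied per cross-validation split: each split's training data yields one
combination; the deduplicated combinations with more than 2 electrodes are
each scored with the full cross-validated pipeline, and the best one is
returned. Extraction never sees test-fold data, but candidate scoring
re-runs cross-validation on the same session — the optimistic bias this
introduces is inherent to the procedure and is why cross-session transfer
checks exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csp import CSPModel, class_covariances, fit_csp
from .exceptions import NoCandidatesError, ValidationError
from .io import ChannelSubset, EpochSet, resolve_channels, subset_channels
from .pipeline import AccuracyResult, CVConfig, crossval_accuracy
from .preprocess import FilterSpec, bandpass

__all__ = [
    "SelectionConfig",
    "select_electrodes_from_pattern",
    "extract_combination",
    "approach2_best",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Threshold-selection settings.

    theta : threshold multiplier on the pattern's standard deviation.
    n_patterns : how many leading CSP components to inspect.
    min_electrodes : smallest combination worth evaluating ("more than 2
        electrodes" -> 3).
    sample_sd : use the n-1 standard-deviation convention instead of the
        population one.
    """

    theta: float = 1.5
    n_patterns: int = 8
    min_electrodes: int = 3
    sample_sd: bool = False

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValidationError(f"theta must be positive, got {self.theta}")
        if self.n_patterns < 1:
            raise ValidationError("n_patterns must be >= 1")
        if self.min_electrodes < 1:
            raise ValidationError("min_electrodes must be >= 1")


def select_electrodes_from_pattern(
    pattern: np.ndarray,
    ch_names: tuple[str, ...],
    theta: float = 1.5,
    sample_sd: bool = False,
) -> set[str]:
    """Channels whose pattern value deviates from the pattern mean by more
    than theta standard deviations.

    Invariant to affine transforms of the pattern (a*p + b, a != 0). A
    constant pattern selects nothing (sd = 0, strict inequality).
    """
    p = np.asarray(pattern, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValidationError("pattern must be a vector of length >= 2")
    if p.size != len(ch_names):
        raise ValidationError(
            f"pattern length {p.size} != {len(ch_names)} channel names"
        )
    sd = p.std(ddof=1 if sample_sd else 0)
    keep = np.abs(p - p.mean()) > theta * sd
    return {ch_names[i] for i in np.flatnonzero(keep)}


def extract_combination(
    model: CSPModel, cfg: SelectionConfig = SelectionConfig()
) -> ChannelSubset | None:
    """Union the per-pattern selections of the leading components.

    Returns the combination in the model's channel order, or None when
    every inspected pattern is (near-)constant and nothing is selected.
    """
    n = min(cfg.n_patterns, model.n_components)
    selected: set[str] = set()
    for i in range(n):
        selected |= select_electrodes_from_pattern(
            model.patterns[i], model.ch_names, cfg.theta, cfg.sample_sd
        )
    if not selected:
        return None
    return ChannelSubset(tuple(c for c in model.ch_names if c in selected))


def approach2_best(
    session: EpochSet,
    cv: CVConfig = CVConfig(),
    filter_spec: FilterSpec | None = FilterSpec(),
    n_components: int = 8,
    cfg: SelectionConfig = SelectionConfig(),
    base: ChannelSubset | None = None,
    shrinkage: float = 0.0,
) -> tuple[ChannelSubset, AccuracyResult, list[ChannelSubset]]:
    """Per-split extraction plus best-accuracy combination selection.

    `base` chooses the montage the CSP is fit on before extraction: None
    uses all channels of the session (AlgoFull-style), a 16-channel
    subset gives the Algo16-style variant. The same CV splits drive
    extraction and candidate scoring, making the whole procedure a
    deterministic function of (session, seeds, config).

    Raises
    ------
    NoCandidatesError
        When every extracted combination has fewer than
        `cfg.min_electrodes` electrodes; callers fall back to a baseline.
    """
    work = subset_channels(session, base) if base is not None else session
    if filter_spec is not None:
        work = bandpass(work, filter_spec)

    candidates: list[ChannelSubset] = []
    seen: set[tuple[str, ...]] = set()
    fit_components = min(cfg.n_patterns, n_components, work.n_channels)
    for train_idx, _ in cv.splits(work.labels):
        covs = class_covariances(work.select_trials(train_idx), shrinkage=shrinkage)
        model = fit_csp(covs, n_components=fit_components)
        combo = extract_combination(model, cfg)
        if combo is not None and combo.names not in seen:
            seen.add(combo.names)
            candidates.append(combo)

    evaluable = [c for c in candidates if len(c) >= cfg.min_electrodes]
    if not evaluable:
        raise NoCandidatesError(
            f"no extracted combination has >= {cfg.min_electrodes} electrodes "
            f"(candidates: {[c.names for c in candidates]})"
        )
    scored = [
        (
            c,
            crossval_accuracy(work, c, cv, None, min(n_components, len(c))),
        )
        for c in evaluable
    ]
    best, best_result = min(
        scored,
        key=lambda ca: (
            -ca[1].mean_accuracy,
            len(ca[0]),
            tuple(int(i) for i in resolve_channels(work.ch_names, ca[0])),
        ),
    )
    return best, best_result, evaluable
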