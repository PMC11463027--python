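"""Exhaustive electrode-subset search with t-test significance selection.

Every subset of a fixed montage with at least `min_size` electrodes is run
through the cross-validated pipeline on every subject. For each subset the
per-subject percentage changes against that subject's fixed-montage
baseline are tested with a one-sided one-sample t-test

    H0: mu <= 0    vs.    Ha: mu > 0,    alpha = 5%,

and subsets rejecting H0 are flagged as generalizing across subjects. No
multiple-testing correction is applied across the enumerated family (a
Benjamini-Hochberg report is available as an explicit deviation switch);
under a no-signal cohort each subset's rejection rate is therefore the
nominal alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .io import ChannelSubset, EpochSet, Montage16, resolve_channels
from .pipeline import (
    AccuracyResult,
    CVConfig,
    crossval_accuracy,
    percentage_change,
)
from .preprocess import FilterSpec, bandpass

__all__ = [
    "TTestConfig",
    "CombinationResult",
    "enumerate_subsets",
    "one_sided_ttest",
    "search_combinations",
    "best_per_subject",
    "benjamini_hochberg_flags",
]


@dataclass(frozen=True)
class TTestConfig:
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class CombinationResult:
    """One electrode subset with its across-subject evidence."""

    subset: ChannelSubset
    per_subject_pct_change: tuple[float, ...]
    mean_pct_change: float
    p_value: float
    significant: bool


def enumerate_subsets(
    montage: Montage16 | ChannelSubset, min_size: int
) -> list[ChannelSubset]:
    """All subsets with >= `min_size` electrodes, in canonical order.

    Canonical order: size ascending, then lexicographic by montage index;
    each subset keeps montage order internally.
    """
    names = montage.names
    if not 1 <= min_size <= len(names):
        raise ValidationError(
            f"min_size must be in [1, {len(names)}], got {min_size}"
        )
    out = []
    for size in range(min_size, len(names) + 1):
        for combo in itertools.combinations(names, size):
            out.append(ChannelSubset(combo))
    return out


def one_sided_ttest(changes, cfg: TTestConfig = TTestConfig()) -> float:
    """Upper-tail p of the one-sample t-test of H0: mean <= 0.

    Sample sd (n-1 denominator), t with n-1 degrees of freedom. A
    degenerate all-identical sample yields p = 0 when the common value is
    positive and p = 1 otherwise.
    """
    x = np.asarray(changes, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values for the t-test")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0 if x[0] > 0 else 1.0
    t = x.mean() / (sd / np.sqrt(x.size))
    return float(stats.t.sf(t, df=x.size - 1))


def search_combinations(
    sessions: list[EpochSet],
    montage: Montage16 | ChannelSubset = Montage16(),
    min_size: int = 8,
    cv: CVConfig = CVConfig(),
    filter_spec: FilterSpec | None = FilterSpec(),
    n_components: int = 8,
    cfg: TTestConfig = TTestConfig(),
    accuracy_cache: dict[tuple[str, ...], list[AccuracyResult]] | None = None,
) -> list[CombinationResult]:
    """Run the full subset sweep over a cohort (one session per subject).

    Per subject the session is band-passed once and the montage baseline
    computed once; every enumerated subset is then cross-validated with
    the same folds and scored as a percentage change against that
    subject's baseline. If `accuracy_cache` is a dict it is filled with
    subset-names -> per-subject AccuracyResult, letting callers build
    per-subject-best variants without re-running the sweep.
    """
    if not sessions:
        raise ValidationError("empty cohort")
    for s in sessions:
        resolve_channels(s.ch_names, montage.names)
    subsets = enumerate_subsets(montage, min_size)
    filtered = [
        bandpass(s, filter_spec) if filter_spec is not None else s for s in sessions
    ]
    baselines = [
        crossval_accuracy(s, ChannelSubset(montage.names), cv, None, n_components)
        for s in filtered
    ]
    results = []
    for subset in subsets:
        accs = [
            crossval_accuracy(
                s, subset, cv, None, min(n_components, len(subset))
            )
            for s in filtered
        ]
        if accuracy_cache is not None:
            accuracy_cache[subset.names] = accs
        changes = tuple(
            percentage_change(a.mean_accuracy, b.mean_accuracy)
            for a, b in zip(accs, baselines)
        )
        p = one_sided_ttest(changes, cfg)
        results.append(
            CombinationResult(
                subset=subset,
                per_subject_pct_change=changes,
                mean_pct_change=float(np.mean(changes)),
                p_value=p,
                significant=p < cfg.alpha,
            )
        )
    return results


def benjamini_hochberg_flags(
    results: list[CombinationResult], alpha: float = 0.05
) -> list[bool]:
    """FDR-corrected significance flags for a finished search.

    Off the main path: the reproduced methodology tests each combination
    at alpha with no correction, so this is an explicit deviation switch
    for users who want family-wise control over the enumerated subsets.
    """
    if not results:
        raise ValidationError("empty result list")
    adjusted = stats.false_discovery_control(
        [r.p_value for r in results], method="bh"
    )
    return [float(q) < alpha for q in adjusted]


def _canonical_key(subset: ChannelSubset, ch_names: tuple[str, ...]) -> tuple[int, ...]:
    return tuple(int(i) for i in resolve_channels(ch_names, subset))


def best_per_subject(
    candidates: list[ChannelSubset],
    session: EpochSet,
    cv: CVConfig = CVConfig(),
    filter_spec: FilterSpec | None = FilterSpec(),
    n_components: int = 8,
) -> tuple[ChannelSubset, AccuracyResult]:
    """The candidate with maximal cross-validated accuracy on one session.

    Ties break toward fewer electrodes, then canonical (montage-index)
    order; duplicates in the candidate list do not affect the winner.
    """
    if not candidates:
        raise ValidationError("empty candidate list")
    seen: set[tuple[str, ...]] = set()
    unique: list[ChannelSubset] = []
    for c in candidates:
        if c.names not in seen:
            seen.add(c.names)
            unique.append(c)
    work = bandpass(session, filter_spec) if filter_spec is not None else session
    scored = [
        (
            c,
            crossval_accuracy(work, c, cv, None, min(n_components, len(c))),
        )
        for c in unique
    ]
    return min(
        scored,
        key=lambda ca: (
            -ca[1].mean_accuracy,
            len(ca[0]),
            _canonical_key(ca[0], work.ch_names),
        ),
    )
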