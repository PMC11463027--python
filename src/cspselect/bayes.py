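"""Bayesian A/B evaluation of pipeline variants.

Per-trial classification correctness is dichotomic, so each variant's
pooled correct/incorrect counts over all subjects update a beta prior
(default Beta(6, 4), encoding a mild better-than-chance belief; with
thousands of pooled trials its influence is negligible). Variants are
compared against the all-electrode baseline by Monte-Carlo: draw accuracy
pairs (a, b) independently from the two posteriors, average the fractions
a/b, and report 100 * (mean - 1) as the percentual improvement.

Note the estimator's self-comparison bias: for independent draws
E[a/b] = E[a] * E[1/b] > 1 even when variant and baseline share one
posterior (E[1/X] = (alpha+beta-1)/(alpha-1) for a beta distribution).
This is a property of the mean-of-ratios estimator and is reported, not
corrected.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .pipeline import AccuracyResult

__all__ = [
    "BetaPrior",
    "BetaPosterior",
    "ImprovementSummary",
    "posterior_from_results",
    "mc_improvement",
    "evaluate_variants",
    "posterior_density_table",
]


@dataclass(frozen=True)
class BetaPrior:
    alpha: float = 6.0
    beta: float = 4.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("beta prior shapes must be positive")


@dataclass(frozen=True)
class BetaPosterior:
    """Conjugate posterior Beta(prior.alpha + successes, prior.beta + failures)."""

    alpha: float
    beta: float
    successes: int = 0
    failures: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("posterior shapes must be positive")
        if self.successes < 0 or self.failures < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class ImprovementSummary:
    """Monte-Carlo summary of variant/baseline accuracy fractions."""

    mean_fraction: float
    pct_improvement: float
    n_draws: int
    seed: int
    credible_interval: tuple[float, float]


def posterior_from_results(
    results: list[AccuracyResult], prior: BetaPrior = BetaPrior()
) -> BetaPosterior:
    """Pool per-trial correctness over subjects and update the prior."""
    if not results:
        raise ValidationError("empty result list")
    successes = int(sum(r.correct for r in results))
    failures = int(sum(r.total - r.correct for r in results))
    return BetaPosterior(
        alpha=prior.alpha + successes,
        beta=prior.beta + failures,
        successes=successes,
        failures=failures,
    )


def mc_improvement(
    variant: BetaPosterior,
    baseline: BetaPosterior,
    n_draws: int = 10_000,
    seed: int = 0,
) -> ImprovementSummary:
    """Monte-Carlo mean of variant/baseline accuracy ratios.

    Draws are independent between variant and baseline; the central 95%
    interval of the sampled fractions is attached as a convenience.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    if baseline.alpha <= 1:
        raise ValidationError(
            "baseline posterior alpha must exceed 1 (E[1/b] diverges otherwise)"
        )
    rng = np.random.default_rng(seed)
    a = rng.beta(variant.alpha, variant.beta, size=n_draws)
    b = rng.beta(baseline.alpha, baseline.beta, size=n_draws)
    fractions = a / b
    mean = float(fractions.mean())
    lo, hi = np.percentile(fractions, [2.5, 97.5])
    return ImprovementSummary(
        mean_fraction=mean,
        pct_improvement=100.0 * (mean - 1.0),
        n_draws=n_draws,
        seed=seed,
        credible_interval=(float(lo), float(hi)),
    )


def _variant_seed(seed: int, name: str) -> int:
    """Order-independent per-variant seed (stable across insertion order)."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


def evaluate_variants(
    variant_results: dict[str, list[AccuracyResult]],
    baseline_results: list[AccuracyResult],
    prior: BetaPrior = BetaPrior(),
    n_draws: int = 10_000,
    seed: int = 0,
    comb_from: list[str] | None = None,
) -> dict[str, ImprovementSummary]:
    """One ImprovementSummary per variant versus the shared baseline.

    All variants must cover the same subjects (equal-length result
    lists, one entry per subject). When `comb_from` names variants, an
    additional "Comb" variant is built by taking each subject's best
    accuracy across those variants' results before pooling.
    """
    if not baseline_results:
        raise ValidationError("empty baseline results")
    n_subjects = len(baseline_results)
    for name, results in variant_results.items():
        if len(results) != n_subjects:
            raise ValidationError(
                f"variant {name!r} covers {len(results)} subjects, "
                f"baseline covers {n_subjects}"
            )
    variants = dict(variant_results)
    if comb_from:
        missing = [n for n in comb_from if n not in variants]
        if missing:
            raise ValidationError(f"comb_from names unknown variants: {missing}")
        variants["Comb"] = [
            max(
                (variants[n][i] for n in comb_from),
                key=lambda r: r.mean_accuracy,
            )
            for i in range(n_subjects)
        ]
    base_post = posterior_from_results(baseline_results, prior)
    return {
        name: mc_improvement(
            posterior_from_results(results, prior),
            base_post,
            n_draws=n_draws,
            seed=_variant_seed(seed, name),
        )
        for name, results in sorted(variants.items())
    }


def posterior_density_table(
    posteriors: list[BetaPosterior],
    grid: np.ndarray,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Beta densities on a grid in (0, 1), one column per posterior."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(grid >= 1):
        raise ValidationError("grid points must lie strictly inside (0, 1)")
    if names is None:
        names = [f"Beta({p.alpha:g},{p.beta:g})" for p in posteriors]
    data = {
        name: stats.beta.pdf(grid, p.alpha, p.beta)
        for name, p in zip(names, posteriors)
    }
    return pd.DataFrame(data, index=pd.Index(grid, name="accuracy"))
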