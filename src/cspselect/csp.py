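"""Two-class common spatial patterns.

CSP finds spatial filters w maximizing the variance ratio of one class to
the other. With trace-normalized class covariances S1, S2 this is the
generalized eigenproblem

    S1 w = lambda (S1 + S2) w,   lambda in [0, 1],

whose eigenvalue is the fraction of composite variance that class 1
contributes along w: lambda near 1 means a component dominated by class 1,
near 0 dominated by class 2, 0.5 non-discriminative. Components are
ordered by discriminability max(lambda, 1 - lambda) descending, which
interleaves both spectrum tails.

The *filters* W (rows) extract component time courses s = W x; the
*patterns* are the rows of W^{-1} (columns of the mixing matrix), i.e. how
each component projects back onto the electrodes. The patterns are what
pattern-based electrode selection inspects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import ValidationError
from .io import EpochSet

__all__ = ["ClassCovariances", "CSPModel", "class_covariances", "fit_csp", "apply_csp"]

#: Relative ridge added to the composite covariance before the
#: eigendecomposition; guards rank deficiency only.
_COMPOSITE_FLOOR = 1e-9


@dataclass(frozen=True)
class ClassCovariances:
    """Per-class average covariance, trace-normalized per trial.

    `class_order` records which label maps to `sigma1` (labels in sorted
    order, so "left" before "right").
    """

    sigma1: np.ndarray
    sigma2: np.ndarray
    class_order: tuple[str, str]
    ch_names: tuple[str, ...]

    def swapped(self) -> "ClassCovariances":
        return ClassCovariances(
            sigma1=self.sigma2,
            sigma2=self.sigma1,
            class_order=(self.class_order[1], self.class_order[0]),
            ch_names=self.ch_names,
        )


@dataclass(frozen=True)
class CSPModel:
    """Fitted CSP decomposition.

    filters : (n_components, n_channels) — rows applied to channel space.
    patterns : (n_components, n_channels) — mixing-matrix rows, one per
        component; used for electrode selection.
    eigvals : (n_components,) generalized eigenvalues in [0, 1], ordered by
        discriminability.
    """

    filters: np.ndarray
    patterns: np.ndarray
    eigvals: np.ndarray
    ch_names: tuple[str, ...]
    n_components: int
    class_order: tuple[str, str]


def class_covariances(epochs: EpochSet, shrinkage: float = 0.0) -> ClassCovariances:
    """Average trace-normalized trial covariances within each class.

    Each trial's covariance is divided by its trace before averaging, so
    trials contribute equal total power regardless of amplitude. The
    optional `shrinkage` fraction pulls each class covariance toward
    (trace/n_channels) * identity.
    """
    if not 0 <= shrinkage <= 1:
        raise ValidationError(f"shrinkage must be in [0, 1], got {shrinkage}")
    if epochs.n_samples < 2:
        raise ValidationError("need more than one sample per trial")
    classes = epochs.classes
    n_ch = epochs.n_channels
    x = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    trial_covs = np.einsum("tcs,tds->tcd", x, x) / (epochs.n_samples - 1)
    traces = np.trace(trial_covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise ValidationError(
            f"trial(s) {np.flatnonzero(traces <= 0).tolist()} have zero variance"
        )
    trial_covs /= traces[:, None, None]
    sigmas = []
    for cls in classes:
        idx = np.flatnonzero(epochs.labels.astype(str) == cls)
        if idx.size < 2:
            raise ValidationError(
                f"class {cls!r} has {idx.size} trial(s); at least 2 required"
            )
        sigma = trial_covs[idx].mean(axis=0)
        if shrinkage > 0:
            sigma = (1 - shrinkage) * sigma + shrinkage * (
                np.trace(sigma) / n_ch
            ) * np.eye(n_ch)
        sigmas.append((sigma + sigma.T) / 2)
    return ClassCovariances(
        sigma1=sigmas[0],
        sigma2=sigmas[1],
        class_order=(classes[0], classes[1]),
        ch_names=epochs.ch_names,
    )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude coefficient is positive.

    Eigenvector sign is arbitrary; without a convention, pattern-based
    electrode selection would not be reproducible.
    """
    v = vectors.copy()
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    return v


def fit_csp(
    covs: ClassCovariances,
    n_components: int = 8,
    ordering: str = "discriminability",
) -> CSPModel:
    """Solve S1 w = lambda (S1 + S2) w and package filters and patterns.

    `ordering` is "discriminability" (max(lambda, 1-lambda) descending,
    default) or "descending" (plain lambda descending).

    Raises a numerical error advising shrinkage when the composite
    covariance is singular.
    """
    n_ch = covs.sigma1.shape[0]
    if not 1 <= n_components <= n_ch:
        raise ValidationError(
            f"n_components must be in [1, {n_ch}], got {n_components}"
        )
    if ordering not in ("discriminability", "descending"):
        raise ValidationError(f"unknown ordering {ordering!r}")
    composite = covs.sigma1 + covs.sigma2
    try:
        eigvals, vecs = linalg.eigh(covs.sigma1, composite)
        if not np.all(np.isfinite(eigvals)):
            raise linalg.LinAlgError("non-finite eigenvalues")
    except linalg.LinAlgError:
        # rank-deficient composite: retry with a tiny identity floor
        floored = composite + _COMPOSITE_FLOOR * np.trace(composite) * np.eye(n_ch)
        try:
            eigvals, vecs = linalg.eigh(covs.sigma1, floored)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "composite covariance is singular; refit with shrinkage > 0"
            ) from exc
        if not np.all(np.isfinite(eigvals)):
            raise np.linalg.LinAlgError(
                "composite covariance is singular; refit with shrinkage > 0"
            )
    eigvals = np.clip(eigvals, 0.0, 1.0)

    if ordering == "discriminability":
        # ties in max(lambda, 1-lambda) put the high-lambda component first
        order = np.lexsort((-eigvals, -np.maximum(eigvals, 1 - eigvals)))
    else:
        order = np.argsort(-eigvals, kind="stable")
    w_full = _fix_signs(vecs[:, order])  # columns are filters, Sc-orthonormal
    patterns_full = linalg.inv(w_full)   # rows are patterns

    return CSPModel(
        filters=np.ascontiguousarray(w_full.T[:n_components]),
        patterns=np.ascontiguousarray(patterns_full[:n_components]),
        eigvals=eigvals[order][:n_components],
        ch_names=covs.ch_names,
        n_components=n_components,
        class_order=covs.class_order,
    )


def apply_csp(model: CSPModel, epochs: EpochSet) -> np.ndarray:
    """Log-variance features: one row per trial, one column per component.

    The channel order must match the order the model was fit on.
    """
    if epochs.ch_names != model.ch_names:
        missing = set(model.ch_names) ^ set(epochs.ch_names)
        raise ValidationError(
            "channel mismatch between model and epochs"
            + (f"; differing names: {sorted(missing)}" if missing else " (order differs)")
        )
    projected = np.einsum("kc,tcs->tks", model.filters, epochs.data)
    var = projected.var(axis=-1, ddof=1)
    if np.any(var <= 0):
        raise ValidationError("a projected trial has zero variance")
    return np.log(var)
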