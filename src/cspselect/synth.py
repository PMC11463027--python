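"""Synthetic two-class motor-imagery EEG sessions with known ground truth.

The generator emulates the band-power (event-related desynchronization
style) contrast that common spatial patterns exploit: every channel carries
a band-limited Gaussian oscillation plus broadband noise, and on a chosen
set of discriminative channels the oscillation variance is scaled by a
class-dependent factor. The "left" class boosts the first half of the
discriminative channels and "right" the second half, so both tails of the
CSP eigenvalue spectrum carry signal. A fixed tridiagonal mixing operator
smears signal into neighbouring channels, emulating volume conduction.

All outputs are pure functions of the :class:`SimConfig` (including its
seed), which is what makes parameter-recovery tests well-posed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .exceptions import ValidationError
from .io import DEFAULT_MONTAGE16, EpochSet, canonicalize

__all__ = ["SimConfig", "generate_session", "generate_subject"]


@dataclass(frozen=True)
class SimConfig:
    """Full generative description of one synthetic session.

    Parameters
    ----------
    n_channels : int
        Number of electrodes; when 16, `ch_names` defaults to the standard
        sensorimotor montage.
    n_trials_per_class : int
        Trials per class; the session has twice this many trials.
    n_samples : int
        Samples per trial (default 256, i.e. 2 s at 128 Hz).
    disc_channels : tuple of str
        Channels carrying the class contrast. "left" trials boost the
        oscillation variance of the first half of this tuple by `effect`,
        "right" trials the second half.
    effect : float
        Variance ratio (>= 1) applied to the boosted channels.
    band : (low, high) in Hz
        Passband of the oscillatory component.
    noise_sd : float
        Standard deviation of the broadband noise added to every channel.
    mixing_strength : float in [0, 1)
        Off-diagonal coefficient of the row-normalized tridiagonal spatial
        mixing operator; 0 disables mixing.
    """

    n_channels: int = 16
    ch_names: tuple[str, ...] | None = None
    n_trials_per_class: int = 50
    n_samples: int = 256
    sfreq: float = 128.0
    disc_channels: tuple[str, ...] = ("C3", "C4")
    effect: float = 4.0
    band: tuple[float, float] = (8.0, 30.0)
    noise_sd: float = 0.5
    mixing_strength: float = 0.2
    seed: int = 0
    session_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.ch_names is None:
            if self.n_channels == 16:
                names = DEFAULT_MONTAGE16
            else:
                names = tuple(f"CH{i + 1}" for i in range(self.n_channels))
            object.__setattr__(self, "ch_names", names)
        else:
            object.__setattr__(
                self, "ch_names", tuple(canonicalize(c) for c in self.ch_names)
            )
        object.__setattr__(
            self, "disc_channels", tuple(canonicalize(c) for c in self.disc_channels)
        )
        object.__setattr__(self, "band", tuple(float(b) for b in self.band))
        if len(self.ch_names) != self.n_channels:
            raise ValidationError(
                f"{len(self.ch_names)} channel names for n_channels={self.n_channels}"
            )
        missing = set(self.disc_channels) - set(self.ch_names)
        if missing:
            raise ValidationError(f"disc_channels not in ch_names: {sorted(missing)}")
        if self.effect < 1:
            raise ValidationError(f"effect must be >= 1, got {self.effect}")
        if not 0 <= self.mixing_strength < 1:
            raise ValidationError(
                f"mixing_strength must be in [0, 1), got {self.mixing_strength}"
            )
        if self.n_trials_per_class < 1:
            raise ValidationError("n_trials_per_class must be >= 1")
        if not 0 < self.band[0] < self.band[1] < self.sfreq / 2:
            raise ValidationError(
                f"band {self.band} invalid for sfreq={self.sfreq}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@lru_cache(maxsize=32)
def _band_sos_and_gain(band: tuple[float, float], sfreq: float) -> tuple[np.ndarray, float]:
    """Band-pass SOS plus the std gain of white noise pushed through it.

    The gain is sqrt(sum h[k]^2) of the impulse response, so dividing the
    filtered noise by it restores (asymptotically) unit variance without
    touching the per-trial sample statistics.
    """
    sos = signal.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    impulse = np.zeros(8192)
    impulse[0] = 1.0
    h = signal.sosfilt(sos, impulse)
    return sos, float(np.sqrt(np.sum(h**2)))


def _mixing_operator(n_channels: int, strength: float) -> np.ndarray:
    """Row-normalized identity-plus-tridiagonal neighbour leakage."""
    m = np.eye(n_channels)
    if strength > 0 and n_channels > 1:
        off = strength * (np.eye(n_channels, k=1) + np.eye(n_channels, k=-1))
        m = m + off
        m /= m.sum(axis=1, keepdims=True)
    return m


def generate_session(config: SimConfig) -> EpochSet:
    """Generate one balanced two-class session from `config`.

    Trials are ordered all-"left" then all-"right". With
    ``mixing_strength=0`` the oscillation variance of a boosted channel is
    exactly `effect` times its un-boosted variance in expectation, so
    sample-variance ratios recover `effect` up to the broadband-noise
    floor.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_per = cfg.n_trials_per_class
    n_trials = 2 * n_per
    shape = (n_trials, cfg.n_channels, cfg.n_samples)

    sos, gain = _band_sos_and_gain(cfg.band, cfg.sfreq)
    osc = signal.sosfilt(sos, rng.standard_normal(shape), axis=-1) / gain
    noise = cfg.noise_sd * rng.standard_normal(shape)

    # class-dependent amplitude scaling on the discriminative channels
    scale = np.ones((n_trials, cfg.n_channels))
    ch_index = {c: i for i, c in enumerate(cfg.ch_names)}
    disc_idx = [ch_index[c] for c in cfg.disc_channels]
    k = (len(disc_idx) + 1) // 2
    amp = np.sqrt(cfg.effect)
    scale[np.ix_(range(n_per), disc_idx[:k])] = amp            # "left" trials
    scale[np.ix_(range(n_per, n_trials), disc_idx[k:])] = amp  # "right" trials

    x = osc * scale[:, :, None] + noise
    mix = _mixing_operator(cfg.n_channels, cfg.mixing_strength)
    x = np.einsum("ij,tjs->tis", mix, x)

    labels = np.array(["left"] * n_per + ["right"] * n_per)
    return EpochSet(
        data=x,
        labels=labels,
        ch_names=cfg.ch_names,
        sfreq=cfg.sfreq,
        session_id=cfg.session_id or f"sim-{cfg.seed}",
        subject_id=cfg.subject_id or "sim",
    )


def derive_session_seeds(seed: int, n_sessions: int) -> list[int]:
    """Deterministic per-session seeds spawned from a subject seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_sessions)]


def generate_subject(config: SimConfig, n_sessions: int) -> list[EpochSet]:
    """Generate several sessions of one subject.

    Sessions share the discriminative channels and effect size but differ
    in their derived seeds, emulating repeated recordings of one subject.
    """
    if n_sessions < 1:
        raise ValidationError("n_sessions must be >= 1")
    seeds = derive_session_seeds(config.seed, n_sessions)
    subject = config.subject_id or f"sub-{config.seed}"
    sessions = []
    for i, s in enumerate(seeds):
        cfg = dataclasses.replace(
            config, seed=s, session_id=f"{subject}-ses{i}", subject_id=subject
        )
        sessions.append(generate_session(cfg))
    return sessions
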