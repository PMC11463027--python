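"""Domain types and session container I/O.

The universal currency of the package is the :class:`EpochSet`: a stack of
fixed-length multichannel EEG trials with two-class labels ("left" / "right"
motor imagery), 10-10 channel names and a sampling rate. Sessions are stored
on disk as compressed ``.npz`` archives with named arrays, one file per
session.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ChannelLookupError, FormatError, ValidationError

__all__ = [
    "EpochSet",
    "ChannelSubset",
    "Montage16",
    "DEFAULT_MONTAGE16",
    "canonicalize",
    "read_session",
    "write_session",
    "subset_channels",
]

#: Default 16-electrode sensorimotor montage (10-10 names), overridable
#: everywhere a montage is accepted.
DEFAULT_MONTAGE16: tuple[str, ...] = (
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C3", "C1", "Cz", "C2", "C4",
    "CP3", "CP1", "CPz", "CP2", "CP4",
)

#: Minimum sampling rate (Hz) a session must declare.
MIN_SFREQ = 90.0


def canonicalize(name: str) -> str:
    """Canonicalize a channel name to 10-10 spelling, case-insensitively.

    ``"fcZ" -> "FCz"``, ``"c3" -> "C3"``. Midline electrodes keep a
    lowercase trailing ``z``; everything else is upper-cased.
    """
    s = name.strip().upper()
    if len(s) > 1 and s.endswith("Z"):
        s = s[:-1] + "z"
    return s


@dataclass(frozen=True, eq=False)
class EpochSet:
    """Labelled multichannel trial data.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial time courses (volts or arbitrary units, consistent within a
        session). Must be finite.
    labels : array of str, length n_trials
        Exactly two distinct class tags (conventionally "left" / "right").
    ch_names : sequence of str
        Unique channel identifiers, canonicalized to 10-10 spelling.
    sfreq : float
        Sampling rate in Hz, at least 90.
    """

    data: np.ndarray
    labels: np.ndarray
    ch_names: tuple[str, ...]
    sfreq: float
    session_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels)
        names = tuple(canonicalize(str(c)) for c in self.ch_names)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "ch_names", names)
        object.__setattr__(self, "sfreq", float(self.sfreq))
        if data.ndim != 3:
            raise ValidationError(
                f"data must be (trials, channels, samples), got ndim={data.ndim}"
            )
        if data.shape[0] == 0:
            raise ValidationError("empty trial axis")
        if not np.all(np.isfinite(data)):
            raise ValidationError("data contains non-finite values")
        if labels.shape != (data.shape[0],):
            raise ValidationError(
                f"{labels.shape[0] if labels.ndim == 1 else labels.shape} labels "
                f"for {data.shape[0]} trials"
            )
        classes = np.unique(labels)
        if classes.size != 2:
            raise ValidationError(
                f"exactly 2 classes required, found {classes.size}: {list(classes)}"
            )
        if len(set(names)) != len(names):
            raise ValidationError("duplicate channel names")
        if len(names) != data.shape[1]:
            raise ValidationError(
                f"{len(names)} channel names for {data.shape[1]} channels"
            )
        if self.sfreq < MIN_SFREQ:
            raise ValidationError(
                f"sampling rate {self.sfreq} Hz below the {MIN_SFREQ} Hz minimum"
            )

    # -- convenience accessors -------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> tuple[str, ...]:
        """The two class tags in sorted order."""
        return tuple(str(c) for c in sorted(np.unique(self.labels)))

    def select_trials(self, indices: np.ndarray) -> "EpochSet":
        """Return a copy restricted to the given trial indices (order kept).

        The two-class invariant must still hold on the selection.
        """
        return dataclasses.replace(
            self, data=self.data[indices], labels=self.labels[indices]
        )

    def with_data(self, data: np.ndarray) -> "EpochSet":
        return dataclasses.replace(self, data=data)

    def equals(self, other: "EpochSet", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Field-by-field equality; exact metadata, tolerance-based data."""
        return (
            self.ch_names == other.ch_names
            and self.sfreq == other.sfreq
            and self.session_id == other.session_id
            and self.subject_id == other.subject_id
            and np.array_equal(self.labels.astype(str), other.labels.astype(str))
            and self.data.shape == other.data.shape
            and np.allclose(self.data, other.data, rtol=rtol, atol=atol)
        )


@dataclass(frozen=True)
class ChannelSubset:
    """An ordered electrode combination, applied to an :class:`EpochSet`."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(canonicalize(str(n)) for n in self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValidationError("empty channel subset")
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate names in subset: {names}")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


@dataclass(frozen=True)
class Montage16:
    """A fixed 16-electrode sensorimotor montage."""

    names: tuple[str, ...] = field(default=DEFAULT_MONTAGE16)

    def __post_init__(self) -> None:
        names = tuple(canonicalize(str(n)) for n in self.names)
        object.__setattr__(self, "names", names)
        if len(names) != 16:
            raise ValidationError(f"montage must have 16 channels, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValidationError("duplicate montage channels")

    def as_subset(self) -> ChannelSubset:
        return ChannelSubset(self.names)


# -- container I/O --------------------------------------------------------

_REQUIRED_FIELDS = ("data", "labels", "ch_names", "sfreq")


def write_session(epochs: EpochSet, path: str | Path) -> None:
    """Write a session to a compressed ``.npz`` container.

    Bit-faithful for labels, names and sampling rate; data is stored as
    float64 and round-trips exactly.
    """
    path = Path(path)
    np.savez_compressed(
        path,
        data=epochs.data.astype(np.float64),
        labels=epochs.labels.astype(str),
        ch_names=np.array(epochs.ch_names, dtype=str),
        sfreq=np.float64(epochs.sfreq),
        session_id=np.str_(epochs.session_id),
        subject_id=np.str_(epochs.subject_id),
    )


def read_session(path: str | Path) -> EpochSet:
    """Read a session container written by :func:`write_session`.

    Raises
    ------
    FormatError
        If a required array is missing from the container.
    ValidationError
        If the stored session violates an :class:`EpochSet` invariant
        (e.g. not exactly two classes).
    """
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        missing = [f for f in _REQUIRED_FIELDS if f not in npz.files]
        if missing:
            raise FormatError(
                f"session container {path} missing field(s): {', '.join(missing)}"
            )
        return EpochSet(
            data=npz["data"],
            labels=npz["labels"].astype(str),
            ch_names=tuple(npz["ch_names"].astype(str)),
            sfreq=float(npz["sfreq"]),
            session_id=str(npz["session_id"]) if "session_id" in npz.files else "",
            subject_id=str(npz["subject_id"]) if "subject_id" in npz.files else "",
        )


def resolve_channels(
    ch_names: tuple[str, ...], requested: "ChannelSubset | tuple[str, ...]"
) -> np.ndarray:
    """Map requested channel names to indices in ``ch_names`` (order kept)."""
    names = requested.names if isinstance(requested, ChannelSubset) else tuple(requested)
    index = {canonicalize(c): i for i, c in enumerate(ch_names)}
    unknown = [n for n in names if canonicalize(n) not in index]
    if unknown:
        raise ChannelLookupError(
            f"channel(s) not in montage {list(ch_names)}: {unknown}"
        )
    return np.array([index[canonicalize(n)] for n in names], dtype=int)


def subset_channels(epochs: EpochSet, subset: ChannelSubset) -> EpochSet:
    """Reduce an :class:`EpochSet` to the given channels, in subset order.

    Trials and labels are unchanged; idempotent for a fixed subset.
    """
    idx = resolve_channels(epochs.ch_names, subset)
    return dataclasses.replace(
        epochs,
        data=epochs.data[:, idx, :],
        ch_names=tuple(epochs.ch_names[i] for i in idx),
    )
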