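"""Core data containers shared by all pipeline stages.

The package works on three in-memory objects:

``ContinuousRecording``
    a channels x time array in microvolts with channel labels, channel
    groups (scalp / left ear / right ear / EOG), a 2-D montage for the
    scalp channels, and the sampling rate;
``EventTable``
    word-onset events with condition labels (target / non-target, in the
    attended or unattended stream), carried as a pandas DataFrame;
``EpochSet`` / ``ERPWave``
    epochs x channels x samples tensors cut around event onsets, and the
    per-condition averages derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Valid condition tokens.  AT/AN/UT/UN are used for competing-stream
#: paradigms (target / non-target in the attended / unattended stream);
#: TARGET/NONTARGET are used for the single-stream oddball paradigm.
CONDITIONS = frozenset({"AT", "AN", "UT", "UN", "TARGET", "NONTARGET"})

#: Channel group names.
GROUPS = ("scalp", "ear_left", "ear_right", "eog")

#: Required columns of an event table, in on-disk order.
EVENT_COLUMNS = ("onset", "duration", "trial_type", "stream", "trial")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

class EventTable:
    """Word-onset events with condition labels.

    Parameters
    ----------
    df
        DataFrame with columns ``onset`` (seconds from recording start),
        ``duration`` (seconds), ``trial_type`` (condition token),
        ``stream`` (``single``, ``left`` or ``right``) and ``trial``
        (0-based trial index).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        self.df = df.reset_index(drop=True)[list(EVENT_COLUMNS)].copy()
        if validate:
            self.validate()

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.df.equals(other.df)

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset"].to_numpy(float)

    @property
    def conditions(self) -> np.ndarray:
        return self.df["trial_type"].to_numpy(str)

    def validate(self) -> None:
        for i, cond in enumerate(self.df["trial_type"]):
            if cond not in CONDITIONS:
                raise ValidationError(
                    f"row {i}: unknown condition token {cond!r}"
                )
        onsets = self.onsets
        if np.any(onsets < 0):
            row = int(np.flatnonzero(onsets < 0)[0])
            raise ValidationError(f"row {row}: negative onset")
        # onsets must be strictly increasing within each trial and stream
        for (trial, stream), grp in self.df.groupby(["trial", "stream"]):
            o = grp["onset"].to_numpy(float)
            if np.any(np.diff(o) <= 0):
                bad = int(grp.index[np.flatnonzero(np.diff(o) <= 0)[0] + 1])
                raise ValidationError(
                    f"row {bad}: onsets not strictly increasing within "
                    f"trial {trial} / stream {stream}"
                )

    def select(self, conditions: str | Iterable[str]) -> "EventTable":
        if isinstance(conditions, str):
            conditions = [conditions]
        mask = self.df["trial_type"].isin(list(conditions))
        return EventTable(self.df[mask], validate=False)


# ---------------------------------------------------------------------------
# continuous recording
# ---------------------------------------------------------------------------

@dataclass
class ContinuousRecording:
    """Multi-channel continuous EEG in microvolts.

    ``samples`` has shape (n_channels, n_times).  ``channel_groups`` maps
    each label to one of ``GROUPS``.  ``montage2d`` holds planar (x, y)
    coordinates for (at least) the scalp channels; it is required by the
    spatial cluster test's adjacency construction.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    channel_groups: dict[str, str]
    montage2d: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{self.samples.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        missing = [c for c in self.channel_labels if c not in self.channel_groups]
        if missing:
            raise ValidationError(f"channels without group assignment: {missing}")
        bad = {g for g in self.channel_groups.values() if g not in GROUPS}
        if bad:
            raise ValidationError(f"unknown channel groups: {sorted(bad)}")
        no_pos = [
            c for c in self.channel_labels
            if self.channel_groups[c] == "scalp" and c not in self.montage2d
        ]
        if no_pos:
            raise ValidationError(f"scalp channels without montage2d: {no_pos}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def group_indices(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channel_labels)
             if self.channel_groups[c] == group],
            dtype=int,
        )

    def get_channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def copy(self) -> "ContinuousRecording":
        return replace(
            self,
            samples=self.samples.copy(),
            channel_labels=list(self.channel_labels),
            channel_groups=dict(self.channel_groups),
            montage2d=dict(self.montage2d),
        )

    def pick(self, labels: Sequence[str]) -> "ContinuousRecording":
        idx = [self.channel_index(c) for c in labels]
        return ContinuousRecording(
            self.samples[idx].copy(),
            self.sampling_rate,
            list(labels),
            {c: self.channel_groups[c] for c in labels},
            {c: self.montage2d[c] for c in labels if c in self.montage2d},
        )


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Epochs cut on the window [-200, 1000) ms around event onsets.

    ``data`` has shape (n_epochs, n_channels, n_samples); ``times_ms`` is
    the shared time axis in milliseconds relative to event onset, built
    with a half-open [tmin, tmax) convention; ``conditions`` holds one
    condition token per epoch.
    """

    data: np.ndarray
    times_ms: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    channel_groups: dict[str, str]
    conditions: np.ndarray
    montage2d: dict[str, tuple[float, float]] = field(default_factory=dict)
    events: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be 3-D")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValidationError("channel count mismatch")
        if self.data.shape[2] != self.times_ms.size:
            raise ValidationError("time axis length mismatch")
        if self.data.shape[0] != self.conditions.size:
            raise ValidationError("one condition per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def get_channel(self, label: str) -> np.ndarray:
        """Return (n_epochs, n_samples) data for one channel."""
        return self.data[:, self.channel_index(label), :]

    def select(self, conditions: str | Iterable[str]) -> "EpochSet":
        if isinstance(conditions, str):
            conditions = [conditions]
        mask = np.isin(self.conditions.astype(str), list(conditions))
        return self._subset(mask)

    def _subset(self, mask: np.ndarray) -> "EpochSet":
        events = self.events[mask].reset_index(drop=True) if self.events is not None else None
        return EpochSet(
            self.data[mask],
            self.times_ms,
            self.sampling_rate,
            list(self.channel_labels),
            dict(self.channel_groups),
            self.conditions[mask],
            dict(self.montage2d),
            events,
        )

    def pick_channels(self, labels: Sequence[str]) -> "EpochSet":
        idx = [self.channel_index(c) for c in labels]
        return EpochSet(
            self.data[:, idx, :],
            self.times_ms,
            self.sampling_rate,
            list(labels),
            {c: self.channel_groups[c] for c in labels},
            self.conditions,
            {c: self.montage2d[c] for c in labels if c in self.montage2d},
            self.events,
        )

    def pick_group(self, group: str) -> "EpochSet":
        labels = [c for c in self.channel_labels if self.channel_groups[c] == group]
        if not labels:
            raise ValidationError(f"no channels in group {group!r}")
        return self.pick_channels(labels)

    def crop(self, tmin_ms: float, tmax_ms: float) -> "EpochSet":
        """Restrict the time axis to [tmin_ms, tmax_ms] (inclusive)."""
        mask = (self.times_ms >= tmin_ms) & (self.times_ms <= tmax_ms)
        if not mask.any():
            raise ValidationError(f"empty crop window ({tmin_ms}, {tmax_ms}) ms")
        return EpochSet(
            self.data[:, :, mask],
            self.times_ms[mask],
            self.sampling_rate,
            list(self.channel_labels),
            dict(self.channel_groups),
            self.conditions,
            dict(self.montage2d),
            self.events,
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.times_ms.copy(), self.sampling_rate,
            list(self.channel_labels), dict(self.channel_groups),
            self.conditions.copy(), dict(self.montage2d),
            None if self.events is None else self.events.copy(),
        )


def concatenate_epochs(sets: Sequence[EpochSet]) -> EpochSet:
    """Stack several EpochSets (same channels and time axis) into one."""
    if not sets:
        raise ValidationError("no epoch sets to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.channel_labels != first.channel_labels:
            raise ValidationError("channel sets differ")
        if not np.allclose(s.times_ms, first.times_ms):
            raise ValidationError("time axes differ")
    return EpochSet(
        np.concatenate([s.data for s in sets], axis=0),
        first.times_ms,
        first.sampling_rate,
        list(first.channel_labels),
        dict(first.channel_groups),
        np.concatenate([s.conditions for s in sets]),
        dict(first.montage2d),
        None,
    )


# ---------------------------------------------------------------------------
# ERP waves
# ---------------------------------------------------------------------------

@dataclass
class ERPWave:
    """A channels x samples average waveform (one condition or contrast).

    ``n`` counts the epochs (individual ERP) or subjects (grand average)
    that contributed.
    """

    data: np.ndarray
    times_ms: np.ndarray
    label: str
    n: int
    channel_labels: list[str]

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.shape != (len(self.channel_labels), self.times_ms.size):
            raise ValidationError("ERP data shape mismatch")

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data.T, columns=self.channel_labels)
        df.insert(0, "time_ms", self.times_ms)
        return df
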