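"""Condition averaging, difference waves, grand averages and peak measures."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import EpochSet, ERPWave, ValidationError


class EmptyConditionError(ValidationError):
    """Raised when averaging is requested for a condition with no epochs."""


def average_epochs(epochs: EpochSet, condition: str | Iterable[str]) -> ERPWave:
    """Sample-wise mean over the epochs of one condition (individual ERP)."""
    sel = epochs.select(condition)
    if sel.n_epochs == 0:
        raise EmptyConditionError(f"no epochs for condition {condition!r}")
    label = condition if isinstance(condition, str) else "+".join(condition)
    return ERPWave(
        sel.data.mean(axis=0),
        epochs.times_ms.copy(),
        label,
        sel.n_epochs,
        list(epochs.channel_labels),
    )


def difference_wave(a: ERPWave, b: ERPWave) -> ERPWave:
    """a - b, sample-wise; the label records the contrast."""
    if a.channel_labels != b.channel_labels:
        raise ValidationError("channel sets differ")
    if a.times_ms.shape != b.times_ms.shape or not np.allclose(a.times_ms, b.times_ms):
        raise ValidationError("time axes differ")
    return ERPWave(
        a.data - b.data,
        a.times_ms.copy(),
        f"{a.label}-{b.label}",
        min(a.n, b.n),
        list(a.channel_labels),
    )


def grand_average(waves: Sequence[ERPWave]) -> ERPWave:
    """Unweighted mean over subjects: each wave contributes equally."""
    if len(waves) == 0:
        raise ValidationError("no waves to grand-average")
    first = waves[0]
    for w in waves[1:]:
        if w.channel_labels != first.channel_labels:
            raise ValidationError("channel sets differ")
        if not np.allclose(w.times_ms, first.times_ms):
            raise ValidationError("time axes differ")
    data = np.mean([w.data for w in waves], axis=0)
    return ERPWave(
        data,
        first.times_ms.copy(),
        first.label,
        len(waves),
        list(first.channel_labels),
    )


@dataclass
class PeakMeasure:
    """A local-maximum measurement inside a time window."""

    amplitude: float   # uV
    latency: float     # ms
    edge: bool         # True when the maximum sits on the window boundary

    def __iter__(self):
        yield self.amplitude
        yield self.latency


def quantify_peak(
    wave: ERPWave, channel: str, window: tuple[float, float]
) -> PeakMeasure:
    """Maximum of the waveform (positive-going peak) in ``window`` (ms).

    The window is usually the extent of a significant cluster.  Ties break
    toward the earliest latency.  If the maximum lands on either window
    edge it is flagged (``edge=True``): it is then not a local peak.
    """
    lo, hi = window
    mask = (wave.times_ms >= lo) & (wave.times_ms <= hi)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValidationError(f"empty window {window}")
    y = wave.get_channel(channel)[idx]
    k = int(np.argmax(y))
    return PeakMeasure(
        amplitude=float(y[k]),
        latency=float(wave.times_ms[idx[k]]),
        edge=(k == 0 or k == idx.size - 1),
    )
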