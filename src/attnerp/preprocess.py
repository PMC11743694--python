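"""Preprocessing chain for continuous scalp + ear EEG.

Order of operations (the canonical chain is :func:`preprocess_recording`):

1. re-reference: scalp channels to the scalp average, ear channels to the
   average within each ear (the two references are independent, so scalp
   and ear signals decouple);
2. zero-phase FIR bandpass 0.1-40 Hz;
3. ICA-based removal of ocular components (scalp channels only):
   components whose activation correlates with the EOG channel beyond a
   threshold are dropped before reconstruction;
4. epoching on [-200, 1000) ms around event onsets;
5. baseline correction with the [-200, 0) ms window;
6. peak-to-peak epoch rejection at 200 uV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA

from .core import ContinuousRecording, EpochSet, EventTable, ValidationError

#: Internal seed of the FastICA solver: the decomposition must be
#: reproducible run-to-run independent of any user-level seed.
_ICA_SEED = 1914


@dataclass
class RejectionLog:
    """Book-keeping of peak-to-peak epoch rejection."""

    kept: np.ndarray                  # boolean, one per input epoch
    offending_channel: list[str | None]
    peak_to_peak: np.ndarray          # worst channel's p2p value, per epoch
    threshold: float

    @property
    def n_rejected(self) -> int:
        return int((~self.kept).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(self.kept.size),
                "kept": self.kept,
                "offending_channel": [c or "" for c in self.offending_channel],
                "peak_to_peak": self.peak_to_peak,
            }
        )


@dataclass
class ICAReport:
    """Which independent components were removed and why."""

    n_components: int
    correlations: np.ndarray          # |r| with the EOG channel, per component
    removed: list[int]
    threshold: float


# ---------------------------------------------------------------------------
# step 1: re-referencing
# ---------------------------------------------------------------------------

def rereference(rec: ContinuousRecording, scheme: str) -> ContinuousRecording:
    """Re-reference one channel group to its own average.

    ``scheme`` is ``"scalp_average"`` (all scalp channels minus the scalp
    mean) or ``"per_ear_average"`` (each ear's channels minus that ear's
    mean).  Channels outside the scheme's group are untouched.
    """
    out = rec.copy()
    if scheme == "scalp_average":
        groups = [rec.group_indices("scalp")]
    elif scheme == "per_ear_average":
        groups = [rec.group_indices("ear_left"), rec.group_indices("ear_right")]
    else:
        raise ValueError(f"unknown re-referencing scheme {scheme!r}")
    for idx in groups:
        if idx.size == 0:
            raise ValidationError(f"re-referencing scheme {scheme!r}: empty group")
        out.samples[idx] -= out.samples[idx].mean(axis=0, keepdims=True)
    return out


def rereference_all(rec: ContinuousRecording) -> ContinuousRecording:
    """Scalp-average reference for scalp, per-ear average for ear channels."""
    return rereference(rereference(rec, "scalp_average"), "per_ear_average")


# ---------------------------------------------------------------------------
# step 2: zero-phase FIR bandpass
# ---------------------------------------------------------------------------

def design_bandpass(
    low: float,
    high: float,
    sampling_rate: float,
    trans_low: float = 0.1,
    trans_high: float = 10.0,
) -> np.ndarray:
    """Hamming windowed-sinc bandpass kernel (symmetric, zero-phase).

    Built as the convolution of a high-pass (transition ``trans_low`` Hz)
    and a low-pass (transition ``trans_high`` Hz) kernel; the -6 dB points
    sit at the corner frequencies.  The kernel has exact zero gain at DC.
    """
    nyq = sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"need 0 < low < high < Nyquist, got ({low}, {high}) at fs={sampling_rate}"
        )

    def _odd(n: int) -> int:
        return n + 1 if n % 2 == 0 else n

    # Hamming window: transition width ~ 3.3 / numtaps (normalised freq)
    nt_hp = _odd(max(int(np.ceil(3.3 * sampling_rate / trans_low)), 3))
    nt_lp = _odd(max(int(np.ceil(3.3 * sampling_rate / trans_high)), 3))
    lp_for_hp = signal.firwin(nt_hp, low, window="hamming", fs=sampling_rate)
    hp = -lp_for_hp
    hp[nt_hp // 2] += 1.0  # spectral inversion: exact null at DC
    lp = signal.firwin(nt_lp, high, window="hamming", fs=sampling_rate)
    return np.convolve(hp, lp)


def _zero_phase_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Centered convolution with odd-reflection edge padding (zero phase)."""
    half = kernel.size // 2
    n = x.shape[-1]
    pad = min(half, n - 1)
    left = 2 * x[..., :1] - x[..., pad:0:-1]
    right = 2 * x[..., -1:] - x[..., -2:-pad - 2:-1]
    ext = np.concatenate([left, x, right], axis=-1)
    y = signal.fftconvolve(ext, kernel[None, :], mode="same", axes=-1)
    return y[..., pad:pad + n]


def bandpass_filter(
    rec: ContinuousRecording, low: float = 0.1, high: float = 40.0
) -> ContinuousRecording:
    """Zero-phase FIR bandpass of every channel.

    The kernel is symmetric (linear phase) and applied centred, so the
    output has no group delay: a filtered impulse is symmetric about its
    input position and sinusoids in the passband keep their phase.
    """
    kernel = design_bandpass(low, high, rec.sampling_rate)
    out = rec.copy()
    out.samples = _zero_phase_convolve(rec.samples, kernel)
    return out


# ---------------------------------------------------------------------------
# step 3: ICA-based EOG removal
# ---------------------------------------------------------------------------

def remove_eog_ica(
    rec: ContinuousRecording,
    eog_channel: str = "EOG",
    r_threshold: float = 0.8,
    n_components: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    decim: int = 4,
) -> tuple[ContinuousRecording, ICAReport]:
    """Remove ocular independent components from the scalp channels.

    FastICA is run on the scalp channels only (the EOG channel is excluded
    from the decomposition).  Components whose activation has an absolute
    Pearson correlation with the EOG channel above ``r_threshold`` are
    zeroed out and the scalp signals are rebuilt from the mixing matrix.
    The number of components defaults to (scalp channels - 1), the rank of
    average-referenced data.  The unmixing matrix is estimated on every
    ``decim``-th sample (plenty for a spatial decomposition) and then
    applied to the full recording; correlations are computed on the full
    activations.
    """
    if eog_channel not in rec.channel_labels:
        raise ValidationError(f"missing EOG channel {eog_channel!r}")
    scalp_idx = rec.group_indices("scalp")
    if scalp_idx.size < 2:
        raise ValidationError("need at least two scalp channels for ICA")
    X = rec.samples[scalp_idx].T  # samples x channels
    eog = rec.get_channel(eog_channel)
    if n_components is None:
        n_components = scalp_idx.size - 1
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=_ICA_SEED,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional convergence warnings
        ica.fit(X[:: max(int(decim), 1)])
        sources = ica.transform(X)       # samples x components
    if not np.all(np.isfinite(sources)):
        raise RuntimeError("ICA decomposition failed: non-finite sources")

    eog_c = eog - eog.mean()
    eog_sd = eog_c.std()
    if eog_sd == 0:
        corr = np.zeros(sources.shape[1])
    else:
        s_c = sources - sources.mean(axis=0)
        s_sd = s_c.std(axis=0)
        s_sd[s_sd == 0] = np.inf
        corr = np.abs(s_c.T @ eog_c / (s_c.shape[0] * s_sd * eog_sd))
    removed = [int(i) for i in np.flatnonzero(corr > r_threshold)]

    out = rec.copy()
    if removed:
        sources_kept = sources.copy()
        sources_kept[:, removed] = 0.0
        X_clean = ica.inverse_transform(sources_kept)
        out.samples[scalp_idx] = X_clean.T
    report = ICAReport(
        n_components=n_components,
        correlations=corr,
        removed=removed,
        threshold=r_threshold,
    )
    return out, report


# ---------------------------------------------------------------------------
# step 4: epoching
# ---------------------------------------------------------------------------

def epoch(
    rec: ContinuousRecording,
    events: EventTable,
    tmin: float = -0.2,
    tmax: float = 1.0,
) -> EpochSet:
    """Cut epochs on the half-open window [tmin, tmax) around each onset.

    Events whose full window does not fit inside the recording are dropped
    (their indices are recoverable from the returned ``events`` frame).
    Overlap between epochs is permitted and expected: events are ~1 s
    apart while the window spans 1.2 s.
    """
    fs = rec.sampling_rate
    n_win = int(round((tmax - tmin) * fs))
    offset = int(round(tmin * fs))
    starts = np.round(events.onsets * fs).astype(int) + offset
    ok = (starts >= 0) & (starts + n_win <= rec.n_times)
    kept = np.flatnonzero(ok)
    data = np.empty((kept.size, rec.n_channels, n_win))
    for j, i in enumerate(kept):
        data[j] = rec.samples[:, starts[i]:starts[i] + n_win]
    times_ms = (np.arange(n_win) + offset) / fs * 1000.0
    df = events.df.iloc[kept].reset_index(drop=True)
    return EpochSet(
        data,
        times_ms,
        fs,
        list(rec.channel_labels),
        dict(rec.channel_groups),
        df["trial_type"].to_numpy(object),
        dict(rec.montage2d),
        df,
    )


# ---------------------------------------------------------------------------
# step 5: baseline correction
# ---------------------------------------------------------------------------

def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-0.2, 0.0)
) -> EpochSet:
    """Subtract each channel's pre-stimulus mean from the whole epoch.

    ``window`` is in seconds, half-open [start, stop).
    """
    lo, hi = (w * 1000.0 for w in window)
    mask = (epochs.times_ms >= lo) & (epochs.times_ms < hi)
    if not mask.any():
        raise ValidationError("empty baseline window")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# step 6: peak-to-peak rejection
# ---------------------------------------------------------------------------

def reject_peak_to_peak(
    epochs: EpochSet, threshold: float = 200.0
) -> tuple[EpochSet, RejectionLog]:
    """Drop epochs whose min-max span exceeds ``threshold`` on any channel."""
    if epochs.n_epochs == 0:
        log = RejectionLog(np.zeros(0, bool), [], np.zeros(0), threshold)
        return epochs.copy(), log
    p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # epochs x channels
    worst = p2p.max(axis=1)
    worst_ch = p2p.argmax(axis=1)
    kept = worst <= threshold
    offending = [
        None if k else epochs.channel_labels[c]
        for k, c in zip(kept, worst_ch)
    ]
    log = RejectionLog(kept, offending, worst, threshold)
    return epochs._subset(kept), log


# ---------------------------------------------------------------------------
# canonical chain
# ---------------------------------------------------------------------------

def preprocess_recording(
    rec: ContinuousRecording,
    events: EventTable,
    low: float = 0.1,
    high: float = 40.0,
    run_ica: bool = True,
    eog_channel: str = "EOG",
    r_threshold: float = 0.8,
    p2p_threshold: float = 200.0,
    tmin: float = -0.2,
    tmax: float = 1.0,
) -> tuple[EpochSet, RejectionLog, ICAReport | None]:
    """Run the full chain (steps 1-6) and return cleaned epochs."""
    rec = rereference_all(rec)
    rec = bandpass_filter(rec, low, high)
    report = None
    if run_ica:
        rec, report = remove_eog_ica(rec, eog_channel, r_threshold)
    eps = epoch(rec, events, tmin, tmax)
    eps = baseline_correct(eps, (tmin, 0.0))
    eps, log = reject_peak_to_peak(eps, p2p_threshold)
    return eps, log, report
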