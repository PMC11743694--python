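"""Synthetic scalp + ear EEG with an embedded attention-modulated cognitive
component.

The generator emulates a word-category oddball experiment: trials of spoken
word events in which rare semantic targets elicit a parietal-maximal,
positive, P3b-like deflection peaking around 625 ms, while non-targets and
all events in an unattended stream elicit nothing.  Three paradigms are
supported:

``P1``
    single word stream, 20 events per 20 s trial, 2-5 targets, first two
    events always non-targets, inter-word gaps uniform on [0.8, 1.2] s;
``P2``
    two competing word streams (left / right), each structured like P1;
    per trial one stream is attended (balanced over trials), giving the
    four conditions AT / AN / UT / UN;
``P3``
    two competing continuous word streams (dense onsets, gaps uniform on
    [0.25, 0.6] s by default) with 2-5 sparse targets per stream.

The forward model is a fixed leadfield: a cognitive source (parietal lobe
positive, frontal lobe opposite sign, attenuated in the ear channels with a
zero-mean per-ear sign pattern), an ocular blink source mixed frontally and
recorded on a dedicated EOG channel, and independent 1/f^alpha background
noise per channel (ear channels noisier by a fixed factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ContinuousRecording, EventTable
from .montage import (
    cognitive_leadfield,
    default_channels,
    default_montage2d,
    leadfield_vector,
    ocular_leadfield,
)

PARADIGMS = ("P1", "P2", "P3")

#: Default attended-target peak amplitude (microvolts) per paradigm,
#: matching the component strengths the generator is meant to emulate.
DEFAULT_AT_AMPLITUDE = {"P1": 4.15, "P2": 3.3, "P3": 1.61}

#: Default number of trials per paradigm.
DEFAULT_N_TRIALS = {"P1": 16, "P2": 20, "P3": 20}


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated subject/recording.

    Amplitudes are peak values in microvolts; the AN/UT/UN amplitudes
    default to 0 (non-targets and unattended events elicit no component).
    ``noise_sigma`` is the standard deviation of the broadband 1/f^alpha
    background on scalp channels before any filtering; ear channels are
    scaled by ``ear_noise_factor``.
    """

    paradigm: str = "P1"
    n_trials: int | None = None
    sampling_rate: float = 1000.0
    erp_latency: float = 625.0          # ms
    erp_width: float = 300.0            # ms, Gaussian FWHM
    erp_amplitude: dict[str, float] | None = None   # uV per condition
    noise_sigma: float = 10.0           # uV
    noise_exponent: float = 1.0         # 1/f^alpha slope
    eog_rate: float = 0.12              # blinks / s
    eog_amplitude: float = 120.0        # uV at the EOG channel
    ear_attenuation: float = 0.15
    ear_noise_factor: float = 3.0
    eog_noise_factor: float = 0.2
    trial_length: float = 20.0          # s
    events_per_trial: int = 20          # P1/P2 streams
    target_range: tuple[int, int] = (2, 5)
    gap_range: tuple[float, float] = (0.8, 1.2)       # s, P1/P2
    dense_gap_range: tuple[float, float] = (0.25, 0.6)  # s, P3 word stream
    start_offset: float = 0.5           # s, first onset within a trial
    leadfield: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ConfigError(f"unknown paradigm {self.paradigm!r}")
        if self.n_trials is None:
            self.n_trials = DEFAULT_N_TRIALS[self.paradigm]
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.erp_width <= 0:
            raise ConfigError("erp_width must be positive")
        lo, hi = self.target_range
        if not (1 <= lo <= hi <= 5):
            raise ConfigError(
                f"target_range {self.target_range} must lie within [1, 5]"
            )
        if hi >= self.events_per_trial - 2:
            raise ConfigError("too many targets for the events per trial")
        if self.erp_amplitude is None:
            self.erp_amplitude = {
                "AT": DEFAULT_AT_AMPLITUDE[self.paradigm],
                "AN": 0.0, "UT": 0.0, "UN": 0.0,
            }
        else:
            amp = {"AT": 0.0, "AN": 0.0, "UT": 0.0, "UN": 0.0}
            amp.update(self.erp_amplitude)
            self.erp_amplitude = amp

    @property
    def duration(self) -> float:
        return self.n_trials * self.trial_length

    def amplitude_for(self, condition: str) -> float:
        # single-stream tokens map onto the attended-stream amplitudes
        alias = {"TARGET": "AT", "NONTARGET": "AN"}
        return self.erp_amplitude[alias.get(condition, condition)]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def pink_noise(
    shape: int | tuple[int, ...],
    exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """1/f^exponent Gaussian noise, unit standard deviation per row.

    Spectral shaping of white Gaussian noise: the FFT of a white draw is
    multiplied by f^(-exponent/2) (DC removed) and inverted.
    """
    if np.isscalar(shape):
        return pink_noise((1, int(shape)), exponent, rng)[0]
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def make_erp_template(
    latency: float,
    fwhm: float,
    amplitude: float,
    sampling_rate: float,
    duration: float = 1000.0,
) -> np.ndarray:
    """Parametric single-channel component waveform.

    A Gaussian bump (peak ``amplitude`` microvolts at ``latency`` ms, width
    given as FWHM in ms) with the straight line through its endpoint values
    subtracted so that the waveform is exactly zero at both window edges,
    then rescaled so the maximum equals ``amplitude`` at the sample nearest
    the requested latency.
    """
    if fwhm <= 0 or sampling_rate <= 0 or duration <= 0:
        raise ConfigError("fwhm, sampling_rate and duration must be positive")
    if not 0 <= latency <= duration:
        raise ConfigError(f"latency {latency} ms outside [0, {duration}] ms")
    n = int(round(duration / 1000.0 * sampling_rate))
    t = np.arange(n) / sampling_rate * 1000.0  # ms
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = np.exp(-((t - latency) ** 2) / (2.0 * sigma ** 2))
    ramp = g[0] + (g[-1] - g[0]) * (t - t[0]) / max(t[-1] - t[0], 1.0)
    y = np.maximum(g - ramp, 0.0)  # ramp can undershoot by ~1e-4 relative
    y[0] = y[-1] = 0.0             # exact zeros despite rounding
    peak = y.max()
    if amplitude == 0.0 or peak <= 0:
        return np.zeros(n)
    return y * (amplitude / peak)


def _blink_template(sampling_rate: float, width: float = 0.35) -> np.ndarray:
    """Unit-amplitude blink waveform (raised-cosine bump, ``width`` s)."""
    n = max(int(round(width * sampling_rate)), 3)
    return np.sin(np.pi * np.arange(n) / (n - 1)) ** 2


def _draw_gaps(
    rng: np.random.Generator,
    n_gaps: int,
    lo: float,
    hi: float,
    total: float,
    max_tries: int = 1000,
) -> np.ndarray:
    """Draw ``n_gaps`` uniform gaps on [lo, hi] that sum exactly to ``total``.

    Gaps are drawn i.i.d. and shifted by a common constant so the sum is
    exact; draws whose shifted gaps leave [lo, hi] are rejected and
    redrawn, so the stated range is honoured exactly.
    """
    if not n_gaps * lo <= total <= n_gaps * hi:
        raise ConfigError(
            f"cannot fit {n_gaps} gaps in [{lo}, {hi}] summing to {total}"
        )
    for _ in range(max_tries):
        g = rng.uniform(lo, hi, n_gaps)
        g = g + (total - g.sum()) / n_gaps
        if g.min() >= lo - 1e-12 and g.max() <= hi + 1e-12:
            return np.clip(g, lo, hi)
    raise ConfigError("could not draw a valid gap sequence")


# ---------------------------------------------------------------------------
# event sequences
# ---------------------------------------------------------------------------

def _oddball_stream(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One P1/P2-style stream: trial-relative onsets and a target mask."""
    n_ev = config.events_per_trial
    lo, hi = config.gap_range
    mean_gap = 0.5 * (lo + hi)
    gaps = _draw_gaps(rng, n_ev - 1, lo, hi, total=mean_gap * (n_ev - 1))
    onsets = config.start_offset + np.concatenate([[0.0], np.cumsum(gaps)])
    n_targets = int(rng.integers(config.target_range[0], config.target_range[1] + 1))
    target_idx = rng.choice(np.arange(2, n_ev), size=n_targets, replace=False)
    mask = np.zeros(n_ev, dtype=bool)
    mask[target_idx] = True
    return onsets, mask


def _dense_stream(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One P3-style stream: dense word onsets with sparse targets."""
    lo, hi = config.dense_gap_range
    onsets = [config.start_offset]
    while True:
        nxt = onsets[-1] + rng.uniform(lo, hi)
        if nxt > config.trial_length - config.start_offset:
            break
        onsets.append(nxt)
    onsets = np.array(onsets)
    n_ev = onsets.size
    if n_ev < 5:
        raise ConfigError("dense stream too short to place targets")
    n_targets = int(rng.integers(config.target_range[0], config.target_range[1] + 1))
    target_idx = rng.choice(np.arange(2, n_ev), size=n_targets, replace=False)
    mask = np.zeros(n_ev, dtype=bool)
    mask[target_idx] = True
    return onsets, mask


def make_event_sequence(
    config: SimulationConfig,
    trial: int,
    rng: np.random.Generator,
    attended_stream: str | None = None,
) -> EventTable:
    """Generate the event table of one trial.

    Onsets are absolute (seconds from recording start, the trial starting
    at ``trial * trial_length``).  For competing-stream paradigms the
    attended side may be fixed with ``attended_stream``; otherwise it is
    drawn from ``rng``.
    """
    t0 = trial * config.trial_length
    rows = []
    if config.paradigm == "P1":
        onsets, mask = _oddball_stream(config, rng)
        for o, is_t in zip(onsets, mask):
            rows.append((t0 + o, 0.0, "TARGET" if is_t else "NONTARGET",
                         "single", trial))
    else:
        if attended_stream is None:
            attended_stream = str(rng.choice(["left", "right"]))
        if attended_stream not in ("left", "right"):
            raise ConfigError(f"bad attended_stream {attended_stream!r}")
        maker = _oddball_stream if config.paradigm == "P2" else _dense_stream
        for stream in ("left", "right"):  # fixed order for determinism
            onsets, mask = maker(config, rng)
            attended = stream == attended_stream
            for o, is_t in zip(onsets, mask):
                cond = ("AT" if is_t else "AN") if attended else \
                       ("UT" if is_t else "UN")
                rows.append((t0 + o, 0.0, cond, stream, trial))
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type",
                                     "stream", "trial"])
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    return EventTable(df)


# ---------------------------------------------------------------------------
# full forward model
# ---------------------------------------------------------------------------

def simulate_recording(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ContinuousRecording, EventTable]:
    """Simulate one subject's continuous recording and its event table.

    samples = leadfield_cog * cognitive_source
            + leadfield_eog * blink_source
            + per-channel 1/f^alpha noise,
    where the cognitive source is a sum of per-event component templates
    scaled by each event's condition amplitude.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    labels, groups = default_channels()
    montage = default_montage2d()

    if config.leadfield is not None:
        cog_w = dict(config.leadfield["cognitive"])
        eog_w = dict(config.leadfield["ocular"])
    else:
        cog_w = cognitive_leadfield(ear_attenuation=config.ear_attenuation)
        eog_w = ocular_leadfield()
    cog = leadfield_vector(cog_w, labels)
    ocu = leadfield_vector(eog_w, labels)

    # events: balanced attended sides for competing-stream paradigms
    if config.paradigm == "P1":
        sides: list[str | None] = [None] * config.n_trials
    else:
        half = (config.n_trials + 1) // 2
        sides = (["left", "right"] * half)[: config.n_trials]
        sides = [sides[i] for i in rng.permutation(config.n_trials)]
    tables = [
        make_event_sequence(config, trial, rng, attended_stream=sides[trial])
        for trial in range(config.n_trials)
    ]
    events = EventTable(pd.concat([t.df for t in tables], ignore_index=True))

    n_times = int(round(config.duration * fs))

    # cognitive source: per-event templates
    source = np.zeros(n_times)
    template = make_erp_template(
        config.erp_latency, config.erp_width, 1.0, fs, duration=1000.0
    )
    for onset, cond in zip(events.onsets, events.conditions):
        amp = config.amplitude_for(cond)
        if amp == 0.0:
            continue
        s0 = int(round(onset * fs))
        s1 = min(s0 + template.size, n_times)
        source[s0:s1] += amp * template[: s1 - s0]

    # ocular source: Poisson blink train
    blink_src = np.zeros(n_times)
    if config.eog_rate > 0:
        n_blinks = rng.poisson(config.eog_rate * config.duration)
        blink = _blink_template(fs)
        starts = np.sort(rng.uniform(0, config.duration, n_blinks))
        amps = config.eog_amplitude * rng.uniform(0.8, 1.2, n_blinks)
        for t_b, a in zip(starts, amps):
            s0 = int(round(t_b * fs))
            s1 = min(s0 + blink.size, n_times)
            blink_src[s0:s1] += a * blink[: s1 - s0]

    noise_scale = np.array(
        [
            config.noise_sigma
            * {
                "scalp": 1.0,
                "ear_left": config.ear_noise_factor,
                "ear_right": config.ear_noise_factor,
                "eog": config.eog_noise_factor,
            }[groups[c]]
            for c in labels
        ]
    )
    if config.noise_sigma > 0:
        noise = pink_noise((len(labels), n_times), config.noise_exponent, rng)
        noise *= noise_scale[:, None]
    else:
        noise = np.zeros((len(labels), n_times))

    samples = cog[:, None] * source + ocu[:, None] * blink_src + noise
    rec = ContinuousRecording(samples, fs, labels, groups, montage)
    return rec, events


def simulate_subjects(
    config: SimulationConfig, n_subjects: int
) -> list[tuple[ContinuousRecording, EventTable]]:
    """Simulate a cohort: per-subject child seeds derived from the root seed."""
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(n_subjects)
    return [
        simulate_recording(config, rng=np.random.default_rng(child))
        for child in children
    ]
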