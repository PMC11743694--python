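"""Preprocessing chain: referencing, filtering, ICA, epoching, rejection."""

import numpy as np
import pytest

from attnerp import (
    ContinuousRecording,
    SimulationConfig,
    ValidationError,
    simulate_recording,
)
from attnerp.montage import default_channels, default_montage2d
from attnerp.preprocess import (
    bandpass_filter,
    baseline_correct,
    design_bandpass,
    epoch,
    preprocess_recording,
    reject_peak_to_peak,
    remove_eog_ica,
    rereference,
    rereference_all,
)


def _recording(samples, fs=250.0):
    labels, groups = default_channels()
    return ContinuousRecording(samples, fs, labels, groups, default_montage2d())


# ---------------------------------------------------------------------------
# re-referencing
# ---------------------------------------------------------------------------

def test_common_scalp_signal_vanishes_under_average_reference(rng):
    labels, groups = default_channels()
    n = 500
    common = rng.standard_normal(n)
    samples = rng.standard_normal((len(labels), n))
    scalp = [i for i, c in enumerate(labels) if groups[c] == "scalp"]
    samples[scalp] = common  # all scalp channels identical
    rec = _recording(samples)
    out = rereference(rec, "scalp_average")
    np.testing.assert_allclose(out.samples[scalp], 0.0, atol=1e-12)


def test_scalp_channels_sum_to_zero_after_average_reference(rng):
    labels, groups = default_channels()
    rec = _recording(rng.standard_normal((len(labels), 400)))
    out = rereference(rec, "scalp_average")
    scalp = out.group_indices("scalp")
    np.testing.assert_allclose(out.samples[scalp].sum(axis=0), 0.0, atol=1e-10)


def test_per_ear_reference_leaves_other_groups_untouched(rng):
    labels, groups = default_channels()
    rec = _recording(rng.standard_normal((len(labels), 400)))
    out = rereference(rec, "per_ear_average")
    for grp in ("scalp", "eog"):
        idx = rec.group_indices(grp)
        assert out.samples[idx].tobytes() == rec.samples[idx].tobytes()
    left = out.group_indices("ear_left")
    np.testing.assert_allclose(out.samples[left].mean(axis=0), 0.0, atol=1e-10)


def test_rereference_empty_group_errors(rng):
    labels = ["Pz", "Cz"]
    rec = ContinuousRecording(
        rng.standard_normal((2, 100)), 100.0, labels,
        {c: "scalp" for c in labels},
        {"Pz": (0, -0.45), "Cz": (0, 0)},
    )
    with pytest.raises(ValidationError):
        rereference(rec, "per_ear_average")


def test_rereference_is_idempotent(rng):
    labels, groups = default_channels()
    rec = _recording(rng.standard_normal((len(labels), 300)))
    once = rereference_all(rec)
    twice = rereference_all(once)
    np.testing.assert_allclose(twice.samples, once.samples, atol=1e-10)


# ---------------------------------------------------------------------------
# bandpass filter
# ---------------------------------------------------------------------------

def test_dc_is_removed_and_passband_preserved():
    fs = 250.0
    t = np.arange(int(30 * fs)) / fs
    labels, groups = default_channels()
    n_ch = len(labels)
    dc = np.full((n_ch, t.size), 7.0)
    rec = _recording(dc, fs)
    out = bandpass_filter(rec, 0.1, 40.0)
    mid = slice(int(5 * fs), int(25 * fs))
    assert np.abs(out.samples[:, mid]).max() < 0.01 * 7.0

    sine = np.tile(np.sin(2 * np.pi * 10.0 * t), (n_ch, 1))
    out = bandpass_filter(_recording(sine, fs), 0.1, 40.0)
    amp = np.abs(out.samples[0, mid]).max()
    assert amp == pytest.approx(1.0, rel=0.05)
    # zero phase: peak cross-correlation with the input at lag 0
    seg_in = sine[0, mid]
    seg_out = out.samples[0, mid]
    lags = range(-5, 6)
    xc = [np.dot(seg_out, np.roll(seg_in, k)) for k in lags]
    assert list(lags)[int(np.argmax(xc))] == 0


def test_filtered_impulse_is_symmetric():
    kernel = design_bandpass(0.1, 40.0, 250.0)
    np.testing.assert_allclose(kernel, kernel[::-1], atol=1e-12)
    assert abs(kernel.sum()) < 1e-9  # exact DC null


def test_invalid_corner_frequencies_error():
    fs = 250.0
    labels, _ = default_channels()
    rec = _recording(np.zeros((len(labels), 1000)), fs)
    for low, high in ((0.0, 40.0), (40.0, 0.1), (0.1, 200.0)):
        with pytest.raises(ValueError):
            bandpass_filter(rec, low, high)


def test_filtering_and_epoching_commute_with_channel_permutation(rng):
    cfg = SimulationConfig(paradigm="P1", sampling_rate=125.0, n_trials=1,
                           seed=3, eog_rate=0.0)
    rec, events = simulate_recording(cfg)
    perm = rng.permutation(rec.n_channels)
    labels_p = [rec.channel_labels[i] for i in perm]
    rec_p = rec.pick(labels_p)
    a = epoch(bandpass_filter(rec), events)
    b = epoch(bandpass_filter(rec_p), events)
    for c in ("Pz", "EL_A"):
        np.testing.assert_allclose(a.get_channel(c), b.get_channel(c), atol=1e-9)


# ---------------------------------------------------------------------------
# ICA-based EOG removal
# ---------------------------------------------------------------------------

def test_blink_component_is_removed_and_frontal_channel_cleaned():
    cfg = SimulationConfig(paradigm="P1", sampling_rate=125.0, n_trials=8,
                           seed=17, eog_rate=0.15)
    rec, events = simulate_recording(cfg)
    filtered = bandpass_filter(rereference_all(rec))
    cleaned, report = remove_eog_ica(filtered)
    assert len(report.removed) >= 1
    eog = filtered.get_channel("EOG")
    r_after = np.corrcoef(cleaned.get_channel("Fp1"), eog)[0, 1]
    assert abs(r_after) < 0.3


def test_no_blinks_means_no_components_removed():
    cfg = SimulationConfig(paradigm="P1", sampling_rate=125.0, n_trials=4,
                           seed=19, eog_rate=0.0)
    rec, events = simulate_recording(cfg)
    filtered = bandpass_filter(rereference_all(rec))
    cleaned, report = remove_eog_ica(filtered)
    assert report.removed == []
    # nothing removed -> scalp data untouched
    np.testing.assert_allclose(cleaned.samples, filtered.samples, atol=1e-9)


def test_missing_eog_channel_errors(rng):
    labels, groups = default_channels()
    rec = _recording(rng.standard_normal((len(labels), 500)))
    with pytest.raises(ValidationError):
        remove_eog_ica(rec, eog_channel="nope")


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def test_epoch_window_convention_and_clipping(rng):
    labels, _ = default_channels()
    fs = 125.0
    rec = _recording(rng.standard_normal((len(labels), int(10 * fs))), fs)
    import pandas as pd

    from attnerp.core import EventTable

    df = pd.DataFrame({
        "onset": [0.1, 2.0, 5.0, 9.5],   # first starts before 0, last clipped
        "duration": 0.0,
        "trial_type": ["NONTARGET"] * 4,
        "stream": "single",
        "trial": 0,
    })
    eps = epoch(rec, EventTable(df))
    assert eps.n_epochs == 2
    assert eps.n_samples == round(1.2 * fs)
    assert eps.times_ms[0] == pytest.approx(-200.0)
    assert eps.times_ms[-1] < 1000.0  # half-open [tmin, tmax)
    # content check: epoch 0 is the slice around 2.0 s
    i0 = int(round(2.0 * fs)) + int(round(-0.2 * fs))
    np.testing.assert_array_equal(eps.data[0], rec.samples[:, i0:i0 + eps.n_samples])


def test_all_events_inside_gives_one_epoch_per_event(clean_p1):
    _, rec, events, _ = clean_p1
    eps = epoch(rec, events)
    inside = ((events.onsets >= 0.2) &
              (events.onsets + 1.0 <= rec.duration)).sum()
    assert eps.n_epochs == inside


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------

def test_baseline_of_constant_epoch_is_zero_and_offset_invariant(clean_p1):
    *_, eps = clean_p1
    const = eps.copy()
    const.data[:] = 3.14
    out = baseline_correct(const)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    shifted = eps.copy()
    shifted.data = shifted.data + 42.0
    np.testing.assert_allclose(
        baseline_correct(shifted).data, baseline_correct(eps).data, atol=1e-9
    )


def test_baseline_window_mean_is_zero_after_correction(noisy_p1):
    *_, eps, _ = noisy_p1
    base = eps.times_ms < 0
    means = eps.data[:, :, base].mean(axis=2)
    np.testing.assert_allclose(means, 0.0, atol=1e-9)


def test_empty_baseline_window_errors(clean_p1):
    *_, eps = clean_p1
    with pytest.raises(ValidationError):
        baseline_correct(eps, window=(-0.5, -0.4))


# ---------------------------------------------------------------------------
# peak-to-peak rejection
# ---------------------------------------------------------------------------

def test_peak_to_peak_rejection_boundary(clean_p1):
    *_, eps = clean_p1
    mod = eps.copy()
    mod.data[:] = 0.0
    mod.data[0, mod.channel_index("Cz"), 5] = 250.0   # span 250 -> rejected
    mod.data[1, :, 10] = 100.0
    mod.data[1, :, 20] = -100.0                       # span exactly 200 -> kept
    kept, log = reject_peak_to_peak(mod, threshold=200.0)
    assert not log.kept[0] and log.kept[1:].all()
    assert log.offending_channel[0] == "Cz"
    assert kept.n_epochs == mod.n_epochs - 1
    assert log.kept.sum() + log.n_rejected == mod.n_epochs


def test_empty_epoch_set_passes_through(clean_p1):
    *_, eps = clean_p1
    empty = eps._subset(np.zeros(eps.n_epochs, bool))
    out, log = reject_peak_to_peak(empty)
    assert out.n_epochs == 0 and log.kept.size == 0


# ---------------------------------------------------------------------------
# whole chain
# ---------------------------------------------------------------------------

def test_noise_free_preprocessed_epoch_matches_template(clean_p1):
    """After the full chain, the average target-minus-non-target wave at Pz
    reproduces the embedded template within filter-transition tolerance."""
    cfg, _, _, eps = clean_p1
    from attnerp import average_epochs, difference_wave, make_erp_template

    d = difference_wave(average_epochs(eps, "TARGET"),
                        average_epochs(eps, "NONTARGET"))
    tpl = make_erp_template(cfg.erp_latency, cfg.erp_width, 4.15,
                            cfg.sampling_rate, 1000.0)
    got = d.get_channel("Pz")[eps.times_ms >= 0][: tpl.size]
    assert np.abs(got - tpl).max() < 0.10 * 4.15
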