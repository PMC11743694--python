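# attnerp

Analysis of a late, attention-modulated cognitive ERP component — a
P3b-like positive deflection over centro-parietal scalp, peaking around
625 ms after semantically defined spoken-word targets — in scalp **and
in-ear EEG**. The package is aimed at auditory-attention-decoding (AAD)
research: unlike envelope-tracking methods, which exploit the early
response to a stimulus' acoustics, this component indexes the *cognitive
processing* of speech events and is elicited only by targets in the
attended stream.

Because datasets for this paradigm are not generally available, the
package ships a forward-model simulator as a first-class, tested module:
paradigm-structured event sequences (single-stream oddball, competing
word streams, competing continuous speech), a parietal-maximal component
whose amplitude depends on attention and paradigm realism, frontal
ocular artifacts, 1/f background noise, and 32 scalp + 2×6 ear channels.
Every downstream stage runs identically on simulated or real recordings
stored in the BIDS-style layout.

## What it computes

* **Preprocessing** — average-reference (scalp) / within-ear reference,
  zero-phase FIR bandpass 0.1–40 Hz, FastICA removal of EOG-correlated
  components, epoching on [−200, 1000) ms, baseline correction,
  200 µV peak-to-peak rejection.
* **ERPs** — condition averages, difference waves (e.g. AT−AN),
  unweighted grand averages, peak quantification inside significant
  windows.
* **Max-SNR ear-EEG spatial filter** — the weight vector `w` maximizing

  ```
  w' R_T w   subject to   w' R_N w = 1
  ```

  where `R_T` is the autocorrelation of the averaged target epoch and
  `R_N` that of the concatenated non-target epochs; solved as a
  generalized eigenvalue problem (top eigenvector of `(R_T, R_N)`), with
  shrinkage regularization, a positive-going sign convention, and
  leave-one-paradigm-out cross-task validation. Model/results idiom:

  ```python
  res = MaxSNRFilter(target_epochs, nontarget_epochs, ear="left").fit()
  virtual = res.apply(heldout_epochs)   # single virtual channel
  print(res.summary())
  ```

* **Statistics** — label-permutation tests, temporal and spatial
  (channel-adjacency) cluster-based permutation tests thresholding the
  raw mean-difference statistic, a cosine-similarity permutation test
  between ear and scalp difference ERPs, and Bonferroni bookkeeping.
  All p-values use the add-one rule, so the minimum attainable p at
  1,000 permutations is ~0.001.

See `docs/methods.md` for the model, its assumptions and all numerical
choices.

## Worked example

Simulate a 10-subject single-stream oddball cohort, run the full chain,
and test the target−non-target contrast at Pz:

```python
import numpy as np
from attnerp import (SimulationConfig, simulate_recording,
                     preprocess_recording, average_epochs, difference_wave,
                     grand_average, quantify_peak, temporal_cluster_test)

diffs, pooled_t, pooled_n = [], [], []
for child in np.random.SeedSequence(11).spawn(10):
    cfg = SimulationConfig(paradigm="P1", sampling_rate=125.0)
    rec, events = simulate_recording(cfg, rng=np.random.default_rng(child))
    epochs, log, ica = preprocess_recording(rec, events)
    diffs.append(difference_wave(average_epochs(epochs, "TARGET"),
                                 average_epochs(epochs, "NONTARGET")))
    pz = epochs.get_channel("Pz")
    pooled_t.append(pz[epochs.conditions == "TARGET"])
    pooled_n.append(pz[epochs.conditions == "NONTARGET"])

res = temporal_cluster_test(np.concatenate(pooled_t), np.concatenate(pooled_n),
                            threshold=1.0, n_perm=1000, seed=5,
                            times_ms=epochs.times_ms)
print(res.summary())
ga = grand_average(diffs)
print(quantify_peak(ga, "Pz", res.extents_ms()[int(res.p_values.argmin())]))
```

Output:

```
temporal cluster permutation test (two-sided, threshold 1, 1000 permutations)
    cluster       stat  p_value
392..840 ms 144.411096 0.000999
PeakMeasure(amplitude=3.8971281560182747, latency=616.0, edge=False)
```

The cluster test finds one significant cluster (p ≈ 0.001, the smallest
value 1,000 permutations can resolve) spanning 392–840 ms, and the
grand-average difference wave peaks at 3.90 µV, 616 ms — recovering the
embedded 4.15 µV / 625 ms component to within sampling noise at this
cohort size.

The same chain is scriptable from the shell:

```sh
attnerp simulate --paradigm 1 --subjects 4 --rate 125 --seed 3 --out data/
attnerp preprocess --in data/ --out prep/
attnerp cluster-test --in prep/ --channel Pz --threshold 1.0 --n-perm 1000 --seed 1
attnerp run-all --subjects 10 --paradigms P1,P2,P3 --rate 125 --seed 1 --out run/
```

`run-all` writes grand-average ERP tables, spatial/temporal cluster
tables, per-ear cross-task-validated filters, a Table-style ear–scalp
similarity summary, and `summary.tsv` with cluster extents and p-values
per paradigm and contrast.

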