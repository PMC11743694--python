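# Methods

`attnerp` analyses a late, attention-modulated cognitive ERP component —
a P3b-like positive deflection over centro-parietal sites peaking around
625 ms after a semantically defined target word — in scalp and in-ear EEG.
Because no public dataset accompanies this problem setting, the package
pairs the analysis chain with a forward-model simulator, so every stage is
testable end to end and its statistical behaviour (calibration, power,
parameter recovery) can be measured rather than assumed.

## The simulated experiment

Three paradigms of increasing realism are generated:

* **P1 (word-category oddball).** One stream of 20 spoken-word events per
  20 s trial; 2–5 of them are semantic targets, the first two events are
  always non-targets, and consecutive onsets are 0.8–1.2 s apart.
  Default: 16 trials per subject.
* **P2 (competing word streams).** Two P1-like streams (left/right), one
  attended per trial (balanced over trials), giving the conditions AT/AN
  (target/non-target in the attended stream) and UT/UN (unattended).
  Default: 20 trials.
* **P3 (competing continuous speech).** Dense word onsets (gaps uniform
  on 0.25–0.6 s — a configurable placeholder, since word-rate statistics
  of natural story reading are not part of this model) with 2–5 sparse
  targets per stream. Default: 20 trials.

To reconcile the fixed gap distribution with the fixed 20 s trial length,
the 19 gaps of an oddball stream are drawn i.i.d. from U(0.8, 1.2) s and
shifted by a common constant so they sum to exactly 19 s; draws whose
shifted gaps leave the interval are rejected and redrawn, so both the
stated range and the trial length hold exactly. The first onset falls
0.5 s into the trial, which keeps inter-event gaps across trial
boundaries near 1 s in the concatenated recording.

## Forward model

The recording has 32 scalp channels (10/20 layout), two 6-electrode
earpieces (sites A, B, C, T, E, I per ear) and one EOG channel, sampled
at 1 kHz by default. Three sources are mixed through a fixed leadfield:

* **Cognitive component.** A windowed-Gaussian waveform (peak amplitude
  per condition, latency 625 ms, FWHM 300 ms; endpoint-ramp-corrected so
  it is exactly zero at the window edges) added at every event onset.
  The scalp pattern is parietal-maximal with an opposite-sign frontal
  lobe and is centred to zero mean across scalp channels — a dipolar
  potential integrates to approximately zero over the scalp, and a
  zero-mean pattern is invariant under average referencing, so the
  generated Pz amplitude equals the nominal amplitude after
  preprocessing. Default condition amplitudes: AT 4.15 µV (P1), 3.3 µV
  (P2), 1.61 µV (P3); AN/UT/UN 0 µV (non-targets and unattended events
  elicit nothing).
* **Ear projection.** Each ear sees the component attenuated by 0.15
  with the sign pattern (+1, +0.7, +0.4, −0.4, −0.7, −1) across its six
  sites: an in-ear projection of a distant source plausibly changes sign
  along the canal, and a zero-mean pattern survives within-ear average
  referencing. These numbers are model choices, not measurements; ear
  SNR is controlled independently of the scalp.
* **Ocular artifacts.** Raised-cosine blinks (0.35 s) at a Poisson rate
  of 0.12 blinks/s, 120 µV at the EOG channel, mixed frontally into the
  scalp with weights decaying toward the back of the head.
* **Background noise.** Independent per-channel 1/f^α noise (α = 1),
  generated by spectral shaping of white Gaussian noise; the scalp
  standard deviation defaults to 10 µV broadband, a realistic magnitude
  for 0.1–40 Hz EEG relative to a ~4 µV single-trial component, and ear
  channels are 3× noisier.

One root seed drives everything; subject-level streams are spawned
deterministically from it, so identical configuration + seed gives
bit-identical output.

### What the simulator does *not* emulate

No acoustic stimulus content, no envelope-following (exogenous) response,
no alpha rhythm or other structured oscillations, no muscle or line
noise, no inter-subject variability in latency/topography/anatomy, and
no spatially correlated noise (channels are independent). Consequently,
passing recovery and power checks demonstrates that the *chain* is
correct and calibrated under its stated assumptions — not that real
ear-EEG will show the component at these effect sizes; the real-data
situation is precisely the hard regime discussed under "spatial filter"
below.

## Preprocessing

1. Scalp channels re-referenced to the scalp average; ear channels to
   the average within each ear (the references are independent, so the
   two modalities decouple).
2. Zero-phase FIR bandpass, 0.1–40 Hz. The kernel is a symmetric Hamming
   windowed-sinc (high-pass transition 0.1 Hz, low-pass transition
   10 Hz, −6 dB at the corners) applied as a single centred convolution
   with odd-reflection edge padding. A symmetric kernel applied centred
   is exactly zero-phase while preserving the designed magnitude
   response; a forward–backward pass would square the response instead.
   The high-pass is built by spectral inversion, so DC gain is exactly 0.
3. FastICA on the scalp channels only (component count = channels − 1,
   the rank after average referencing; EOG excluded from the
   decomposition). Components whose activation correlates with the EOG
   channel at |r| > 0.8 are removed before reconstruction. The unmixing
   matrix is estimated on every 4th sample — a spatial decomposition
   needs far fewer samples than the recording holds — then applied to
   the full data; correlations use the full activations. The solver's
   internal seed is fixed, so the decomposition is reproducible. The
   correlation is computed on bandpassed signals against a dedicated EOG
   channel (both configurable).
4. Epochs cut on the half-open window [−200, 1000) ms around each
   onset (events snapped to the nearest sample; epochs whose window
   does not fit inside the recording are dropped). Overlap between
   epochs is inherent: events are ~1 s apart while windows span 1.2 s.
5. Baseline correction: per epoch and channel, the mean over
   [−200, 0) ms is subtracted from the whole epoch.
6. Peak-to-peak rejection: an epoch is dropped when *any* channel spans
   more than 200 µV (the any-channel reading; requiring all channels to
   exceed would essentially never reject).

## ERP measures

Individual ERPs are sample-wise means over a condition's surviving
epochs; difference waves subtract condition ERPs; grand averages are
unweighted across subjects (every subject counts equally regardless of
surviving-epoch counts). Peaks are measured as the maximum of the
(positive-going) waveform inside a window — by default the extent of the
most significant cluster — with ties broken toward the earliest latency
and a flag raised when the maximum sits on the window edge (not a local
peak). Peak quantification on the grand average is the default; per-
subject peaks can be measured with the same function when the
mean-of-individual-peaks convention is wanted.

## Max-SNR spatial filter

For each ear, the filter w (one weight per ear channel) maximizes

    w' R_T w   subject to   w' R_N w = 1,

with R_T the autocorrelation of the *averaged* target epoch and R_N that
of the non-target epochs concatenated along time. The solution is the
top generalized eigenvector of (R_T, R_N); the attained eigenvalue is
the maximized energy ratio, and any positive rescaling of a maximizer is
also a maximizer, which the unit-output-power constraint resolves.

Numerical choices:

* **Shrinkage.** Within-ear average referencing leaves R_N rank
  deficient, so R_N is shrunk toward scaled identity,
  (1−γ)R_N + γ(tr R_N/C)I, γ = 0.05 by default. The returned w is
  rescaled against the *raw* R_N whenever that is non-degenerate, so the
  stated constraint holds exactly.
* **Sign.** The eigenvector sign is arbitrary; it is chosen so the
  filtered average-target waveform has non-negative mean over
  400–800 ms, making the virtual channel positive-going like the scalp
  component (needed for meaningful cosine similarity).
* **Degenerate target.** If the averaged target epoch is (near) zero the
  objective is ill-defined; the filter falls back to the direction of
  largest non-target variance with an explicit warning rather than
  failing silently.
* **Training window.** R_T/R_N use the full [−200, 1000) ms epoch.

Cross-task validation trains each paradigm's filter on the *pooled*
epochs of the other paradigms (pooling maximizes the training sample;
averaging per-paradigm covariances first is the obvious alternative and
is deliberately not the default) and applies it to the held-out
paradigm only; the result records its training provenance.

## Statistics

All tests permute condition labels and use the add-one rule
p = (1 + #{perm ≥ obs})/(1 + n_perm), so p = 0 cannot occur and the
smallest attainable p at 1,000 permutations is ~0.001. The permutation
unit is the epoch, pooled across subjects (a subject-level unit can be
emulated by testing per subject); all procedures accept a seed.

* **Temporal cluster test.** The per-sample mean difference waveform is
  thresholded (default 1.0 µV for scalp, 0.5 µV for the low-amplitude
  ear channels); maximal runs of same-sign supra-threshold samples form
  clusters scored by the summed difference; the null is the maximum
  (absolute) cluster score per permutation, with 0 for permutations
  without clusters. The cluster-forming threshold moves sensitivity,
  not the false-alarm rate — the calibration experiment measures this
  directly at both default thresholds.
* **Spatial cluster test.** Per-channel statistics are window-averaged
  mean differences; clusters are connected components of same-sign
  supra-threshold channels in an adjacency graph built from the planar
  montage (channels within 1.5× the median nearest-neighbour distance).
* **Cosine similarity.** The angle between the (spatially filtered,
  single-channel) ear difference ERP and a scalp difference wave over
  the full epoch; the null shuffles the ear epochs' target/non-target
  labels and rescores. Proportional waveforms score exactly 1,
  orthogonal ones 0; a zero-norm waveform raises an error.
* **Bonferroni.** α/n for n planned comparisons (0.0125 for the four
  condition contrasts, 0.025 for two ears).

## Validation experiments and problem sizes

The `experiments` module packages the end-to-end checks. Statistical
experiments run at 125 Hz: the component lives below ~5 Hz, so an 8 ms
sample step changes nothing statistically while cutting memory and time
roughly 8-fold. Sizes used by the test suite:

* GEVD exactness: 20 random 4×4 SPD pairs against a 100,000-direction
  random Rayleigh search.
* Parameter recovery: one 20-subject default P1 cohort (peak amplitude,
  latency, cluster extent); detection power: 20 repetitions of 8-subject
  cohorts (pooled epochs per repetition give ample power, so the
  repetition count, not the cohort size, limits the rate estimate).
* Type-I calibration: 200 no-component cohorts (1 subject × 4 trials),
  each tested at thresholds 1.0 and 0.5 µV.
* Ear SNR gain: 50 single-subject datasets at noise σ = 0.5 µV with 48
  trials, filter trained on 32 and compared on the held-out 16 against
  the best single ear channel's energy ratio. This is deliberately a
  *mechanism* test: at the realistic default noise (σ = 10 µV) the
  component is far below the single-subject training-covariance noise
  floor, the GEVD cannot find it, and held-out gains vanish — matching
  the known difficulty of extracting this component from real ear-EEG.
  The clean regime verifies that the estimator does what it claims when
  the component is identifiable at all.
* Similarity null: 500 runs of 1/f-noise-only ear epochs, 300
  permutations each.

## Known limitations

* The FastICA step removes only EOG-correlated components; other
  artifact classes pass through (by design).
* Cluster inference is at the cluster level: extents are descriptive,
  not pointwise confidence regions.
* The epoch-level permutation unit treats pooled epochs as exchangeable
  across subjects; with strong between-subject heterogeneity a
  subject-level scheme is more faithful.
* The simulator's independence assumptions (noise across channels,
  subjects identical up to noise) make power estimates optimistic
  relative to real recordings.
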