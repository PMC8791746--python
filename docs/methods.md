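# Methods

## Problem and scope

The package classifies single 4-second EEG epochs ("instances") into a
small set of silently-repeated command words plus a rest state, using
only spectral shape, a bank of pairwise linear SVMs with majority
voting, and Monte-Carlo cross-validation. All stages operate per
subject: no cross-subject transfer is attempted, and no real-data
accuracies are claimed — the synthetic generator exists precisely so the
pipeline's *behaviour* (counts, invariances, orderings, chance levels)
can be verified without access to clinical recordings.

## Synthetic acquisition model

One subject's campaign is 5 sessions × 2 parts × 3 tests = 30 records.
Parts are numbered chronologically 0–9 ("record id"). Each test
presents 2 words + Silence for 20 trials; a trial is an independent
uniform permutation of the three classes, so a test is 60 instances at
Ti = 4 s spacing, back to back (the schedule generator warns when a test
would exceed the 240 s comfort cap). Each word therefore yields 200
instances and Silence 600 per subject. Two sync rows mirror the
schedule: one holds the class code as a constant level during the
instance, the other a 50 ms pulse at onset — any lossless encoding would
do; this one is the fixed internal convention.

Signal model per instance window, on each of the 19 scalp channels:

* background: Gaussian 1/f^α noise (α = 1 by default), RMS 10 µV,
  independent per channel and instance, DC-free;
* class signal: a sum of sinusoids from the class's `ClassSignature`
  with random phase per channel and instance. Default signatures give
  each word a single peak of 2.5 µV, with within-test pairs 2 Hz apart
  (10/12, 15/17, 20/22 Hz) — separable on the 1 Hz feature grid, but
  close enough that drift mixes them when records are pooled. Silence
  has no peaks. A1/A2 (earlobe references) carry background only.

Nonstationarity is modelled as *record-common* linear drift: amplitudes
scale by (1 + 0.05·record_id) and peak frequencies shift by
0.25 Hz·record_id, shared across the classes of a record. This is the
mechanism that makes the three time modes differ: within one record the
common shift cancels (short-time), between records it either adds
between-class separation (mixed-time) or smears a pooled class
(long-time). These defaults are the study conditions of every test; they
were chosen once as a plausible caricature of electrode-placement and
state drift and are not adjusted per experiment.

What the generator does **not** model: dipole/forward-model physiology,
eye-blink or EMG artifact morphology (the emulated protocol minimizes
blinks; artifacts enter only via `inject_artifact`'s energy scaling),
inter-channel correlation structure, and any genuine linguistic
content. Passing tests therefore demonstrate that the *pipeline*
behaves correctly and that its accuracy respects the drift structure —
not that real imagined speech is decodable at any particular rate.

## Preprocessing choices

* Filter: 4th-order Butterworth low-pass at 32 Hz, applied zero-phase
  (forward-backward), so sync onsets stay aligned; the 50 Hz mains line
  is attenuated far beyond the 20 dB requirement.
* Downsampling: block averaging with factor 5 (500 → 100 Hz); trailing
  remainder samples are dropped. Order is fixed filter-first — block
  averaging alone would alias content above 50 Hz.
* Segmentation: one segment per sync event, cropped from the end or
  zero-padded at the end to exactly Ti·fs = 400 samples; an onset
  beyond the data end skips that instance with a warning.
* Artifact rejection: energy = mean squared sample pooled over
  channels (one scalar per instance); reject iff outside [Ē/k, Ē·k]
  with k = 3 by default, Ē the mean over the segment batch being
  processed (per record-batch, not per subject — either reading is
  defensible; the batch is whatever the caller passes). k is a knob,
  and the < 2 % rejection rate observed on clean synthetic data is a
  sanity check, not a calibration target. Note the criterion needs a
  reasonably large batch: a single 100× outlier among only ~15 segments
  inflates Ē enough to flag everything, which is why rejection is a
  batch step over at least one full 60-instance record.

## Feature choices

* Window: T_w = 1 s wait (covers cue + rest), T_s = 2.5 s analysed,
  hence native resolution 0.4 Hz.
* Magnitude FFT, rectangular window (no taper).
* 1 Hz resampling by averaging native bins with centers in
  [f − 0.5, f + 0.5) for integer f ∈ 0..32 — robust to leakage; linear
  interpolation is available as `resample_method="interp"`.
* Normalization per channel by that channel's maximum (channels differ
  in gain; an all-zero channel passes through as zeros), then DC is
  dropped and the 1..31 Hz band kept: N_f = 31, L_f = 589. The
  retained band is configurable; 1..32 Hz (N_f = 32) is selectable via
  `freq_hi_hz=32` — the DC-exclusion reading (31 values) is the
  default because only bins 0..31 survive the 32 Hz filter intact.
* Consequences proved in tests: features live in [0, 1], are invariant
  to overall amplitude scaling, and their length is independent of
  sampling rate and window duration.

## Classifier choices

* Base learner: scikit-learn `SVC(kernel="linear", C=1.0)`; only the
  hyperplane (w, b) is retained. No probability calibration, no
  decision-value fallback — votes are hard, as the majority rule
  requires. Classes are assumed balanced; no class weighting.
* Tie-break: the specialist rule applies only to an *exactly*-two-way
  tie at the maximum vote count; three or more tied classes yield
  Unknown. The implementation is verified against an independent
  restatement of the rule on every possible vote pattern for n ≤ 4.
* Unknown predictions always stay in the accuracy denominator.

## Evaluation choices

* Splits are stratified per class, train size floor(0.7·n_c), at least
  one sample on each side; a class with fewer than 2 samples is an
  error. σ is the population standard deviation over the round
  accuracies. The identity trace(C)/sum(C) = count-weighted mean of the
  A_r is asserted exactly; the report separates the per-round spread
  from anything pooled over classifiers so the two are never conflated.
* A master `SeedSequence` spawns one child per Monte-Carlo round, so
  any round is reproducible in isolation; every stochastic entry point
  takes an int or SeedSequence.
* Mixed-time enumeration (604 800 assignments for 7 classes on 10
  records) is counted exactly but never enumerated for evaluation;
  callers sample assignments (the convention elsewhere is ~100 random
  assignments).

## Chance-level benchmarking

`label_independence_benchmark` draws label-independent uniform feature
vectors (40 per class by default) and cross-validates the bank. Because
Monte-Carlo rounds reuse one dataset, the per-round spread understates
the estimator's true error; the benchmark therefore averages replicate
datasets and reports the standard error across replicates. Expected
accuracy is (1 − P(Unknown))/n ≤ 1/n; measured Unknown rates are ~0 %
(n = 2), ~2 % (n = 3) and ~3 % (n = 7), so the recovered levels sit
just below 50 / 33.3 / 14.3 % — the small deficit is a property of the
vote rule, not a bug, and is reported as computed.

## Problem sizes

Default test and benchmark sizes — one full synthetic subject
(30 records, 1800 instances), 10–30 Monte-Carlo rounds, 8–20 chance
replicates — were chosen so the whole suite runs in well under a minute
while keeping every standard error small relative to the effects being
checked.

## Known limitations

* The synthetic drift is linear and record-common; real EEG
  nonstationarity is richer, so the mixed ≥ short ≥ long ordering is
  reproduced qualitatively, not at the published real-data accuracy
  levels (raw data are available only on request from the original
  study's authors and are not redistributed here).
* EDF export is not provided (no writer dependency); records travel as
  HDF5. An EDF *reader* (`silenttalk.io.read_edf_record`, requiring
  the optional `mne` dependency) accepts externally supplied
  recordings with sync data channels.
* The energy criterion is batch-relative; streaming/online rejection
  would need a running estimate of Ē.
* Whether the original 70/30 split was stratified is unknowable from
  the published description; stratification is used here to keep
  classes balanced in every round.
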