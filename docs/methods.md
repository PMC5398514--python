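# Methods

## Model and procedure

`nirsmvpa` decodes two stimulus conditions from multichannel HbO
recordings *across* subjects. The pipeline is:

1. **Pattern extraction.** For a trial with onset `o` and analysis window
   `[start, end)` seconds, the window covers the samples `i` with
   `o + start ≤ i/fs < o + end` (half-open; no interpolation; sample 0 is
   t = 0). Each channel's value is the mean of `(sample − baseline)` over
   the window, where the baseline is the *first sample inside the shifted
   window* — not the onset sample, which matters for windows that start
   after onset (e.g. 6–12.5 s block designs). A 0–10 s window at 10 Hz
   therefore covers exactly 100 samples. Windows that would extend past
   the recording are excluded with a logged warning and counted in the
   result metadata; silently averaging a truncated window would bias the
   estimate.
2. **Condition averages.** Trial patterns are averaged element-wise within
   subject and condition; unequal trial counts across conditions are
   expected and tracked (`r` per average).
3. **Group model and decoding.** The group model for a test subject is the
   unweighted mean of the other N−1 subjects' condition averages. The
   subject-level rule compares the two label permutations by summed
   `arctanh`-transformed Pearson correlations; the trial-level rule
   compares a single trial's two Fisher-z correlations. `arctanh` is
   monotone, so the trial decision equals the raw-r comparison; the
   transform is kept for symmetry with the subject-level sum, where it
   variance-stabilises before adding.
4. **Aggregation.** Subject-level accuracy is the fraction of correctly
   labeled subjects. Trial-level accuracy averages within subject and
   condition first, then across subjects (per condition and grand mean),
   so subjects contributing more trials do not get more weight. Percentages
   are reported rounded to the nearest integer alongside full precision.

## Statistical inference

Leave-one-out couples the N decisions (each subject appears in the other
N−1 models), so a binomial test on the accuracy is invalid. The package
builds an empirical null by shuffling condition labels across trials
independently *within* each subject — preserving each subject's
per-condition trial counts and hence its data volume — recomputing the
condition averages, and re-running the complete cross-validated analysis.
The p-value uses the add-one estimator `p = (1 + #{null ≥ observed}) /
(1 + M)` (minimum attainable `1/(M+1)`, never 0). Default `M = 1000`.
Permutation `i` draws from `SeedSequence(seed, spawn_key=(i,))`, so
increasing M extends the null without changing earlier draws. At the trial
level the observed statistic is the grand-mean trial accuracy, and
per-condition p-values are computed against per-condition nulls. The
scheme is recorded in the result metadata because other null constructions
(subject-level swaps, sign flips) exist and yield different nulls.

## Numerical choices

- **Fisher clamp.** `arctanh(±1)` is infinite; correlations are clamped to
  magnitude `1 − 1e−7` before the transform, preserving order while
  keeping sums finite (`z(±1) ≈ ±8.41`).
- **Pearson correlation** is computed across channels within a pattern
  pair with sample normalisation; a constant (zero-variance) pattern makes
  it undefined and raises a `DegeneratePatternError` naming the unit —
  fabricating r = 0 would silently corrupt accuracies. In the subset
  analysis, where restrictions can produce constant vectors, the affected
  subject is excluded from that subset's accuracy and counted, rather than
  failing the whole map.
- **Ties** (equal summed correlations, or equal trial correlations) score
  0 with a logged warning: conservative, and the decision stays binary.
- **Size-2 subsets** are degenerate — the correlation of two 2-vectors is
  ±1 — and are computed but flagged with a warning; they are included
  because small-subset informativeness maps conventionally start at k = 2.
- Exactly two conditions are supported; condition sets of any other size
  are rejected with an explicit error.

## Univariate comparison

`univariate_contrast` runs, per channel, a two-sided paired t-test across
subjects on the difference of windowed condition means (df = N−1), with a
Bonferroni flag at `0.05 / n_channels`. Channels whose per-subject
differences are exactly constant (a zero-variance edge that arises in
noise-free simulation) are reported as t = 0 when the difference is zero
and ±∞ with p = 0 otherwise.

## Synthetic data generator

The generator emulates the regime of a typical infant event-related fNIRS
study: 19 subjects, 10 channels at 10 Hz, two conditions with 6 trials
each, 1 s stimuli separated by jittered 4–9 s baselines, and a 0–10 s
analysis window (all configurable). Each condition has a group spatial
pattern (defaults: two Gaussian bumps over different channel
neighbourhoods, peak ≈ 0.9 in arbitrary concentration units). Hierarchical
Gaussian noise enters at three levels, per channel: subject
(`subject_sd = 0.2`, idiosyncratic topography), trial (`trial_sd = 0.3`)
and sample (`noise_sd = 0.3`, measurement noise). A trial's time course is
its amplitude times a peak-normalised gamma-family HRF (shape-6 gamma,
peak 5 s, minus a 1/6-weight shape-16 undershoot, truncated at 25 s)
convolved with the stimulus boxcar.

**Epoching contract.** Real hemodynamic responses superpose across closely
spaced trials; under a 0–10 s window and 4–9 s baselines the neighbouring
trials' responses would dominate the extraction window and no exact
ground-truth statement about extracted patterns would hold. The generator
instead confines each trial's response to its own analysis epoch:
consecutive onsets are separated by `max(trial_duration + baseline,
window_length)` and a trial's response is truncated at the next onset.
This buys an exact contract — with trial and sample noise at zero, the
extracted pattern equals the subject's planted pattern times the *window
scaling constant* reported by `window_scale()` (the windowed,
baseline-corrected mean of the response kernel; ≈ 0.52 for the defaults) —
at the cost of not modelling response overlap. The jittered baseline
remains operative whenever `trial_duration + baseline` exceeds the window
length (e.g. short windows). Consequences for interpretation: passing
tests demonstrate correctness of the decoding machinery on data with
group-shared patterns and Gaussian noise; they do not show robustness to
overlapping responses, motion artifacts, or heavy-tailed physiological
noise, none of which the generator emulates.

`make_null_spec` replaces both conditions' patterns by their common mean,
making the two labels exchangeable by construction: decoding accuracy then
has expectation 0.5 and permutation p-values are (conservatively) valid,
which is what the calibration tests and `scripts/acceptance.py` verify
(200 replicate datasets; permutation checks at M = 99 in the test suite).
Problem sizes in the test suite are scaled to a desk machine: reduced
regimes (6–8 subjects, 4–6 channels) for unit tests, the full 19 × 10
default regime for the calibration and noiseless end-to-end checks.

## On-disk formats

Datasets: per subject a time-series CSV (`time_s,<ch1>,…`, one row per
sample) and an events CSV (`onset_s,condition`), plus a JSON config
(`conditions`, `included_channels`, `sample_rate_hz`, `window`,
`subjects`). The dialect is writable from any preprocessing stack; the
package consumes *preprocessed* HbO (filtering, motion correction and
Beer–Lambert conversion are upstream concerns). Subjects lacking trials in
some condition are rejected by name at load; `drop_invalid=True` (CLI:
`--drop-invalid-subjects`) converts this to a logged exclusion, mirroring
the practice of fixing inclusion before analysis. Results are written as
tidy long-format CSVs plus JSON summaries carrying accuracies, parameters,
seed and software version; writes round-trip to full floating-point
precision (`%.17g` on write, round-trip float parsing on read).

## Known limitations

- Two conditions only; no multi-class or representational-similarity
  extension.
- No learned-weight classifiers (SVM etc.) — the method is deliberately
  correlation-based and parameter-free.
- Within-subject decoding, spatial searchlights, and mixed-effects
  modelling of subset outcomes are out of scope (subset outcomes are
  exported per subject so external stats packages can model them).
- The exact choice of analysis window is consequential and left to the
  user; the package takes it as configuration and records it in all
  outputs.
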