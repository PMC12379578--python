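# Methods

This note documents the models and procedures implemented in `megspeech`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## The decoding problem

A participant produces the words *yes* and *no* at a self-paced rate of
roughly one word per 4–5 s while magnetoencephalography (MEG) and a
synchronized audio track are recorded. Each utterance defines three
equal-length trial windows on the MEG time axis: **overt** speech (acoustic
onset → offset, length L), **intended** speech (the L samples before
onset), and **postspeech** (the L samples after offset). The task is binary
classification of the word from the gradiometer signals in each window,
under an evaluation protocol that never mixes temporal order.

## Synthetic sessions

No public recording exists, so the package ships a generator whose output
has the statistical structure the analysis assumes. One session
("participant") per seed; all randomness derives from a single
`numpy.random.SeedSequence`, so sessions are bit-reproducible.

**Sensor model.** Per channel: 1/f-amplitude Gaussian background noise
(spectrum flattened below 1 Hz), standardized to `noise_sd` (default 1.0);
power-line sinusoids at 60 Hz and harmonics up to the 5th, random amplitude
per channel around `line_amp/h`, common phase; blink artifacts (biphasic
~300 ms template, Poisson arrivals at `blink_rate_per_min`) and cardiac
artifacts (triphasic ~80 ms QRS-like template at `heart_rate_bpm` with 2%
rhythm jitter), each projected through a fixed random topography normalized
to peak amplitude `blink_amp` / `ecg_amp` × noise SD, and mirrored at high
gain into dedicated EOG/ECG reference channels.

**Event schedule.** Labels are a seeded random permutation of
`n_reps_per_word` copies of each word — i.i.d. uniform draws with each
class capped at its quota, which matches a speaker instructed to randomize
rather than alternate, stopped once both words reach the quota (default 80,
hence exactly 160 events). Inter-onset gaps are uniform on
`inter_word_interval` (default [4, 5] s); durations are per-class Gaussian
(default 0.45 ± 0.08 s, equal across classes, truncated at 100 ms).
Configurations whose interval could force adjacent phase windows to
overlap (interval < 3 × mean duration) are rejected.

**Class signal.** For each phase and class, a fixed *focal* topography: a
random subset of ~1/8 of the gradiometers (at least 4), with random
weights normalized to unit RMS over the active set. Real sensor-space
speech responses concentrate on a minority of sensors, and a focal pattern
gives the effect-size axis a usable dynamic range — a dense unit-norm
pattern spread over all channels is undetectable against 1/f noise at any
moderate amplitude, while a per-sensor-unit dense pattern saturates
accuracy. Within each trial's phase window the topography is modulated by
a half-sine envelope times an 8 Hz carrier and scaled by
`effect_size × noise_sd`; the three phases use independent topographies so
their decodabilities can be controlled independently. Effect size
therefore reads as *standardized per-active-sensor amplitude*. Defaults
(0.6 intended, 1.5 overt, 0.9 post) encode the qualitative finding the
pipeline is expected to reproduce: overt > post > intended decodability.

**Audio.** Each utterance is a voiced burst (harmonic stack, f0 150 Hz for
*yes*, 110 Hz for *no*, 20 ms attack/release) at unit RMS, over white
background noise set by `audio_snr_db` (default 15 dB). The two words
differ acoustically so voice activity detection is non-degenerate, but
labels always come from ground-truth overlap matching, not acoustics.

**What the generator does not emulate:** anatomy and field spread (no
forward model), neural variability across trials beyond additive noise,
co-articulation or prosody, sensor drift, movement artifacts. Passing the
synthetic benchmark shows the *pipeline machinery* is correct and
calibrated; it says nothing about decodability of real MEG.

## Preprocessing

Continuous data are filtered before epoching so filter transients never
fall inside trials: 4th-order Butterworth low-pass at 250 Hz, applied
forward–backward (zero phase), then second-order IIR notches (default
bandwidth 1 Hz) at 60 Hz and harmonics below the low-pass cutoff, also
forward–backward, cascaded as one second-order-section stack. Auxiliary
channels bypass all filters so they remain faithful artifact references.

**Bad channels.** The per-channel statistic is a robust variance (squared
scaled MAD about the median), deliberately insensitive to sparse
transients such as blinks: flat channels fall below `flat_tol`, noisy
channels exceed a robust z-score of `noise_z = 5` on the log statistic
across channels. Flagging more than 20% of channels raises a
corrupt-session warning. These criteria are heuristics standing in for
manual inspection.

**Artifact ICA.** FastICA (negentropy-maximizing) on the good MEG
channels, fitted on time-decimated data (default every 20th sample) for
speed; sources are then computed at full rate. The *deflation* variant is
used: it extracts strongly non-Gaussian components (blinks, heartbeats)
first and is indifferent to the Gaussian background subspace, where the
symmetric variant has no stable fixed point and does not converge on this
kind of data. Components whose absolute temporal correlation with the EOG
or ECG channel exceeds `threshold = 0.8` are removed by subtracting their
back-projection — so cleaned + removed equals the input exactly, and a
second pass removes nothing. Non-convergence or a non-finite unmixing
matrix triggers a bounded seed-retry before erroring.

## Acoustic events

The audio track is denoised with a short-time spectral Wiener filter: the
noise spectrum is the mean periodogram of the lowest-energy 10% of frames,
inflated by an oversubtraction factor β = 2 (the lower tail underestimates
the stationary level), gain `max(0, 1 − βN/P)` per bin, overlap-add
resynthesis.

Voice activity detection is frame-energy based: 25 ms frames, 10 ms hop,
threshold either fixed (dB) or adaptive (30th energy percentile + 6 dB), a
5-frame hangover bridging intra-word dips, merging of gaps under 200 ms,
rejection of events under 150 ms, and sample-level boundary refinement at
the envelope threshold crossing. The exact-shift property under silence
padding holds in fixed-threshold mode; the adaptive threshold moves
slightly with padded content, so boundaries may shift by a few samples
there. Detected segments inherit the label of the maximally overlapping
ground-truth event; non-overlapping or tied detections are dropped and
counted (standing in for the manual audition/correction a human study
uses).

**Duration equivalence.** Yes/no durations are compared with two one-sided
tests (TOST) against symmetric standardized bounds ±`bound_d` (default
0.3 — a conventional "small" effect; the bound is a design choice, stated
with every result): t statistics on the raw mean difference against
margins `±bound_d·s_p`, `df = n₁+n₂−2`, equivalence declared when
`max(p_lower, p_upper) < α`. Note the procedure is conservative at small
n: identical samples are *not* declared equivalent unless
`bound_d·√(n/2)` is large enough.

## Decoders

**Shrinkage LDA on RMS features.** Features are per-channel RMS amplitudes
over each trial's own length (length-agnostic, one value per retained
gradiometer). The discriminant assumes two Gaussian classes with a shared
covariance; the pooled within-class covariance is shrunk toward its
diagonal, `Σ = (1−γ)Σ̂ + γ·diag(Σ̂)` (default γ = 0.2), and coefficients
whose standardized magnitude `|w_j|·s_j` falls below `reg_delta` × the
maximum are zeroed (default δ = 0 — off). Priors are the (weighted)
empirical class frequencies; per-example weights enter the means and
covariance, which is how Bayesian-bootstrap weights reach the model.
Hyperparameters (γ, δ) are tuned by a Gaussian-process (Matérn ν = 2.5)
expected-improvement search over past evaluations, 5 random initial
points, seeded. The source text's "alpha and beta parameters of the
Dirichlet distribution" has no interpretable counterpart among standard
LDA hyperparameters; (γ, δ) are this package's documented substitution.

**1D CNN.** Architecture, fixed: two blocks of [1D convolution → ReLU →
normalization] with 32 and 64 filters of width 5, then global average
pooling over time, flatten, a 2-node fully connected layer, softmax.
Global average pooling makes the head input-length-agnostic, so ragged
trials are processed at native length — no padding convention exists to
document. The normalization kind is configurable: batch normalization
over the channel dimension (default; statistics pooled over all time
points of the minibatch, running estimates for inference) or layer
normalization. Training: weighted two-class cross-entropy, Adam
(β₁ = 0.9, β₂ = 0.999), initial learning rate default 0.003 with the grid
{0.003, 0.0045, 0.006} searchable, at most 100 epochs (default cap;
studies below use shorter schedules), batch size 16, no augmentation,
dropout or weight decay. When a validation set is supplied, the weights
with the best validation accuracy are retained; early stopping is off by
default. The implementation is pure numpy — im2col convolutions as BLAS
matrix products in float32, hand-written backward pass verified against
numerical differentiation — and is bit-reproducible given the seed.

## Evaluation protocol

Per phase: the first ⌊0.7·n⌋ trials (acquisition order) train, the rest
test; a split never shuffles. Within the training set, fourfold CV over
*contiguous temporal blocks* (preserving the temporal-order rationale),
repeated 10 times (default) by the Bayesian bootstrap: per repetition,
flat-Dirichlet weights over the training-fold trials are scaled by n (both
decoders are weight-scale invariant) and passed as example weights to the
fit; the held-out fold is scored unweighted. Uniform weights with one
repetition reduce exactly to plain fourfold CV. Accuracy is the exact
proportion of correct predictions.

Statistics: two-sided one-sample t against the 0.5 chance level (df =
n−1; zero spread at floating-point resolution is reported as a signed
infinite t with a flag); paired decoder comparison as a one-sample t on
differences; one-way fixed-effects ANOVA across the three phases with
Tukey HSD (Tukey–Kramer for unequal sizes) via the studentized-range
distribution; TOST as above. Within one session these tests run on
fold×bootstrap CV accuracies; across sessions (`simulate_study`) they run
on per-session test accuracies, mirroring a per-participant analysis.
Per-session significance against chance additionally uses an exact
binomial test on the test-set predictions, which is the appropriate test
for a single proportion.

## Canned studies and problem sizes

Both desk-scale studies (in `megspeech.studies`) run the complete chain —
generation, filtering, bad channels, ICA, Wiener + VAD, epoching, both
decoders — at 64 gradiometers, 1 kHz, 80 repetitions per word, sizes
chosen so a study finishes in minutes on one CPU while keeping the trial
counts of the protocol (112 train / 48 test after the 70/30 split).

* **Chance calibration:** 20 zero-effect sessions; every (session, phase,
  decoder) test accuracy is compared with the 95% binomial interval around
  0.5 and with an exact binomial test at α = .05. A calibrated pipeline
  leaves ~5% of values outside the interval by construction, so the checks
  are rate-based (≤10% violations, ≤10% significant). The CV loop is
  skipped (the checks need only test accuracies) and the CNN trains 15
  epochs — at zero effect the property does not depend on training length.
* **Signal recovery:** one session with effects (0.6, 1.5, 0.9), fourfold
  CV × 2 bootstrap repetitions, CNN 30 epochs. Expected signature: CNN
  accuracy ordering overt > post > intended, high overt accuracy for both
  decoders, phase ANOVA significant.

## Numerical choices and degenerate inputs

* Audio→MEG sample conversion: onset rounds down, offset up; 0-based,
  half-open indices everywhere.
* LDA decision ties (score exactly 0) go to the first class
  (alphabetically "no"); posterior is the logistic of the score
  difference.
* Singular shrunken covariance raises an error naming the remedy (larger
  γ). Zero-length trials, empty epoch sets, folds lacking a class, and
  all-zero audio all raise or degrade explicitly rather than silently.
* CNN training reports divergence (non-finite loss) with the epoch.
* Accuracy-vector spreads at floating-point rounding level are treated as
  zero variance in t statistics.

## Known limitations

* The generator's artifact topographies are random vectors, not
  physiological field maps; ICA separability is therefore easier than in
  real data.
* The energy VAD is a stand-in for the (unspecified) published detector
  the protocol references; at very low SNR its boundary refinement
  degrades before its detection does.
* Fold-level CV accuracies are not independent samples, so within-session
  t statistics on them are descriptive rather than strictly calibrated;
  across-session statistics and the binomial test do not share this
  caveat.
* Batch-norm running statistics need some epochs to stabilize; very short
  schedules can show a small train/inference mismatch.
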