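# Methods

## The classification pipeline

Each session is a stack of fixed-length trials (trials × channels ×
samples) with two class labels, "left" and "right" motor imagery, and a
sampling rate of at least 90 Hz. The pipeline is:

1. **Band-pass** 5–45 Hz (4th-order Butterworth, applied
   forward–backward per trial and channel). Zero-phase filtering is the
   EEG default because phase distortion would bleed into the covariance
   estimates CSP consumes; `sosfiltfilt`'s reflective padding handles the
   short epochs. Only the band is dictated by the methodology; the filter
   family and order are this package's choice.
2. **Channel subsetting** to the electrode combination under evaluation.
   Filtering is per-channel, so it commutes with subsetting; bulk sweeps
   filter each session once up front.
3. **CSP.** Per-trial sample covariances (time-demeaned, `n−1`
   denominator) are trace-normalized — every trial contributes equal
   total power — and averaged within class, giving Σ₁, Σ₂. The
   generalized eigenproblem Σ₁w = λ(Σ₁+Σ₂)w is solved with
   `scipy.linalg.eigh`; eigenvalues are clipped to [0, 1]. Components are
   ordered by discriminability max(λ, 1−λ) descending (ties resolve
   toward the high-λ component, then input order), which interleaves the
   two spectrum tails; plain descending-λ ordering is available. Each
   eigenvector is sign-fixed so its largest-magnitude coefficient is
   positive — eigenvector sign is otherwise arbitrary and would make
   pattern-based electrode selection irreproducible. Patterns are the
   rows of the inverse filter matrix (columns of the mixing matrix).
4. **Features and classifier.** Per trial and component, the log of the
   variance of the filtered time course; a two-class Fisher discriminant
   with pooled covariance and equal priors, fit on training folds only.
   A trial exactly on the boundary goes to the first class in sorted
   label order. Default 8 components, aligning the feature count with
   the 8 patterns the extraction algorithm inspects; subsets smaller
   than 8 electrodes are capped at their channel count.
5. **Cross-validation.** Stratified 5-fold with a fixed, config-surfaced
   seed. Splits are a pure function of (labels, n_splits, seed), so every
   subset and variant evaluated on one session shares folds — required
   for fair A/B comparison. Accuracy is the mean over fold accuracies;
   pooled per-trial correctness feeds the Bayesian evaluation.

Numerical guards: a 1e-9·trace identity floor is added to the composite
covariance only if the unfloored eigendecomposition fails (keeping exact
ties exact); an optional shrinkage fraction pulls class covariances
toward (trace/n)·I; the discriminant adds a 1e-10 relative ridge to the
pooled covariance.

## Subset search with t-test selection

All subsets of the montage with at least `min_size` electrodes are
enumerated canonically (size ascending, then lexicographic by montage
index). Per subject, each subset's percentage change
100·(acc − base)/base against the fixed-montage baseline is computed on
shared folds; across subjects a one-sided one-sample t-test (sample sd,
n−1 degrees of freedom) tests H0: μ ≤ 0 at α = 5 %. An all-identical
sample (e.g. the montage against itself, change exactly 0) degenerates
to p = 1 unless the common value is positive (p = 0). No
multiple-testing correction is applied across the enumerated family —
faithful to the methodology being reproduced — so under a no-signal
cohort each subset is flagged at rate ≈ α; an optional
Benjamini–Hochberg report exists as an explicit deviation switch.

## Pattern-threshold extraction

For a pattern p over the montage, an electrode e is selected when
|e_p − mean(p)| > θ·σ(p), θ = 1.5. σ uses the population convention
(divide by n) by default — the sample convention is a switch, and the
selection's affine invariance (a·p + b selects the same set, a ≠ 0)
makes overall pattern scaling immaterial. Selections over the first 8
patterns are unioned; a constant pattern selects nothing. Extraction
runs on each cross-validation split's training data; deduplicated
combinations with more than 2 electrodes are each scored with the full
cross-validated pipeline and the most accurate wins (ties → fewer
electrodes, then canonical order). Scoring re-uses the session that
produced the candidates — an optimistic bias inherent to the procedure;
`transfer_accuracy` (fit on one session, score another) exists for
unbiased cross-session checks, where combinations selected on one
session routinely fail to transfer.

## Bayesian A/B evaluation

Per-trial correctness pooled over a variant's subjects updates a
Beta(α=6, β=4) prior — a mild better-than-chance belief whose influence
is negligible beyond a few thousand trials (posterior means under
Beta(6,4) and Beta(1,1) differ by < 1e-3 at 10⁴ trials). Variants are
compared by drawing 10,000 independent accuracy pairs (a, b) from the
variant and all-electrode baseline posteriors and averaging a/b;
100·(mean − 1) is the percentual improvement. Draws are independent, not
paired. The estimator has a self-comparison bias — for independent
identical posteriors E[a/b] = E[a]·E[1/b] > 1 (e.g. 1.024 for
Beta(16, 9)) — which is reported, not corrected, because it is a
property of the mean-of-ratios estimator itself. Central 95% intervals
of the sampled fractions are attached as an extension. Selection-based
variants (per-subject best of a candidate pool) additionally carry a
genuine winner's-curse bias from maximizing cross-validated accuracy:
under a no-signal cohort their improvement exceeds the self-ratio bias
even though no subset is truly better. This is a property of the
evaluated procedure, not of the evaluator.

## The synthetic-EEG generator

The generator emulates the band-power contrast (event-related
desynchronization physiology) that CSP exploits, not raw EEG: every
channel carries band-limited Gaussian noise (default 8–30 Hz, unit
variance via the filter's impulse-response energy) plus broadband
Gaussian noise (default sd 0.5); on the discriminative channels the
oscillation variance is multiplied by `effect` — first half of the list
for "left" trials, second half for "right", so both CSP tails carry
signal; a fixed row-normalized tridiagonal operator (default strength
0.2) leaks signal into neighbouring channels like volume conduction.
Everything is a pure function of the config, including its seed.
Defaults: 16 channels named after the sensorimotor 10-10 montage, 50
trials/class, 2 s epochs at 128 Hz. The montage's exact 16 names are a
documented package choice and fully overridable.

What the generator does *not* emulate — non-stationarity across a
session, eye/muscle artifacts, 1/f background spectra, realistic
volume-conduction geometry, class-dependent mean shifts — bounds what
passing tests show: parameter recovery on this generator demonstrates
the algorithms find planted variance contrasts under spatial mixing and
noise, not that they cope with artifact-laden recordings.

## Validation scales and design choices in the tests

- Parameter recovery uses effect = 8 on C3/C4, no mixing, 100
  trials/class, 50 sessions: the extraction must contain both planted
  channels in ≥ 90 % of sessions and the selected combination's accuracy
  must stay within 0.05 of the all-electrode baseline in ≥ 80 %.
- The exhaustive search is validated at reduced scale: an 8-channel
  montage with min_size 4 (163 subsets, the same code path as the
  39,203-subset full montage) and cohorts of 5 subjects. The signal
  condition plants a 4-channel contrast at effect 1.35, 96 trials/class,
  1 s epochs, 9–13 Hz band, noise sd 0.5, no mixing — a regime where the
  full montage's extra channels cost real accuracy (baseline ≈ 0.75)
  through covariance-estimation noise. Because a reduced subset's
  advantage over a montage of exchangeable extra channels is purely a
  finite-sample effect, the per-subject advantage has coefficient of
  variation near one in every regime examined, capping a single
  5-subject t-test's power near 70 %: recovery is therefore demonstrated
  across 6 independent cohorts (≥ 2 flags; chance probability ≈ 0.03),
  and a single-cohort flag should be treated as noisy evidence.
- Null calibration of the family-wise flag rate uses 6 no-signal
  cohorts with a cohort-level standard error: the 163 tests within one
  cohort share five subjects' data and are strongly positively
  correlated, so a plain binomial error bar would be too tight.
- The experiment driver's desk-scale defaults mirror the reduced-scale
  study (163 subsets, 5 subjects, ≈ 10 s end to end); the full
  16-electrode enumeration is a config override and costs hours per
  cohort.

## Known limitations

- Only two-class, single-band CSP; no regularized/filter-bank variants,
  no multiclass extension.
- Candidate evaluation on the extraction session is optimistically
  biased by design (see above); cross-session transfer is the honest
  estimate and is exposed but not folded into the selection.
- The session container is a compressed numpy archive; EDF or other raw
  EEG imports are out of scope.
- The discriminant assumes shared class covariance of the log-variance
  features; no probability calibration is attempted.
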