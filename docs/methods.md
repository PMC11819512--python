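# Methods

This note documents the models, numeric choices and assumptions behind
`nbhfsocial`, and what the synthetic benchmarks do and do not establish.

## Data model

A **click** is a detection event (time in seconds since record start,
centroid frequency in kHz); a **train** is a strictly time-ordered click
sequence produced as one vocal event. Derived quantities: inter-click
intervals (ICI, ms), instantaneous rates (1/ICI, clicks per second),
mean rate ((n−1)/duration), and mean frequency. Each deployment carries an
absolute datetime origin; all diel logic uses the origin's local clock.
Analysis **frames** are a fixed 15-s grid anchored at the record start
(a reproducible stand-in for the analyst's scrolling 15-s view; the
alternative — anchoring to clock minutes — changes frame membership only
for trains within one frame length of a boundary).

## Candidate filter

Mirrors the detector-app view settings applied before visual marking:
train mean rate ≥ 100 c/s, mean frequency within 105–140 kHz (both
inclusive; "at least" / "between" read inclusively), and only frames with
≥ 256 clicks are scanned. Frame eligibility counts every click in the
frame regardless of train membership or class. The filter is monotone
(relaxing a threshold never removes a passing train) and the candidate
view is idempotent.

## Social criteria

Four visually-defined criteria become numeric rules with explicit,
configurable tolerances (`SocialCriteria`):

* **(a) not foraging.** *Searching phase*: the fraction of instantaneous
  rates below 200 c/s may not exceed 0.1, and no contiguous sub-threshold
  run may exceed 10 ICIs — a tolerance standing in for "no *visible*
  searching phase", which is analyst judgment. *Terminal buzz*: over the
  last 10 ICIs, a Theil–Sen slope > 0 together with a one-sided sign test
  on successive rate differences at p < 0.05, and a terminal rate above
  the train median. Robust statistics are used because single-ICI jitter
  is large at these rates. Either finding vetoes the train (the
  conservative rule: anything foraging-like is never marked social).
* **(b) discrete.** Silence of ≥ 150 ms before the first and after the
  last click, relative to every other click in the record. 150 ms is
  ~15× the 10-ms ICI boundary that separates social-rate from
  foraging-rate clicking; the criterion's source says only "separated by
  intervals of silence".
* **(c) repeated.** Within the same 15-s frame, at least `min_repeats`
  (default 2) bursts must be mutually similar: duration ratio within
  [0.5, 2] and Pearson correlation ≥ 0.7 between rate profiles linearly
  time-warped to 50 points. Repetition of *shape*, not of pattern label:
  a mushroom repeated by a mushroom-like burst counts, matching how the
  repetition is judged visually.
* **(d) rate band.** Mean rate within 200–1,000 c/s inclusive (the
  operational marking band; the captive-study literature cites 250–1,000,
  which is the generator's narrower default so synthetic positives sit
  inside the classifier's band). Inclusive comparisons carry a 1e-9
  relative epsilon so boundary trains are not lost to float accumulation.

Social trains are labelled **mushroom** (exactly one prominent interior
maximum of the 5-point-smoothed, 50-point resampled profile) or **wiggle**
(two or more). Prominence is 5% of the profile range (scipy `find_peaks`),
so timing jitter on a plateau cannot split one peak into many; smoothing
uses edge padding to avoid fabricating end dips.

## DPM aggregation

A minute is social-positive if ≥ 1 social train clicks in it, likewise
non-social; the total is the union (a minute positive for both counts
once — "total DPM" means all detections, and summing the two classes
would double-count shared minutes). Every hour the record covers gets a
row; uncovered periods are absent, not zero-filled. DPM is invariant to
splitting trains within a minute. Hours are 0–23 internally; report
rendering uses the 1–24 display convention. Group-level proportions are
reported to one decimal; a group with zero total DPM has an undefined
(missing) proportion. Inter-rater agreement is the pair of directional
overlap percentages of marked social minutes.

## Temporal models

**Nonparametric layer.** Shapiro–Wilk for normality (n limited to 3–5,000);
Kruskal–Wallis with tie correction on hourly social-DPM proportions
grouped by hour, month or year; Dunn's post-hoc z from pooled ranks with
the usual tie term and Bonferroni correction over all pairs in the tested
factor. Both rank tests are verified exactly against an independent
brute-force implementation on an exhaustive family of small instances.

**NB-GAM.** Hourly DPM counts, log link, negative binomial (NB2,
Var = μ + αμ²). Cyclic cubic regression splines for hour (df 8, period
0–24) and month (df 6, period wrapping December–January), year as a
factor. Two details matter:

* *Knots and period.* Basis knots are equally spaced over the full
  period with explicit wrap bounds. Quantile-placed knots on an hourly
  grid leave their widest gap at the 20–24 h wrap, exactly where
  nocturnal activity peaks, visibly distorting the fitted curve there.
  The fitted hour effect at 24:00 equals 00:00 by construction.
* *Smoothing selection.* Penalty weights come from a deterministic
  coordinate-wise grid search minimizing BIC (−2ℓ + log(n)·edf, edf =
  penalized effective df). AIC was examined and is nearly flat (≈1 unit)
  across orders of magnitude of the penalty on weak-signal DPM series,
  which makes the selected fit unstable; BIC's stronger complexity charge
  resolves the tie toward smoother, reproducible curves.

Dispersion α is estimated by iterating the Cameron–Trivedi moment
estimator (Σ[(y−μ)²−μ]/Σμ²) with the penalized fit from a Poisson start;
results report size k = 1/α. Per-term p-values are Wald chi-square tests
on each coefficient block (approximate for penalized smooths; df = basis
dimension, which is conservative). Adjusted R² uses the edf-corrected
residual variance; deviance explained compares against the intercept-only
fit of the same family.

**Peak location.** `GamFitResult.smooth_peak` reads the peak of a cyclic
smooth as the circular mean direction of its response-scale profile
exp(f). For a symmetric unimodal effect this equals the argmax, but it
pools the entire curve: at realistic DPM signal levels the literal argmax
of the fitted spline has a standard error near one hour, while the
circular reading is an order of magnitude tighter (it is the standard
phase estimator for cyclic intensity data). For asymmetric multi-modal
curves the two differ; `method="argmax"` returns the literal maximum.

**Autocorrelation.** Lag-1 ACF of time-ordered Pearson residuals; above
0.2 the model is refit as an AR1-whitened penalized GLS on the linearized
(working-response) model, keeping the NB working weights and the selected
penalties; the reported covariance is the corresponding sandwich. The
refit leaves the scientific conclusions (smooth shapes, peak locations,
term signs) stable for ρ ≤ 0.6.

**Backward selection.** The least-significant term with p > 0.05 is
dropped and the model refit until all retained terms are significant;
removing everything returns an intercept-only model with a warning. The
AIC trajectory is reported. A "separate models per covariate" reading of
the modelling protocol is available by passing single-term `GamSpec`s;
the joint model is the default.

## Synthetic deployments

The generator encodes the study conditions the analysis assumes:

* **Encounter process**: hour-by-hour thinning with intensity
  (base/24) × diel × month, diel = 1 + a·cos(2π(h−peak)/24) (default
  peak 23:00, a = 0.8), monthly weights peaking in May with a smaller
  fall rise. A per-hour Gamma(k, 1/k) multiplier makes hourly counts
  NB-dispersed with size k (default 2). Default base is 12 encounters/day
  with 15% social — chosen so simulated DPM per day (~2 social, ~20
  total) matches the order of magnitude a long-term coastal deployment
  reports (~38 total DPM/day).
* **Foraging trains**: search (4–10 s at 20–120 c/s, drifting upward),
  approach (1–3 s ramp), buzz (0.5–1.5 s rising into 300–600 c/s), with
  multiplicative ICI jitter largest (±25%) in the search phase.
* **Social sequences**: 2–4 bursts of 0.3–1.0 s within one 15-s frame,
  0.5–2.5 s silent gaps, rates in 250–1,000 c/s (sine rise–fall for
  mushrooms; 2–3-cycle oscillation ending on a descent for wiggles).
  Bursts within a sequence share one base shape/duration/rate with ±15%
  jitter, clamped so instantaneous rates stay in band — they are
  repetitions of the same call, which is what makes criterion (c)
  meaningful. Mean frequencies are drawn in 110–135 kHz with 1.5 kHz
  per-click jitter.
* Encounters are kept ≥ 1 s apart (3 s in the "easy" scenario, which
  also uses ≥ 3 longer, slower-gapped bursts so every social frame
  clears the 256-click threshold); an encounter that cannot be placed in
  a crowded hour is dropped.

What this does *not* emulate: propagation/detection range, ambient noise
and vessel masking, overlapping animals vocalizing simultaneously, clock
drift, or the KERNO-F train segmenter itself (input is assumed already
train-segmented). Benchmark precision/recall therefore measures the
criteria's internal consistency on clean train-level data, not field
performance; on real data, segmentation errors and overlap would lower
both.

## Problem sizes

The shipped benchmarks use 90 simulated days (classifier fidelity),
180 days (temporal-structure recovery; ~4,300 hourly observations), and
5–10 days for self-consistency and determinism checks — sizes at which
every quantity has stabilized while a full validation run completes in a
few minutes on one CPU.

## Known limitations

* The criteria tolerances (sub-threshold fraction, 150 ms gap, 0.7
  similarity) are reproducible proxies for visual judgment, not fitted
  quantities; changing them changes the social count monotonically.
* NB dispersion is a moment estimate, not ML; with very low counts it is
  noisy, and hourly DPM (bounded at 60, minute-binarized) is only
  approximately NB.
* Smooth-term p-values are upper-bound-df Wald approximations, slightly
  conservative relative to mgcv-style tests.
* The AR1 refit is a one-step working-correlation GLS, not a joint
  likelihood; ρ is estimated once from the uncorrected fit.
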