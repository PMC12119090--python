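# Methods

## The analysis model

The pipeline treats a dyadic play session as a pair of alternating-renewal
point processes (infant and caregiver gaze) observed alongside continuous
covariates sampled at the video frame rate (50 Hz): infant relative theta
power, caregiver look duration, and caregiver F0 rate of change. Three
families of questions are asked of these series.

**Oscillatory structure (part 1).** Each actor's looks are recoded as an
alternating 0/1 series (category-blind); its partial autocorrelation
function measures excess self-similarity of attention-shift timing after
controlling for shorter lags. PACF(k) is defined as the OLS coefficient of
`x(t−k)` in the regression of `x(t)` on `x(t−1) … x(t−k)` (with intercept)
over complete cases — not the Durbin–Levinson recursion, which assumes
stationarity and complete data. Whether the PACF reflects duration
*inter-dependence* rather than the duration *distribution* is assessed
against a baseline in which look durations are shuffled in time (100
permutations per session): shuffling preserves the duration multiset and
hence the distributional component exactly. Dyadic coupling is probed by
the Spearman cross-correlation of the two binary series at lags 0..+10 s
(500 ms steps), tested against 100 Poisson surrogate dyads whose
exponential look durations match each session's mean.

**Continuous lagged dependence (parts 2–3).** Continuous variables are
log-transformed, masked at ±2 inter-quartile ranges beyond the quartiles,
and detrended with the better (by small-sample AIC) of a linear or
quadratic polynomial in time. `r(τ) = corr(x(t), y(t+τ))` is computed at
lags −30..+30 s in 500 ms steps, with `x` always the infant-side variable,
so positive lags mean the second variable follows the first. Curves are
averaged over a participant's play sections, then across participants.
Significance uses the derangement null: participants are re-paired with a
uniformly drawn fixed-point-free permutation (rejection sampling, ~e draws
per success) and the full observed pipeline re-run per draw.

**Event-locked and per-look analyses.** Around each infant object-look
onset a ±5 s window of the (log, outlier-masked) variable is extracted;
samples after the locked look's offset are missing, because the question
is what happens around *that* attention episode. Within-look modulation
splits each look into three chunks (boundaries at `round(i·n/3)`), averages
the first `ceil(size/2)` samples of each chunk, and compares chunks with
Wilcoxon signed-rank tests under Benjamini–Hochberg correction. The
per-look mixed model predicts standardized log look duration from the
standardized per-look mean of the predictor, with a random intercept and an
uncorrelated by-participant random slope, fitted by maximum likelihood
(statsmodels `MixedLM`; the slope enters as a variance component). On
non-convergence the slope component is dropped and the downgrade recorded.

## Cluster-based Monte-Carlo inference

Pointwise flags mark lags where the observed curve falls outside the
2.5th–97.5th centiles of the surrogate curves. Clusters are maximal runs
of same-sign flags; cluster mass is the run length (count) by default,
with a summed-exceedance variant available (``mass="sum"``). The threshold
distribution is built leave-one-out: each surrogate's own maximal cluster,
computed against the centiles of the remaining surrogates, contributes one
draw; an observed cluster is significant when its size exceeds the 95th
centile of those draws, and `p` is the exceedance proportion. Because
cluster sizes are small discrete counts the procedure is conservative
(exceedance p-values are super-uniform); the test suite therefore checks
that the false-positive tail does not exceed the nominal level, rather
than exact uniformity.

## The synthetic-dyad generator

The generator exists to give every stage a ground truth; its defaults are
the study conditions under which the calibration and recovery properties
are evaluated.

- **Gaze**: look durations are log-normal, parameterised by the mode
  (infant 1.5 s, caregiver 0.35 s) with log-scale sd 0.9 / 0.8 and lag-1
  autocorrelation 0.3 / 0.2 on consecutive log durations. The modes place
  the duration histograms' peaks in the observed 1–2 s (infant) and
  200–500 ms (caregiver) ranges; the sds reproduce the heavy right tail of
  naturalistic looking, including study-wide maximum episodes of order
  100 s. Targets are i.i.d. categorical (infants mostly objects, caregivers
  more partner-directed). Uncodable segments arrive as a Poisson overlay
  (0.01/s, mean 1 s) and truncate the looks they cover.
- **Theta**: `theta(t) = 0.30 + a·log d(t−L) + AR(1) noise`, where
  `d(t−L)` is the duration of the look active `L = 1.5 s` earlier,
  `a = 0.005` relative-power units per log-second, and the noise has
  stationary sd 0.05 with lag-1 coefficient 0.9 at 50 Hz. These values put
  the session-level peak duration×theta correlation near 0.05 — the
  magnitude reported for real dyads — which yields a bounded, asymmetric
  significance window rather than grid-wide saturation. Values are clipped
  to (0, 1), the range of a relative power share.
- **EEG surrogate**: per channel, a 4.5 Hz oscillator whose instantaneous
  power share of the total oscillator power equals the target theta,
  plus fixed 8 and 12 Hz components and optional white noise. This is an
  additive surrogate, not a forward head model: it exercises the wavelet,
  band-averaging and downsampling stages, not source physics.
- **Caregiver response**: a look starting within 4 s after an infant
  object-look onset has its duration multiplied by `1 − depth` (default
  depth 0, i.e. off). With depth 0.3 the event-locked log-duration curve
  drops by ≈ log 0.7 ≈ −0.36 after onset.
- **F0**: voiced stretches (exponential alternation, default voiced
  fraction 0.5) carry `carrier + A·sin(2π f t)` (220 Hz, A = 40 Hz,
  f = 3 Hz); per-second total variation is then ≈ 4·A·f.

What the generator does **not** emulate: joint-attention semantics,
gaze-following structure, realistic vocal acoustics beyond an F0 contour,
volume-conducted or artifactual EEG, and any dependence of caregiver
*look targets* (rather than durations) on the infant. Passing tests
therefore certify the measurement and inference machinery, not claims
about real infant data.

## EEG processing choices

Morlet wavelets (7-cycle Gaussian envelope, unit-energy kernels) on a
1–16 Hz grid at 1 Hz steps; power as squared magnitude; relative power as
the share of total power over the grid per time point and channel, then
averaged over 3–6 Hz and the fronto-central set (AF3, AF4, FC1, FC2, F3,
F4, Fz; matched case-insensitively). The first and last 500 ms and 500 ms
guards around missing segments are masked. Sessions where any
fronto-central channel exceeds 100 µV on more than 15% of samples are
excluded (strict inequality). Downsampling to 50 Hz takes per-window
medians: each full second is covered by 50 windows — 38 of 10 samples and
12 of 11 (summing to 512) — with the long windows' positions shuffled per
second by a seeded generator; a window is missing when more than half its
samples are missing, and a trailing partial second gets proportionally
many windows. Relative power is normalised per channel before channel
averaging.

## Vocal salience

"Rate of change" of F0 is the total variation (sum of absolute first
differences) of the filtered contour per 1000 ms interval, written to the
interval's 50 frames; a signed sum telescopes to the net change and is
available only behind a flag. The contour interpolates unvoiced gaps
linearly, is low-pass filtered at 20 Hz with a 9th-order zero-phase
Butterworth (SOS form), and excludes non-caregiver, co-vocalisation and
clipped spans; sessions with more than 30% of voiced time excluded are
dropped from vocal analyses. Interpolation across long silent stretches
produces low-variation intervals by construction; the voiced fraction and
exclusion threshold are configurable.

## Numerical and procedural conventions

- Half-open look intervals `[onset, offset)`; a sample at `t` belongs to
  the look with `onset ≤ t < offset`. The first codable look takes binary
  value 0.
- Uncodable periods mask themselves and exactly one neighbouring look on
  each side (their true extent is unknown).
- A lag needs ≥ 100 jointly valid samples (2 s) to be defined; a PACF lag
  needs ≥ 30 complete cases.
- Re-binning of the binary series to coarse PACF grids is by majority
  vote, ties taking the bin-start value; a bin with more than half its
  samples missing is missing.
- Cross-participant pairings truncate both series to the shorter common
  length from session start.
- Mixed-sign flag runs are split at sign changes.
- Exact Wilcoxon enumeration for ≤ 12 non-zero pairs (subset-sum over
  doubled mid-ranks); above that a normal approximation with continuity
  and Edgeworth kurtosis corrections (the null is symmetric, so no skew
  term). Zeros dropped, ties mid-ranked.
- Duration bins are log-spaced from the minimum to the maximum observed
  object look (a zero lower edge is impossible on a log scale).
- Onsets within 5 s of a session edge contribute partial, missing-padded
  windows.

## Problem sizes used in the test and acceptance runs

Replicate studies use 20 dyads of 300 s sessions: one section per dyad for
type-I calibration (100 replicates, 200 derangement permutations or 100
Poisson surrogates — the null's calibration does not depend on data
volume), and the study's two-section design for coupling-lag recovery
(50 replicates), where data volume sharpens the significance-window
edges. Mixed-model recovery uses 60 participants × 50 looks × 100
replicates. The acceptance script reports the same quantities at 30/20
replicates. Derangement nulls cache the curve of each ordered participant
pair, so cost grows with the ~n² distinct pairs rather than with the
permutation count.

## Known limitations

- The Poisson baseline compares lognormal-generated (and, in real use,
  naturalistic) binary series against exponential-duration surrogates;
  the surrogate curves are intrinsically more dispersed, so the binary
  cluster test is conservative: its empirical type-I rate sits at the very
  bottom of the nominal level. This mirrors the published procedure; the
  derangement null, which is exchangeable by construction, is the
  calibrated alternative.
- OLS-PACF on a binary series is a linear probe of a nonlinear process;
  its baseline comparison is therefore interpreted only relative to the
  duration-shuffle distribution.
- The event-locked "drop" recovered from the generator is measured against
  the length-biased mean log caregiver duration (`μ + 2σ²` under the
  mode parameterisation), since time-sampling over-represents long looks.
- With heavy-tailed look durations the duration series has long memory;
  correlations at ±30 s lags are genuinely nonzero under coupling, and the
  significance-window edges are accordingly noisy at realistic effect
  sizes.
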