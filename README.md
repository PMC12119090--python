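# dyadtheta

Analysis pipeline for naturalistic caregiver–infant interaction recordings:
coded gaze events for both partners, infant EEG, and the caregiver's voice.
The package asks two questions about how infant attention is organised
during free-flowing joint play at the end of the first year:

1. Do *endogenous* neural rhythms — infant theta-band (3–6 Hz) oscillations
   over fronto-central electrodes — forwards-predict how long infants
   attend, or change reactively after an attention shift?
2. Do *caregiver* behaviours (gaze durations, vocal pitch salience)
   forwards-predict infant attention, or adapt contingently to it?

## What it computes

From per-actor look event tables (onset, offset, target), pre-cleaned
512 Hz EEG, and a voiced-F0 track, the pipeline builds 50 Hz series and
relates them with four statistical engines:

- **Lagged dependence** — the partial autocorrelation function (PACF) of a
  binary attention-alternation series, computed by OLS regression of
  `x(t)` on `x(t−1..k)` so that PACF(k) is the coefficient of `x(t−k)`;
  and lagged cross-correlations `r(τ) = corr(x(t), y(t+τ))` (Spearman for
  binary, Pearson for continuous variables after log-transform, 2·IQR
  outlier removal and polynomial detrending).
- **Cluster-based Monte-Carlo inference** — pointwise two-sided flags at
  the 2.5th/97.5th centiles of a surrogate distribution, maximal
  same-sign runs as clusters, and a max-cluster-size threshold built by a
  leave-one-out pass over the surrogates. Three nulls: duration shuffling,
  Poisson point-process surrogate dyads, and between-participant
  derangement (fixed-point-free) pairing.
- **Event-locked analysis** — any 50 Hz variable extracted ±5 s around
  infant object-look onsets, masked after the locked look ends, optionally
  split into five log-spaced look-duration bins.
- **Per-look models** — within-look modulation (3 chunks, Wilcoxon
  signed-rank, Benjamini–Hochberg FDR) and a linear mixed model
  `log duration ~ predictor + (1|participant) + (0+predictor|participant)`
  with standardized slopes.

A synthetic-dyad generator (`dyadtheta.synthetic`) produces full studies
with known structure — alternating-renewal gaze with log-normal AR(1)
durations, theta lag-coupled to look durations, a contingent caregiver
response, EEG and F0 surrogates — so every stage is testable against
ground truth.

## Worked example

```python
import numpy as np
import dyadtheta as dt
from dyadtheta.pipeline import AnalysisConfig, run_part2

# a 20-dyad synthetic study with theta coupled to attention at +1.5 s
cfg = dt.SyntheticConfig(seed=1, theta_gain=0.02, theta_lag=1.5)
sessions, truth = dt.simulate_study(cfg, n_dyads=20)

res = run_part2(sessions, AnalysisConfig(seed=1, n_perm=200))
peak = res.xcorr.lags[np.nanargmax(res.xcorr.group_mean)]
print(f"peak lag: {peak:+.1f} s, r = {np.nanmax(res.xcorr.group_mean):.3f}")
for c in res.clusters.significant_clusters:
    print(f"significant cluster {c.start_lag:+.1f}..{c.end_lag:+.1f} s, p = {c.p:.3f}")
print(f"mixed-model slope: beta = {res.lme.beta:.2f} (p = {res.lme.pvalue:.2g})")
```

prints

```
peak lag: +1.5 s, r = 0.279
significant cluster -12.0..+17.0 s, p = 0.000
mixed-model slope: beta = 0.39 (p = 2.3e-69)
```

The cross-correlation peaks at the injected +1.5 s lag (attention
durations lead theta), the surrounding cluster is asymmetric about zero,
and longer looks carry higher mean theta (positive standardized slope).

A `dyadtheta` console script exposes the same pipeline
(`dyadtheta simulate|part1|part2|part3|all --seed ... --out ...`).

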