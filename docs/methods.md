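# Methods

## The event-locked effect statistic

All analysis runs on a per-session pNN50 series: at every beat *k* (from the
100th on), the proportion of adjacent beat pairs within the trailing
100-beat window whose RR intervals differ by **strictly more than 50 ms**.
The denominator is the number of adjacent pairs actually inside the window
(99 on clean data; fewer when artifact rejection has punched gaps, since a
difference across a gap is not a beat-to-beat difference and is never
counted).  pNN50 is kept as a proportion in [0, 1], not a percent: the
effect magnitudes the statistic produces (~10⁻⁴ /s over a 60 s lag, i.e.
ΔpNN50 ≈ 0.01–0.05) only make sense on that scale.

For a nod at time *t*, with lag t0 = 60 s:

* `pNN50(x)` resolves to the **latest valid sample at or before** *x*
  (last-observation anchoring, no interpolation).  This preserves the
  window semantics: the sample at *t* is computed entirely from pre-nod
  beats, the sample at *t* + t0 from the post-nod minute.
* `Ns = (pNN50(t+t0) − pNN50(t)) / Δt`, where Δt is the elapsed time
  between the two *anchored* samples.  On a regular grid Δt = t0; on the
  uneven beat grid using Δt rather than the nominal t0 is what makes the
  statistic an actual slope — an exactly linear series yields `Ns = slope`
  for every *t*, to machine precision, and adding a global ramp `c·t`
  shifts `Ns` and `Nall` by exactly the same `c`.
* `Nall` is the OLS slope of value against time over all valid samples of
  the session.  First- and second-half recordings are separate sessions
  with separate `Nall` (the rest break interrupts the recording).
* `N = Ns − Nall`.  Negative N: pNN50 falling faster than the session
  trend — read as increased arousal following the event.

The lag t0 = 60 s matches the ≈ 1-minute pNN50 window, so the *t* + t0
sample covers exactly the post-event minute.  Nods whose anchors cannot be
resolved (event before the first valid sample, or *t* + t0 past the last
one) are excluded and logged; every nod is accounted for either as a sample
or as a logged exclusion.  Nods during labelled sleep are kept by default
(`sleep_policy="exclude"` drops them).  Nods closer together than t0 each
still produce their own sample; their windows simply share beats.

**Matched baseline.**  Every valid sample time *s* with no nod inside
[*s* − guard, *s* + t0] (guard = t0 by default, so the trailing window at
*s* is also nod-free) is an eligible probe, and the identical statistic
N(*s*) is computed there.  `baseline_stride` thins the probe grid; the
cohort-level studies use stride 175 beats (≈ 150 s at the default 850 ms
mean RRI), i.e. one probe per dependence span of the statistic
(100-beat window ≈ 85 s plus the 60 s lag ≈ 145 s), which makes baseline
samples approximately independent and keeps the baseline pool comparable in
size to the nod pools.

## Group comparison

The three pooled samples — baseline N from all sessions, nod N from
sessions without forced nodding (no-video and video/not-forced pooled), nod
N from forced sessions — enter a tie-corrected Kruskal–Wallis test
(mid-ranks; H referred to chi-square with k − 1 df).  Pairwise follow-up is
the protected LSD on the pooled mid-ranks (Conover style): pooled
within-group rank variance on N − k df, two-sided t reference, no further
multiplicity adjustment — the protection step (pairs are only tested after
a significant omnibus test) is the LSD's control.  A raw-scale Fisher LSD
is available via `on_ranks=False`; the omnibus alpha for protection is
configurable separately from the pairwise alpha.

Every nod is treated as an independent sample, which ignores
within-participant clustering; the report prints per-session sample counts
so the clustering is visible.  See Limitations.

## Synthetic sessions

The generator emulates one lecture-half recording from a 1 kHz chest ECG:

    RRI_k = baseline(t) + LF sinusoid + HF sinusoid + AR(1) noise,

rounded to integer ms (the sensor's resolution) and clamped to
[300, 2000] ms (clamps are counted in the ground truth).  Beat times are
cumulative RRI sums.  Defaults: 3600 s duration, 850 ms mean RRI
(~70 bpm), zero drift (piecewise-linear drift configurable), AR(1) with
coefficient 0.3 and 25 ms innovation scale, Mayer-wave component 15 ms at
0.095 Hz and respiratory component 20 ms at 0.28 Hz — together giving
resting pNN50 around 0.1–0.3, typical for young adults.  Sinusoid phases
are drawn uniformly per session: recording onset is arbitrary relative to
respiration, and fixed phases would correlate sessions with each other.

Nods are a homogeneous Poisson process (spontaneous; default 0.5/min) or
explicit/periodic cue times (forced).  The injected event effect
multiplies the AR innovation scale by (1 + δ) for 60 s after each nod
onset, overlapping windows taking their union.  pNN50 responds directly to
successive-difference variability, so δ < 0 lowers pNN50 in the window —
the arousal direction — with analytically known sign.  δ defaults to 0;
the cohort studies use ±0.3, chosen to produce per-group mean effects of
order 10⁻⁴–10⁻³ /s, the magnitude scale this statistic operates on.

The three study templates (`study_templates`) are: no-video sessions with
no nods (they supply the nod-free baseline pool), not-forced sessions with
Poisson nodding at 0.5/min and δ = −0.3, forced sessions cued every 120 s
with δ = +0.3 — about 30 nods per hour-long session in both nodding
conditions.  Cue spacing is kept above the 60 s effect duration: cues much
denser than that (e.g. every 35 s) merge all effect windows into one
continuous block, and a change that covers the whole recording has no
event-locked signature for *any* estimator to recover.

What the generator does **not** model: ECG waveform shape and beat
detection, ectopic beats, respiration–cardiac coupling beyond a fixed-rate
sinusoid, baroreflex feedback, circadian structure, or participant-level
heterogeneity (all sessions of a template share its parameters).  Passing
the synthetic-cohort tests therefore shows the estimator chain is correct
under a controlled autonomic model — not that real lecture recordings
would show the same effect sizes.

## Simulation studies

* **Sign recovery** — 100 cohorts of 10 sessions per condition with
  δ = −0.3 / 0 / +0.3: the pooled group means must order
  mean(not_forced) < mean(baseline) < mean(forced).
* **Type-I error** — 200 cohorts with δ = 0 everywhere; the omnibus
  rejection rate at α = 0.05 should sit near nominal.  This holds under
  the study conditions above (10 sessions/group, decorrelated probe
  spacing); with fewer clusters per group, or with baseline probes at
  every beat (stride 1, heavily overlapping windows), the samples are
  positively correlated and the chi-square reference is anticonservative.

## Numerical and degenerate-input choices

* Strict inequality in pNN50 (a 50.000 ms difference does not count).
* pNN50 is exact integer counting (cumulative sums), so the sliding
  implementation equals a per-window recount bit-for-bit.
* A pair of beats is *adjacent* when |Δt − rri/1000| ≤ 5 ms; artifact
  rejection keeps original timestamps, so removals become gaps that break
  adjacency rather than silently splicing the series.
* Artifact rule: bounds [300, 2000] ms plus a 30 % relative-jump rule
  against the last accepted beat.
* LF/HF: Lomb–Scargle on the mean-subtracted tachogram over a 120 s
  trailing window, band powers by trapezoidal integration on a 2 mHz grid,
  LF 0.04–0.15 Hz / HF 0.15–0.40 Hz (the conventional bands;
  configurable).  Windows with fewer than 30 beats, constant values, or
  vanishing HF power give invalid samples, not errors.  A cubic-spline
  resampled (4 Hz) Welch estimator is available and agrees with
  Lomb–Scargle within ~20 % on stationary series.
* Kruskal–Wallis requires non-identical pooled values (else a
  degenerate-data error); with no ties the correction factor is exactly 1.
* Empty event lists, empty eligible baseline sets, and too-short series
  produce empty results with warnings, not exceptions; invalid parameters
  raise errors naming the offending field.

## Limitations

* **Clustering.**  Pooling all nods and probes as independent samples
  ignores participant/session-level correlation.  The per-session counts
  in the report expose the imbalance; a mixed-effects re-analysis is out
  of scope.
* **Lag sensitivity.**  t0 = 60 s is an assumption tied to the pNN50
  window length; the true latency and duration of any nod response are
  unknown.  t0 is configurable for sensitivity analyses.
* **Forced-nodding density.**  At realistic cued-nodding densities
  (≈ every 35 s) effect windows overlap completely and the event-locked
  design cannot identify the effect; the synthetic forced condition
  therefore uses 120 s cue spacing.
* **Chi-square approximation.**  For tiny groups (N ≤ 8) the chi-square
  p deviates from the exact permutation p by up to ~0.1; the test suite
  quantifies this.
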