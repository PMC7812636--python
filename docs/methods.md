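# Methods

This note documents the algorithms and statistical conventions implemented
in `dyadflow`, in pipeline order. It is self-contained: every choice that
affects numbers is stated here.

## 1. Signals and session layout

Each session records one dyad (subjects *a* and *b*) in one of three
conditions — `Alone`, `CoopNT` (cooperation without talking) and `CoopT`
(cooperation with talking) — on a shared clock:

* 0–60 s eyes-closed baseline (used for IAF estimation),
* 60–120 s rest baseline (used for SCL baseline normalization),
* 120 s onward: the task window (up to 240 s) used for all coupling
  analysis.

Modalities: 25-channel earlobe-referenced EEG at 256 Hz, single-lead ECG at
256 Hz, EDA at 64 Hz. On-disk formats are standard EDF (16-bit, 1-s
records) or a documented CSV dialect; a YAML manifest carries session
timing and per-subject file references.

## 2. Preprocessing

**EEG.** Zero-phase Butterworth band-pass 1–35 Hz (order 5, applied
forward and backward via second-order sections) plus a 50 Hz notch. The
record is cut into non-overlapping 1-s epochs. An (epoch, channel) cell is
rejected — set to NaN — if any of three criteria fire: absolute amplitude
> 100 µV; least-squares linear slope > 10 µV/s; successive-sample step
> 25 µV. An optional eye-blink reduction regresses a frontal proxy channel
(Fpz) out of all channels.

**ECG.** Band-pass 5–20 Hz, then Pan–Tompkins QRS detection: derivative,
squaring, 150 ms moving-window integration, adaptive thresholding with
search-back. Detected peaks are refined to the maximum of |ECG| within
±75 ms. RR intervals deviating more than 25 % from the local 5-beat median
or outside the physiologic 0.3–2.0 s range are replaced by local medians;
a series needing more than 20 % replacements is rejected as unusable.

**EDA.** Decimated to 16 Hz (anti-aliased), then a centered 10 s sliding
median followed by a 4 s moving average yields the tonic skin-conductance
level (SCL); the median suppresses sparse positive phasic responses
without the systematic slope-dependent shift a low-percentile filter would
introduce on trending signals. The SCL is baseline-normalized against the
rest interval (subtractive by default, divisive optional).

## 3. Neurometrics

Per-epoch power spectral densities use a Hann taper with scaling
`1/(fs·Σw²)` and one-sided doubling — for 1-s epochs the bin grid is
exactly 1 Hz. The individual alpha frequency (IAF) is the largest peak of
the epoch- and channel-averaged eyes-closed spectrum over parietal and
parieto-occipital channels within 7–13 Hz (prominence ≥ 1.5× the band
median; fallback 10 Hz with a warning). Bands are IAF-anchored:
theta [IAF−6, IAF−2), alpha [IAF−2, IAF+2), beta [IAF+2, IAF+16) Hz.

Candidate neurometrics (29 in total):

* **Workload** = mean frontal theta power / mean parietal alpha power,
* **Engagement** = mean frontal beta / (frontal alpha + frontal theta),
* one series per (ROI, band) pair over nine ROIs — Frontal, rPFC, lPFC,
  PFC, LFT, Parietal, RCP, RTP, RT — and three bands.

Band powers are means over channels and bins, ignoring rejected cells.

## 4. Time-series preparation

For each dyad/condition and candidate neurometric, six node series are
aligned on a common 1 Hz integer-second grid: SCL, RR and the neurometric
for each subject. NaN gaps (rejected epochs) are filled with a cubic
spline through observed samples (nearest-value edge extension; a series
with ≥ 50 % missing is rejected). The tonic SCL — an integrated, trending
signal — is double-differenced. The RR tachogram, stamped at beat
midpoints, and all other series are cubic-spline resampled at integer
seconds. Columns are z-scored (population SD) and checked with the
augmented Dickey–Fuller test (lags by AIC); a non-stationary column raises
a warning, not an error. The result is an *n* × 6 matrix, *n* ≥ 60.

## 5. Granger causality

A zero-mean M-variate series is modelled as a VAR(p),
`Y_n = Σ_k A_k Y_{n−k} + U_n`, fitted by OLS; the model order is selected
by BIC (AIC optional) over 1…5 with all candidates scored on the same
effective sample. One order per dyad/condition is chosen on the four
autonomic columns (shared by all 29 candidate models).

**Block GC.** For driver set *X*, target set *Y* and conditioning set *Z*
(all other series excluded), two regressions of *Y∪Z*'s future are
compared: the full one on the past of *X∪Y∪Z* and the restricted one
omitting *X*'s past. With Λ the generalized prediction-error variance
(determinant of the MLE residual covariance of the *Y* components),

```
F_{X→Y|Z} = ln( Λ_restricted / Λ_full )  ≥ 0.
```

Both covariances use 1/n normalization so that under the null
`n·F ~ χ²(p·|X|·|Y|)` asymptotically; this is the **link test**. Negative
numerical values are clamped to zero and flagged.

**Dyad-level GC** takes each subject's three-node block as driver and the
other's as target; the direction-agnostic summary is the mean of the two
directions. **Pairwise conditional GC** computes every directed scalar
link i→j conditioned on the remaining four series, so links mediated by a
third series are suppressed (for M < 3 plain pairwise GC is used).

**Surrogate null.** 100 phase-randomized surrogates per dyad matrix:
each column's rFFT amplitudes are kept exactly while phases of all
non-DC/non-Nyquist bins are redrawn uniformly (independently per column;
a block-wise variant shares one draw within each subject's three columns,
preserving within-subject cross-spectra). Real dyad-GC summaries are
compared against per-dyad surrogate means with a paired *t* test across
dyads; the effect size is Cohen's `d = mean(diff)/sd(diff)`.

## 6. Model screening, networks and condition comparisons

For each of the 29 candidate systems and each condition the real-vs-
surrogate test is run across dyads. A model is **flagged** when the real
GC is significantly above the surrogate null (p < 0.05, real mean above
surrogate mean) in *every* cooperative condition.

For flagged models, the pairwise-conditional GC network of each
dyad/condition is thresholded at the χ² p < 0.05 (uncorrected by default;
Benjamini–Hochberg optional). The **between-subject density** is the
fraction of the 18 possible directed cross-subject links present;
within-subject densities use the 6 intra-block links. Densities are
compared across conditions on paired dyads with the Friedman test
(Wilcoxon signed-rank for two conditions) and Dunn–Šidák-adjusted pairwise
Wilcoxon post hocs. Link prevalence (per-link fraction of dyads showing
the link) summarizes network topology per condition.

## 7. Behaviour and effectiveness

Task performance is scored as
`score = 1 − (t_el/240)·((w+m)/15)` with elapsed time `t_el`, wrongly
placed pieces `w`, missing pieces `m` (15 pieces, 240 s total). Pooled
cooperative scores are split at their quartiles: ≤ Q1 *ineffective*,
≥ Q3 *effective*, otherwise neutral. Raw signal levels of effective vs
ineffective instances are compared with Mann–Whitney rank sums, and
dyad-level GC is correlated with the score via Spearman's rho.
Questionnaires: the weighted NASA-TLX is `Σ rating_i·weight_i / 15` with
weights the pairwise-comparison win counts; team-workload and cooperation
scores are unweighted six-item means.

## 8. Synthetic ground truth

The generator defines a stable 6-node VAR(1) at the 1 Hz analysis grid.
Within-subject dynamics are fixed (SCL autoregressive at 0.70 and driven
by the neurometric; RR at 0.50 driven by SCL; neurometric at 0.50);
between-subject links (other's RR→SCL, NEURO→SCL, SCL→RR, both
directions) are scaled by a per-dyad gain drawn from U(0.15, 0.30) and
switched on only in cooperative conditions. Latent series are rendered
upward into raw signals:

* **EEG**: 25-channel 1–35 Hz noise plus a posterior alpha rhythm in the
  baselines; frontal beta amplitude per second is `∝ exp(0.25·latent)`,
  making band power rank-monotone in the latent neurometric; ±160 µV
  spikes are injected at a configurable rate.
* **ECG**: a triphasic QRS pulse train with interbeat intervals
  `0.85 + 0.05·latent` seconds (mapping must stay in 0.3–2.0 s).
* **EDA**: the latent SCL is scaled (3×10⁻³ µS) and double-integrated into
  a tonic level, decorated with exponential phasic bumps and sensor noise,
  so the pipeline's double differencing recovers it.

Behavioural scores decrease in missing pieces generated as a decreasing
function of the coupling gain, giving the GC-vs-score correlation a known
positive ground truth. All randomness derives from a single master seed
through hierarchical `SeedSequence` spawning (derived seeds < 2³¹).

## 9. Statistical conventions

* All significance thresholds default to α = 0.05, two-sided.
* χ² link tests are asymptotic; the surrogate test is the primary guard
  against their small-sample optimism at the screening stage.
* VAR residual covariances use the unbiased divisor for reporting
  (`n − p − Mp − 1`) but MLE (1/n) inside GC ratios, as the χ² theory
  requires.
* Quartiles use linear interpolation between order statistics.
* Effect sizes: Cohen's d on paired differences; rank-based tests
  otherwise.
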