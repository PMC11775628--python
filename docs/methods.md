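# Methods

`stnlfp` reimplements, as a tested pipeline, the analysis of intraoperative
subthalamic-nucleus (STN) local field potentials recorded while Parkinson's
disease patients perform the Simon conflict task during DBS electrode
placement. Because the patient recordings underlying that analysis are not
publicly deposited, every stage is exercised against a synthetic-data
generator that reproduces the *statistical structure* the analysis assumes;
the published group-level summary tables are retained only as arithmetic
cross-check inputs (`stnlfp.reference`).

## Signal processing chain

**Preprocessing.** Each hemisphere contributes three parallel microelectrode
channels sampled at a high rate (44 kHz in the original acquisition; the
generator's default is 11 kHz, with both supported — see *Problem sizes*).
The channel with the highest variance over the concatenated
stimulus-to-response periods is selected for analysis; the three channels are
demeaned samplewise (common-average reference), cancelling line interference
and any common-mode component. The selected channel is then anti-alias
decimated to 1000 Hz (`scipy.signal.resample_poly`), linearly detrended,
band-pass filtered 1–100 Hz (2nd-order Butterworth) and band-stop filtered
59–61 Hz (2nd-order). All filters are applied forward–backward: the paper's
analysis is response-locked, and zero-phase filtering guarantees that filter
group delay cannot shift power relative to the response timestamp. Filter
family and phase handling are configurable (`PreprocConfig`); the defaults
are the minimal-assumption reading of a "2nd-order 1–100 Hz band-pass with a
59–61 Hz notch".

**Time–frequency decomposition.** Band power comes from complex Morlet
wavelets implemented as frequency-domain Gaussian filters applied to the
analytic signal (single FFT of the trace, one Gaussian per analyzed
frequency, peak gain 1). Frequencies run 2–100 Hz in 1 Hz steps; the number
of cycles ramps linearly from 4 at the lowest analyzed frequency to 12 at the
highest, trading temporal precision at low frequencies for spectral precision
at high ones. Samples within 3.5 Gaussian SDs of the trace edge are flagged
invalid and trials touching them are dropped. Theta is 4–7 Hz, low beta
12–22 Hz, both inclusive row-means of the power map; "broadband" is the mean
over the full analyzed grid and feeds the trial QC test. A streaming
accumulator (`band_power_series`) computes the three band series without
materializing the full time × frequency map, keeping memory O(n) for
multi-minute recordings.

**Epoching, baseline and QC.** The analysis window is [−380, 0) ms before the
button response, split into four 95 ms bins (bin 1 earliest). Only correct
trials are analysed. Each trial carries an equal-length baseline window
selected by `baseline_policy`:

* `intertrial` (default): 380 ms ending 100 ms before stimulus onset, inside
  the preceding intertrial interval — non-overlapping with the response
  period and statistically cleaner;
* `literal_preresponse`: the 380 ms window [−480, −100) ms before the
  response.

Both are provided because the two descriptions of the baseline in the source
protocol (intertrial period vs a window 500–100 ms before the response)
cannot be reconciled from the text; the default is the non-overlapping
reading. Per trial, a paired t-test compares the broadband analysis window
against its baseline samplewise; trials that do not differ (two-sided
p ≥ 0.05) carry no reliable modulation and are excluded. Degenerate cases: an
identical pair is excluded, a constant non-zero offset is a certain deviation
and is included. QC uses broadband by default (`qc_broadband=False` switches
to per-band testing); the outcome applies to both bands of that trial.

**Normalization.** Two normalizations are computed per epoch: (i) the
*power ratio* — the analysis-window band power divided by its own baseline
mean — whose natural log is the response modelled by the statistics; (ii) a
z-score against per-subject pooled baseline statistics (all of a subject's
baselines within subregion × band), retained for time-course plotting.
Decibel scaling (10·log10 power/baseline-mean) is available for display.
Modelling the log *ratio* rather than the z-score is deliberate: z-scores can
be negative and have no meaningful log, while the log-ratio is exactly the
quantity whose cell means are reported on a log scale.

**Baseline summaries for the correlations.** A subject's baseline band level
is the mean baseline-window band power over all correct-trial epochs within
subregion × band, across hemispheres, expressed as 10·log10(power)
(dB re 1 a.u.²). No within-subject reference is divided out — any such
reference would cancel exactly the between-subject differences the
correlation analysis needs — and Spearman correlation is invariant to this
monotone choice of scale.

## Behavioural battery

RTs below 150 ms are removed as anticipations; then, within each
subject × depth × correspondence cell, RTs above mean + 3 SD of the remaining
responded trials are removed in a single pass. Accuracy denominators count
responded trials (omissions and too-early trials excluded). Mean RTs use
correct trials only. Distributional analyses rank-order single-trial RTs into
four equal-sized bins (stable sort; remainder trials go to the earliest
bins): the delta plot places interference d_b = meanRT_NC − meanRT_Cs at
x_b = (meanRT_NC + meanRT_Cs)/2 per bin, computed on correct trials, and the
final suppression slope is (d₄−d₃)/(x₄−x₃); the conditional accuracy function
is percent-correct per bin over responded trials including errors, with the
fastest NC bin indexing impulse capture. Subjects are aggregated first;
group inference is a two-sided paired t-test with Cohen's d =
mean(diff)/SD(diff), matching the degrees of freedom implied by
subject-level analysis.

## Statistical model

For each band, log power-ratio PowerCells (subject × subregion × relative
hemisphere × correspondence × time-bin) are fitted by REML (statsmodels
MixedLM) with fixed effects subregion + correspondence + hemisphere +
subregion×correspondence + hemisphere×correspondence +
subregion×correspondence×hemisphere, a random intercept per subject, a random
slope for correspondence, and a random time-bin slope nested within
subregion × correspondence (a variance component over the centered bin
index). Time bins enter only the random part. Because the fixed part omits
the subregion×hemisphere two-way term, the design matrix is completed by the
factorization of the three-way term, leaving all eight cell means estimable;
estimated marginal means and their contrasts are linear functions of the
fixed coefficients with SEs from the coefficient covariance.

**Convergence ladder.** If a fit fails to converge (tried with L-BFGS, then
Powell), the random structure is simplified stepwise — drop the nested time
slope, then the correspondence slope — and the step used is recorded in the
result and the report bundle.

**Denominator degrees of freedom.** Exact small-sample df corrections
(Satterthwaite/Kenward–Roger) are not available in the fitting engine.
Every design factor varies within subject and all reported contrasts cancel
the subject intercept, so the effective replication units are the
per-subject hemisphere recording series, giving df = 2(n_subjects − 1). This
choice was verified by null-simulation calibration: with the estimated random
structure at n = 10, residual-based df rejects true-null fixed terms at
6–7% (α = 5%) and subject-based df = n − 1 at 2–3%, while the intermediate
stratum keeps every term within 3–6%. The df printed by the original
analysis software arise from its own approximation and are not a target.

**Correlations.** Spearman rank correlations relate per-subject baseline band
power (per subregion, averaged across hemispheres) to the Simon effects
measured in the blocks at that subregion's depth (RT cost and accuracy
cost), two-sided, no multiple-comparison correction beyond α = 0.05 —
matching the protocol's single stated significance level.

## Synthetic-data generator

The generator has two tiers.

**Signal tier** (`simulate_recording` / `simulate_cohort`): raw three-channel
traces. Each microelectrode carries predominantly *local* activity — its own
1/f (pink) noise floor, its own ongoing narrowband theta and beta
realizations, and response-locked theta and beta bursts with
channel-specific phases — scaled by per-channel gains (1.0/0.75/0.55) so
channel selection is meaningful, plus a genuine common-mode component (60 Hz
line + shared pink noise) that exercises the three-channel demeaning. Pink
noise is normalized to unit SD *within the 1–100 Hz analysis band*, which
makes burst-to-background ratios independent of the raw sampling rate (the
same configuration behaves identically at 44 kHz, 11 kHz or a desk-scale
rate). Bursts are Hann-windowed oscillations of 300–400 ms centred 150 ms
(±50 ms jitter) before each response, inside the [−380, 0) ms analysis
window. Burst gain = band base amplitude × condition gains × subject random
effect, with three condition gains: theta × 1.5 on dorsal NC trials,
beta × 1.4 when the recording hemisphere is ipsilateral to the response on NC
trials, and beta × 1.3 in dorsal recordings. Base amplitudes were calibrated
once so that the resulting log power-ratio cell means fall in the range the
group tables report (theta ≈ 0.6–1.0, beta ≈ 1.2–1.7) and the per-trial QC
excludes only a few percent of trials; the gains are set for reliable
recovery at n = 10, not to reproduce the published effect magnitudes, which
are not stated in physical units.

**Behaviour.** Deliberate responses follow an ex-Gaussian
(μ = 430, σ = 60, τ = 150 ms, subject intercept SD 30 ms) with a +40 ms Simon
cost on NC trials; an optional `suppression_gain` shrinks the cost at slow
RTs to emulate build-up of selective suppression (default 0 — flat delta
plots, matching the near-zero published slopes). NC errors arise from two
channels scaled by a single log-normal subject impulse-strength trait
(log-SD 0.8): fast *impulse capture* (launch probability 0.05; the impulse
races the deliberate response with latency 280 + Exp(60) ms and, when it
wins on an NC trial, produces a fast error toward the stimulus side) and
*residual suppression failures* (probability 0.06, errors at the deliberate
latency). On Cs trials both routes issue the same response, so capture is
unobservable there. A colour-rule lapse (0.09) applies to both conditions.
This two-channel structure is what lets the generator jointly produce a
fastest-NC-bin accuracy near 70%, overall accuracies near 90% (Cs) / 80%
(NC), and enough between-subject spread in the accuracy Simon effect for the
coupling below; a single fast-capture channel cannot satisfy all three.

**Baseline-beta/behaviour coupling.** A subject's ventral baseline beta level
(log-normal, SD 0.4) and their impulse strength are linked by a Gaussian
copula. The configured `baseline_beta_behavior_rho` targets the *observable*
Spearman correlation between generated baseline beta and the measured
accuracy Simon effect; since the latter is estimated from a finite number of
trials, the latent copula correlation is the target divided by an analytic
attenuation factor (signal SD over total SD of the per-subject effect),
squared as an empirical correction for the stronger attenuation of rank
correlations under skewed trait distributions, and clipped at 0.99. At the
default ρ = 0.8 and n = 10 this yields sample Spearman ≥ 0.5 in ≈ 86% of
replicate cohorts (mean sample ρ ≈ 0.67).

**Cell tier** (`simulate_powercells`): PowerCells drawn directly from the
mixed-model generative structure (grand mean + `effect_transfer` × log burst
gain + subject intercept + correspondence slope + nested time slope +
residual), bypassing signal synthesis. Replicate-heavy Monte-Carlo checks —
type-I calibration over hundreds of null cohorts, contrast power, the
coupling calibration — run at this tier or the behaviour-only tier; a full
signal-tier cohort at n = 10 runs once per seeded analysis. This split is a
deliberate design decision: signal-tier replicates at study scale are
computationally out of proportion to what they would add, and the signal
chain is itself verified end-to-end on seeded cohorts and against
periodogram oracles.

**What the generator does not emulate.** No biophysical neural-mass dynamics,
no spikes, no nonstationarity across the session, no electrode drift or
movement artifacts, no disease-severity covariates, and Parkinsonian
physiology only as elevated dorsal beta gain. Passing tests therefore show
that the *pipeline* recovers the structure it assumes from data of realistic
dimensionality and noise — not that the published patient-level findings
would replicate.

## Numerical choices and degenerate inputs

* Epoch windows are half-open in ms relative to the response; bin edges
  [−380,−285,−190,−95,0) ms.
* Channel-selection ties break to the lowest index; quantile-bin ties keep
  input order (stable sort); remainder trials go to the earliest bins.
* `log_transform` flags non-positive ratios (excluded, counted) and raises
  if they exceed 5% of values — a symptom of a mis-configured baseline.
* Zero-variance paired differences: excluded if identically zero, included
  if a constant non-zero offset. Zero-variance paired t inputs raise.
* The final delta slope is undefined (raises) when the last two bin mean RTs
  coincide.
* Byte-level determinism: all randomness flows from `SimConfig.seed` through
  spawned `SeedSequence` streams; recordings are regenerated lazily from
  stored per-recording seeds so cohorts never hold all raw traces in memory;
  report CSVs are written with a fixed float format.

## Problem sizes

Defaults follow the study conditions: 10 subjects, bilateral recordings at
two depths, two blocks of 144 trials per depth, ITI 750–1250 ms, 1000 ms
deadline. The generator's default raw rate is 11 kHz rather than the
acquisition system's 44 kHz — the analysis band ends at 100 Hz, so after
decimation to 1000 Hz the two are equivalent, and 44 kHz is supported when
wanted. The test suite exercises the full chain on reduced cohorts
(2–4 subjects, one block per depth, 2.5–4 kHz) and the Monte-Carlo suites on
100–400 replicate cohorts at the cell/behaviour tier; `scripts/acceptance.py`
runs one full-scale signal-tier cohort plus the replicate suites.

## Known limitations

* The published tables contain two internal inconsistencies (ventral Simon
  RT 34.8 ms vs the 31.0 ms cell difference, presumably subject-weighted
  means; contralateral beta Cs/NC marginals interchanged between text and
  table). The cross-checks report the cell arithmetic and document, rather
  than reconcile, the discrepancies.
* The df convention for fixed-term tests is a calibrated approximation, not
  Satterthwaite; p-values within ±1 df stratum of the chosen one differ
  slightly.
* The QC test inherits the autocorrelation of band-power series, so its
  nominal α is exact only for exchangeable samples (as in the null
  calibration); on real signals it is anticonservative, which only makes the
  inclusion criterion easier to meet — consistent with the few-percent
  exclusion rates observed.
* `fit_mixed` assumes the complete eight-cell design; severely unbalanced
  real data (e.g. a missing depth) will fit but contrasts into absent cells
  are extrapolations of the reduced fixed structure.
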