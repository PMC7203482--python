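# Methods

## Problem setting

`affectlearn` analyses psychophysiological recordings of self-regulated
learning sessions. During one 60-minute session a participant (proband)
wears a five-electrode consumer EEG headset (AF3, AF4, T7, T8, Pz) that
streams precomputed band power for theta (4–8 Hz), alpha (8–12), low beta
(12–16), high beta (16–25) and gamma (25–45 Hz) at a nominal 8 Hz, and a
wrist band sampling galvanic skin resistance (GSR, kΩ) at 5 Hz. Every
270 s a vibration alarm prompts a five-slider self-report (interest,
energy, valence, focus, tension; each in [−4000, 4000]), giving 13
*process* measurements per session; responses slower than 60 s are
invalid. After the session, *outcome* questionnaires yield per-proband
scale scores (mean of ordinal items).

The analytic question is whether the sensor streams predict (a) the 13
embedded experience samples and (b) the outcome scores, better than a
sensor-free baseline.

## Pipeline

1. **Masking.** Samples recorded while the proband answered the slider
   questionnaire are removed from every stream (half-open windows
   `[alarm, alarm + response duration)`). With the reference design (13
   responses averaging 16.36 s in 3600 s) this discards ≈ 6% of the data.
2. **Segmentation.** Process-level features use the 270 s preceding each
   alarm (`[alarm − 270, alarm)`, anchored to the nominal alarm time);
   outcome-level features use the whole masked session. Segments with
   less than half their nominal samples are flagged; flagged rows are
   retained by default and excludable via configuration.
3. **Features.** Per stream and segment, seven summary statistics: mean,
   median, sample standard deviation (n−1), max, min, max−min, and
   *tendency* = median(first 30 s) − median(last 30 s) of the segment's
   span. On top of the 25 electrode/band streams, four pointwise index
   families are derived first: BLA = low-beta/alpha per site, the
   engagement index NASA = (low-beta + high-beta)/(theta + alpha) per
   site, and the laterality differences T7−T8 and AF3−AF4 per band. That
   gives 45 × 7 = 315 EEG features and 7 GSR features. Ratio denominators
   are floored at 1e−12 (logged) since band power can reach zero.
4. **Models.** Ridge regression in closed form (intercept unpenalized,
   features standardized with training-set statistics only; dual solve
   when features outnumber rows) and gradient-boosted trees (XGBoost,
   single-threaded for determinism, split-count importances).
   Hyperparameters are tuned per training set by seeded random search
   (default budget 50) over log₁₀λ ∈ [−4, 6] for ridge and depth 2–8,
   learning rate 0.01–0.3 (log-uniform), 50–500 rounds, subsample 0.5–1
   for boosting, scored by threefold CV RMSE with folds grouped by
   proband for process data. Recursive feature elimination with CV
   (drop the 10% smallest |weight| per iteration, near-ties in the subset
   score prefer fewer features) is available but off by default.
5. **Evaluation.** Outcome scores: leave-one-out CV. Process labels:
   leave-one-proband-out CV — all 13 rows of a proband held out together,
   inner tuning folds also grouped, so no information about the held-out
   person can leak. Metrics: RMSE, MAE and label-prediction correlation
   (LPC). LOPO metrics are averaged over probands; LOPO LPC is the mean
   per-proband correlation (a pooled variant is available). Missing
   process labels (invalid alarms) are excluded from training and
   evaluation.

## Baselines and the significance rule

The baseline predicts a held-out proband's label(s) as the mean of all
*other* probands' labels. Two algebraic identities follow and serve as
exact self-checks: the LOO baseline prediction is a strictly decreasing
affine function of the held-out label, so its LPC is exactly −1 for any
non-constant label vector; and its RMSE equals n/(n−1) times the
population standard deviation of the labels.

Model and baseline are compared with a paired two-sided Student's t-test
on per-proband absolute errors; the effect size is Cohen's d for paired
data, mean(diff)/sd(diff) with diff = baseline error − model error. The
pairing unit (per-proband absolute error) and the table markers (`+` for
error below baseline, `*` for p < 0.05) are this package's documented
choices. "The model predicts above baseline" is declared only when
p < 0.05 *and* d > 0 — a model significantly worse than the baseline is
not a positive finding. If the error differences have zero variance, p is
reported as 1 when the errors are identical and as missing otherwise,
with d = 0 and a flag.

Scale reliability is Cronbach's alpha, α = k/(k−1)·(1 − Σvar(itemⱼ)/var(Σ)).

## Spectral front end

The headset's on-device preprocessing is emulated from raw 128 Hz EEG: a
2 s Hanning window stepped by 16 samples (8 Hz output; a 125-sample step
is configurable), FFT, and per band the **sum** of squared magnitudes over
bins with frequency in `[low, high)` — at the 0.5 Hz bin resolution the
shared 8 Hz bin therefore belongs to alpha, not theta. The output sample
carries the window's end time. Absolute power scale and the sum-vs-mean
convention are immaterial downstream because all features are compared
within-pipeline; whether the real device reports mean or sum power is
undocumented, so it is a configuration choice here. The vendor's
undocumented filtering and the 2048→128 Hz decimation are out of scope.

## Synthetic cohorts

Real recordings of this kind are not publicly available, so the generator
produces cohorts with the statistical structure the analysis assumes.

Per proband: outcome traits z ~ N(0, I₃); a *separate* state trait; a
per-site activation trait a[site] ~ N(0, 0.5²) (how strongly each
electrode site fires for this person); a latent affective state s(t) — a
1 Hz AR(1)/Ornstein–Uhlenbeck process (relaxation time 120 s, stationary
sd 1) reverting to 0.5 × state-trait, interpolated to sensor rates. Band
power is `baseline · exp(0.2·s(t) + a[site]) · lognormal(σ=0.3)` —
positive and right-skewed like real power. GSR is a subject baseline
(200 ± 30 kΩ) plus a 40 kΩ/h tonic drift, a −10 kΩ state coupling
(arousal lowers resistance) and noise, floored at 1 kΩ. Sliders map the
state at the alarm affinely to the ±4000 scale (gain 1500, noise sd 500,
clipping after noise), with per-scale couplings (interest 1.0, energy
0.8, focus 0.7, valence 0.6, tension −0.5). Response durations are
truncated-normal (mean 16.36 s, sd 7.36, support (0, 60]).

Outcome scales: each scale's latent factor mixes the outcome traits with
fresh noise, standardized analytically. Ordinal items (1–7) follow a
one-factor model whose loading is set from the target alpha via the
Spearman–Brown inversion r̄ = α/(k − (k−1)α); the latent inter-item
correlation is inflated by 13/12 to offset the ≈ 1/12 quantization
variance added by rounding to unit-spaced levels, so the measured alpha
hits the target (verified at α = 0.8, k = 10, n = 500). Default
reliabilities per scale follow the study design the generator emulates
(0.37–0.90 across twelve scales).

**Design choice — disjoint latent drivers.** The state trait (which moves
the sensors) is independent of the outcome traits (which move the
questionnaire scores). In the base configuration there is therefore *no*
sensor→outcome path at all: any association must be planted explicitly.
This makes the base configuration an exact null for type-I-error checks
of the full pipeline, at the cost of not modelling any natural
physiology–disposition correlation.

**Planted effect.** `plant_t7_effect(cfg, strength)` rewrites the
intrinsic-motivation factor as `−strength · a_T7/sd + √(1−strength²) ·
base factor`, so `strength` *is* the planted correlation between T7
activation and the latent outcome (1 = fully determined). An additive
coefficient with fixed noise could not span the full dependence range,
which is why the mixing is variance-preserving. Strength 0 leaves the
cohort bit-identical to the base configuration. Because the activation
trait multiplies all five T7 band-power streams, every T7 summary feature
becomes a noisy proxy of the planted cause, while the BLA/NASA ratios at
T7 cancel it — exactly the signature the feature-screening checks look
for.

What the generator does **not** emulate: real electrode artifacts and
contact-quality dropouts, oscillatory (narrow-band) EEG dynamics,
phasic skin-conductance responses, non-stationary response behaviour,
and any natural correlation between physiology and questionnaire
dispositions. Passing the planted-recovery and null-calibration checks
therefore shows the *pipeline* is sound (no leakage, honest baselines,
recoverable effects), not that real wearable data carry such signals.

## Problem sizes and numerical choices

The validation suite uses a 60-proband cohort (strength 0.8, ridge tuning
budget 20) for planted-effect recovery, ten such cohorts for the
feature-screening dominance check, and twenty 30-proband null cohorts
(budget 10) for type-I control; these sizes give stable outcomes while
keeping a full run in minutes on one CPU. At the planted conditions the
ceiling on achievable LPC is ≈ 0.68 (0.8 planted correlation × √0.81
score reliability × ≈ 0.97 feature-proxy fidelity), and observed LOO
ridge LPC is typically 0.4–0.6 with paired p between 0.01 and 0.07 —
the significance test sits near its detection threshold at n = 60, which
is informative in itself about designs of this size.

Other numerical choices: intervals are half-open everywhere; the alarm
count uses a 1e−9 relative tolerance in the floor division; ridge falls
back to minimum-norm least squares at λ = 0; constant feature columns are
zeroed, not divided by zero; the 1 s vibration alarm is not modelled
(response windows start at the alarm); invalid (> 60 s) responses keep
their recorded window for masking but contribute no label.

## Known limitations

- The t-test pairing, the d formula and the `+`/`*` markers are package
  conventions; other choices (two-sample tests, pooled LOPO LPC) change
  table values.
- RFECV with grouped inner folds is supported but not exercised by the
  default experiments.
- Raw-EEG synthesis is intentionally minimal (tones/noise for spectral
  tests); cohort band power is generated directly at 8 Hz.
- Low-reliability scales (α ≲ 0.4) still show mild quantization
  attenuation in measured alpha despite the 13/12 correction.
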