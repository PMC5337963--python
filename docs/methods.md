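# Methods

This note documents the models implemented in `pupilbias`, the defaults
and the reasoning behind design choices that were genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal-detection model of decision uncertainty

A trial's decision variable is dv ~ N(μ, σ) with μ the signed sensory
evidence; the choice is sign(dv − c) (the measure-zero tie dv = c resolves
to +1) and

    confidence = Φ(|dv − c| / σ),   uncertainty = 1 − confidence ∈ [0, 0.5].

Defaults: σ = 2.723 (the inverse of a probit psychometric slope of 0.367
per motion-energy unit, estimated from a probit fit to pooled group
choice data for this task), c = 0 (no overall bias), evidence strength uniform on [0, 6] with
random sign. The uniform evidence distribution is a documented stand-in
for the empirical one, which is not available without the original
recordings; all three qualitative signatures (uncertainty splitting by
outcome, accuracy falling 100% → 50% across uncertainty bins and never
below chance, the uncertainty effect at matched evidence) are insensitive
to that choice. `mean_uncertainty` evaluates the conditional expectation
by adaptive quadrature against the truncated normal density; the
simulation route is cross-checked against it in the tests.

Binning: accuracy-vs-uncertainty uses equal-count (quantile) bins so no
bin is empty; evidence axes use equal-width bins. Default simulation size
is 10⁶ trials, which keeps the Monte-Carlo error of every binned point
below ~0.5 percentage points at 100 bins while running in seconds; larger
runs change nothing qualitatively.

## Stimulus sequences and the generative observer

**Counterbalancing.** Each block derives from a 53-trial category
sequence whose 52 transitions are a shuffled multiset of 26 repeats and
26 alternations, integrated from a random initial category and truncated
to 50 trials. Only the counterbalancing constraint itself is specified
by the study design, not an algorithm; the shuffled-multiset
construction is the simplest sequence satisfying it exactly. Unsigned coherence levels (sets easy =
{2.5, 5, 10, 20, 30}, medium = {1.25, 2.5, 5, 10, 30}, hard = {0.625,
1.25, 2.5, 5, 20} % coherence difference) are assigned within category by
cycling through the 5-level set and shuffling; because the category split
of a transition-balanced sequence is not exactly 25/25, level counts are
balanced to within one rather than exactly five per level.

**Observer.** The generative observer makes a noisy comparison
dv = μ_t + σ·η against a criterion shifted trial by trial by its history:

    c_t = c − σ·b_t,
    b_t = δ' + Σ_k [ ω_c,k·choice_{t−k} + ω_s,k·stim_{t−k}
                     + pupil_{t−k}·(ν_pc,k·choice_{t−k} + ν_ps,k·stim_{t−k})
                     + rt_{t−k}·(ν_rc,k·choice_{t−k} + ν_rs,k·stim_{t−k}) ],

so bias weights are expressed in criterion units of σ. With
`noise="logistic"` η is standard logistic and these weights coincide
exactly with the logit-scale weights of the fitted regression model; the
recovery and coverage experiments use the logistic observer for that
reason (a Gaussian observer's weights differ from the logistic fit's by a
probit-to-logit factor ≈ 1.7, which would conflate scale mismatch with
estimator error). Modulator values enter in standardized units; the
generator standardizes with moments calibrated from an internal
zero-history simulation, matching the per-session z-scoring applied at
fit time. Lapses replace the choice with a fair coin at the lapse rate.

Uncertainty (1 − F(|dv − c_t|/σ)) drives the physiological channels:
pupil = 2.0·uncertainty + N(0, 0.25) z-units, and RT = 0.35 s +
1.0 s·uncertainty + lognormal(median 0.2 s, σ_log 0.2), clipped to
(0, 3] s. The gains are chosen once so that simulated pupil and RT ranges
resemble typical group data for this task class; the lognormal RT noise
SD of 0.2 is arbitrary and documented as such. Evidence is μ_t =
0.15·(coherence difference in %) + N(0, 0.8) motion-energy units, which
maps the easy set onto roughly the [−6, 6] range the SDT module assumes.

**Synthetic eye recordings.** The 1000-Hz pupil trace is a slow drift
(random walk on 30-s knots) plus one arousal event per trial — a boxcar
at the trial's true pupil amplitude sustained from the choice until
feedback — convolved with the canonical pupil impulse-response function
h(t) = (t/t_max)^w e^{−w(t/t_max − 1)} (t_max = 0.93 s, w = 10.1),
normalized to unit area so the pre-feedback plateau equals the amplitude,
plus white measurement noise and Poisson blink dropouts. A brief impulse
at the choice was considered and rejected: the variable 1.5–2.5 s
feedback delay would sample the impulse response's decaying tail at
amplitudes ranging over a factor of ~60, so the pre-feedback scalar would
carry essentially no amplitude information by construction. A sustained
input is also the physiologically sensible reading — uncertainty-related
arousal persists until feedback resolves it.

**RDK movies.** Dots live in an annulus (defaults: outer radius 12°,
inner 2°, 1.7 dots/deg², 0.2° dots, 60 Hz). Three interleaved
subsequences update in rotation; on its update a signal dot (selected per
update with probability = coherence) steps speed/frame_rate = 0.192°
along the motion direction, so the displayed effective speed is
speed/3 = 3.83 °/s; noise dots re-plot uniformly at random ("random
position" noise, "different" rule). Signal dots wrap to the
diametrically opposite point on leaving the annulus (a dot stepping into
the inner hole re-plots randomly, since the opposite point is also in the
hole) and are re-plotted after a 4-update lifetime. The nominal dot count
(round(density × area) = 748) differs slightly from the 768-dot display
count conventionally used with this geometry; the count is exposed as an
override.

## Motion energy

Spatial filters f1 = cos⁴(α)cos(4α)·exp(−y²/2σ_g²) and the sine
analogue, α = atan(x/σ_c), on a grid rotated into the motion direction
(σ_g = 0.05°, σ_c = 0.35°, support ±0.7° at 10 px/deg). Temporal filters
g(t) = (kt)^n e^{−kt}[1/n! − (kt)²/(n+2)!] with k = 60 s⁻¹; n = 3 peaks
earlier (fast), n = 5 later (slow). The temporal support defaults to
0.35 s: at 0.3 s the n = 5 filter's negative lobe has only decayed to
~1.6% of peak, which the decay check rejects. Quadrature pairs
f1·g_slow + f2·g_fast and f2·g_slow − f1·g_fast are applied by spatial
correlation (convolution would flip the odd filter's parity and with it
the preferred direction) and causal temporal convolution; outputs are
squared, summed over the two filters and all pixels, and the energy of
the 180°-opposite direction (computable from the same responses by
negating the odd filter) is subtracted. Per-trial evidence is the mean
opponent energy over the test interval minus the reference interval,
discarding the first 0.15 s of each (filter ramp-up); evidence strength
is its absolute value.

A practical note on sampling: σ_g = 0.05° is 0.5 px at the default
10 px/deg and grossly undersampled at coarser renders; tests that assert
quantitative evidence quality use full-resolution filters on a
down-scaled annulus, while parity/antisymmetry properties (exact at any
resolution) use cheap coarse renders.

## Pupil preprocessing

Order: blink interpolation → event-response deconvolution → band-pass,
z-score, resample → epoching and baseline → scalar response →
residualization. One "run" is one block (the tracker is recalibrated
between blocks).

* Blink intervals (tracker events, padded ±150 ms) and velocity
  artifacts are linearly interpolated. The velocity criterion is
  |Δpupil|·rate exceeding max(10 robust SDs of velocity, 50·SD(pupil)
  per second); the absolute floor is needed because on clean recordings
  the MAD of velocity shrinks until smooth physiological slopes would
  cross a purely relative threshold.
* Blink/saccade-evoked responses are estimated jointly by least-squares
  FIR deconvolution (boxcar taps at 10 Hz over 6 s, normal equations)
  and subtracted. Event types with fewer than 5 events are skipped.
* Band-pass 0.01–10 Hz, second-order Butterworth, applied zero-phase
  (forward-backward; avoids latency shifts). The DC level is removed
  before filtering because the 0.01 Hz corner's edge transient would not
  decay within a run. The filtered trace is z-scored per run and
  decimated to 100 Hz (the pass-band ends below the output Nyquist, so
  plain decimation is alias-free).
* Epochs lock to reference onset and to feedback on the 100-Hz grid;
  baseline = mean over the 500 ms before reference onset, subtracted.
  Trials whose epochs exceed the recording are flagged, never dropped;
  the per-trial fraction of interpolated samples is reported as a
  diagnostic.
* The scalar pupil response is the mean baseline-corrected signal in the
  250 ms before feedback; NaN if that window is fully interpolated.
* Residualization projects log RT out of the scalars:
  y' = y − r(rᵀy) with r unit-normalized. y and r are centred (and y
  scaled) first, so corr(y', r) = 0 exactly and the operation equals the
  OLS residual on [1, log RT]; without centring a mean-driven correlation
  survives the bare projection.

## Psychometric models and behavioral analyses

Choice model: P(r=1|s) = γ + (1 − γ − λ)·logistic(αs + δ) with γ = λ
(one lapse), fit by bounded L-BFGS-B from 10 restarts. Accuracy model:
P(c=1|s) = 0.5 + (0.5 − λ)(1 − e^{−(s/θ)^β}); sensitivity = 1/θ, and at
s = θ with λ = 0 accuracy is 0.5 + 0.5(1 − 1/e) ≈ 81.6%. The standard
convention (γ lower asymptote, λ upper) is adopted.

On conditional subsets of a few hundred trials the free-lapse model has
a degenerate global optimum — a step function with lapse ≈ 0.3 and the
bias at its bound — under which the bias term loses its meaning. The
serial-bias analysis therefore bounds lapse at 0.1 for its per-bin fits;
the unconditional fit keeps the full range.

Serial bias: trials are binned by the previous trial's pupil response or
RT into tertiles computed within session (guards against slow drifts),
a psychometric function is fitted per bin × previous choice, δ is mapped
to P = e^δ/(1+e^δ), and the two previous-choice curves are collapsed into
a repetition probability. Post-error slowing: evidence strength is
regressed out of RT per session, then isolated errors (correct
neighbours on both sides, same block) contribute post- minus pre-error
RT. Pupil–evidence regressions use OLS per outcome with intercept,
standardized evidence strength and log RT, and (in time-course mode)
sample-wise gaze nuisances; correctness is predicted from standardized
pupil responses by logistic regression.

## History model

Design: per trial, signed evidence, an intercept, the previous seven
choices and stimuli (±1, never crossing block boundaries; the first
seven trials of each block are masked), each 7-lag block projected onto
three exponentially decaying basis functions with time constants 1, 3
and 9 lags (columns unit-normalized; the constants are a package choice,
the specific constants being a package
choice within the three-exponential family), plus
pupil×history and RT×history interactions and the modulators' main
effects as nuisances. Modulators (residualized pupil response, log RT)
are z-scored per session. Back-projection kernel = B·w is exact both
ways since B has full column rank.

Fitting is EM over a latent lapse state: E-step computes per-trial lapse
posteriors; M-step updates the lapse rate in closed form and the
logistic weights by Newton-IRLS with step halving on the
posterior-weighted likelihood. The lapse state guesses symmetrically
(probability 0.5 for either response) by default. A freely fitted guess
probability (available via `fit_guess=True`) tends to its 0/1 bound on
finite samples, where it mimics response runs and becomes confounded
with the choice-history weights, inflating them; the symmetric state
removes that confound. Convergence: |Δ log-likelihood| < 1e-6, up to
2000 iterations (the lapse direction converges slowly), 5 restarts;
monotonicity of the log-likelihood is asserted at every iteration.
Permutation significance refits the full model to order-shuffled trials
(1000 by default), warm-started at the intact estimate; bootstrap CIs
resample blocks with replacement (percentile intervals, 68% by default
to match the convention for single-observer error bars; 95% for coverage
experiments).

Strategy space: correct-weights = choice + stimulus kernels,
error-weights = choice − stimulus; observers are repeaters or
alternators by the sign of the lag-1 choice weight, and choice- vs
stimulus-dominated quadrants follow the larger magnitude at lag 1. The
history share of decision-variable variance is var(history terms of the
linear predictor)/var(full predictor) within evidence-strength bins. The
population analysis correlates lag-1 choice weights with their pupil/RT
modulation weights and tests the difference of the two correlations by
the coin-flip swap permutation.

## Group statistics

Permutation tests flip signs (one-sample/paired) or exchange labels
(unpaired), 10,000 draws, two-sided on |mean difference|, with +1
smoothing. Cluster-based permutation uses per-sample two-sided t tests
at α = 0.05 to form same-sign contiguous clusters, summed-t mass, and a
max-mass sign-flip null. The repeated-measures ANOVA is the standard
one-way within-subject decomposition. The JZS Bayes factor for a
correlation integrates the default Jeffreys-Zellner-Siow marginal
likelihood over g by adaptive quadrature and depends only on (n, r);
the ANOVA Bayes factor offers a Monte-Carlo JZS route (g-priors with
scales 0.5 for the effect and 1 for subjects) and a BIC approximation.
No reference implementation for the ANOVA factor exists in this
environment, so only qualitative behaviour (bounds at null and large
effects, reciprocity) is asserted for it.

## Validation scales and what passing shows

The recovery experiments run at 20 observers × 2500 trials (5 sessions ×
10 blocks × 50), full EM fits, 60 bootstrap resamples per observer with
warm starts, and pupil-amplitude recovery pooled over 20 one-block
recordings — the pupil pipeline is strictly block-local, so more blocks
per observer would only repeat the same computation. Generative kernels
lie inside the exponential-basis span (amplitude × e^{−(lag−1)}); a pure
single-lag kernel is not representable by three smooth exponentials and
would conflate basis bias with estimator error.

The synthetic generators reproduce the statistical structure the
analyses assume — transition-balanced sequences, uncertainty-scaled
pupil/RT, IRF-smeared pupil traces with blinks, coherence-graded motion
energy — but not everything about real data: no saccade-related gaze
artifacts beyond jitter, no foreshortening, no slow fatigue or learning
drifts in the psychometric parameters, stationary lapse rates, and a
single fixed IRF across trials and observers. Passing tests therefore
certify the estimators (identifiability, calibration, error control)
under the stated model, not the neuroscientific conclusions themselves
on new empirical data.

Known limitations: the EM lapse estimate is noisy at 2500 trials
(its finite-sample distribution is skewed; kernels remain sign-correct
and CI-calibrated); the JZS ANOVA factor is Monte-Carlo and seeded; RDK
rendering is binary (no anti-aliasing), which adds broadband spatial
noise to motion energy at coarse resolutions.
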