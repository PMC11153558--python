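# Methods

This note documents the models implemented by `whiskpop`, the generative
assumptions behind the synthetic-session generator, the numerical choices
that were genuinely open, and what passing the recovery tests does and does
not establish about real recordings.

## Task and session structure

A session is a sequence of trials, each 4 s long: 1 s baseline, 1 s
simultaneous vibrotactile stimulation of two adjacent whiskers at
frequencies (F1, F2), and a 2 s decision window in which the subject may
lick one of two spouts.  The reward rule is "first lick to the side of the
faster whisker"; on F1 = F2 trials any response counts as correct (rewarded
at chance in the task).  The default stimulus set is the full 5 × 5 grid of
frequencies {0, 22.5, 45, 67.5, 90} Hz without the blank (0, 0) condition,
so that the three sensory regressors of the encoding model are well
conditioned; a 9-level anti-diagonal set (F1 + F2 = 90 Hz) is available for
purely psychometric work.

Choice behaviour follows the lapse-rate logistic

    psi(x) = gamma + (1 - gamma - lambda) / (1 + exp(alpha - x beta)),

with x = F1 − F2 in Hz.  Defaults: gamma = lambda = 0.05, alpha = 0
(unbiased), beta = 0.06 /Hz, which puts accuracy at ~77 % for |dF| = 22.5 Hz
— an expert but imperfect observer.  The last 30 % of trials form a
contiguous disengaged block with no responses, emulating end-of-session
miss blocks.  Engaged trials are categorized as pre-stimulus movement
(24.4 %), impulsive (41.2 %, movement before stimulus offset) or delayed
(the rest), with reaction times drawn lognormally after stimulus offset for
delayed trials.

Optogenetic trial types impose horizontal psychometric shifts: choices on a
W1-column-block trial are drawn from psi(dF − 13.4) (rightward shift) and on
a W2-column-block trial from psi(dF + 26.4) (leftward), with 25 % of trials
optogenetic and the rest labelled sham when the manipulation is enabled.

## Ground-truth encoding weights

Per-neuron sensory weights (betaF1, betaF2, betaF1xF2) are drawn from a
Gaussian copula with a shared heavy-tail scale mixture (10 % of neurons at
3× scale — the "highly responsive" tail).  Correlation targets are
Pearson 0.55 for betaF1–betaF2 and Spearman −0.65 / −0.62 for the two
single-whisker weights against the interaction weight.  Because the class
imposition below perturbs the raw copula correlations, the sampler runs a
deterministic fixed-point calibration (12 iterations on 60 000-neuron
draws, fixed internal seed, cached per parameter set) of the copula inputs
so the *output* table hits the targets; the calibration is part of the
generator, identical for every session generated under one configuration.

Response classes are imposed by drive quantiles.  The session-mean evoked
drive of a neuron is d = betaF1·E[√F1] + betaF2·E[√F2] + betaF1xF2·E[√(F1·F2)]
over the stimulus set.  A common positive shift of the single-whisker weight
means is solved so that cutting the drive distribution at its upper 52.3 %
and lower 32.3 % quantiles leaves symmetric cuts around zero; neurons above
the upper cut are "activated", below the lower cut "suppressed", and the
dead-band neurons ("none", 15.4 %) have their sensory triple scaled by 0.05
so they carry no detectable evoked response.  The cutpoints are frozen at
calibration time on a large reference draw, making the weight distribution
independent of session size and the *expected* class fractions exact.  The
margin between the cuts guarantees essentially full power for the
activated/suppressed test at default noise, so the recovered prevalences
equal the configured ones up to binomial noise.

The interaction-weight scale (SD 0.006 against 0.06 for the single-whisker
weights) is chosen below the point where cov(betaF1xF2, d) changes sign, so
the betaF1xF2-weighted population average of evoked activity is robustly
negative — the generator's expression of net multi-whisker suppression.

Choice weights (betaC1, betaC2; SD 0.35) and the engagement weight
(betaEng; SD 0.15) are independent of the sensory triple and of each other.
Baseline rates beta0 are lognormal with mean 3 and SD 0.8 (arbitrary
rate units per second).

`GeneratorConfig.symmetric()` produces a fully whisker-symmetric variant:
every sampled neuron is mirrored across the whiskers (betaF1 <-> betaF2,
betaC1 <-> betaC2) and the engagement targets of the two single-whisker
pools are set to their mean.  This is the configuration used wherever
"symmetric, balanced pools" are the stated condition.

## Firing rates

Epoch-level mean rates are the primary product.  For every trial,

* baseline mean = beta0 + betaEng·[engaged] + noise,
* stimulus mean = baseline terms + (1 + r·[engaged])·d(F1, F2)
  + choice term·(mean ramp over the epoch) + noise,
* decision mean = baseline terms + choice term·(mean ramp) + noise,

with independent Gaussian noise (SD 0.25) per epoch and trial, and rates
clipped at zero.  The choice term injects only the side-differential
component ±(betaC1 − betaC2)/2 — a side-independent component would be
movement-related activity, which the emulated analyses deliberately
exclude — ramping linearly from stimulus onset to saturation 1.5 s later.
Within-trial bins add the adaptation profile (onset transient ×3.3 of
baseline for 0.25 s, sustained ×1.8, normalized to preserve the epoch
mean) and optional Poisson event discretization.

The engagement gain is a per-neuron modulation *ratio* r: on engaged trials
the stimulus drive is scaled by (1 + r), so the gain lies inside each
neuron's own regression span and cannot leak into other fitted weights.
The vector r is the minimal-norm pattern that satisfies exactly the three
pooled constraints

    sum(w_p d r) / sum(w_p d) = target_p,  target = (+0.22, +0.16, -0.07)

for the Rw1, Rw2 (whisker-preference pools) and Rw1xw2 (betaF1xF2 over all
neurons) signals.  The solution lies in the span of the drive-weighted pool
weights, so realized gains grow with a neuron's single-whisker weights and
anti-relate to its interaction weight; r is clipped to ±0.8 with re-solve
passes on the unclipped part (clipping affects <1 % of neurons at
defaults).  A simple linear-in-weights rule cannot reach all three targets
with bounded coefficients because the interaction weight is a vanishing
lever on the two whisker pools.

Optionally, shared (correlated) trial-to-trial variability can be added: a
common component plus a differential component loaded by whisker
selectivity.  It is **off by default**: with it on, pooled decoding
accuracy becomes realistic (~93 % AUC instead of near-perfect), but the
coherent component contaminates fitted weights enough to push the
recovered correlation structure outside its tolerance.  The default
conditions favour exact parameter recovery; this is the main respect in
which passing tests do not speak to real data (see Limitations).

## Fluorescence and markers

ROI fluorescence is synthesized as
`F = amp·(kernel * events) + alpha·Fp + drift + noise`, with a
single-exponential calcium kernel (tau = 0.5 s), per-neuron contamination
alpha drawn uniformly from [0.55, 0.80], and a shared smooth positive
neuropil trace Fp (baseline 100 a.u.) carrying stimulus-locked structure.
A separate sparse-transient synthesizer (Poisson events at 0.2 Hz, ~8 a.u.
transients over 1.5 a.u. noise) provides the low-activity regime in which
the neuropil-factor estimator is validated; dense default sessions serve the
deconvolution round trip instead.

Marker streams emulate tracked facial features: the nose trace steps at
each trial's reaction time (detectable as a >0.1 Z jump after the session
5 %-convention Z-scoring), tongue likelihood exceeds its baseline
mean + 3 SD threshold only during lick events sided relative to the teeth
position, pupil baseline is dilated on disengaged trials, and the neuropil
master trace carries a 5 Hz oscillation that doubles in amplitude on miss
trials.

## Analysis conventions

* **Encoding fits.**  One design per session; responses are per-neuron
  z-scored concatenated baseline + stimulus 1-s means with sensory
  regressors zero at baseline; all columns z-scored; every neuron solved in
  one QR-based multi-RHS least squares.  The choice variant uses stimulus
  rows of delayed/no-response trials only (choice regressors are undefined
  at baseline); the engagement variant keeps both epochs of those trials.
  Besides z-scored weights, fits report native-scale weights
  (`*_raw`, rate per unit regressor), which are the pooling weights.
* **Pooling.**  Pools by strict preference between the two defining raw
  weights (ties excluded); the interaction pool spans all neurons weighted
  by betaF1xF2 (the interaction signal has no rival alternative; a
  dominance-restricted variant is provided).  Pooled signals are weighted
  means normalized by the summed absolute weights, computed on raw
  epoch-mean rates.
* **Threshold decoding.**  Youden-optimal threshold over midpoints between
  observed values; candidates within one reclassified trial per class of
  the maximum are treated as ties and the centre of the tying range is
  returned, keeping the estimate symmetric on flat maxima.  Per-session
  thresholds are heavy-tailed (occasional wide-gap sessions), so
  session-ensemble summaries use the median.
* **Choice geometry.**  The choice-variant model supplies both the sensory
  and the choice weights; weights are split-half cross-fitted (each half's
  trial coordinates use the other half's weights) because same-trial
  fitting tilts the transition angle systematically below 90°.  The
  sensory dimension (Rw1 − Rw2) is evaluated on stimulus-epoch activity and
  the choice dimension (Rc1 − Rc2) on decision-epoch activity — each where
  its signal is expressed.  Within a target side, group means are computed
  after equalizing choice-1/choice-2 counts per stimulus condition; axes
  are z-scored before the angle (a no-standardization mode exists), and
  angles are folded to [0°, 180°).
* **Engagement modulation.**  Pooling weights are fitted on the disengaged
  (gain-free) trials; fitting on gain-bearing trials folds the gain
  heterogeneity into the weights and inflates the measured pooled ratios.
  Modulation is 100·(engaged/disengaged − 1) of the evoked
  (stimulus − baseline) pooled signal over stimulus-matched trials.
* **Choice probability.**  Per-neuron AUROC with classes balanced by
  subsampling; values < 0.5 indicate higher firing on F1 > F2 / choice-1
  trials.  Significance by label permutation (default) or bootstrap CI95.
* **Response classification.**  Two-sided paired t-test of per-trial
  stimulus vs baseline means at alpha = 0.05 (configurable).

## Problem sizes used by the acceptance script

All ensembles are generated at run time from the supplied seed: transition
angles from 100 sessions of 150 neurons × 800 trials per target side; the
decoding threshold from 11 whisker-symmetric sessions of 300 neurons ×
4 000 trials (median across sessions); response prevalences and engagement
modulation from 11 default sessions of 300 neurons × 500 trials; the fitted
weight correlation from 11 sessions of 300 neurons × 800 trials (3 300
neurons pooled); the optogenetic shifts from 12 replicate simulations of
4 000 trials each per condition (the per-simulation midpoint-difference SD
is ~4 Hz, so replicates are averaged).

## Limitations

* Default sessions are far cleaner than real recordings: single-neuron
  explained variance is several times the values typical of cortical data,
  and trial-to-trial variability is independent across neurons.  Recovery
  of weights, correlations and pooled modulations under these defaults
  demonstrates correctness of the estimators, not their robustness to
  realistic noise; the `shared_noise_*` options exist to explore the
  harder regime.
* The generator produces epoch-level rate structure plus a separable
  within-trial profile; it contains no spike-timing (temporal-code)
  structure, no whisker kinematics and no pixel-level video.
* The engagement gain, choice dynamics and marker models reproduce the
  qualitative patterns they emulate (sign structure, timing, detectability)
  through explicitly chosen generative rules, not fitted mechanisms.
* ΔF/F0 preprocessing assumes upward transients on a neuropil-dominated
  baseline; the no-intercept neuropil regression is biased when an ROI has
  a large activity-independent fluorescence pedestal (kept small in the
  synthesizer).
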