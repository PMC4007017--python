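# Methods

This note records the models, numerical choices, and design decisions
behind `bimocon`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Task timing

A run is 17 alternating 20 s blocks — nine rest, eight task, rest first —
for 340 s total. Task blocks carry a coupling mode (default alternating
in-phase / anti-phase, four each) and a pacing frequency f ∈ {1.0, 1.5,
2.0} Hz. A *cycle* is one alternation of the pacing picture pair; cue
onsets sit at k/f from block onset, so a 20 s block holds 20·f cues. At
TR = 3 s the default acquisition is 113 volumes (339 s): the trailing
partial volume is not acquired, and the schedule validates
`n_volumes · TR ≤ duration + TR`.

## Behavioral generator and scorer

Each cue demands one press per hand. In-phase cues pair the same finger on
both hands; anti-phase cues pair opposite fingers, alternating with cue
parity. The generator's error structure has four dials, all per
`BehaviorProfile`:

* `timing_sd_s` (default 0.05 s) — Gaussian jitter per press;
* `swap_prob` — probability a cycle *phase-slips*: the left hand mirrors
  the right, turning an anti-phase pattern into the in-phase one and vice
  versa. In the noiseless limit expected accuracy is exactly
  1 − swap_prob, which anchors the scorer calibration tests;
* `miss_prob` (0.02) — a cued press is omitted;
* `extra_prob` (0.01) — a spurious press lands uniformly within the cycle.

The scorer implements the paired-finger latency rule: a press is correct
when its time difference to the opposite hand's *paired* finger (same
finger in-phase, different finger anti-phase) is smaller than to the
unpaired one. The rule alone does not say how presses are matched, so
three artifact-level choices close the gap:

* matching is nearest-in-time per opposite-hand finger label within a
  window of half the cue period (`config_for_pacing`); a finger with no
  press in the window counts as infinitely far;
* exact ties count incorrect (conservative; ties are measure-zero in real
  latencies) — `tie_policy="exclude"` is available;
* presses with no counterpart in the window count incorrect (a press
  without a partner is not a correct bimanual movement) —
  `unmatched_policy="exclude"` is available.

Each press is classified independently; no cycle segmentation is imposed.
The accuracy denominator includes spurious extra presses (the alternative
— excluding presses — is reachable via the exclude policies).

Frequency selection maximizes the (reference group − other group) mean
anti-phase accuracy difference among frequencies where the reference
group's mean anti-phase accuracy stays ≥ 0.8 (configurable floor), with
ties broken toward the lower frequency — i.e. the fastest pace the
reference group still manages. If no frequency clears the floor, all are
eligible and a warning is issued.

The default per-condition accuracy targets give the young group high
accuracy everywhere except anti-phase at 2.0 Hz, and the elderly group
collapsed anti-phase accuracy throughout (0.34–0.45). With those targets
the 1.0 Hz and 1.5 Hz divergences differ by under two percentage points,
so at 20 subjects per group the realized selection can fall on either
frequency depending on the seed; the pipeline invariant is that the
reported selection always equals `select_frequency` applied to the
report's own accuracy table.

## BOLD simulation and GLM

The canonical HRF is the double-gamma form — positive lobe with delay
parameter 6 s (mode near 5 s), undershoot with delay 16 s at 1/6 relative
amplitude, unit dispersion — normalized to unit peak. Task regressors are
mode boxcars convolved with the HRF on a 10× oversampled grid, sampled at
the volume times, and rescaled by the HRF integral so a long block
plateaus at 1: a simulated amplitude of a yields a sustained response of
height a, and the GLM beta is directly in amplitude units. The design adds
the regressors' finite-difference temporal derivatives, an intercept, and
Legendre-style polynomial drift up to order 1 (an SPM-style cosine basis
is not replicated).

Fitting is ordinary least squares per ROI; the per-subject "parameter
estimate" forwarded to the connectivity stage is the task-vs-rest contrast
on the HRF column only — the derivative column absorbs onset-latency
mismatch but is excluded from the contrast (a switch
`include_derivative=True` exists). Simulated noise is stationary AR(1)
with marginal sd `noise_sd` (default 0.1) and lag-1 correlation ρ = 0.2.
No prewhitening is applied, so OLS standard errors are only calibrated
when ρ = 0; the calibration tests (null-contrast z values, 95% CI coverage
in 93–97% over 200 subjects × 10 ROIs) therefore run with white noise,
and under the default ρ = 0.2 the standard errors are mildly optimistic —
a known limitation shared with unwhitened OLS on real BOLD data.

## Path analysis (SEM)

Observations are modeled as x = A x + ζ, ζ ~ N(0, Ψ), Ψ diagonal by
default (free disturbance covariances can be declared but none are used by
the bundled models), giving Σ(θ) = (I−A)⁻¹ Ψ (I−A)⁻ᵀ. The ML discrepancy
F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimized over path coefficients and
log disturbance variances with L-BFGS-B and the analytic gradient
(∂F/∂A = 2(I−A)⁻ᵀ G Σ, ∂F/∂Ψ = diag((I−A)⁻ᵀ G (I−A)⁻¹),
G = Σ⁻¹ − Σ⁻¹SΣ⁻¹). Conventions and numerical choices:

* sample covariance uses denominator N−1 and χ² = (N−1)·F_min;
* starting values are per-equation OLS regressions on S (residual
  variances from the same regressions), falling back to A = 0,
  Ψ = diag(S);
* convergence: optimizer success or projected-gradient ∞-norm < 1e-6
  (ftol 1e-13), max 500 iterations; non-convergence yields a *flagged*
  fit, never a silent one;
* disturbance variances are bounded to [1e-4, 10] × the observed variance.
  Without the bound, weakly identified blocks (notably reciprocal path
  pairs at small N) drift onto improper ridges with exploding variances
  (Heywood-type solutions). At a bound the affected variance's standard
  error is reported as NaN;
* standard errors come from the observed information, (N−1)/2 × the
  Hessian of F at the solution (central finite differences of the analytic
  gradient, original parameter scale). A rank-deficient information matrix
  raises an "empirically unidentified" error naming the null-space
  parameters — unless the flat directions are confined to bound-active
  variances, in which case the covariance is pseudo-inverted;
* reciprocal (nonrecursive) pairs are permitted; stability is checked via
  the spectral radius of A at the solution and warned about when ≥ 1;
* with fewer than 2t observations the fit carries an explicit low-N
  reliability warning rather than being refused (the 10-ROI models have
  t = 36 at the design's N = 20 per group);
* fit battery: GFI = 1 − tr[(Σ̂⁻¹S−I)²]/tr[(Σ̂⁻¹S)²]; CFI against the
  independence baseline (free variances, zero covariances — closed form
  F_B = Σln S_ii − ln|S|); RMSEA = √(max(χ²−df,0)/(df(N−1))), undefined at
  df = 0; AIC = χ² + 2t and BIC = χ² + t·ln N. The χ²-based AIC/BIC
  convention differs from the likelihood-based one by a constant shared
  across models on the same moments, so only differences are meaningful
  (a test verifies the sign agreement against directly computed Gaussian
  log-likelihoods).

Standardized coefficients are β_ij = â_ij σ̂_j/σ̂_i with σ̂ from the
fitted Σ diagonal; they are invariant to rescaling of the observations
(verified by refitting on correlation-scaled data). Path significance uses
two-sided normal p-values of estimate/se, tiered at p < 0.001, p < 0.01,
and ns (p ≥ 0.01 — the boundary itself is ns). Cross-condition comparison
reports tiers only and flags paths strong in one condition but
non-significant or absent in another; raw coefficients are never compared
across topologies.

The specification search is a greedy hill-climb over single-edge
additions, deletions, and reversals (self-loops excluded; the addition
neighborhood can be restricted via `candidate_edges`). Candidates are
warm-started from the incumbent's estimates and fitted without standard
errors; the move minimizing AIC (BIC selectable) is accepted, with ties
broken toward fewer free parameters, then lexicographic edge order. The
search halts when the incumbent meets the conventional battery
(χ² p > 0.05, GFI > 0.95, CFI > 0.95, RMSEA < 0.05) or no move improves
the criterion; the full evaluated-move trace is returned.

## Bundled ground-truth models

Four synthetic 10-ROI path models (young/elderly × in-phase/anti-phase)
each carry 26 directed paths, so t = 36 and df = 19. Strong paths
(coefficients 0.4–0.5 against weak 0.1, disturbance variances 0.5) encode
the qualitative group/mode contrasts the comparison stage is designed to
detect: a reciprocal bilateral-PMd pair and a strong left-PMd → right-SPL
path (anti-phase) in the young models, left-hemisphere drive routed
PMd → M1 → S1 and a reciprocal bilateral-M1 pair (anti-phase) in the
elderly models. The coefficients are fixture choices for testability, not
estimates from any dataset.

## What the tests show — problem sizes

* Parameter recovery: 100 replicates at n = 5000 from the young in-phase
  model — mean absolute path bias < 0.02, 95% CI coverage within
  [92%, 98%].
* χ² calibration: 1000 replicates at n = 500 fitting the generating model
  — mean χ² within 5% of df = 19.
* Search: a deleted strong path is restored exactly in ≥ 18/20 runs at
  n = 5000.
* Scorer: noiseless accuracy 1.0; accuracy within 3 binomial SE of
  1 − swap_prob over 1000 cycles; mode duality under within-hand finger
  relabeling holds press-for-press.
* GLM: noiseless recovery to 1e-8; CI coverage 93–97% over 200 subjects.

These sizes were chosen so the full suite runs in well under a minute per
heavy check on a single CPU while keeping Monte-Carlo error far below the
asserted tolerances.

Passing them shows the estimator, indices, search, and scorer are
internally correct and calibrated under the generator's assumptions —
Gaussian disturbances, linear paths, stationary noise, no measurement
confounds. They do not show that real BOLD data satisfy those assumptions,
and real-data idiosyncrasies (autocorrelation beyond AR(1), motion,
physiological noise, ROI mislocalization) are explicitly out of scope.

## Known limitations

* At the design's own sample size (N = 20 per group, p = 10, t = 36) the
  covariance-structure fit is heavily under-determined: estimates carry
  the low-N warning, and GFI rarely exceeds ~0.9 on synthetic data even
  for the generating topology or after a full specification search — GFI
  degrades with small N and many variables. The pipeline reports the
  criteria flags honestly rather than forcing them.
* OLS without prewhitening under AR(1) noise yields mildly optimistic
  standard errors (see above).
* Group inferential statistics (repeated-measures ANOVA, post-hocs) are
  deliberately not reimplemented; the pipeline reports descriptive means
  with t-based 95% CIs and leaves inference to standard packages.
* Latent-variable measurement models, Bayesian estimation, and multi-group
  simultaneous estimation with equality constraints are out of scope; the
  SEM observations are one beta per subject per mode (the generator can
  also pool runs by concatenating draws).
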