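# Methods

This note documents the models, the generative conditions the synthetic
cohorts use, the numerical choices, and the limits of what the simulations
can show. Nothing here reports a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Task model

A run is an induction phase (default 36 trials at the very-high action
duration, 1880 ms) followed by a testing phase (default 108 trials split
evenly over the three shortened durations 1480/1560/1640 ms), with control
trials interleaved at random positions. Evidence levels are coded ordinally
1–4 in every analysis; milliseconds appear only in the event tables.

The 66/33 prior bias is realised as an exact integer allocation —
round(bias·n) likely trials per phase × evidence-level cell — rather than
Bernoulli sampling, so all simulated subjects see identical cell counts.
The induction phase is what installs the prior, so the same 2:1 allocation
is applied there (24/12 of 36). The number of interleaved control trials is
a free parameter (default 12 per run). Event timings are uniformly jittered
(fixation 0.5–2.5 s, preparation 1.0–1.5 s, delay 0.5–1.0 s, response
window 1.5 s) and rounded to the millisecond, which makes exported event
tables byte-identical across reruns of a seed.

In the social variant the first actor's move is fair-coin, and "likely"
means the second actor mirrors it (tit-for-tat); the mirroring bias uses
the same 2:1 integer allocation. A separate `generate_tft_sequence`
provides the Bernoulli version of the bias where independence across trials
matters. Analyses of one task condition may pool induction and testing
trials: the 4-level evidence factor needs the very-high level, which only
the induction phase contains.

## Observer

The observer keeps, per intention, an exponentially lag-weighted event
count, `w_i = Σ_p α^(-p)·1[lag p event = i]` (lag 1 = most recent), and
converts counts to probabilities with one pseudo-count per intention:
`prob_i = (w_i + s)/Σ_j (w_j + s)`, s = 1 by default. This normalization —
one smoothing constant per intention in the denominator — is required for
rows to sum to one; with a single shared constant in the denominator the
"probabilities" would not normalise. The update is incremental (each new
event divides all weights by α and enters at weight 1/α), so a trace over n
trials costs O(n·k).

α ≥ 1 with α = 1 the ideal observer: the trace then reduces exactly to
Laplace-smoothed relative frequency. The prior regressor for trial t is the
observer's probability of the intention actually enacted on trial t,
computed from trials 1..t−1. Probabilities reset to flat at each task
boundary and are carried across runs (configurable). In the social task the
counts are conditioned on the first actor's move: a separate history per
context, with the trial's row read from its own context.

One property worth stating precisely: discounting does **not** uniformly
favour the most recent intention. The relative weight of the lag-1 event
against strictly older events is non-decreasing in α, but with additional
old same-intention events the weight ratio can be non-monotone, and because
smoothing is constant while all weighted counts shrink as α grows, α → ∞
drives every prior back to flat ("forgetting everything"). The property
tests assert the provable sub-case and the flat-prior limit, not the naive
monotonicity claim.

Decay estimation scans α on [1, 3] in steps of 0.05; each candidate's prior
trace feeds the logistic choice model and is scored by the sum of squared
residuals between correct responses and fitted probabilities (a Brier
score, matching the least-squares criterion on correct responses); the best
grid point is refined by golden-section search to 1e-3. Ties break toward
smaller α. A single shared α is the default; a per-intention α vector is
supported but off by default.

## Choice model and group summaries

`fit_choice_model` z-scores prior and evidence, forms the interaction as
the product of the standardized terms, and fits the Bernoulli logistic
model by plain maximum likelihood (IRLS). Separation — including constant
responses and diverging coefficients (|β| > 15) — triggers a flagged refit
with a small ridge penalty (1e-4, intercept unpenalized); flagged
coefficients should not be interpreted.

The prior effect is %CR(likely) − %CR(unlikely) per evidence level:
positive when the induced prior helps, with empty cells flagged rather than
imputed. The two-factor repeated-measures ANOVA uses the classical
univariate decomposition, each effect tested against its own
effect-by-subject interaction, with η²p = SS_effect/(SS_effect+SS_error);
sums of squares below a cancellation floor (1e-12 of the total variation)
are treated as exact zeros so constant tables report F = 0. No sphericity
correction and no multiple-testing correction are applied; post-hoc
comparisons are uncorrected paired t-tests (Fisher-LSD style). `correlate`
is a plain Pearson r with the two-sided t-test.

## GLM

The canonical HRF is the double-gamma difference (peak gamma: delay 6 s,
dispersion 1 s; undershoot: delay 16 s, dispersion 1 s, ratio 1/6),
sampled on a 0.1 s microtime grid over 32 s and peak-normalized; its mode
falls near 5 s. Regressors are built at microtime as amplitude-weighted
boxcars (the motor regressor as a one-bin stick), convolved, and sampled at
the volume times.

Per condition the columns are: preparation boxcar, inference boxcar
(movement onset to response-screen onset), control boxcar, motor stick,
plus prior on preparation and evidence/prior/interaction on inference —
16 task regressors for a two-condition session. Modulator amplitudes are
mean-centered per condition before convolution; the three inference
modulators are then serially orthogonalized *as sampled columns*, each
residualized against the constant, its categorical parent and its earlier
siblings in the fixed order evidence → prior → interaction. Orthogonalizing
the sampled columns (rather than the per-trial amplitude vectors) makes the
sibling orthogonality exact in the design matrix, which is the property the
attribution argument rests on: shared variance is credited to the earlier
regressor, so the interaction column carries only its unique signal. The
order of residualization is recorded in the design-matrix object.

Drift is handled by DCT high-pass columns at a 128 s cutoff; motion and
scan-series covariates enter as an arbitrary nuisance matrix (a helper
provides the second-degree polynomial expansion of motion parameters).
Fitting is OLS with closed-form contrast t statistics; a single
Cochrane–Orcutt pass (optional, default off in `fit_glm`) estimates the
lag-1 residual autocorrelation and refits on quasi-differenced data. Rank
deficiency falls back to the minimum-norm solution with a warning.

## PPI

The seed series is deconvolved to the microtime grid by ridge-regularized
least squares: x̂ = K'(KK' + λI)⁻¹y, where K is the HRF convolution
operator — algebraically identical to the primal ridge solution but solved
at volume size; the operator and its Cholesky factor are cached per
(length, TR, kernel, λ). Default λ = 1e-2. The deconvolved series is
multiplied by the signed psychological contrast (+1/−1 on the inference
events of the two conditions, 0 elsewhere) and reconvolved.
`estimate_ppi` then regresses the target on [constant, seed, convolved
psychological term, PPI term]: with ±1 coding the condition slopes are
b_seed ± b_ppi and the slope difference (2·b_ppi) is the PPI. The
regression prewhitens by default: under AR(1) noise with ρ = 0.3 plain OLS
inflated the nominal 5% PPI test to ≈8% in calibration runs, and the
Cochrane–Orcutt correction restores ≈5% (the acceptance suite recomputes
this).

Two caveats the simulations make visible. First, deconvolution is
ill-posed: noise in the seed propagates into the PPI regressor and
attenuates the interaction estimate, so seed quality matters — the
end-to-end tests therefore extract the seed as the first principal
component of a simulated 20-voxel ROI (mirroring sphere-based seed
extraction) rather than a single noisy series. Second, with shared
task-locked inputs to both regions a misspecified PPI regression can show a
nonzero slope difference even without modulatory coupling; the exact-null
test uses a target strictly linear in the seed, and the calibration test a
seed-plus-noise target, where the null is well-defined.

## DCM

Neural dynamics are bilinear over three regions (preparatory area, mPFC,
TPJ): dz/dt = (A + Σ u_j B_j)z + Cu, integrated by fixed-step RK4 at
dt = 0.1 s with inputs piecewise-constant per step (the integration loop is
JIT-compiled with numba; a pure-NumPy path is kept and tested for
equality). A must be stable (negative real parts); divergence raises a
named error. Region BOLD is the HRF-convolved state sampled at the TR.
"Forward" follows the inference hierarchy upward (TPJ → mPFC,
prep → mPFC); "backward" is the top-down mPFC → TPJ direction.

The model space is 5 nested anatomical families — from full bilateral
connectivity (including prep↔TPJ) down to a lone prep→mPFC forward
connection — crossed with 8 modulatory configurations: {modulated mPFC–TPJ
connection: forward, backward} × {modulator set: INT; PE; INT+PE;
INT+PE+PE×INT}, with INT always gating prep→mPFC. B entries are masked by
the family's A, so families lacking the target connection lose that
modulation (their models coincide structurally; evidence then differs only
through the parameter count, which is computed from the effective masks).
Both tables are plain data and can be replaced wholesale.

Estimation is deliberately desk-scale: free parameters are the masked
off-diagonal A entries, masked B entries and masked C entries, with
self-connections fixed at −1 Hz; Levenberg–Marquardt least squares on the
HRF-convolved prediction, and log evidence approximated as −BIC/2 with
Gaussian residuals. This replaces variational free energy with a
hemodynamic forward model — adequate for model *ranking* on simulated ROI
series, not a reimplementation of full DCM estimation. Random-effects BMS
follows the standard variational Dirichlet scheme (uniform prior counts,
softmax responsibilities, concentration updates to 1e-8), with exceedance
probabilities by Dirichlet Monte-Carlo sampling (default 1e5 draws, seeded)
and family evidences aggregated as log-sum-exp minus log family size
(uniform within-family prior).

## Generative conditions (what the passing tests do and do not show)

Synthetic subjects default to α = 1.5, β = (0, 1, 1, −0.5) on the
standardized scale and no lapse: strong prior and evidence effects with a
negative interaction, the direction the tasks are built to elicit. BOLD
noise is AR(1) (innovation sd scaled so the stationary sd hits the target
SNR, ρ = 0.3) plus a slow cosine drift absorbed by the 128 s high-pass; an
18-subject cohort at these settings shows the prior effect largest at the
lowest evidence level with a significant prior-by-evidence interaction.

The connectivity study (`synthetic.coupling_study`) freezes one generative
setup: intrinsic couplings A = 0.2–0.4 Hz off-diagonal with −1 Hz
self-decay (family-2 structure), every modulated mPFC→TPJ strength 1.0 Hz,
the INT gate on prep→mPFC 0.3 Hz, driving inputs at prep (preparation
events) and TPJ (inference events), trials every 7 s, conditions
alternating in 25 s blocks, PE uniform in [−1, 1] on inference events.
PPI recovery is checked at SNR 1 with a 20-voxel PC-extracted seed over 285
volumes; model identification at SNR 4 over 120 volumes (ROI-averaged
series warrant higher SNR than single voxels, and BIC evidence is coarser
than free energy) with 20 replicates — problem sizes chosen to keep a full
40-model × cohort sweep on one core in minutes.

What passing these checks shows: the estimators recover the direction and
rough magnitude of effects they were built for, at realistic trial counts,
under the noise model stated above. What they do not show: robustness to
physiological noise, motion, hemodynamic variability across regions
(a single canonical HRF generates and analyses the data), model
misspecification beyond the enumerated space, or anything about real
participants — the simulations share the analysis's assumptions by
construction.

## Known limitations

- The BIC evidence ignores parameter covariances and hemodynamic states;
  absolute evidences are not comparable to SPM-DCM free energies.
- PPI deconvolution uses a fixed ridge rather than empirical-Bayes
  regularisation; λ trades attenuation against noise amplification and is
  exposed as a parameter.
- The observer assumes a binary intention alphabet per task (k-ary traces
  work, but all study designs here are two-alternative).
- `simulate_subject` standardizes predictors within session, so generative
  β are comparable across subjects only under equal designs (which the
  integer allocation guarantees).
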