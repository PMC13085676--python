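# Methods

## Model

A counterfactual population is specified per (stratum m, arm a) cell by its
mass Pr(A=a, M=m) and a distribution over the four response types — the
joint values of the potential outcomes (Y⁰, Y¹): doomed (1,1), helped
(1,0), hurt (0,1), immune (0,0). This is the minimal parameterization that
determines every quantity the package computes: factual risks follow by
consistency (Y = Y^a in arm a), counterfactual risks are margins of the
response-type distribution, and the joint probabilities Pr(Y=1, Y^a=1)
needed by the proportion measures are read off the types directly. All
probabilities are exact finite sums over at most 2·(number of strata)
cells; nothing is estimated or approximated at the population level.

Measures implemented, all with denominator Pr(Y=1):

| measure  | numerator              | range      |
|----------|------------------------|------------|
| PF_total | Pr(Y=1) − Pr(Y¹=1)     | (−∞, 1]    |
| AF_total | Pr(Y=1) − Pr(Y⁰=1)     | (−∞, 1]    |
| PP_total | Pr(Y=1) − Pr(Y=1,Y¹=1) | [0, 1]     |
| AP_total | Pr(Y=1) − Pr(Y=1,Y⁰=1) | [0, 1]     |

PF ≤ PP and AF ≤ AP always: the caseload numerator equals
Pr(Y=1, Y¹=0) − Pr(Y=0, Y¹=1), the proportion numerator minus the cases
*created* by intervention; equality holds exactly when the relevant arm
carries no "hurt" type.

Stratum measures condition every probability on M=m; the decomposition
identity PF_total = Σ_m PF_m Pr(M=m|Y=1) (and its AF/PP/AP analogues) is
verified numerically on every call path rather than assumed — `decompose`
returns the residual between the weighted sum and the directly computed
total. Stratum measures are computed in two algebraically equivalent forms
(definitional, via conditional risks given M=m, and a Bayes-rule form
accumulated from the relevant arm's cell only); the implementation raises
if they split by more than 1e-12, a transcription-error guard.

Strata with zero cases have weight 0 and are excluded from the weighted
sum; requesting their stratum measure alone is an error (the denominator
Pr(Y=1, M=m) is zero).

## Identification and estimation

The plug-in estimator fills an empirical population from records (m, a, y):
cell masses and factual risks are empirical frequencies; each cell's
counterfactual margin is imputed under a declared assumption:

- `conditional_exchangeability` (default): Pr(Y¹=1|A=0,M=m) ←
  Pr̂(Y=1|A=1,M=m) — standardization over M. Requires positivity: both
  arms observed in every stratum (violations raise an error naming the
  empty cell).
- `marginal_exchangeability`: the imputation ignores M; appropriate when
  randomization is marginal, though the conditional version remains the
  default because stratum-level reporting conditions on M anyway.
- `oracle_potential_outcomes`: synthetic data carry y0/y1 columns and the
  response types are tabulated directly. This is the only route to PP/AP
  from data, unless monotonicity (no "hurt" type) is declared, under which
  PP ≡ PF and AP ≡ AF and the factual-data estimates are reported.

Inference is a nonparametric percentile bootstrap (default 1000
replicates, explicit seed mandatory), resampling individuals with
replacement — implemented as a multinomial redraw over the distinct
(stratum, arm, outcome) record types, which is distributionally identical
and vectorizes over replicates. Replicates that empty a required cell are
redrawn up to 100 times, then dropped with a warning, keeping intervals
well-defined for small strata without contaminating them with undefined
values. Stored estimates are never rounded; rounding happens only in
reports. Finite-sample inference is an engineering layer of this package:
the population theory is exact and carries no sampling notion.

## Simulator

`sample_population` draws each individual's cell from the masses and a
response type within the cell, then sets y by consistency — the sampler
emulates a marginally randomized trial with stratified recruitment when
given such a scenario. It uses the counter-based Philox generator with a
fixed number of uniforms per row in row order, so row i is independent of
the total n (prefix stability under the same seed). `proportional_sample`
allocates (cell, type) classes exactly and is the no-noise path used to
check that plug-in estimation reproduces population values to machine
precision; infeasible sizes report the smallest feasible n.

`random_spec` generates property-sweep populations with optional
constraints (exchangeability within strata, monotonicity, null effect,
marginal randomization). Cell masses are bounded below by 0.01 and factual
risks kept in [0.02, 0.98] so sweeps do not trip over positivity by
construction. What the simulator does **not** emulate: enrolment dynamics,
dropout, measurement error, confounding, continuous modifiers. Passing
tests therefore demonstrate correctness of the arithmetic and estimator
under clean randomized-trial data, not robustness to those real-data
features.

## The packaged scenario

The fixture encodes a six-cell marginally randomized preventive-treatment
trial (stratum/arm masses 0.25/0.25/0.15/0.15/0.10/0.10, factual risks
0.50/0.30/0.30/0.20/0.16/0.12, set-to-treated risks
0.30/0.30/0.20/0.20/0.12/0.12). Two completions are recorded in its
metadata rather than silently assumed: the untreated potential outcome in
the treated arm is pinned to the stratum's arm-0 factual risk
(exchangeability within M, which marginal randomization implies), and the
within-cell joint of (Y⁰, Y¹) is completed from its margins by the
monotone (Fréchet upper-bound, "no one harmed") coupling,
Pr(doomed) = min(r₀, r₁). All caseload quantities depend only on the
margins and are invisible to the coupling choice; the proportion measures
do depend on it, which is why the estimator refuses PP/AP without either
oracle potential outcomes or an explicit monotonicity declaration.

## Classical formulas

Miettinen's AF = Pr(A=1|Y=1)(RR−1)/RR and Levin's AF = p(RR−1)/(1+p(RR−1))
(p = Pr(A=1), RR the crude risk ratio) are computed from observable
margins only. Partial exchangeability under no exposure (Y⁰ ⊥ A) is
necessary and sufficient for them to equal the causal AF; the flag is
evaluated structurally on the counterfactual population (comparing
Pr(Y⁰=1|A=1) with Pr(Y⁰=1|A=0) at 1e-12), since the condition is
untestable from factual data. Built from the same crude quantities the two
formulas are algebraically identical; implementing both from their
separate textbook forms and asserting agreement guards against
transcription error.

## Numerical choices

- Probability-sum validation at 1e-12; equivalent-form agreement at 1e-12;
  decomposition residuals and oracle (census) agreement at 1e-9 —
  comfortably above double-precision accumulation noise for the ≤ 10³
  strata this package targets.
- Zero-probability conditioning events and zero-case denominators raise
  typed errors instead of returning NaN; silent NaN propagation hides
  scenario mistakes.
- Stratum labels are opaque ordered strings; a multi-covariate modifier is
  encoded as a composite label.
- Test problem sizes: identity sweeps use 200 random populations; census
  comparisons enumerate 10⁶ individuals on 20 rational-mass populations
  (masses and type probabilities snapped to a 1/1000 grid so the
  allocation is exact); estimator calibration uses one n = 200 000 draw
  and 500 coverage replicates of n = 2 000 with 500 bootstrap replicates
  each. These sizes make every check exact or tightly bounded while the
  full suite runs in seconds.

## Known limitations

- Binary exposure and outcome only; no time-to-event structure.
- No confounding adjustment (no IP weighting or outcome modelling): the
  estimators presume the declared exchangeability assumption holds.
- PP/AP identification relies on monotonicity or oracle potential
  outcomes; no partial-identification bounds are provided.
- Bootstrap intervals are percentile-based; no studentized or BCa variants.
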