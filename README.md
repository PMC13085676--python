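# prevfrac

Preventable and attributable fractions under effect modification, in the
potential-outcomes framework.

## The problem

Public-health impact measures contrast the factual caseload of a population
with a counterfactual one. For a binary exposure A and binary outcome Y,
with Y^a the potential outcome had A been set to a:

- **Preventable fraction** (protective exposure):
  PF_total = (Pr(Y=1) − Pr(Y¹=1)) / Pr(Y=1) — the relative reduction in
  cases had everyone been treated.
- **Attributable fraction** (harmful exposure):
  AF_total = (Pr(Y=1) − Pr(Y⁰=1)) / Pr(Y=1) — the relative reduction had
  the exposure been absent. Reversing the exposure coding turns one measure
  into the other.
- **Preventable / attributable proportions** PP_total, AP_total replace the
  counterfactual caseload by Pr(Y=1, Y¹=1) (resp. Y⁰), counting only
  factual cases removed; they lie in [0, 1], whereas the caseload fractions
  can be negative.

When a covariate M modifies the causal risk difference, the total-population
measure is a weighted average of stratum-specific ones,

    PF_total = Σ_m PF_m · Pr(M=m | Y=1),

with **case-frequency weights** Pr(M=m | Y=1) — the share of *cases* in each
stratum, not the population share Pr(M=m). High-risk strata therefore
dominate the total even when they are small, which matters for how a single
headline fraction should be read and for where an intervention pays off.

`prevfrac` makes all of this computable: exact measures on a fully specified
counterfactual population (per-cell response types doomed / helped / hurt /
immune), the stratum decomposition with its weights, plug-in estimation from
trial records with bootstrap intervals, a trial simulator, and the classical
Miettinen and Levin attributable-fraction formulas together with the partial
exchangeability condition (Y⁰ ⊥ A) under which they are exact. It is aimed
at epidemiologists and biostatisticians studying population intervention
effects.

## Worked example

The packaged scenario is a marginally randomized trial of a preventive
treatment in which enrolment depended on a three-level effect modifier M
(worse-prognosis strata recruited preferentially), and the risk difference
varies across M:

```python
import prevfrac as pf

spec = pf.table1()
print(pf.report_table(spec, "pf", round_to=2))
```

```
m   a   pr_a_m  risk_factual  risk_set1  pr_y1_given_m  pf_m  weight  pf_total
0   0   0.25    0.50          0.30       0.40           0.25  0.66
0   1   0.25    0.30          0.30
1   0   0.15    0.30          0.20       0.25           0.20  0.25
1   1   0.15    0.20          0.20
2   0   0.10    0.16          0.12       0.14           0.14  0.09
2   1   0.10    0.12          0.12
Total       1.00    0.30          0.23                             1.00    0.23
```

Marginally, Pr(Y=1) = 0.30 and Pr(Y¹=1) = 0.23, so treating everyone would
prevent 23% of cases (PF_total = 0.23). Stratum M=0 holds 50% of the
population but 66% of the cases, so its weight is 0.66 and its strong
stratum effect (PF = 0.25) drives the total; stratum M=2 (20% of people,
PF = 0.14) contributes only 9%.

The same numbers are recovered from simulated individual-level data:

```python
records = pf.sample_population(pf.SimConfig(spec, n=20_000, seed=7))
result = pf.ImpactFractionModel(records, measure="pf").fit(b_reps=1000, seed=11)
print(result.summary())
```

```
Impact fraction estimate (plug-in)
==========================================================
measure:            pf
assumption:         conditional_exchangeability
n records:          20000
bootstrap reps:     1000 (seed=11, dropped=0)
----------------------------------------------------------
              estimate      ci_low     ci_high
total           0.2303      0.2103      0.2507
m=2             0.1322      0.0576      0.2001   weight=0.0958
m=0             0.2648      0.2418      0.2880   weight=0.6717
m=1             0.1713      0.1279      0.2163   weight=0.2325
==========================================================
```

The `prevfrac` command line exposes the same operations: `measures`,
`estimate`, `simulate`, `classical` and `fixture` (see `prevfrac --help`).

## Layout

- `prevfrac.population` — counterfactual populations, risks, total measures,
  scenario JSON I/O, packaged fixture
- `prevfrac.decomposition` — stratum measures, case weights, weighted-average
  identities, reverse coding, reports
- `prevfrac.estimation` — records I/O, `ImpactFractionModel` /
  `ImpactFractionResults`, positivity checks, bootstrap
- `prevfrac.simulate` — trial sampler, exact proportional allocation, random
  scenario generator
- `prevfrac.classical` — Miettinen/Levin formulas and their validity flag
- `prevfrac.cli` — the `prevfrac` command

See `docs/methods.md` for the model, assumptions and design choices.
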