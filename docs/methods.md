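# Methods

## Model overview

`oohcba` evaluates a policy that removes unhealthy food and drink
advertising from state-owned transport assets. The causal chain is:
advertising exposure → unhealthy-food energy purchased → energy intake →
body weight → BMI → incidence of obesity-related disease → survival,
health-adjusted life years (HALYs) and healthcare costs → monetised
societal benefits versus policy costs.

The effect seed is the evaluated purchasing change of a comparable
restriction (−6.7 %, 95 % CI −10.1 to −3.2, of energy purchased from
restricted foods). It is treated as transferable 1:1 from household
purchasing to individual consumption — no household-size or waste
correction — and no substitution toward unrestricted foods is modelled
(the source evaluation found no significant spillover). Both choices make
the intake effect an upper bound if substitution exists.

### Effectiveness adjustments

Context differences enter as multiplicative reductions a_i, each in
[0, 1]; the applied effect is `relative_change × Π(1 − a_i)`, which is
order-independent. The primary configuration carries one adjustment of
0.20 for lower weekly out-of-home advertising exposure (≈78 % of
Australians vs ≈98 % in the UK). A coverage adjustment for assets outside
the policy is computed as `shelter_coverage × shelter_asset_share`
(0.90 × 0.20 = 0.18) and is switched on only in scenario s3; scenario s4
removes all adjustments.

### Energy to weight

The conversion uses the steady-state linear energy-balance rule
Δweight = ΔEI / ε with ε_adult = 94 kJ/day per kg — the widely used adult
approximation — and a growth-adjusted child coefficient ε_child = 420
kJ/day per kg for age bands below 18. Both are configurable per age band
(`EnergyBalance.overrides`), so a different child equation can be dropped
in without touching the pipeline. The weight change is realised at the
end of year 1 and maintained for the whole horizon (no regain); BMI
change is Δweight/height², using the stratum mean height.

## Potential impact fractions

BMI in a stratum is Normal(μ, σ) truncated below at the TMREL (default
21 kg/m²), with log-linear relative risk RR(x) = rr^max(0, x − tmrel) per
disease. The PIF for a shift Δ is

    PIF = 1 − E[RR(B + Δ)] / E[RR(B)].

Both expectations are evaluated by 64-node Gauss–Legendre quadrature on
[tmrel, μ + 12σ], split at the RR kink (x = tmrel − Δ) so each segment is
smooth; agreement with adaptive quadrature is better than 1e-6 relative.
A point-mass (σ = 0) branch uses the closed form, and a categorical
(BMI-band) evaluator is provided as a cross-check. PIFs are computed per
cohort at its starting BMI distribution and held constant (the weight
change is maintained), while the incidence they scale varies with age.

## Lifetable mechanics

Cohorts are the 5-year-band × sex strata of a closed population (no
births or migration), starting at their band midpoint age and ageing one
year per annual cycle; rates are looked up from the band containing the
cohort's current age, with the oldest band used beyond it. Each disease
follows the recursion (per unit cohort, annual probabilities i, f, r):

    healthy' = healthy·(1 − i) + diseased·r
    diseased' = diseased·(1 − f − r) + healthy·i

with prevalence measured among that process's survivors and disease
mortality f·prevalence fed into the main lifetable. Other-cause mortality
is recomputed every year as all-cause minus the summed baseline disease
mortality; the model refuses (raises) if that remainder goes negative,
rather than silently clamping. Intervention and baseline arms share
other-cause mortality, differing only through PIF-adjusted incidence from
the cycle after the weight change is realised.

HALY(t) = person-years(t) × (1 − Σ_d prevalence_d(t)·dw_d), with the
disability burden capped at 1; a multiplicative combination
(1 − Π(1 − prev·dw)) is available by flag. Healthcare cost(t) =
Σ_d prevalence_d(t) × alive(t) × unit-cost_d. Person-years are end-of-year
survivors: half-cycle correction is off by default so hand arithmetic and
the brute-force test oracle are exact; discounting uses the end-of-year
convention Σ_t v_t/(1+r)^t, t = 1…T, with year-0 items undiscounted.
Outcomes are truncated at the horizon (default 30 years): no tail credit
for within-horizon incident cases.

## Cost–benefit accounting

All amounts are 2019 A$. Government costs: policy development in year 0
(FTE-years by grade at loaded wages — base wage × (1 + 14 % oncosts) ×
(1 + 17.5 % leave loading on 4/52 of the year; the 4-week leave base is
an Australian-convention choice and configurable); monitoring from year 1
as half a national monitoring cost floored at one loaded compliance
officer; forgone advertising revenue from year 1 as the unhealthy share
(55 %) of transit food-advertising income plus a Main Roads component
imputed by the billboard:non-billboard ratio (58/42) — a reconstruction,
overridable by a direct amount. Industry cost: national transport
advertising revenue × state concentration (7 %) × unhealthy-ad share
(21 %) × profit margin (13 %), annually from year 1. Optional year-0
legislation cost (A$1 306 180, scenario s7).

Benefits = HALYs gained × VSLY (A$213 000; A$314 772 in s6) + healthcare
savings. NPV = benefits − costs; BCR = benefits/costs, reported from
unrounded internals (note that ratios of independently rounded headline
numbers will differ from a BCR computed on unrounded components). A run
is flagged *dominant* when healthcare savings alone exceed total costs.
BCR with zero total costs is reported as infinite rather than raising.

## Uncertainty analysis

2000 Monte Carlo iterations by default. The effect size is sampled from a
normal reconstructed from its 95 % CI (sd = width/(2 × 1.959964));
expert-judgement parameters (consumption scale, development cost scale,
monitoring cost, both revenue inputs, healthcare unit-cost scale) use a
Pert distribution at mean ± 25 % with shape λ = 4 via its Beta
reparameterisation. Draws are independent across parameters — no
correlation structure is asserted — and each parameter has its own RNG
stream keyed by (master seed, CRC32 of its name), so adding a parameter
never perturbs the others' draws. Uncertainty intervals are empirical
2.5th/97.5th percentiles with linear interpolation between order
statistics; identical seeds give bit-identical draw sets. A draw whose
parameter vector breaks the model is recorded, and the run fails if more
than 0.1 % of draws error.

## Scenarios

Only deltas from the primary configuration are recorded: s1 horizon 10
years (the alternative horizon is not pinned by the source description —
10 is this package's documented default), s2 horizon 4, s3 adds the 0.18
coverage adjustment, s4 removes all adjustments, s5 applies
category-specific effects to the categories with statistically
significant purchasing changes (the packaged values −0.15 for chocolate
and confectionery and −0.10 for puddings and biscuits are synthetic
stand-ins, configurable via `SCENARIO5_CATEGORY_EFFECTS`), s6 VSLY
A$314 772, s7 adds legislation cost, s8 removes both revenue-loss
streams, s9 models full advertising replacement from year 2
(replacement fraction configurable), s10 phases the whole intervention —
effects and recurring costs — in after 10 years.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of the real inputs: a ~2.1 M
closed population in 5-year bands (the 2–4 band is 3 years wide) by sex;
Gompertz-like all-cause mortality (non-decreasing above age 35, male
excess ×1.4); adult BMI means near 27 kg/m² rising with age; five
unhealthy food categories totalling ~1200–2300 kJ/day in adults; ten
disease processes with age-ramped incidence and case fatality, remission
0 except a 0.10/yr "cured" rate for cancers, log-linear RRs between 1.02
and 1.12 per BMI unit above TMREL 21; and the cost/revenue defaults
listed above. Initial prevalence is set to 60 % of a steady state with a
0.05/yr turnover floor (capping implied case duration at ~20 years) so
that summed disease mortality stays strictly inside all-cause mortality
at every age. Everything is deterministic under the seed, and ground
truth is written to `manifest.json`.

It does **not** reproduce survey microdata, nutrient mappings,
socioeconomic gradients, secular trends in consumption or mortality, or
correlated parameter uncertainty. Passing tests therefore demonstrate
the correctness of the machinery (accounting identities, oracle
equivalence, monotonicities, reproducibility) — not the real-world
magnitude of the policy's effect, which depends on the unpublished
inputs the synthetic tables stand in for.

## Numerical choices and degenerate inputs

- PIF quadrature: 64 Gauss–Legendre nodes per segment, kink-split; ≤1e-6
  relative error against adaptive quadrature on the tested grid.
- Disease recursions and the cohort lifetable are exact difference
  equations in float64; person conservation holds to 1e-9 relative.
- Zero effect short-circuits to PIF = 0 exactly, so the null intervention
  reproduces baseline bitwise and NPV = −costs exactly.
- Probability overflow (i > 1 or f + r > 1), negative other-cause
  mortality, adjusted incidence outside [0, 1], and zero-cost payer
  shares all raise typed errors naming the offending stratum/year or
  field instead of propagating NaNs.
- Default problem sizes (40 strata × 10 diseases × 30 years; 2000 draws)
  run in well under a minute on a single CPU; draw counts and horizons
  are plain arguments.

## Known limitations

- Productivity impacts, dietary substitution, equity analysis, CPI
  re-basing and early contract-termination costs are out of scope.
- Health gains flow only through BMI; direct sugar/salt/saturated-fat
  risk pathways are not modelled, understating benefits.
- No cancer lag: incidence responds to BMI from the cycle after the
  weight change; a lag structure would delay and discount cancer
  benefits.
- Disease processes are independent conditional on survival (the
  proportional assumption); comorbidity interacts only through the
  capped additive disability weights.
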