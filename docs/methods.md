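# Methods

## Model structure

The model is a hybrid of a one-month decision tree and a monthly Markov
cohort process over the four NYHA functional classes, run in parallel for
two strategies (PMVR, OMT) on a closed cohort entering in NYHA III at age
62 (77% male, 63.9% with severe FMR). Cycle length is one month; the
base-case horizon is 120 cycles.

The PMVR arm carries two sub-cohorts with separate dynamics but pooled
accrual: *implanted* (successful annuloplasty, share `1 − p_unsuccessful`)
and *recaptured* (device removed intra-operatively, share
`p_unsuccessful`), the latter following OMT dynamics from cycle 2 under
the intention-to-treat convention. Within a cycle the order of events is
death first, then transition among survivors — the published transition
matrices are observed among trial survivors, so this order keeps them
unbiased as inputs. No half-cycle correction is applied; state costs and
utilities accrue for full cycles on the end-of-cycle occupancy.

Cycle 1 is special-cased: the PMVR arm's only mortality is the
peri-procedural probability (0.019), while the OMT arm already experiences
the full combined disease mortality. This asymmetry follows the decision
tree's structure (procedural outcomes versus first-month disease course);
it also means an "effect-stripped" PMVR arm does not exactly equal the OMT
arm in cycle 1 when disease mortality is non-zero, which is why the
corresponding equivalence test runs under zero mortality.

## Mortality and hospitalization

Monthly all-cause mortality per state combines, as independent competing
risks, `1 − (1 − p_bg)(1 − p_excess)`:

* **Background** `p_bg`: sex-mixed annual probability from a period life
  table at the cohort's current integer age (the cohort ages 1/12 year per
  cycle; lookups clamp at the table's last row). The bundled table carries
  German period-table values for ages 50–100, log-linearly interpolated
  between quinquennial anchors.
* **Excess** `p_excess`: the six-month NYHA-specific probabilities
  converted to monthly under constant hazard, `1 − (1 − p₆)^{1/6}`, times
  a severe-MR adjustment. NYHA I carries no excess mortality.

The severe-MR relative risks enter through the mixture multiplier
`m(p) = (1 − p) + p·RR`. Two referent conventions coexist, matching the
provenance of the baselines and calibrated against the published
validation mortality and arm costs:

* the excess-*mortality* baselines describe the trial-average cohort
  (63.9% severe), so the adjustment is the ratio `m(p)/m(0.639)` — equal
  to 1 for the untreated cohort;
* the *hospitalization* baselines are treated as a non-severe referent, so
  the full multiplier `m(p)` applies.

Successful implantation is modelled as removing the excess risk
attributable to severe regurgitation: the implanted sub-cohort's
adjustment is additionally divided by the RR, on top of the prevalence
fall (0.639 at baseline, 0.35 in months 2–5, 0.258 from month 6). This
treatment-effect definition is deliberately strong — a pure
prevalence-mixture adjustment cannot reproduce the separation of the two
published survival curves, because any linear mixture fixes the
implanted/untreated hazard ratio at `m(0.258)/m(0.639) ≈ 0.86` regardless
of referent. With the protective-RR convention the model reproduces the
published cumulative mortality at 1/2/5/10 years within ~1 percentage
point in both arms. With RR = 1 the severity structure has no effect, and
all adjustments are monotone in prevalence and RR.

Hospitalization is a cost-only event (it alters neither utilities nor
transitions): expected admissions per cycle are occupancy times the
monthly NYHA-specific probability times the severity adjustment, priced
at the DRG-mix mean admission cost. The published mix percentages sum to
98.2% after rounding and are used verbatim; the loader warns but does not
renormalize, since the printed expected-cost arithmetic uses the raw
weights.

## Costs, utilities, discounting

Routine management uses NYHA-specific annual tariffs accrued monthly on
surviving occupancy; the dead accrue nothing. Cycle 1 of the PMVR arm
adds device + procedure cost for the whole arm (attempted implantations
included, per the statutory-insurance coverage assumption — also applied
to peri-procedural deaths) and the expected perforation-management cost
`0.02 × €1,998`; peri-procedural myocardial infarction and arrhythmia are
assumed cost-neutral. No hospitalization cost accrues in PMVR cycle 1
(the procedural admission is already priced). All amounts are 2013 euros;
no inflation or currency machinery is included.

Utilities are NYHA-specific, independent of treatment and hospitalization
status; the PMVR arm subtracts the one-month procedural decrement in
cycle 1. Discounting is annual-step at 3%/year with the first model year
exempt: factor `(1.03)^{−⌊(m−1)/12⌋}` for month `m > 12`, 1 otherwise.
Monthly compounding was rejected as less faithful to the stated rule; the
difference in totals is below 1%.

## Transition matrices

Six 4×4 row-stochastic matrices (arm × regime: cycle 1, cycles 2–11,
cycle 12+), conditional on surviving the cycle. Two published rows sum to
0.99 and 1.01 under two-decimal rounding; the loader renormalizes rows
within ±0.02 of 1 (with a WARNING finding) and rejects larger deviations.
The all-zero NYHA I rows of the OMT matrices are replaced by identity
rows and flagged — the state is unreachable in that arm, so the
substitution preserves row-stochasticity without inventing dynamics.
Cycle-1 matrices only define the NYHA III row (the whole cohort enters
there); the other rows are structural identities.

## Scenarios

* **Fade-out**: the implanted sub-cohort loses its entire treatment
  effect after month 36 (the device studies' observed follow-up):
  transition matrices, the severe-MR trajectory and the protective RR all
  revert to OMT dynamics. Reverting only the matrices leaves the scenario
  nearly inert, contradicting its published purpose of bounding the
  extrapolation risk, so full reversion was chosen.
* **Lifetime**: the horizon extends to cohort extinction (occupancy below
  1e-9) or age 100, whichever comes first; at the cap only ~0.1% of the
  PMVR cohort remains. Discounting is unchanged. The model's lifetime
  ICER (≈ €9,700/QALY) is ~23% above the published €7,914 even though the
  10-year quantities agree within ~9%; undiscounted, the same run gives
  ≈ €7,400/QALY. The published lifetime figures fall between the two
  conventions, indicating a tail assumption (life table, age cap, or
  discount handling) that the source does not describe; the uniformly
  discounted convention is retained.

## Sensitivity analysis

One-way DSA re-runs both arms at each parameter's published range bound,
all else at base; the tornado table sorts by ICER span. Parameters
without a published range (hospitalization mix shares, discount rate,
horizon) are excluded. Because the baseline severe-MR share is also the
mortality referent, much of its one-way leverage cancels and it ranks
mid-table; the other published top drivers (device cost, age,
implantation failure probability) emerge on top here as well.

PSA distributions follow the published table: Beta with the printed
(α, β) for probabilities and utilities (where the printed parameters
imply slightly different means than the base values — e.g. NYHA II
management cost 874 vs Gamma mean 910 — the printed distribution is used
verbatim); Gamma(α = 1, scale λ) for management costs, interpreting λ as
the scale so the mean ≈ the base cost; log-normal centred at ln(base)
with the printed log-scale SE for the relative risks; Normal(62, 12) for
age, truncated to the life table's supported range (ages below 50 have no
background-mortality data); Beta with effective count n = 53 for the male
fraction, for which no parameters are printed. Transition rows and the
hospitalization mix are Dirichlet draws with concentration = proportions
× effective count (implanted n = 36, control n = 17, admission mix
n = 813); structurally zero transitions stay zero, identity rows are not
resampled, and the effective counts are plain parameters (0 disables
resampling, giving point-mass behaviour). DRG tariffs and
device/procedure costs carry no uncertainty. The CEAC is the fraction of
draws with positive net monetary benefit over a €0–100,000 grid in €1,000
steps. A fixed seed makes the whole PSA bit-reproducible.

The PSA mean incrementals sit above the base case (ΔQALY mean ≈ 1.0 vs
1.13 base here; the source reports a similar, stronger shift to 0.77) —
an expected consequence of the nonlinear mortality response to the
Dirichlet and RR draws at these small effective counts.

## Synthetic data

`synth_life_table` builds a Gompertz-style table `q(age) = q₅₀·g^(age−50)`
per sex — adequate for adult ages, with no infant/accident hump, capped at
1. `simulate_trajectories` steps individual patients through
death-then-transition cycles under the same matrices and any death model,
so `estimate_transition_matrix` (row-wise empirical proportions among
survivors) is unbiased by construction. The trajectories emulate the
structure of trial panel data — monthly NYHA readings with absorbing
death — not its messiness: no missed visits, no inter-rater noise, no
informative dropout. Passing recovery tests therefore demonstrates
estimator and engine correctness, not robustness to real-world data
defects.

## Problem sizes and numerics

Tests run the microsimulation cross-check and estimator recovery at 10⁵
patients (3 Monte-Carlo-SE and 0.01 max-row-error tolerances) and the PSA
at 5,000 draws, matching the published simulation size. Row sums are
enforced to 1e-9 after load-time renormalization; conservation
(occupancy + cumulative deaths = 1) holds to 1e-9 at every cycle;
probabilities are capped at 1 after multiplier application. Ties and
degenerate inputs: zero-QALY differences yield a dominance label or NaN
ICER rather than a division error; empty occupancy accrues nothing.

## Known limitations

* The severe-MR referent conventions and the protective-RR treatment
  effect are reverse-engineered from published outputs, not stated by the
  source; alternative conventions change the ICER by up to ~60%.
* The bundled life table is an interpolated approximation of German
  period values; tails above age 90 are the weakest part.
* Recaptured patients inherit OMT dynamics wholesale; no procedural harm
  beyond the shared peri-procedural mortality is modelled.
* No re-intervention, device durability failure, or hospitalization
  effect on utilities/transitions; no EVPI or two-way DSA.
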