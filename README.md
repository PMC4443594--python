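# pmvr-cea

Cost-utility model of percutaneous mitral valve repair (PMVR, coronary-sinus
annuloplasty with the Carillon device) versus prolonged optimal medical
treatment (OMT) in patients with heart failure and moderate-to-severe
functional mitral regurgitation (FMR), from the perspective of the German
statutory health insurance.

The package is aimed at health-economic modellers who want a tested,
scriptable re-implementation of this evaluation: every input is an explicit,
overridable parameter, every analysis (base case, deterministic and
probabilistic sensitivity analysis, scenarios) is a library call or a CLI
subcommand, and a synthetic-data module generates life tables and
patient-level NYHA trajectories so the whole pipeline can be exercised
without any external data.

## Model

A first-month decision tree feeds a monthly Markov cohort model over the
four NYHA functional classes (I–IV) plus death:

* **Decision tree (cycle 1).** All patients start in NYHA III. In the PMVR
  arm a fraction `p_periop = 0.019` dies peri-procedurally; survivors split
  into an *implanted* sub-cohort (68%) distributed over NYHA classes by the
  first-month PMVR transition row, and a *recaptured* sub-cohort (32%,
  unsuccessful implantation, device removed) that follows OMT dynamics
  thereafter (intention to treat). Device (€18,000) and procedure (€4,844)
  costs are borne for every attempt; a one-month utility decrement (0.043)
  applies to the whole arm.
* **Markov process (cycles 2+).** Each month, state-specific death first,
  then transition among survivors under regime-specific matrices (months
  2–11 vs 12 onwards, per arm). Monthly mortality combines German
  life-table background mortality, NYHA-specific excess mortality
  (six-month probabilities `p₆ = 0.04/0.07/0.28` for NYHA II/III/IV,
  converted as `1 − (1 − p₆)^(1/6)`), and a severe-MR adjustment built from
  the mixture multiplier `(1 − p) + p·RR` (RR 1.5 mortality, 1.7
  hospitalization). Successful implantation lowers the severe-MR prevalence
  (0.639 → 0.35 → 0.258) and removes the severe-MR relative risk for the
  treated sub-cohort. Hospitalizations are cost-only events priced at the
  DRG admission mix (≈ €5,646 per admission).
* **Economics.** Costs (2013 €) and QALYs accrue monthly on surviving
  occupancy and are discounted at 3%/year in annual steps with the first
  year exempt; the headline result is the incremental cost-effectiveness
  ratio ICER = ΔC/ΔQALY against a willingness-to-pay threshold of
  €35,000/QALY.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```python
from pmvr_cea import default_parameters, run_cea
from pmvr_cea.mortality import LifeTable

params = default_parameters()                 # all published inputs embedded
life_table = LifeTable.bundled_german()       # period table, ages 50-100

result = run_cea(params, life_table)          # 10-year base case
print(f"PMVR: €{result.intervention.total_cost:,.0f}, "
      f"{result.intervention.total_qaly:.2f} QALY")
print(f"OMT:  €{result.comparator.total_cost:,.0f}, "
      f"{result.comparator.total_qaly:.2f} QALY")
print(f"ICER: €{result.icer:,.0f}/QALY")
```

prints

```
PMVR: €36,616, 4.08 QALY
OMT:  €17,561, 2.95 QALY
ICER: €16,887/QALY
```

i.e. over 10 years the repair arm costs ~€19,055 more but yields 1.13
additional QALYs (1.38 life-years), so PMVR is cost-effective at the
German threshold. The same analysis from the shell:

```sh
pmvr-cea basecase --out results/        # Table-style CSV + traces + mortality
pmvr-cea dsa      --out results/        # tornado.csv (one-way DSA)
pmvr-cea psa --n 5000 --seed 7 --out results/   # draws, CEAC, summary
pmvr-cea scenarios --out results/       # fade-out and lifetime horizons
pmvr-cea validate                       # configuration findings
pmvr-cea synth --n 1000 --out synth/    # synthetic life table + trajectories
```

Parameters are overridden with a YAML config, e.g.
`pmvr-cea basecase --config my.yaml` where `my.yaml` contains
`cost_device: 12600`.

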