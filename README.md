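# drphenome

Survival, factorial-phenotype and aging-trait analysis for dietary-
restriction rodent cohort studies.

Intermittent fasting — in its strictest rodent form, every-other-day
(EOD) feeding — extends mouse lifespan. Whether it does so by *slowing
aging* or merely by postponing lethal disease is a different question,
and answering it takes more than a survival curve: it takes a lifespan
analysis (does the mortality rate doubling time change, or only the
baseline hazard?), a deep phenotyping screen across young and old
animals of both diets, and bookkeeping that distinguishes aging traits
the diet *prevents* from traits it shifts *regardless of age*.
`drphenome` implements that full analytical arc for biostatisticians and
aging researchers, exercised end-to-end on synthetic cohorts that mirror
the design of a large EOD study (two arms of 43/37 animals followed to
death, a 2×2 age × diet screen of ~239 parameters).

## What it computes

* **Survival**: Kaplan–Meier curves, log-rank test, mean lifespan, and
  "maximum lifespan" as the mean of the longest-living 20%
  (k = ⌈0.2·n⌉ per arm, Welch t-test between subsets); cause-of-death
  proportions and tumor-burden comparison.
* **Gompertz mortality model**: maximum-likelihood fit of
  h(t) = a·e^{bt} with right censoring; mortality rate doubling time
  MDT = ln 2 / b with standard errors from the observed information.
* **Derived phenotypes**: indirect calorimetry (RER = VCO₂/VO₂,
  HP = (4.44 + 1.43·RER)·VO₂ mW), echocardiography (FS, Teichholz
  volumes, EF, corrected LV mass, stroke volume, cardiac output), ECG
  (Bazett QTc = QT/√RR, HRV, rMSSD, pNN50) and hematology (HCT, MCH,
  MCHC, PCT).
* **Factorial statistics**: two-way age × diet ANOVA (textbook
  decomposition when balanced, Type-III when not), Tukey HSD, Fisher's
  exact test, three-way split-plot ANOVA with Greenhouse–Geisser
  correction, and a crossed random-intercept mixed model
  (weight ~ diet + (1|cage) + (1|week), REML) for longitudinal body
  weights.
* **Trait classification** into five categories: aging traits
  *prevented* by the diet (rescued in old, silent in young),
  *age-independently opposed* (young animals respond too), *unchanged*,
  *exacerbated*, plus diet-only and null traits — with Venn-style
  summary counts.
* **Effect-size meta-analysis**: Cohen's d (pooled SD) per trait for
  age, diet-in-young and diet-in-old contrasts, and cross-trait Pearson
  correlations that test whether the diet opposes aging
  (r(d_age, d_EOD,old) < 0) and acts age-independently
  (r(d_EOD,young, d_EOD,old) > 0).
* **Synthetic cohorts**: Gompertz lifespans by analytic inverse-CDF
  sampling, Gaussian 2×2 trait panels with per-trait category structure,
  cage-clustered weekly weights, Poisson tumor burdens — all
  byte-reproducible from a seed.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Simulate the default scenario (two arms of 43/37 animals with arm mean
lifespans 806/908 d and MDTs 83.6/91.7 d; a 239-trait panel with
7 prevented / 33 age-independent / 62 unchanged / 14 exacerbated /
36 diet-only / 87 null traits at |d| = 1.5, 20 animals per cell) and
analyse it:

```sh
drphenome report --seed 1 --out demo/
```

prints

```
drphenome report (seed=1, alpha=0.05)
  AL: n=43, mean lifespan 797.0 d, MDT 80.9 d
  EOD: n=37, mean lifespan 894.4 d, MDT 90.4 d
  log-rank chi2=13.33 p=0.000262; mean extension 97.4 d; max-lifespan extension 115.4 d (top-20%: k=9/8)
  traits: 239 classified, 116 aging, 101 diet-modified, 40 ameliorated (8 prevented + 32 age-independent), 13 exacerbated
  body weight: diet effect -5.06 g (SE 0.44, p=1.66e-30, MixedLM-REML)
```

Reading this: the simulated diet arm lives ~97 days longer on average
(log-rank p ≈ 3e−4) while the mortality doubling times (80.9 vs 90.4 d)
stay in the same range — longer life without a proportional slowing of
the hazard's doubling. Of 239 traits, 116 show an aging signal and 40 of
those are ameliorated by the diet, but only 8 qualify as *prevented*
(old-only rescue); most ameliorations appear equally in young animals
after a month of treatment, i.e. they are age-independent diet effects
rather than evidence of slowed aging — the generating panel encoded
7/33, so the screen recovers the structure up to sampling noise. The
full per-trait tables, KM coordinates, fits and Venn counts land in
`demo/` as TSV/JSON.

The same stages run individually (`drphenome simulate | survival |
traits | validate`) or from Python:

```python
import drphenome as dp

cohort = dp.generate_survival_cohort(n=500, a=1e-5, b=0.0077, seed=1)
fit = dp.fit_gompertz(cohort)
print(fit.mdt)          # mortality rate doubling time, days
```

## Layout

```
src/drphenome/
  simulate.py    synthetic cohorts (ScenarioConfig, generators)
  phenotypes.py  derived-measure formulas
  survival.py    KM, log-rank, lifespans, Gompertz MLE, endpoints
  factorial.py   ANOVA, Tukey, Fisher, GG epsilon, mixed models
  classify.py    trait categories and Venn counts
  effects.py     Cohen's d and cross-trait correlations
  io.py          CSV readers and input validation
  pipeline.py    end-to-end orchestration
  cli.py         command-line interface
```
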