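# Methods

This note documents the statistical models behind `drphenome`, the
choices made where the design was genuinely open, and what the
synthetic-cohort generator does and does not emulate.

## Study design being modelled

The pipeline targets a two-arm mouse aging study: C57BL/6J males fed ad
libitum (AL) or every-other-day (EOD, alternating 24 h free access and
24 h food deprivation), with a lifespan cohort followed to natural death
(AL n = 43, EOD n = 37) and cross-sectional deep phenotyping of four
groups — young and old animals of both diets — across ~239 parameters
analysed cell-wise (typical cell sizes 16–23). Statistical conventions
follow the phenotyping literature: per-trait two-way ANOVA at
α = 0.05 with Tukey HSD post hocs, no multiple-testing correction
across traits (a Benjamini–Hochberg switch exists but is off by
default so that trait counting reproduces the per-trait convention).

## Gompertz mortality model

Hazard h(t) = a·e^{bt}; survivor S(t) = exp(−(a/b)(e^{bt}−1)).
The mortality rate doubling time MDT = ln 2 / b summarizes the aging
rate; a pure shift in vulnerability changes a, not MDT.

Fitting is by maximum likelihood over (log a, log b) (Nelder–Mead,
objective tolerance 1e−8), with censored animals contributing the
log-survivor term. The log parameterization keeps both rates positive
without active bounds; on effectively exponential data the slope is
driven toward zero rather than hitting a boundary, and
`mortality_doubling_time` refuses b ≤ 0 (the hazard never doubles).
Initialization: a from the exponential fit (deaths / total exposure),
b = 1e−3 per day. Standard errors come from the observed information at
the optimum (numerical Hessian on the log scale, delta method back).
The study source gives no fitting recipe (MLE vs regression on binned
log-hazard) and does not say whether censored phenotyping animals
entered the lifespan estimates; MLE with explicit censoring terms is
used here as the statistically efficient default.

## Lifespan summaries

* Mean lifespan: arithmetic mean of observed death times; censored
  animals are excluded with a logged count (the lifespan cohort was
  followed to natural death, so restricted-mean estimators are out of
  scope).
* Maximum lifespan: mean of the longest-living 20% per arm, with
  subset size k = ⌈0.2·n_deaths⌉. The ceiling rule is deliberate: it
  yields subsets of 9 of 43 and 8 of 37 animals (floor or round-half-even
  would give 8 and 7). Subsets are compared with a Welch t-test.
* Log-rank test via lifelines, with the standard hypergeometric-variance
  tie correction.
* Everywhere a two-sample t-test is unspecified further, the Welch
  (unequal-variance) form is used.

## Factorial trait statistics

Two-way ANOVA (age × diet, both two-level): balanced designs use the
orthogonal textbook decomposition; unbalanced designs use marginal
(Type-III) sums of squares under sum-to-zero coding, the convention for
unequal phenotyping cells. On balanced data the two coincide. Missing
values are dropped listwise within a trait.

Tukey HSD uses the Tukey–Kramer studentized-range statistic with the
exact range distribution; panel screening uses a cached monotone-cubic
interpolant of the distribution's tail (maximum absolute error ~2e−6,
i.e. far below any decision threshold) because exact evaluation costs
~10 ms per p-value and a screen computes thousands.

Fisher's exact test (presence/absence traits) reports the two-sided p by
probability-mass ordering — the sum of hypergeometric probabilities of
tables no more probable than the one observed — and the sample odds
ratio with 0/∞ at zero margins. Note that the exact test is
intrinsically conservative on discrete tables; its null rejection rate
approaches 0.05 only for large margins.

The three-way split-plot ANOVA (age × diet between subjects, one
within-subject factor such as sound intensity) uses the univariate
approach: between terms are tested on subject means; within-involving
terms on orthonormally (Helmert) contrasted scores with Type-III
full-vs-reduced sums of squares. The Greenhouse–Geisser ε̂ is estimated
from the pooled within-cell covariance of the contrast scores and
applied unconditionally (not gated on a sphericity pretest) by
multiplying both degrees of freedom; the uncorrected p is reported
alongside. ε is clipped to [1/(k−1), 1]. The df deflation is
conservative in the small-p tail; for middling F (~1.2) the corrected
and uncorrected tails can cross slightly — an algebraic property of the
F distribution, not an implementation artifact. Complete within-subject
data is required; subjects with missing levels are named in the error.

Longitudinal body weights are modelled as
weight ~ diet (fixed) + (1|cage) + (1|week), fitted by REML via crossed
variance components (statsmodels MixedLM). Random intercepts only: the
design statement ("cage and time as random effects") specifies no slope
structure. On non-convergence the model falls back to a Welch comparison
of cage-level means, which is unbiased for the diet effect under the
same model, and flags the result.

## Trait classification

A trait is an *aging trait* when the old/AL vs young/AL Tukey contrast
is significant — the control-arm contrast, not the age main effect, so
that the definition is not contaminated by diet (a main-effect switch
exists). For an aging trait with aging direction s:

| old-diet contrast              | young-diet contrast | category        |
|--------------------------------|---------------------|-----------------|
| significant, direction = s     | (any)               | EXACERBATED     |
| significant, direction = −s    | not significant     | PREVENTED       |
| significant, direction = −s    | significant         | AGE_INDEPENDENT |
| n.s., but diet main effect significant without interaction, direction −s | | AGE_INDEPENDENT |
| otherwise                      |                     | UNCHANGED_AGING |

Non-aging traits are DIET_ONLY if any diet term is significant, else
NULL. A zero direction never counts as "opposing". The AGE_INDEPENDENT
row accepts a significant young-diet contrast of either direction: a
young response of any kind shows the diet acts without the aging
context, and requiring direction-compatibility would let a trait jump
from UNCHANGED_AGING to PREVENTED as α shrinks, breaking the intended
monotonicity of the decision table. Exacerbated traits are flagged as a
separate category inside the "not measurably improved" aging set, so
aging = prevented + age-independent + unchanged + exacerbated.
Constant (zero-variance) traits are untestable: category withheld with
a warning. Binary traits follow the same table with Fisher's exact
contrasts on cell-wise 2×2 tables.

## Effect sizes

Cohen's d with the Bessel-corrected pooled SD (the stated measure of the
screen; Hedges g is available as an option since cells are small).
Three d's per trait: age (old/AL vs young/AL), diet-in-young, and
diet-in-old. Binary traits can enter via a continuity-corrected probit
transform of proportions, flagged distinctly. Cross-trait summaries use
Pearson correlation (matching the linear scatter presentation; Spearman
optional): on aging traits, r(d_age, d_diet-in-old) < 0 indicates the
diet opposes aging changes; on diet-modified traits,
r(d_diet-in-young, d_diet-in-old) > 0 indicates age-independent action.

## Derived phenotypes

Closed-form formulas with units fixed at the interface (lengths mm,
volumes µl, intervals ms, gas exchange ml/h): RER = VCO₂/VO₂;
HP (mW) = (4.44 + 1.43·RER)·VO₂; FS% = 100·(LVIDd−LVIDs)/LVIDd;
Teichholz LVvol = 7.0/(2.4+LVID)·LVID³; EF% = 100·(VolD−VolS)/VolD;
LV mass = 0.8·1.053·((LVIDd+LVPWd+IVSd)³−LVIDd³); SV = VolD−VolS;
CO = SV·HR; QTc = QT/√RR; HCT = MCV·RBC; MCH = HGB/RBC;
MCHC = HGB/HCT; PCT = MPV·PLT; HRV = mean |ΔRR|; rMSSD = RMS of ΔRR;
pNN50 = % of |ΔRR| > 50 ms. Three conventions deserve note: the EF
ratio is written with the standard division (which bounds EF at 100%);
QTc takes RR in **seconds** (classic Bazett — parts of the mouse ECG
literature normalize RR to 100 ms instead, so rescale before calling if
that convention is wanted); HRV uses *absolute* successive differences,
since signed differences average to ~0 in any stationary series. QT/QTc
dispersion is implemented as the max−min range across the provided
beats/leads; whether the source meant a range or an SD across leads is
not stated, and this is flagged as an assumption.

## Synthetic-cohort generator

The generator reproduces the statistical structure the analyses assume,
under the study's own design constants (two arms of 43/37 animals; arm
mean lifespans 806/908 days at MDTs 83.6/91.7 days, with the baseline
hazard solved numerically from these two constraints; tumor-burden arm
means 1.28/0.85; a 239-trait panel with 7 prevented / 33
age-independent / 62 unchanged / 14 exacerbated / 36 diet-only / 87 null
traits at standardized effect |d| = 1.5 and 20 animals per cell):

* lifespans by analytic inversion of the Gompertz survivor function on
  uniform deviates (exact, no rejection); b = 0 is an explicit
  exponential branch to avoid 0/0; administrative right-censoring at a
  cutoff time;
* trait panels as homoscedastic Gaussian 2×2 cell-mean models — the
  ANOVA's own assumption; categorical SHIRPA-like traits are emulated as
  presence/absence tables for the Fisher path;
* weekly weights as arm trajectory + Gaussian cage intercept + residual;
* tumor counts as Poisson (only arm means are known; overdispersion is
  deliberately omitted, so a negative-binomial real cohort would show
  wider tumor-burden tests than the simulation suggests).

All randomness flows through NumPy's PCG64 `Generator`; the seed is part
of the public interface and bit-reproducibility is promised for a pinned
NumPy generator version. What the generator does **not** emulate:
instrument noise structure (echo speckle, ECG artifacts), heteroscedastic
or skewed traits, correlated traits within animals, informative
censoring, or seasonal/batch effects — so passing recovery tests shows
the procedures are correct under their assumptions, not that real data
meet those assumptions.

## Problem sizes used in validation

Parameter-recovery and calibration runs use sizes chosen to make
Monte-Carlo error small relative to the tested bands: 100 cohorts of
n = 500 for Gompertz MDT recovery; 2000 null replicates per test for
type-I calibration (log-rank on 50+50 exponential lifespans; ANOVA age
term on 10/cell Gaussian cells; Welch on 20+20; Fisher on two
binomial(500, ½) groups — margins large enough that the exact test's
discreteness leaves its true level at 0.046, inside the 0.04–0.06
band); 25 replicate 239-trait panels for classifier and correlation-sign
recovery. Oracle equivalences are exact: Fisher vs full enumeration for
all tables with total ≤ 20, balanced ANOVA vs orthogonal projections to
1e−8, Kaplan–Meier vs brute-force product limit over all 256 censoring
patterns of an 8-animal cohort, GG ε at its compound-symmetry and
rank-1 bounds.

## Known limitations

* The Gompertz fit offers no Makeham term or Weibull alternative; early-
  life accidental mortality would bias a upward.
* Type-III tests assume the sum-to-zero parameterization; the source
  does not state its SS type for unbalanced cells, and this choice is a
  documented default, not a reproduction.
* The exacerbated/not-improved set algebra of the original trait
  bookkeeping is ambiguous (whether the 14 exacerbated traits sit inside
  the 76 not-improved); counts here treat exacerbated as a separately
  flagged subset of the not-improved aging traits.
* No meta-analytic weighting or standard-error bands on d; correlations
  are descriptive.
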