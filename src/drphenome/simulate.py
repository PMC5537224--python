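"""Synthetic cohort generators.

Every downstream stage of the pipeline (survival statistics, factorial
phenotype screening, trait classification, effect-size meta-analysis,
longitudinal mixed models) is exercised on data produced here, so the
generators implement exactly the statistical structure the analyses
assume:

* lifespans follow a Gompertz law ``h(t) = a * exp(b*t)`` and are drawn
  by analytic inversion of the survival function (no rejection step);
* factorial trait panels are homoscedastic Gaussian 2x2 (age x diet)
  cell-mean models parameterised by standardized effect sizes;
* weekly body weights are cage-clustered with additive random cage
  intercepts; tumor burdens are Poisson counts.

All randomness flows through :class:`numpy.random.Generator` seeded with
PCG64; a fixed seed reproduces every table bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "TraitSpec",
    "ScenarioConfig",
    "generate_survival_cohort",
    "generate_trait_panel",
    "generate_longitudinal_weights",
    "generate_tumor_counts",
    "gompertz_survival",
    "gompertz_mean_lifespan",
    "gompertz_a_for_mean",
    "default_trait_specs",
]

#: Trait categories a generated trait can be designed to fall into.
CATEGORIES = (
    "PREVENTED",
    "AGE_INDEPENDENT",
    "UNCHANGED_AGING",
    "EXACERBATED",
    "DIET_ONLY",
    "NULL",
)


@dataclass(frozen=True)
class TraitSpec:
    """Design of one synthetic trait in the 2x2 (age x diet) panel.

    Effects are standardized (units of the within-group SD):

    ``d_age``
        old/AL vs young/AL shift (the aging signal in the control arm).
    ``d_diet_young``
        young/EOD vs young/AL shift (short-term diet effect).
    ``d_diet_old``
        old/EOD vs old/AL shift (long-term diet effect).

    ``true_category`` records which classification outcome the effect
    pattern encodes; :meth:`validate` enforces consistency between the
    label and the pattern so that classifier-recovery simulations are
    meaningful.
    """

    trait_id: str
    true_category: str
    d_age: float = 0.0
    d_diet_young: float = 0.0
    d_diet_old: float = 0.0
    baseline_mean: float = 0.0
    sd: float = 1.0

    def validate(self) -> None:
        if self.true_category not in CATEGORIES:
            raise ValueError(f"unknown category {self.true_category!r}")
        if not self.sd > 0:
            raise ValueError(f"trait {self.trait_id}: sd must be > 0")
        c = self.true_category
        age, dy, do = self.d_age, self.d_diet_young, self.d_diet_old
        ok = {
            "PREVENTED": age != 0 and do * age < 0 and dy == 0,
            "AGE_INDEPENDENT": age != 0 and do * age < 0 and dy * do > 0,
            "UNCHANGED_AGING": age != 0 and do == 0 and dy == 0,
            "EXACERBATED": age != 0 and do * age > 0,
            "DIET_ONLY": age == 0 and (dy != 0 or do != 0),
            "NULL": age == 0 and dy == 0 and do == 0,
        }[c]
        if not ok:
            raise ValueError(
                f"trait {self.trait_id}: effect pattern "
                f"(d_age={age}, d_diet_young={dy}, d_diet_old={do}) "
                f"inconsistent with category {c}"
            )


@dataclass
class ScenarioConfig:
    """Full simulation scenario for an end-to-end pipeline run.

    Defaults mirror the study design the pipeline targets: two diet arms
    (ad libitum vs every-other-day feeding) of 43 and 37 animals followed
    to death, a 2x2 factorial phenotype panel, cage-clustered weekly body
    weights, and Poisson tumor burdens with arm means 1.28 and 0.85.
    Gompertz parameters per arm are chosen so that the arm mean lifespans
    are 806 and 908 days at mortality doubling times of 83.6 and 91.7
    days.
    """

    seed: int = 0
    n_al: int = 43
    n_eod: int = 37
    gompertz_b_al: float = np.log(2) / 83.6
    gompertz_b_eod: float = np.log(2) / 91.7
    mean_lifespan_al: float = 806.0
    mean_lifespan_eod: float = 908.0
    censor_time: float | None = None
    tumor_mean_al: float = 1.28
    tumor_mean_eod: float = 0.85
    trait_specs: list[TraitSpec] = field(default_factory=list)
    n_per_group: int = 20
    cages_per_arm: int = 18
    mice_per_cage: int = 4
    weeks: int = 30
    dr_effect_g: float = -5.0
    cage_sd_g: float = 1.5
    resid_sd_g: float = 1.0

    def __post_init__(self) -> None:
        if not self.trait_specs:
            self.trait_specs = default_trait_specs(seed=self.seed)
        for spec in self.trait_specs:
            spec.validate()
        ids = [s.trait_id for s in self.trait_specs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate trait_id in trait_specs")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("cage_sd_g", "resid_sd_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def gompertz_a(self, arm: str) -> float:
        """Baseline hazard solving for the configured arm mean lifespan."""
        if arm == "AL":
            return gompertz_a_for_mean(self.mean_lifespan_al, self.gompertz_b_al)
        if arm == "EOD":
            return gompertz_a_for_mean(self.mean_lifespan_eod, self.gompertz_b_eod)
        raise ValueError(f"unknown arm {arm!r}")


# ---------------------------------------------------------------------------
# Gompertz helpers


def gompertz_survival(t, a: float, b: float):
    """Closed-form survivor function S(t) = exp(-(a/b)(e^{bt}-1))."""
    t = np.asarray(t, dtype=float)
    if b == 0:
        return np.exp(-a * t)
    return np.exp(-(a / b) * np.expm1(b * t))


def gompertz_mean_lifespan(a: float, b: float) -> float:
    """E[T] for the Gompertz law; (1/b) e^{a/b} E1(a/b), or 1/a when b=0."""
    if b == 0:
        return 1.0 / a
    z = a / b
    # exp(z)*E1(z) computed stably via scipy's scaled exponential integral
    return special.exp1(z) * np.exp(z) / b


def gompertz_a_for_mean(mean: float, b: float) -> float:
    """Solve the baseline hazard giving a target mean lifespan at fixed slope."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if b == 0:
        return 1.0 / mean
    f = lambda loga: gompertz_mean_lifespan(np.exp(loga), b) - mean
    lo, hi = np.log(1e-12), np.log(1.0)
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-14)))


# ---------------------------------------------------------------------------
# Generators


def generate_survival_cohort(
    n: int,
    a: float,
    b: float,
    censor_time: float | None = None,
    seed: int | np.random.Generator = 0,
    diet: str = "AL",
    tumor_mean: float | None = None,
    id_prefix: str | None = None,
) -> pd.DataFrame:
    """Simulate one diet arm of a lifespan cohort.

    Lifespans are drawn by inverting the Gompertz survivor function on
    uniform deviates,

        T = (1/b) * log(1 - (b/a) * log(U)),

    which reduces to the exponential draw -log(U)/a when ``b == 0``.
    Records with ``T >= censor_time`` are administratively censored at
    ``censor_time``. Deaths are assigned a cause label (``neoplastic`` or
    ``other``, 70/30) and, when ``tumor_mean`` is given, a Poisson tumor
    count; censored records carry neither.

    Returns a table with columns ``animal_id, diet, time_days, event,
    cause, tumor_count`` (event: 1 = death, 0 = censored).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if a <= 0:
        raise ValueError("baseline hazard a must be > 0")
    if b < 0:
        raise ValueError("slope b must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.uniform(size=n)
    if b == 0:
        t = -np.log(u) / a
    else:
        t = np.log1p(-(b / a) * np.log(u)) / b
    event = np.ones(n, dtype=int)
    if censor_time is not None:
        censored = t >= censor_time
        t = np.where(censored, censor_time, t)
        event = np.where(censored, 0, 1)
    cause = np.where(
        rng.uniform(size=n) < 0.7, "neoplastic", "other"
    ).astype(object)
    cause[event == 0] = None
    if tumor_mean is not None:
        tumors = generate_tumor_counts(n, tumor_mean, rng).astype(object)
        tumors[event == 0] = None
    else:
        tumors = np.full(n, None, dtype=object)
    prefix = id_prefix if id_prefix is not None else diet
    return pd.DataFrame(
        {
            "animal_id": [f"{prefix}-{i + 1:03d}" for i in range(n)],
            "diet": diet,
            "time_days": t,
            "event": event,
            "cause": cause,
            "tumor_count": tumors,
        }
    )


def generate_trait_panel(
    specs: list[TraitSpec],
    n_per_group: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a long-format 2x2 factorial phenotype panel.

    For each trait the four cell means are::

        young/AL  : baseline
        old/AL    : baseline + sd * d_age
        young/EOD : baseline + sd * d_diet_young
        old/EOD   : baseline + sd * (d_age + d_diet_old)

    with iid Gaussian noise of the trait's SD in every cell (the
    homoscedasticity the two-way ANOVA assumes). Animals are shared
    across traits within a cell (same ``animal_id``), as in a real
    deep-phenotyping screen, and assigned round-robin to four cages per
    group for bookkeeping.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    ids = [s.trait_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trait_id")
    for s in specs:
        s.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    cells = [("young", "AL"), ("young", "EOD"), ("old", "AL"), ("old", "EOD")]
    frames = []
    for spec in specs:
        shift = {
            ("young", "AL"): 0.0,
            ("young", "EOD"): spec.d_diet_young,
            ("old", "AL"): spec.d_age,
            ("old", "EOD"): spec.d_age + spec.d_diet_old,
        }
        for age, diet in cells:
            mu = spec.baseline_mean + spec.sd * shift[(age, diet)]
            vals = rng.normal(mu, spec.sd, size=n_per_group)
            frames.append(
                pd.DataFrame(
                    {
                        "animal_id": [
                            f"{age[0]}{diet}-{i + 1:03d}" for i in range(n_per_group)
                        ],
                        "trait_id": spec.trait_id,
                        "age": age,
                        "diet": diet,
                        "cage": [
                            f"{age[0]}{diet}-c{i % 4 + 1}" for i in range(n_per_group)
                        ],
                        "value": vals,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_longitudinal_weights(
    cages_per_arm: int,
    mice_per_cage: int,
    weeks: int,
    dr_effect: float,
    cage_sd: float,
    resid_sd: float,
    seed: int | np.random.Generator = 0,
    baseline_g: float = 30.0,
    growth_g_per_week: float = 0.05,
) -> pd.DataFrame:
    """Simulate cage-clustered weekly body weights for two diet arms.

    weight(mouse, week) = baseline + growth*week + dr_effect*[EOD]
                          + cage intercept (SD ``cage_sd``)
                          + residual (SD ``resid_sd``)

    Returns long format with columns ``diet, cage, mouse_id, week,
    weight_g``; rows ``cages_per_arm * mice_per_cage * weeks`` per arm.
    """
    if min(cages_per_arm, mice_per_cage, weeks) < 1:
        raise ValueError("cages_per_arm, mice_per_cage and weeks must be >= 1")
    if cage_sd < 0 or resid_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    week_idx = np.arange(weeks)
    for diet in ("AL", "EOD"):
        arm_shift = dr_effect if diet == "EOD" else 0.0
        for c in range(cages_per_arm):
            cage_eff = rng.normal(0.0, cage_sd) if cage_sd > 0 else 0.0
            for m in range(mice_per_cage):
                noise = (
                    rng.normal(0.0, resid_sd, size=weeks) if resid_sd > 0 else 0.0
                )
                w = baseline_g + growth_g_per_week * week_idx + arm_shift + cage_eff + noise
                rows.append(
                    pd.DataFrame(
                        {
                            "diet": diet,
                            "cage": f"{diet}-c{c + 1:02d}",
                            "mouse_id": f"{diet}-c{c + 1:02d}-m{m + 1}",
                            "week": week_idx,
                            "weight_g": w,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def generate_tumor_counts(
    n: int, mean_burden: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Poisson tumor counts per animal with the given mean burden."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_burden < 0:
        raise ValueError("mean_burden must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if mean_burden == 0:
        return np.zeros(n, dtype=int)
    return rng.poisson(mean_burden, size=n)


# ---------------------------------------------------------------------------
# Default scenario panel


def default_trait_specs(
    n_prevented: int = 7,
    n_age_independent: int = 33,
    n_unchanged: int = 62,
    n_exacerbated: int = 14,
    n_diet_only: int = 36,
    n_null: int = 87,
    effect: float = 1.5,
    seed: int = 0,
) -> list[TraitSpec]:
    """Build a 239-trait panel mixing categories in the study's proportions.

    Of 239 phenotypes, 116 are aging traits (7 prevented + 33 opposed
    age-independently + 76 not measurably improved, 14 of those
    exacerbated), 89 are diet-modified. Signs of the aging/diet effects
    alternate pseudo-randomly so that both directions occur.
    """
    rng = np.random.default_rng(seed)
    specs: list[TraitSpec] = []

    def sign() -> float:
        return 1.0 if rng.uniform() < 0.5 else -1.0

    plan = [
        ("PREVENTED", n_prevented),
        ("AGE_INDEPENDENT", n_age_independent),
        ("UNCHANGED_AGING", n_unchanged),
        ("EXACERBATED", n_exacerbated),
        ("DIET_ONLY", n_diet_only),
        ("NULL", n_null),
    ]
    k = 0
    for cat, count in plan:
        for _ in range(count):
            k += 1
            s = sign()
            if cat == "PREVENTED":
                eff = dict(d_age=s * effect, d_diet_old=-s * effect, d_diet_young=0.0)
            elif cat == "AGE_INDEPENDENT":
                eff = dict(
                    d_age=s * effect, d_diet_old=-s * effect, d_diet_young=-s * effect
                )
            elif cat == "UNCHANGED_AGING":
                eff = dict(d_age=s * effect, d_diet_old=0.0, d_diet_young=0.0)
            elif cat == "EXACERBATED":
                eff = dict(d_age=s * effect, d_diet_old=s * effect, d_diet_young=0.0)
            elif cat == "DIET_ONLY":
                eff = dict(d_age=0.0, d_diet_old=s * effect, d_diet_young=s * effect)
            else:
                eff = dict(d_age=0.0, d_diet_old=0.0, d_diet_young=0.0)
            specs.append(
                TraitSpec(
                    trait_id=f"T{k:03d}_{cat.lower()}",
                    true_category=cat,
                    baseline_mean=float(rng.normal(0, 10)),
                    sd=1.0,
                    **eff,
                )
            )
    return specs
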