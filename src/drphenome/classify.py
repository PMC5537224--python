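"""Aging-trait classification.

Every phenotype in the screen is sorted into one of five classes by how
it responds to age and to the dietary intervention:

(i)   PREVENTED        — aging trait rescued by the diet in old, long-
                         treated animals only (no effect in young);
(ii)  AGE_INDEPENDENT  — aging trait opposed by the diet with similar
                         outcomes in young, short-treated animals, which
                         is not evidence of slowed aging;
(iii) UNCHANGED_AGING  — aging trait not measurably improved;
      EXACERBATED      — aging trait pushed further in the direction of
                         aging by the diet (a subset of the not-improved
                         aging traits, flagged separately);
(iv)  DIET_ONLY        — modified by diet but not by age;
(v)   NULL             — modified by neither.

"Aging trait" is operationalized as a significant old/AL vs young/AL
post hoc contrast (the control-arm aging signal, uncontaminated by the
diet); an age-main-effect definition is available behind a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factorial import fisher_exact_2x2, tukey_hsd, two_way_anova

__all__ = [
    "TraitOutcome",
    "TraitClass",
    "trait_outcome",
    "trait_outcome_binary",
    "classify_trait",
    "classify_panel",
    "venn_counts",
]

CELL_ORDER = (("young", "AL"), ("young", "EOD"), ("old", "AL"), ("old", "EOD"))

#: the three directional contrasts the classifier consumes
CONTRASTS = {
    "age": (("young", "AL"), ("old", "AL")),
    "diet_young": (("young", "AL"), ("young", "EOD")),
    "diet_old": (("old", "AL"), ("old", "EOD")),
}


@dataclass
class TraitOutcome:
    """Factorial evidence for one trait: omnibus p-values and contrasts.

    ``contrasts`` maps contrast name -> (direction, p) where direction is
    the sign (+1/0/-1) of the second group's mean (or proportion) minus
    the first group's.
    """

    trait_id: str
    p_age_main: float = float("nan")
    p_diet_main: float = float("nan")
    p_interaction: float = float("nan")
    contrasts: dict = field(default_factory=dict)
    dir_diet_main: int = 0
    family: str = "anova"
    testable: bool = True


@dataclass
class TraitClass:
    trait_id: str
    category: str
    is_aging_trait: bool
    is_diet_modified: bool
    is_ameliorated: bool


def _direction(diff: float, tol: float = 0.0) -> int:
    if diff > tol:
        return 1
    if diff < -tol:
        return -1
    return 0


def trait_outcome(panel_slice: pd.DataFrame, alpha: float = 0.05) -> TraitOutcome:
    """Run the factorial battery on one continuous trait.

    ``panel_slice`` holds one trait in long format (columns ``age``,
    ``diet``, ``value``; all four cells present). Returns the two-way
    ANOVA p-values plus the three Tukey HSD contrasts with signed
    directions. A constant (zero-variance) trait is flagged untestable.
    """
    trait_id = (
        str(panel_slice["trait_id"].iloc[0])
        if "trait_id" in panel_slice
        else "trait"
    )
    vals = panel_slice["value"].to_numpy(dtype=float)
    keep = ~np.isnan(vals)
    if not keep.all():
        panel_slice = panel_slice.loc[keep]
        vals = vals[keep]
    if np.nanstd(vals) == 0:
        return TraitOutcome(
            trait_id=trait_id,
            contrasts={k: (0, 1.0) for k in CONTRASTS},
            testable=False,
        )
    age_arr = panel_slice["age"].to_numpy()
    diet_arr = panel_slice["diet"].to_numpy()
    anova = two_way_anova(vals, age_arr, diet_arr)
    cells = {
        (a, d): vals[(age_arr == a) & (diet_arr == d)] for a, d in CELL_ORDER
    }
    pairs = [tuple("/".join(g) for g in gg) for gg in CONTRASTS.values()]
    tk = tukey_hsd(
        {f"{a}/{d}": v for (a, d), v in cells.items()}, pairs=pairs, approx=True
    )
    contrasts = {}
    for (name, (g1, g2)), row in zip(CONTRASTS.items(), tk.itertuples()):
        diff = float(cells[g2].mean() - cells[g1].mean())
        contrasts[name] = (_direction(diff), float(row.p_adj))
    eod = vals[diet_arr == "EOD"]
    al = vals[diet_arr == "AL"]
    return TraitOutcome(
        trait_id=trait_id,
        p_age_main=anova.p("age"),
        p_diet_main=anova.p("diet"),
        p_interaction=anova.p("age:diet"),
        contrasts=contrasts,
        dir_diet_main=_direction(float(eod.mean() - al.mean())),
        family="anova",
    )


def trait_outcome_binary(counts: dict, trait_id: str = "trait") -> TraitOutcome:
    """Factorial evidence for a presence/absence trait via Fisher's exact test.

    ``counts`` maps (age, diet) -> (n_present, n_total) for the four
    cells. Margin p-values come from Fisher's exact test on the pooled
    age and diet 2x2 tables; each directional contrast is a Fisher test
    between its two cells with the sign of the proportion difference.
    """

    def cell_table(g1, g2):
        (k1, n1), (k2, n2) = counts[g1], counts[g2]
        return np.array([[k1, n1 - k1], [k2, n2 - k2]])

    def margin_table(selector):
        tab = np.zeros((2, 2), dtype=int)
        for (age, diet), (k, n) in counts.items():
            i = selector(age, diet)
            tab[i, 0] += k
            tab[i, 1] += n - k
        return tab

    if all(n == 0 or k in (0, n) for k, n in counts.values()) and (
        len({(k > 0) for k, n in counts.values() if n}) <= 1
    ):
        # all cells saturated the same way: nothing to test
        return TraitOutcome(
            trait_id=trait_id,
            contrasts={k: (0, 1.0) for k in CONTRASTS},
            family="fisher",
            testable=False,
        )
    _, p_age = fisher_exact_2x2(margin_table(lambda a, d: int(a == "old")))
    _, p_diet = fisher_exact_2x2(margin_table(lambda a, d: int(d == "EOD")))
    contrasts = {}
    for name, (g1, g2) in CONTRASTS.items():
        tab = cell_table(g1, g2)
        _, p = fisher_exact_2x2(tab)
        p1 = counts[g1][0] / max(counts[g1][1], 1)
        p2 = counts[g2][0] / max(counts[g2][1], 1)
        contrasts[name] = (_direction(p2 - p1), float(p))
    eod_k = sum(k for (a, d), (k, n) in counts.items() if d == "EOD")
    eod_n = sum(n for (a, d), (k, n) in counts.items() if d == "EOD")
    al_k = sum(k for (a, d), (k, n) in counts.items() if d == "AL")
    al_n = sum(n for (a, d), (k, n) in counts.items() if d == "AL")
    return TraitOutcome(
        trait_id=trait_id,
        p_age_main=p_age,
        p_diet_main=p_diet,
        p_interaction=float("nan"),
        contrasts=contrasts,
        dir_diet_main=_direction(eod_k / max(eod_n, 1) - al_k / max(al_n, 1)),
        family="fisher",
    )


def classify_trait(
    outcome: TraitOutcome,
    alpha: float = 0.05,
    aging_by_main_effect: bool = False,
) -> TraitClass | None:
    """Apply the five-way decision table to one trait's evidence.

    Decision order for an aging trait (significant old/AL vs young/AL
    contrast): a significant old-arm diet contrast in the direction of
    the aging change means EXACERBATED; one opposing it means PREVENTED
    when the young-arm diet contrast is non-significant and
    AGE_INDEPENDENT when it is significant (the diet acts in the young
    too); an aging trait without a significant old-arm diet contrast is
    AGE_INDEPENDENT when a significant diet main effect comes without an
    interaction and opposes the aging direction, otherwise
    UNCHANGED_AGING. Non-aging traits are DIET_ONLY when any diet term is
    significant, else NULL. Untestable outcomes yield ``None`` with a
    warning.
    """
    if not outcome.testable:
        warnings.warn(f"trait {outcome.trait_id}: untestable; category withheld")
        return None
    dir_age, p_age_c = outcome.contrasts["age"]
    dir_dy, p_dy = outcome.contrasts["diet_young"]
    dir_do, p_do = outcome.contrasts["diet_old"]

    if aging_by_main_effect:
        aging = outcome.p_age_main < alpha
        if dir_age == 0:
            aging = False
    else:
        aging = p_age_c < alpha and dir_age != 0

    diet_sig = (
        outcome.p_diet_main < alpha
        or (np.isfinite(outcome.p_interaction) and outcome.p_interaction < alpha)
        or p_dy < alpha
        or p_do < alpha
    )

    if aging:
        if p_do < alpha and dir_do != 0 and dir_do == dir_age:
            category = "EXACERBATED"
        elif p_do < alpha and dir_do != 0 and dir_do == -dir_age:
            category = "AGE_INDEPENDENT" if p_dy < alpha else "PREVENTED"
        elif (
            outcome.p_diet_main < alpha
            and not (
                np.isfinite(outcome.p_interaction)
                and outcome.p_interaction < alpha
            )
            and outcome.dir_diet_main == -dir_age
            and outcome.dir_diet_main != 0
        ):
            category = "AGE_INDEPENDENT"
        else:
            category = "UNCHANGED_AGING"
    else:
        category = "DIET_ONLY" if diet_sig else "NULL"

    return TraitClass(
        trait_id=outcome.trait_id,
        category=category,
        is_aging_trait=aging,
        is_diet_modified=diet_sig,
        is_ameliorated=category in ("PREVENTED", "AGE_INDEPENDENT"),
    )


def classify_panel(
    panel: pd.DataFrame, alpha: float = 0.05, aging_by_main_effect: bool = False
):
    """Classify every trait of a long-format panel.

    Returns ``(outcomes, classes)`` lists; untestable traits appear in
    ``outcomes`` but not in ``classes``.
    """
    outcomes, classes = [], []
    for trait_id, grp in panel.groupby("trait_id", sort=True):
        out = trait_outcome(grp, alpha=alpha)
        outcomes.append(out)
        cls = classify_trait(out, alpha=alpha, aging_by_main_effect=aging_by_main_effect)
        if cls is not None:
            classes.append(cls)
    return outcomes, classes


def venn_counts(classes) -> dict:
    """Summary counts behind the aging/diet Venn bookkeeping.

    ``ameliorated = prevented + age_independent``;
    ``aging = ameliorated + unchanged + exacerbated`` (the exacerbated
    traits are a separately flagged subset of the not-improved aging
    traits); ``overlap_aging_diet`` counts aging traits that also carry a
    significant diet term.
    """
    cats = [c.category for c in classes]
    n = dict(
        total=len(classes),
        prevented=cats.count("PREVENTED"),
        age_independent=cats.count("AGE_INDEPENDENT"),
        unchanged=cats.count("UNCHANGED_AGING"),
        exacerbated=cats.count("EXACERBATED"),
        diet_only=cats.count("DIET_ONLY"),
        null=cats.count("NULL"),
    )
    n["ameliorated"] = n["prevented"] + n["age_independent"]
    n["not_improved"] = n["unchanged"] + n["exacerbated"]
    n["aging"] = sum(c.is_aging_trait for c in classes)
    n["diet_modified"] = sum(c.is_diet_modified for c in classes)
    n["overlap_aging_diet"] = sum(
        c.is_aging_trait and c.is_diet_modified for c in classes
    )
    return n
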