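"""Effect-size meta-analysis across the trait panel.

For each trait three standardized mean differences (Cohen's d, pooled
SD) are computed: the aging effect in the control arm (old/AL vs
young/AL), the diet effect in young animals (young/EOD vs young/AL) and
the diet effect in old animals (old/EOD vs old/AL). Cross-trait Pearson
correlations of these effect sizes summarize whether the intervention
opposes aging (d_age vs d_eod_old negative on aging traits) and whether
its action is age-independent (d_eod_young vs d_eod_old positive on
diet-modified traits).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "cohens_d",
    "hedges_g",
    "probit_d",
    "effect_size_table",
    "correlate_effects",
]


def cohens_d(group_a, group_b) -> float:
    """Cohen's d = (mean_b - mean_a) / pooled SD.

    Pooled SD uses Bessel-corrected group variances,
    sqrt(((n_a-1)s_a^2 + (n_b-1)s_b^2) / (n_a+n_b-2)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 <= 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float((b.mean() - a.mean()) / np.sqrt(sp2))


def hedges_g(group_a, group_b) -> float:
    """Small-sample-corrected d (Hedges g): d * (1 - 3/(4(n_a+n_b)-9))."""
    a, b = np.asarray(group_a), np.asarray(group_b)
    J = 1.0 - 3.0 / (4.0 * (a.size + b.size) - 9.0)
    return cohens_d(group_a, group_b) * J


def probit_d(k_a: int, n_a: int, k_b: int, n_b: int) -> float:
    """Standardized effect for a binary trait via the probit transform.

    d = Phi^{-1}(p_b) - Phi^{-1}(p_a) with proportions continuity-
    corrected by 1/(2n) at 0 and 1. Used for traits tested by Fisher's
    exact test so they can enter the effect-size scatter alongside
    continuous traits; flagged distinctly by the caller.
    """
    def z(k, n):
        p = np.clip(k / n, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
        return stats.norm.ppf(p)

    if min(n_a, n_b) < 1:
        raise ValueError("group sizes must be >= 1")
    return float(z(k_b, n_b) - z(k_a, n_a))


def effect_size_table(panel: pd.DataFrame) -> pd.DataFrame:
    """One (d_age, d_eod_young, d_eod_old) triple per trait of a panel.

    Traits with an undefined d (constant cells) are excluded, with the
    excluded count logged. Returns a DataFrame indexed by ``trait_id``.
    """
    rows = []
    dropped = 0
    for trait_id, grp in panel.groupby("trait_id", sort=True):
        cells = {
            (a, d): grp.query("age == @a and diet == @d")["value"].to_numpy(float)
            for a in ("young", "old")
            for d in ("AL", "EOD")
        }
        try:
            rows.append(
                {
                    "trait_id": trait_id,
                    "d_age": cohens_d(cells[("young", "AL")], cells[("old", "AL")]),
                    "d_eod_young": cohens_d(
                        cells[("young", "AL")], cells[("young", "EOD")]
                    ),
                    "d_eod_old": cohens_d(cells[("old", "AL")], cells[("old", "EOD")]),
                }
            )
        except ValueError:
            dropped += 1
    if dropped:
        logger.warning("effect_size_table: %d trait(s) with undefined d excluded", dropped)
    return pd.DataFrame(rows).set_index("trait_id") if rows else pd.DataFrame(
        columns=["d_age", "d_eod_young", "d_eod_old"]
    )


def correlate_effects(
    table: pd.DataFrame,
    x: str,
    y: str,
    subset=None,
    method: str = "pearson",
):
    """Correlation of two effect-size columns over an optional trait subset.

    ``subset`` is a boolean mask or an iterable of trait ids. Returns
    ``(r, p, n)``.
    """
    t = table
    if subset is not None:
        if hasattr(subset, "dtype") and getattr(subset, "dtype", None) == bool:
            t = table[subset]
        else:
            t = table.loc[table.index.intersection(pd.Index(subset))]
    t = t[[x, y]].dropna()
    if len(t) < 3:
        raise ValueError("need at least 3 trait pairs")
    if method == "pearson":
        r, p = stats.pearsonr(t[x], t[y])
    elif method == "spearman":
        r, p = stats.spearmanr(t[x], t[y])
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), int(len(t))
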