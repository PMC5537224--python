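"""Factorial statistics for the 2x2 (age x diet) phenotype screen.

The screen tests every trait with a two-way between-subjects ANOVA
(factors: age old/young and diet EOD/AL), Tukey HSD post hoc contrasts,
Fisher's exact test for presence/absence traits, a three-way split-plot
ANOVA (two between-subjects factors plus one within-subjects factor,
Greenhouse-Geisser corrected) for repeated measurements such as
startle-response sound-intensity series, and a crossed random-intercept
mixed model for cage-clustered longitudinal body weights.

Balanced two-way designs use the textbook orthogonal decomposition
(fast, exact); unbalanced designs use marginal (Type-III) sums of
squares with sum-to-zero coding via statsmodels OLS — the convention in
the mouse-phenotyping literature, where cell sizes routinely differ.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANOVAResult",
    "MixedFitResult",
    "two_way_anova",
    "tukey_hsd",
    "fisher_exact_2x2",
    "gg_epsilon",
    "mixed_rm_anova",
    "fit_longitudinal_mixed",
]


@dataclass
class TermStat:
    term: str
    ss: float
    df: float
    F: float = float("nan")
    p: float = float("nan")
    epsilon: float | None = None  # Greenhouse-Geisser, within terms only
    p_gg: float | None = None


@dataclass
class ANOVAResult:
    """Per-term ANOVA table with residual row included under term 'residual'."""

    terms: list[TermStat] = field(default_factory=list)

    def __getitem__(self, term: str) -> TermStat:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(term)

    def p(self, term: str) -> float:
        return self[term].p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.terms])


@dataclass
class MixedFitResult:
    """Fixed diet effect and variance components of the longitudinal model."""

    dr_effect: float
    se: float
    p: float
    var_cage: float
    var_week: float
    var_resid: float
    converged: bool
    method: str


# ---------------------------------------------------------------------------
# Two-way between-subjects ANOVA


def _validate_cells(values, age, diet):
    values = np.asarray(values, dtype=float)
    age = np.asarray(age)
    diet = np.asarray(diet)
    if not (len(values) == len(age) == len(diet)):
        raise ValueError("values and factors must have equal length")
    keep = ~np.isnan(values)
    values, age, diet = values[keep], age[keep], diet[keep]
    a_levels = sorted(set(age.tolist()))
    d_levels = sorted(set(diet.tolist()))
    if len(a_levels) != 2 or len(d_levels) != 2:
        raise ValueError("both factors must have exactly two observed levels")
    cells = {}
    for ai, di in itertools.product(a_levels, d_levels):
        cell = values[(age == ai) & (diet == di)]
        if cell.size < 2:
            raise ValueError(f"cell ({ai}, {di}) has fewer than 2 observations")
        cells[(ai, di)] = cell
    return values, age, diet, a_levels, d_levels, cells


def _balanced_decomposition(cells, a_levels, d_levels) -> ANOVAResult:
    n = len(next(iter(cells.values())))
    m = {k: v.mean() for k, v in cells.items()}
    grand = np.mean(list(m.values()))
    row = {a: np.mean([m[(a, d)] for d in d_levels]) for a in a_levels}
    col = {d: np.mean([m[(a, d)] for a in a_levels]) for d in d_levels}
    ss_a = 2 * n * sum((row[a] - grand) ** 2 for a in a_levels)
    ss_b = 2 * n * sum((col[d] - grand) ** 2 for d in d_levels)
    ss_ab = n * sum(
        (m[(a, d)] - row[a] - col[d] + grand) ** 2
        for a in a_levels
        for d in d_levels
    )
    ss_e = sum(((v - m[k]) ** 2).sum() for k, v in cells.items())
    df_e = 4 * (n - 1)
    ms_e = ss_e / df_e
    zero_tol = 1e-10 * max(1.0, sum(float((v**2).sum()) for v in cells.values()))
    res = ANOVAResult()
    for name, ss in (("age", ss_a), ("diet", ss_b), ("age:diet", ss_ab)):
        if ss <= zero_tol:
            F = 0.0
        elif ms_e > zero_tol / df_e:
            F = ss / ms_e
        else:
            F = float("inf")
        p = float(stats.f.sf(F, 1, df_e)) if np.isfinite(F) else 0.0
        res.terms.append(TermStat(name, float(ss), 1, float(F), p))
    res.terms.append(TermStat("residual", float(ss_e), df_e))
    return res


def _type3_regression(values, age, diet, a_levels, d_levels) -> ANOVAResult:
    # sum-to-zero coding; Type-III SS by full-vs-reduced RSS comparison
    xa = np.where(age == a_levels[0], 1.0, -1.0)
    xd = np.where(diet == d_levels[0], 1.0, -1.0)
    X = np.column_stack([np.ones_like(xa), xa, xd, xa * xd])

    def rss(cols):
        beta, res_, *_ = np.linalg.lstsq(X[:, cols], values, rcond=None)
        fitted = X[:, cols] @ beta
        return float(((values - fitted) ** 2).sum())

    full = rss([0, 1, 2, 3])
    df_e = len(values) - 4
    ms_e = full / df_e
    zero_tol = 1e-10 * max(1.0, float((values**2).sum()))
    res = ANOVAResult()
    for name, drop in (("age", 1), ("diet", 2), ("age:diet", 3)):
        ss = rss([c for c in range(4) if c != drop]) - full
        ss = max(ss, 0.0)
        if ss <= zero_tol:
            F = 0.0
        elif ms_e > zero_tol / df_e:
            F = ss / ms_e
        else:
            F = float("inf")
        p = float(stats.f.sf(F, 1, df_e)) if np.isfinite(F) else 0.0
        res.terms.append(TermStat(name, ss, 1, float(F), p))
    res.terms.append(TermStat("residual", full, df_e))
    return res


def two_way_anova(values, age, diet) -> ANOVAResult:
    """Two-way between-subjects ANOVA (age x diet), both factors two-level.

    Balanced designs use the orthogonal textbook decomposition;
    unbalanced designs use marginal (Type-III) sums of squares with
    sum-to-zero coding, under which the two coincide on balanced data.
    Missing values are dropped listwise.
    """
    values, age, diet, a_levels, d_levels, cells = _validate_cells(values, age, diet)
    sizes = {len(v) for v in cells.values()}
    if len(sizes) == 1:
        return _balanced_decomposition(cells, a_levels, d_levels)
    return _type3_regression(values, age, diet, a_levels, d_levels)


# ---------------------------------------------------------------------------
# Post hoc and exact tests


_SR_CACHE: dict = {}


def _studentized_range_sf(q, k: int, df: int, approx: bool):
    """Upper tail of the studentized range; optionally via a cached interpolant.

    The interpolated path (monotone cubic on a 241-point grid, max abs
    error ~2e-6) exists because screening a multi-hundred-trait panel
    evaluates this tail thousands of times and the exact integral costs
    ~10 ms per point.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if not approx:
        return stats.studentized_range.sf(q, k, df)
    key = (k, df)
    if key not in _SR_CACHE:
        from scipy.interpolate import PchipInterpolator

        grid = np.linspace(0.0, 10.0, 241)
        _SR_CACHE[key] = PchipInterpolator(grid, stats.studentized_range.sf(grid, k, df))
    out = np.where(q >= 10.0, 0.0, np.clip(_SR_CACHE[key](np.minimum(q, 10.0)), 0.0, 1.0))
    return out


def tukey_hsd(samples: dict, pairs=None, approx: bool = False) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for pairwise group comparisons.

    ``samples`` maps group label -> 1-D array (each >= 2 observations);
    ``pairs`` optionally restricts the table to the given (label, label)
    tuples (the adjustment still spans all k groups). The statistic is
    the Tukey-Kramer studentized range

        q_ij = |m_i - m_j| / sqrt(s^2/2 * (1/n_i + 1/n_j)),

    with s^2 the pooled within-group mean square on N - k df, referred to
    the studentized range distribution with k groups. ``approx=True``
    uses a cached interpolant of the range distribution's tail (error
    ~2e-6), worthwhile when screening large trait panels.

    Returns a table with columns ``group_a, group_b, diff, p_adj``
    (diff = mean_b - mean_a).
    """
    labels = list(samples)
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    k = len(labels)
    n_tot = sum(a.size for a in arrays.values())
    df_err = n_tot - k
    ms_err = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_err
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    rows, qs = [], []
    for ga, gb in pairs:
        a, b = arrays[ga], arrays[gb]
        diff = float(b.mean() - a.mean())
        se = np.sqrt(ms_err / 2.0 * (1.0 / a.size + 1.0 / b.size))
        qs.append(np.abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf))
        rows.append({"group_a": ga, "group_b": gb, "diff": diff})
    qs = np.asarray(qs)
    ps = np.ones_like(qs)
    finite = np.isfinite(qs)
    ps[~finite] = 0.0
    if finite.any():
        ps[finite] = _studentized_range_sf(qs[finite], k, df_err, approx)
    for row, p in zip(rows, ps):
        row["p_adj"] = float(p)
    return pd.DataFrame(rows)


def fisher_exact_2x2(table):
    """Fisher's exact test on a 2x2 count table.

    Two-sided p by probability-mass ordering: the sum of hypergeometric
    probabilities of all tables (at fixed margins) no more probable than
    the observed one. The odds ratio is the sample (a*d)/(b*c), reported
    as inf (or nan for 0/0) at zero margins.

    Returns ``(odds_ratio, p_two_sided)``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or t.sum() == 0:
        raise ValueError("entries must be non-negative with a positive total")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# Repeated measures: Greenhouse-Geisser and the split-plot ANOVA


def _helmert_contrasts(k: int) -> np.ndarray:
    """Orthonormal (k-1) x k contrast matrix orthogonal to the unit vector."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def gg_epsilon(cov: np.ndarray, k: int | None = None) -> float:
    """Greenhouse-Geisser sphericity epsilon from a within-subject covariance.

    The k x k covariance of the repeated measures is orthonormally
    contrasted; epsilon = (tr V)^2 / ((k-1) tr V^2) with V = C S C',
    clipped to [1/(k-1), 1]. Equals 1 under compound symmetry and
    1/(k-1) when the contrasted covariance is rank one.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
        raise ValueError("covariance must be symmetric")
    if k is None:
        k = S.shape[0]
    if k < 2:
        raise ValueError("need at least two within-subject levels")
    C = _helmert_contrasts(k)
    V = C @ S @ C.T
    tr = np.trace(V)
    tr2 = np.trace(V @ V)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mixed_rm_anova(
    df: pd.DataFrame,
    value: str = "value",
    age: str = "age",
    diet: str = "diet",
    within: str = "level",
    subject: str = "subject",
) -> ANOVAResult:
    """Three-way split-plot ANOVA: age x diet between, one within factor.

    Uses the univariate approach: between-subject terms are tested on the
    subject means (marginal Type-III sums of squares); within-involving
    terms are tested on orthonormally contrasted scores with the
    Greenhouse-Geisser epsilon applied unconditionally to their degrees
    of freedom (``p_gg``; the uncorrected ``p`` is reported alongside).
    Requires complete data: every subject measured at every within level.
    """
    levels = sorted(df[within].unique().tolist())
    k = len(levels)
    wide = df.pivot_table(index=subject, columns=within, values=value, aggfunc="mean")
    counts = df.groupby(subject)[within].nunique()
    incomplete = counts[counts != k].index.tolist()
    if incomplete or wide.isna().any().any():
        missing = incomplete or wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"subjects with missing within-levels: {missing}")
    meta = df.drop_duplicates(subject).set_index(subject).loc[wide.index]
    Y = wide.to_numpy(dtype=float)
    subj_means = Y.mean(axis=1)

    if k == 1:
        return two_way_anova(subj_means, meta[age], meta[diet])

    # between-subject part: ANOVA on subject means, SS rescaled by k
    between = two_way_anova(subj_means, meta[age], meta[diet])
    res = ANOVAResult()
    for t in between.terms:
        name = t.term if t.term != "residual" else "residual_between"
        res.terms.append(TermStat(name, t.ss * k, t.df, t.F, t.p))

    # within part: Type-III on contrast scores
    a_levels = sorted(meta[age].unique().tolist())
    d_levels = sorted(meta[diet].unique().tolist())
    if len(a_levels) != 2 or len(d_levels) != 2:
        raise ValueError("both between factors must have exactly two levels")
    xa = np.where(meta[age].to_numpy() == a_levels[0], 1.0, -1.0)
    xd = np.where(meta[diet].to_numpy() == d_levels[0], 1.0, -1.0)
    X = np.column_stack([np.ones_like(xa), xa, xd, xa * xd])
    n = len(xa)
    if n <= 4:
        raise ValueError("need more than 4 subjects")
    C = _helmert_contrasts(k)
    Z = Y @ C.T  # n x (k-1)

    def rss(cols):
        beta, *_ = np.linalg.lstsq(X[:, cols], Z, rcond=None)
        R = Z - X[:, cols] @ beta
        return float((R**2).sum()), R

    full_rss, R = rss([0, 1, 2, 3])
    df_e = (n - 4) * (k - 1)
    ms_e = full_rss / df_e
    # SS below float noise relative to the data's scale count as exactly zero
    zero_tol = 1e-10 * max(1.0, float((Y**2).sum()))
    E = (R.T @ R) / (n - 4)
    tr, tr2 = np.trace(E), np.trace(E @ E)
    eps = (
        float(np.clip(tr**2 / ((k - 1) * tr2), 1.0 / (k - 1), 1.0))
        if tr2 > 0
        else 1.0
    )
    wnames = {
        0: within,
        1: f"{within}:age",
        2: f"{within}:diet",
        3: f"{within}:age:diet",
    }
    for col, name in wnames.items():
        red, _ = rss([c for c in range(4) if c != col])
        ss = max(red - full_rss, 0.0)
        df_h = k - 1
        if ss <= zero_tol:
            F = 0.0
        elif ms_e > zero_tol / df_e:
            F = (ss / df_h) / ms_e
        else:
            F = float("inf")
        p = float(stats.f.sf(F, df_h, df_e)) if np.isfinite(F) else 0.0
        p_gg = (
            float(stats.f.sf(F, df_h * eps, df_e * eps)) if np.isfinite(F) else 0.0
        )
        res.terms.append(TermStat(name, ss, df_h, float(F), p, epsilon=eps, p_gg=p_gg))
    res.terms.append(TermStat("residual_within", full_rss, df_e))
    return res


# ---------------------------------------------------------------------------
# Longitudinal mixed model


def fit_longitudinal_mixed(
    df: pd.DataFrame,
    value: str = "weight_g",
    diet: str = "diet",
    cage: str = "cage",
    week: str = "week",
) -> MixedFitResult:
    """Crossed random-intercept model for cage-clustered weekly weights.

    value ~ diet (fixed) + (1 | cage) + (1 | week), fitted by REML via
    statsmodels MixedLM variance components (a single grouping column
    covering all rows makes the two intercepts crossed). Variance
    components are constrained non-negative by the optimizer. If the fit
    fails or does not converge, falls back to a two-sample comparison of
    cage-level mean weights, which is unbiased for the diet effect under
    the same model.
    """
    if df[cage].nunique() < 4 or df[week].nunique() < 2:
        raise ValueError("need >= 2 cages per arm and >= 2 weeks")
    d_levels = sorted(df[diet].unique().tolist())
    if len(d_levels) != 2:
        raise ValueError("diet must have exactly two levels")
    data = df[[value, diet, cage, week]].copy()
    data["_all"] = 1
    import statsmodels.formula.api as smf

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                f"{value} ~ C({diet})",
                data,
                groups="_all",
                re_formula="0",
                vc_formula={
                    "cage": f"0 + C({cage})",
                    "week": f"0 + C({week})",
                },
            )
            fit = model.fit(reml=True, method="lbfgs")
        term = f"C({diet})[T.{d_levels[1]}]"
        converged = bool(getattr(fit, "converged", True))
        vc = dict(zip(model.exog_vc.names, np.asarray(fit.vcomp, dtype=float)))
        if converged:
            return MixedFitResult(
                dr_effect=float(fit.params[term]),
                se=float(fit.bse[term]),
                p=float(fit.pvalues[term]),
                var_cage=float(max(vc.get("cage", 0.0), 0.0)),
                var_week=float(max(vc.get("week", 0.0), 0.0)),
                var_resid=float(fit.scale),
                converged=True,
                method="MixedLM-REML",
            )
    except Exception:  # noqa: BLE001 - any optimizer failure triggers fallback
        pass
    warnings.warn(
        "mixed model did not converge; falling back to cage-level means"
    )
    cage_means = data.groupby([diet, cage], observed=True)[value].mean()
    g0 = cage_means[d_levels[0]].to_numpy()
    g1 = cage_means[d_levels[1]].to_numpy()
    tt = stats.ttest_ind(g1, g0, equal_var=False)
    est = float(g1.mean() - g0.mean())
    se = float(
        np.sqrt(g1.var(ddof=1) / len(g1) + g0.var(ddof=1) / len(g0))
    )
    return MixedFitResult(
        dr_effect=est,
        se=se,
        p=float(tt.pvalue),
        var_cage=float("nan"),
        var_week=float("nan"),
        var_resid=float("nan"),
        converged=False,
        method="cage-means-fallback",
    )
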