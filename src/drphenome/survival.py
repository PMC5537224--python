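"""Lifespan statistics for a two-arm dietary-restriction cohort.

Kaplan-Meier curves and the log-rank test are delegated to lifelines;
mean/maximum lifespan summaries, the Gompertz mortality model and the
cause-of-death / tumor-burden endpoint summaries are implemented here.

The Gompertz model assumes a mortality hazard that rises exponentially
with age,

    h(t) = a * exp(b * t),

with baseline hazard ``a`` (per day) and slope ``b`` (per day). The
mortality rate doubling time, MDT = ln 2 / b, is the canonical summary
of the aging rate: dietary interventions that merely shift baseline
vulnerability change ``a`` but leave MDT untouched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

logger = logging.getLogger(__name__)

__all__ = [
    "GompertzFit",
    "GompertzFitter",
    "km_estimate",
    "logrank_test",
    "mean_lifespan",
    "max_lifespan",
    "fit_gompertz",
    "mortality_doubling_time",
    "endpoint_summaries",
]


def _times_events(records: pd.DataFrame):
    t = np.asarray(records["time_days"], dtype=float)
    e = np.asarray(records["event"], dtype=int)
    if t.size == 0:
        raise ValueError("empty survival table")
    return t, e


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a step-function table with columns ``time`` and ``survival``
    (right-continuous, starting at S(0) = 1). Censored records shrink the
    risk set without introducing a step.
    """
    t, e = _times_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(records_a: pd.DataFrame, records_b: pd.DataFrame):
    """Two-arm log-rank test; returns ``(chi2, p)``.

    Uses the hypergeometric-variance form with the standard correction
    for tied death times. An arm without any events yields a warning but
    still a defined statistic.
    """
    ta, ea = _times_events(records_a)
    tb, eb = _times_events(records_b)
    if ea.sum() == 0 or eb.sum() == 0:
        warnings.warn("one arm has no observed deaths; log-rank is degenerate")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def mean_lifespan(records: pd.DataFrame) -> float:
    """Mean of observed death times (days); censored animals are excluded."""
    t, e = _times_events(records)
    n_cens = int((e == 0).sum())
    if n_cens:
        logger.warning("mean_lifespan: excluding %d censored record(s)", n_cens)
    deaths = t[e == 1]
    if deaths.size == 0:
        raise ValueError("no death events; mean lifespan undefined")
    return float(deaths.mean())


def max_lifespan(
    records_a: pd.DataFrame, records_b: pd.DataFrame, fraction: float = 0.2
):
    """Maximum lifespan in the cohort-study sense: the longest-living 20%.

    Per arm, k = ceil(fraction * n_deaths) animals with the largest death
    times define the subset; the summary is the subset mean, and the two
    subsets are compared by a Welch two-sample t-test.

    Returns a dict with keys ``k_a, k_b, mean_a, mean_b, extension_days,
    t_stat, p_value``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    out = {}
    tops = []
    for label, rec in (("a", records_a), ("b", records_b)):
        t, e = _times_events(rec)
        deaths = np.sort(t[e == 1])
        if deaths.size == 0:
            raise ValueError(f"arm {label}: no deaths")
        k = int(np.ceil(fraction * deaths.size))
        top = deaths[-k:]
        tops.append(top)
        out[f"k_{label}"] = k
        out[f"mean_{label}"] = float(top.mean())
    out["extension_days"] = out["mean_b"] - out["mean_a"]
    if len(tops[0]) > 1 and len(tops[1]) > 1:
        tt = stats.ttest_ind(tops[1], tops[0], equal_var=False)
        out["t_stat"], out["p_value"] = float(tt.statistic), float(tt.pvalue)
    else:
        out["t_stat"], out["p_value"] = float("nan"), float("nan")
    return out


# ---------------------------------------------------------------------------
# Gompertz mortality model


@dataclass
class GompertzFit:
    """Maximum-likelihood Gompertz fit.

    ``mdt`` (mortality rate doubling time, days) is ln 2 / b.
    Standard errors come from the observed information at the optimum.
    """

    a: float
    b: float
    mdt: float
    loglik: float
    se_a: float
    se_b: float
    converged: bool
    n_deaths: int = 0
    n_censored: int = 0


class GompertzFitter:
    """Gompertz survival model fitted by constrained maximum likelihood.

    Log-likelihood (deaths d, censoring times c):

        sum_d [log a + b t - (a/b)(e^{bt} - 1)] - sum_c (a/b)(e^{bt} - 1)

    optimized over (log a, log b); the log parameterization keeps both
    rates positive without explicit bounds, and for effectively
    exponential data the slope estimate is driven toward zero rather
    than hitting a boundary. Initialization: ``a`` from the exponential
    (b = 0) fit deaths / total exposure, ``b`` = 1e-3 per day.
    """

    def __init__(self, tol: float = 1e-8):
        self.tol = tol

    @staticmethod
    def _negloglik(theta, t, e):
        loga, logb = theta
        a, b = np.exp(loga), np.exp(logb)
        cumhaz = (a / b) * np.expm1(b * t)
        ll = np.sum(e * (loga + b * t)) - np.sum(cumhaz)
        return -ll

    def fit(self, durations, event_observed) -> "GompertzFit":
        t = np.asarray(durations, dtype=float)
        e = np.asarray(event_observed, dtype=int)
        if e.sum() < 5:
            raise ValueError("need at least 5 death events to fit the Gompertz model")
        a0 = e.sum() / t.sum()
        x0 = np.array([np.log(a0), np.log(1e-3)])
        res = optimize.minimize(
            self._negloglik,
            x0,
            args=(t, e),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": self.tol, "maxiter": 4000},
        )
        converged = bool(res.success)
        if not converged:
            warnings.warn("Gompertz fit did not converge; returning best iterate")
        loga, logb = res.x
        a, b = float(np.exp(loga)), float(np.exp(logb))
        # observed information on the (log a, log b) scale -> delta method
        se_a = se_b = float("nan")
        try:
            H = approx_hess(res.x, self._negloglik, args=(t, e))
            cov = np.linalg.inv(H)
            if np.all(np.diag(cov) > 0):
                se_a = a * float(np.sqrt(cov[0, 0]))
                se_b = b * float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            pass
        return GompertzFit(
            a=a,
            b=b,
            mdt=float(np.log(2) / b),
            loglik=float(-res.fun),
            se_a=se_a,
            se_b=se_b,
            converged=converged,
            n_deaths=int(e.sum()),
            n_censored=int((e == 0).sum()),
        )


def fit_gompertz(records: pd.DataFrame, tol: float = 1e-8) -> GompertzFit:
    """Fit the Gompertz mortality model to one arm's survival table."""
    t, e = _times_events(records)
    return GompertzFitter(tol=tol).fit(t, e)


def mortality_doubling_time(fit: GompertzFit) -> float:
    """MDT = ln 2 / b (days); undefined for a flat (b = 0) hazard."""
    if fit.b <= 0:
        raise ValueError("hazard slope is zero; the hazard never doubles")
    return float(np.log(2) / fit.b)


# ---------------------------------------------------------------------------
# Endpoint summaries


def endpoint_summaries(records_a: pd.DataFrame, records_b: pd.DataFrame):
    """Cause-of-death proportions and tumor-burden comparison between arms.

    Proportions are computed over death records carrying a cause label
    and sum to 1 per arm. Tumor burdens are compared with a Welch
    two-sample t-test; a degenerate comparison (zero variance in both
    arms) is reported as p = 1 with a warning.

    Returns a dict: ``causes`` (arm -> {cause: proportion}),
    ``tumor_mean`` (arm -> mean), ``tumor_test`` -> (t, p).
    """
    causes = {}
    tumor_means = {}
    tumor_vals = {}
    for label, rec in (("a", records_a), ("b", records_b)):
        dead = rec[(rec["event"] == 1)]
        with_cause = dead[dead["cause"].notna()] if "cause" in dead else dead.iloc[0:0]
        if len(with_cause) == 0:
            warnings.warn(f"arm {label}: no cause-of-death labels")
            causes[label] = {}
        else:
            causes[label] = (
                with_cause["cause"].value_counts(normalize=True).to_dict()
            )
        if "tumor_count" in dead:
            vals = pd.to_numeric(dead["tumor_count"], errors="coerce").dropna()
        else:
            vals = pd.Series(dtype=float)
        tumor_vals[label] = vals.to_numpy(dtype=float)
        tumor_means[label] = float(vals.mean()) if len(vals) else float("nan")
    va, vb = tumor_vals["a"], tumor_vals["b"]
    if len(va) > 1 and len(vb) > 1 and (va.std() > 0 or vb.std() > 0):
        tt = stats.ttest_ind(va, vb, equal_var=False)
        tumor_test = (float(tt.statistic), float(tt.pvalue))
    else:
        warnings.warn("tumor-burden comparison degenerate; reporting p = 1")
        tumor_test = (0.0, 1.0)
    return {"causes": causes, "tumor_mean": tumor_means, "tumor_test": tumor_test}
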