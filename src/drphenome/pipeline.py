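"""End-to-end pipeline: simulate (or load) a cohort, analyze, report.

A run produces, under the output directory:

``survival.json``        arm lifespan summaries, log-rank, Gompertz fits
``km_<arm>.tsv``         Kaplan-Meier curve coordinates per diet arm
``anova_traits.tsv``     per-trait factorial test statistics
``classification.tsv``   per-trait category, flags, p-values, directions
``venn.json``            category counts (aging / diet-modified algebra)
``effect_sizes.tsv``     per-trait Cohen's d triples
``correlations.json``    cross-trait effect-size correlations
``longitudinal.json``    mixed-model diet effect on body weight
``summary.txt``          human-readable digest

All outputs are deterministic given the seed and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import effects as _effects
from . import io as _io
from . import simulate as _sim
from . import survival as _surv
from .factorial import fit_longitudinal_mixed

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of ``scenario`` (simulate everything) or the input paths
    must be provided. ``adjust`` toggles Benjamini-Hochberg correction of
    the per-trait contrast p-values before classification; the default
    ``none`` mirrors the per-trait alpha = 0.05 counting convention of
    phenotyping screens.
    """

    out_dir: str = "drphenome_out"
    seed: int = 0
    alpha: float = 0.05
    fraction: float = 0.2
    adjust: str = "none"
    scenario: _sim.ScenarioConfig | None = None
    survival_path: str | None = None
    phenotype_path: str | None = None
    longitudinal_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.adjust not in ("none", "bh"):
            raise ValueError("adjust must be 'none' or 'bh'")
        has_paths = any(
            p is not None
            for p in (self.survival_path, self.phenotype_path, self.longitudinal_path)
        )
        if (self.scenario is None) == (not has_paths):
            raise ValueError("provide exactly one of scenario or input paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            specs = scenario.pop("trait_specs", None)
            sc = _sim.ScenarioConfig(**scenario)
            if specs:
                sc.trait_specs = [_sim.TraitSpec(**s) for s in specs]
                for s in sc.trait_specs:
                    s.validate()
            scenario = sc
        return cls(scenario=scenario, **raw)


def _simulate_inputs(cfg: PipelineConfig):
    sc = cfg.scenario
    rng = np.random.default_rng(cfg.seed)
    arms = []
    for diet, n, b, mean, tmean in (
        ("AL", sc.n_al, sc.gompertz_b_al, sc.mean_lifespan_al, sc.tumor_mean_al),
        ("EOD", sc.n_eod, sc.gompertz_b_eod, sc.mean_lifespan_eod, sc.tumor_mean_eod),
    ):
        a = _sim.gompertz_a_for_mean(mean, b)
        arms.append(
            _sim.generate_survival_cohort(
                n, a, b, censor_time=sc.censor_time, seed=rng, diet=diet,
                tumor_mean=tmean,
            )
        )
    survival = pd.concat(arms, ignore_index=True)
    panel = _sim.generate_trait_panel(sc.trait_specs, sc.n_per_group, seed=rng)
    weights = _sim.generate_longitudinal_weights(
        sc.cages_per_arm,
        sc.mice_per_cage,
        sc.weeks,
        sc.dr_effect_g,
        sc.cage_sd_g,
        sc.resid_sd_g,
        seed=rng,
    )
    return survival, panel, weights


def _analyze_survival(survival: pd.DataFrame, cfg: PipelineConfig, out: Path) -> dict:
    arms = {d: survival[survival["diet"] == d] for d in ("AL", "EOD")}
    result: dict = {"arms": {}}
    for diet, rec in arms.items():
        if len(rec) == 0:
            continue
        km = _surv.km_estimate(rec)
        km.to_csv(out / f"km_{diet.lower()}.tsv", sep="\t", index=False)
        entry = {
            "n": int(len(rec)),
            "n_deaths": int((rec["event"] == 1).sum()),
            "mean_lifespan_days": _surv.mean_lifespan(rec),
        }
        if entry["n_deaths"] >= 5:
            fit = _surv.fit_gompertz(rec)
            entry["gompertz"] = {
                "a_per_day": fit.a,
                "b_per_day": fit.b,
                "mdt_days": fit.mdt,
                "loglik": fit.loglik,
                "converged": fit.converged,
            }
        result["arms"][diet] = entry
    if all(len(r) > 0 for r in arms.values()):
        chi2, p = _surv.logrank_test(arms["AL"], arms["EOD"])
        result["logrank"] = {"chi2": chi2, "p": p}
        result["mean_extension_days"] = (
            result["arms"]["EOD"]["mean_lifespan_days"]
            - result["arms"]["AL"]["mean_lifespan_days"]
        )
        result["max_lifespan"] = _surv.max_lifespan(
            arms["AL"], arms["EOD"], fraction=cfg.fraction
        )
        ep = _surv.endpoint_summaries(arms["AL"], arms["EOD"])
        result["causes"] = {"AL": ep["causes"]["a"], "EOD": ep["causes"]["b"]}
        result["tumor_mean"] = {"AL": ep["tumor_mean"]["a"], "EOD": ep["tumor_mean"]["b"]}
        result["tumor_welch_t"] = {"t": ep["tumor_test"][0], "p": ep["tumor_test"][1]}
    return result


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    ok = np.isfinite(pvals)
    adj = pvals.copy()
    if ok.sum():
        adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return adj


def _analyze_panel(panel: pd.DataFrame, cfg: PipelineConfig, out: Path) -> dict:
    outcomes, _ = _classify.classify_panel(panel, alpha=cfg.alpha)
    if cfg.adjust == "bh":
        for name in ("age", "diet_young", "diet_old"):
            raw = np.array([o.contrasts[name][1] for o in outcomes])
            adj = _bh_adjust(raw)
            for o, p in zip(outcomes, adj):
                o.contrasts[name] = (o.contrasts[name][0], float(p))
    classes = []
    for o in outcomes:
        c = _classify.classify_trait(o, alpha=cfg.alpha)
        if c is not None:
            classes.append(c)
    anova_rows = [
        {
            "trait_id": o.trait_id,
            "p_age_main": o.p_age_main,
            "p_diet_main": o.p_diet_main,
            "p_interaction": o.p_interaction,
            "family": o.family,
            "testable": o.testable,
        }
        for o in outcomes
    ]
    pd.DataFrame(anova_rows).to_csv(out / "anova_traits.tsv", sep="\t", index=False)
    cls_rows = []
    by_id = {o.trait_id: o for o in outcomes}
    for c in classes:
        o = by_id[c.trait_id]
        row = dataclasses.asdict(c)
        for name in ("age", "diet_young", "diet_old"):
            row[f"dir_{name}"], row[f"p_{name}"] = o.contrasts[name]
        cls_rows.append(row)
    pd.DataFrame(cls_rows).to_csv(out / "classification.tsv", sep="\t", index=False)
    venn = _classify.venn_counts(classes)
    (out / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))

    es = _effects.effect_size_table(panel)
    es.to_csv(out / "effect_sizes.tsv", sep="\t")
    corr = {}
    aging_ids = [c.trait_id for c in classes if c.is_aging_trait]
    diet_ids = [c.trait_id for c in classes if c.is_diet_modified]
    both_ids = [
        c.trait_id for c in classes if c.is_aging_trait and c.is_diet_modified
    ]
    amel_ids = [c.trait_id for c in classes if c.is_ameliorated]
    for key, (x, y, ids) in {
        "age_vs_eod_old_aging": ("d_age", "d_eod_old", aging_ids),
        "age_vs_eod_old_both": ("d_age", "d_eod_old", both_ids),
        "eod_young_vs_old_diet": ("d_eod_young", "d_eod_old", diet_ids),
        "eod_young_vs_old_ameliorated": ("d_eod_young", "d_eod_old", amel_ids),
    }.items():
        try:
            r, p, n = _effects.correlate_effects(es, x, y, subset=ids)
            corr[key] = {"r": r, "p": p, "n": n}
        except ValueError:
            corr[key] = None
    (out / "correlations.json").write_text(json.dumps(corr, indent=2, sort_keys=True))
    return {"venn": venn, "correlations": corr, "n_traits": len(outcomes)}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the report as a dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.scenario is not None:
        survival, panel, weights = _simulate_inputs(cfg)
        survival.to_csv(out / "simulated_survival.csv", index=False)
        panel.to_csv(out / "simulated_phenotypes.csv", index=False)
        weights.to_csv(out / "simulated_weights.csv", index=False)
    else:
        survival = (
            _io.read_survival_csv(cfg.survival_path) if cfg.survival_path else None
        )
        panel = (
            _io.read_phenotype_csv(cfg.phenotype_path) if cfg.phenotype_path else None
        )
        weights = (
            _io.read_longitudinal_csv(cfg.longitudinal_path)
            if cfg.longitudinal_path
            else None
        )

    report: dict = {"seed": cfg.seed, "alpha": cfg.alpha}
    if survival is not None and len(survival):
        report["survival"] = _analyze_survival(survival, cfg, out)
        (out / "survival.json").write_text(
            json.dumps(report["survival"], indent=2, sort_keys=True)
        )
    if panel is not None and len(panel):
        report["traits"] = _analyze_panel(panel, cfg, out)
    else:
        logger.warning("no phenotype table; trait outputs skipped")
    if weights is not None and len(weights):
        mixed = fit_longitudinal_mixed(weights)
        report["longitudinal"] = dataclasses.asdict(mixed)
        (out / "longitudinal.json").write_text(
            json.dumps(report["longitudinal"], indent=2, sort_keys=True)
        )
    else:
        logger.warning("no longitudinal table; body-weight model skipped")

    lines = [f"drphenome report (seed={cfg.seed}, alpha={cfg.alpha})"]
    if "survival" in report:
        s = report["survival"]
        for diet, e in s["arms"].items():
            mdt = e.get("gompertz", {}).get("mdt_days")
            lines.append(
                f"  {diet}: n={e['n']}, mean lifespan {e['mean_lifespan_days']:.1f} d"
                + (f", MDT {mdt:.1f} d" if mdt else "")
            )
        if "logrank" in s:
            lines.append(
                f"  log-rank chi2={s['logrank']['chi2']:.2f} p={s['logrank']['p']:.3g}; "
                f"mean extension {s['mean_extension_days']:.1f} d; "
                f"max-lifespan extension {s['max_lifespan']['extension_days']:.1f} d "
                f"(top-{cfg.fraction:.0%}: k={s['max_lifespan']['k_a']}/"
                f"{s['max_lifespan']['k_b']})"
            )
    if "traits" in report:
        v = report["traits"]["venn"]
        lines.append(
            f"  traits: {v['total']} classified, {v['aging']} aging, "
            f"{v['diet_modified']} diet-modified, {v['ameliorated']} ameliorated "
            f"({v['prevented']} prevented + {v['age_independent']} age-independent), "
            f"{v['exacerbated']} exacerbated"
        )
    if "longitudinal" in report:
        m = report["longitudinal"]
        lines.append(
            f"  body weight: diet effect {m['dr_effect']:.2f} g "
            f"(SE {m['se']:.2f}, p={m['p']:.3g}, {m['method']})"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
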