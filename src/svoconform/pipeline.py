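"""End-to-end orchestration: design -> simulate -> fit -> measure -> analyze.

A run is fully described by a :class:`RunConfig` (YAML-serialisable,
pydantic-validated).  Every stage writes its artefacts into the run
directory, logs at stage granularity with the seeds in use, and any stage
failure aborts with the stage name while keeping partial outputs on disk.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import inference, measures, stats, synth, task_design
from .models import ALL_MODEL_SPECS, Family, ModelSpec, Scheme
from .task_design import Phase

__all__ = ["RunConfig", "PopulationSettings", "MCMCSettings", "run_pipeline",
           "analyze_measures", "load_config"]

log = logging.getLogger("svoconform")


class PopulationSettings(BaseModel):
    n_per_condition: dict[str, int] = Field(
        default_factory=lambda: {c: 12 for c in synth.CONDITIONS})
    prosocial_fraction: float = 0.75
    compliant_fraction: float = 0.17
    attitude_mean_pro: float = 20.0
    attitude_sd_pro: float = 14.0
    attitude_mean_anti: float = -22.0
    attitude_sd_anti: float = 20.0
    kappa_mean_compliant: float = 11.48
    kappa_mean_noncompliant: float = 1.14
    convergence_shift: dict[str, float] = Field(
        default_factory=lambda: {"baseline": 0.0, "computer": 4.0,
                                 "individual": 6.0, "group": 5.0})
    trials_per_phase: int | None = None
    family: str = "variable"
    missing_rate: float = 0.0

    @field_validator("n_per_condition")
    @classmethod
    def _positive_counts(cls, v):
        bad = [k for k, n in v.items() if n < 1]
        if bad:
            raise ValueError(f"n_per_condition must be >= 1, got 0 for {bad}")
        unknown = [k for k in v if k not in synth.CONDITIONS]
        if unknown:
            raise ValueError(f"unknown conditions {unknown}")
        return v

    def to_config(self, seed: int) -> synth.PopulationConfig:
        return synth.PopulationConfig(
            n_per_condition=self.n_per_condition,
            prosocial_fraction=self.prosocial_fraction,
            compliant_fraction=self.compliant_fraction,
            attitude_mean_pro=self.attitude_mean_pro,
            attitude_sd_pro=self.attitude_sd_pro,
            attitude_mean_anti=self.attitude_mean_anti,
            attitude_sd_anti=self.attitude_sd_anti,
            kappa_mean_compliant=self.kappa_mean_compliant,
            kappa_mean_noncompliant=self.kappa_mean_noncompliant,
            convergence_shift=self.convergence_shift,
            trials_per_phase=self.trials_per_phase,
            family=Family(self.family),
            missing_rate=self.missing_rate,
            seed=seed,
        )


class MCMCSettings(BaseModel):
    chains: int = 2
    iterations: int = 800
    burn_in: int = 300
    thinning: int = 1

    def to_config(self, seed: int) -> inference.MCMCConfig:
        return inference.MCMCConfig(chains=self.chains,
                                    iterations=self.iterations,
                                    burn_in=self.burn_in,
                                    thinning=self.thinning, seed=seed)


class RunConfig(BaseModel):
    """Everything needed to reproduce a run, seeds included."""

    seed: int = 0
    out_dir: str = "runs/latest"
    population: PopulationSettings = Field(default_factory=PopulationSettings)
    models: list[str] = Field(
        default_factory=lambda: [s.name for s in ALL_MODEL_SPECS])
    mcmc: MCMCSettings = Field(default_factory=MCMCSettings)
    compliance_threshold: float = 25.0
    measures_source: str = "fit"  # "fit" (MAP estimates) or "truth"
    verbosity: str = "info"

    @field_validator("models")
    @classmethod
    def _known_models(cls, v):
        known = {s.name for s in ALL_MODEL_SPECS}
        bad = [m for m in v if m not in known]
        if bad:
            raise ValueError(f"unknown model specs {bad}; choose from {sorted(known)}")
        if not v:
            raise ValueError("at least one model spec is required")
        return v

    @field_validator("measures_source")
    @classmethod
    def _known_source(cls, v):
        if v not in ("fit", "truth"):
            raise ValueError("measures_source must be 'fit' or 'truth'")
        return v


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(yaml.safe_load(fh) or {})


def _spec_from_name(name: str) -> ModelSpec:
    fam, scheme = name.split("/")
    return ModelSpec(Family(fam), Scheme(scheme))


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception:
                log.exception("stage %s: FAILED", name)
                raise RuntimeError(f"pipeline stage '{name}' failed") from None
            log.info("stage %s: done", name)
            return out
        return wrapper
    return deco


@_stage("design")
def _write_design(outdir: Path, seed: int) -> synth.StudyDesign:
    design = synth.build_design(seed)
    task_design.write_allocations_csv(outdir / "design.csv", design.subsets)
    return design


@_stage("simulate")
def _simulate(outdir: Path, cfg: synth.PopulationConfig,
              design: synth.StudyDesign) -> list[synth.SyntheticParticipant]:
    log.info("population seed %d", cfg.seed)
    pop = synth.sample_population(cfg, design)
    synth.write_choices_csv(outdir / "choices.csv", pop)
    synth.write_truth_csv(outdir / "truth.csv", pop)
    _write_norm_ratings(outdir / "norm_ratings.csv", pop)
    return pop


def _write_norm_ratings(path, pop) -> None:
    rows = []
    for p in pop:
        if p.norm_ratings is None:
            continue
        for j, r in enumerate(p.norm_ratings):
            rows.append({"participant_id": p.participant_id,
                         "condition": p.condition,
                         "prosocial_agent": p.agent_attitude > 0,
                         "probe": j, "rating": r})
    pd.DataFrame(rows, columns=["participant_id", "condition",
                                "prosocial_agent", "probe", "rating"]
                 ).to_csv(path, index=False)


@_stage("fit")
def _fit(outdir: Path, pop, model_names: Sequence[str],
         mcmc: inference.MCMCConfig):
    data = {p.participant_id: list(p.records) for p in pop}
    specs = [_spec_from_name(n) for n in model_names]
    log.info("fitting %d specs, mcmc seed %d", len(specs), mcmc.seed)
    table, fits = inference.compare_models(data, specs, mcmc=mcmc,
                                           return_fits=True)
    table.to_csv(outdir / "model_comparison.csv", index=False)
    for name, fit in fits.items():
        inference.save_fit(fit, outdir / "fits" / name.replace("/", "_"))
    return table, fits


@_stage("measure")
def _measure(outdir: Path, pop, fit: inference.PosteriorFit | None,
             threshold: float) -> pd.DataFrame:
    rows = []
    for p in pop:
        if fit is None:  # ground-truth measures
            ab, aa = p.true_params_before.attitude, p.true_params_after.attitude
            sb, sa = p.true_params_before.variability, p.true_params_after.variability
            kb = p.true_params_before.bias_kappa
        else:
            ab = fit.map_estimate("attitude", p.participant_id, Phase.before)
            aa = fit.map_estimate("attitude", p.participant_id, Phase.after)
            sb = fit.map_estimate("variability", p.participant_id, Phase.before)
            sa = fit.map_estimate("variability", p.participant_id, Phase.after)
            kb = fit.map_estimate("kappa", p.participant_id, Phase.before)
        rows.append(measures.build_measures_row(
            p.participant_id, p.condition, ab, aa, sb, sa, kb,
            p.agent_attitude, p.before_records, threshold))
    df = measures.measures_frame(rows)
    df.to_csv(outdir / "measures.csv", index=False)
    return df


def _result_or_error(fn, *a, **kw):
    try:
        out = fn(*a, **kw)
        return out.to_dict() if isinstance(out, stats.TestResult) else out
    except (ValueError, ZeroDivisionError) as exc:
        return {"error": str(exc)}


def analyze_measures(
    df: pd.DataFrame,
    norm_ratings: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict:
    """The full statistical battery over a measures table.

    Mirrors the analysis sequence of the study: one-tailed Wilcoxon tests of
    attitude convergence per condition, Kruskal-Wallis with Dunn post-hocs
    across conditions, the same restricted to below-threshold participants,
    the robust regression with the compliance interaction, the kappa/
    compliance association, Bayes factors for the polarisation measure, the
    consistency-increase tests, and the norm-rating batteries.
    """
    report: dict = {}
    conds = [c for c in synth.CONDITIONS if c in set(df.condition)]

    for cond in conds:
        vals = df.loc[df.condition == cond, "delta_diff"].to_numpy()
        report[f"contagion_wilcoxon_{cond}"] = _result_or_error(
            stats.wilcoxon_signed, vals, 0.0, "greater", seed,
            name=f"delta_diff>{0} in {cond}")
        report[f"time_dependence_bf_{cond}"] = _result_or_error(
            lambda v: {"bf10": stats.jzs_bayes_factor(v),
                       "bf01": 1.0 / stats.jzs_bayes_factor(v), "n": len(v)},
            df.loc[df.condition == cond, "delta_alpha"].to_numpy())
        report[f"consistency_wilcoxon_{cond}"] = _result_or_error(
            stats.wilcoxon_signed,
            df.loc[df.condition == cond, "consistency_change"].to_numpy(),
            0.0, "greater", seed, name=f"sigma decrease in {cond}")

    if len(conds) >= 2:
        groups = [df.loc[df.condition == c, "delta_diff"].to_numpy() for c in conds]
        try:
            kw, posthoc = stats.kruskal_with_posthoc(groups, seed=seed,
                                                     name="delta_diff by condition")
            posthoc["pair"] = [f"{conds[int(r.group_i)]}-{conds[int(r.group_j)]}"
                               for r in posthoc.itertuples()]
            report["convergence_kruskal"] = kw.to_dict()
            report["convergence_posthoc"] = posthoc.to_dict("records")
        except ValueError as exc:
            report["convergence_kruskal"] = {"error": str(exc)}

    sub = df[df.compliant == False]  # noqa: E712 — None rows must drop out
    for cond in conds:
        vals = sub.loc[sub.condition == cond, "delta_diff"].to_numpy()
        report[f"below_threshold_wilcoxon_{cond}"] = _result_or_error(
            stats.wilcoxon_signed, vals, 0.0, "greater", seed,
            name=f"delta_diff>0 in {cond}, below threshold")

    defined = df[df.compliance_index.notna()]
    if len(defined) >= 10 and len(conds) >= 2:
        dummies = pd.get_dummies(defined.condition, dtype=float)[conds]
        inter = dummies.mul(defined.compliance_index.to_numpy() / 100.0, axis=0)
        inter.columns = [f"{c}:compliance" for c in conds]
        X = pd.concat([dummies, inter], axis=1)
        report["compliance_regression"] = _result_or_error(
            _regression_report, defined.delta_diff.to_numpy(), X, dummies)
        report["kappa_by_compliance_ranksum"] = _result_or_error(
            _kappa_split, defined, seed)
        report["kappa_compliance_spearman"] = _result_or_error(
            stats.spearman_assoc, defined.kappa_before.to_numpy(),
            defined.compliance_index.to_numpy(), "two-sided", seed,
            name="kappa_before vs compliance index")

    if len(conds) >= 2:
        groups = [df.loc[df.condition == c, "consistency_change"].to_numpy()
                  for c in conds]
        try:
            kw, posthoc = stats.kruskal_with_posthoc(
                groups, seed=seed, name="consistency increase by condition")
            report["consistency_kruskal"] = kw.to_dict()
        except ValueError as exc:
            report["consistency_kruskal"] = {"error": str(exc)}

    if norm_ratings is not None and len(norm_ratings):
        report.update(_norm_reports(norm_ratings, seed))
    return report


def _regression_report(y, X, X_reduced):
    out = stats.robust_linreg(y, X, X_reduced)
    return {
        "coefficients": out["coefficients"].reset_index(names="term")
                                           .to_dict("records"),
        "deviance_test": out["deviance_test"],
    }


def _kappa_split(defined: pd.DataFrame, seed):
    above = defined.loc[defined.compliant == True, "kappa_before"].to_numpy()  # noqa: E712
    below = defined.loc[defined.compliant == False, "kappa_before"].to_numpy()  # noqa: E712
    if len(above) < 3 or len(below) < 3:
        raise ValueError("too few participants on one side of the threshold")
    res = stats.rank_sum(above, below, alternative="greater", seed=seed,
                         name="kappa above vs below threshold")
    d = res.to_dict()
    d["mean_above"], d["mean_below"] = float(above.mean()), float(below.mean())
    return d


def _pivot_ratings(nr: pd.DataFrame) -> pd.DataFrame:
    return nr.pivot_table(index=["participant_id", "condition",
                                 "prosocial_agent"],
                          columns="probe", values="rating").reset_index()


def _norm_reports(norm_ratings: pd.DataFrame, seed) -> dict:
    out: dict = {}
    wide = _pivot_ratings(norm_ratings)
    probe_cols = [c for c in wide.columns
                  if c not in ("participant_id", "condition", "prosocial_agent")]
    comp = wide[wide.condition == "computer"]
    groups = {
        "prosocial": comp.loc[comp.prosocial_agent == True, probe_cols].to_numpy(),   # noqa: E712
        "antisocial": comp.loc[comp.prosocial_agent == False, probe_cols].to_numpy(),  # noqa: E712
    }
    if all(len(g) >= 3 for g in groups.values()):
        table, summary = stats.norm_rating_battery(groups, rscale=2.0, seed=seed)
        out["norm_following"] = {"summary": summary,
                                 "tests": table.to_dict("records")}
    # norm uncertainty: same probes compared across conditions
    human = wide[wide.condition.isin(["computer", "individual", "group"])]
    by_cond = {c: human.loc[human.condition == c, probe_cols].to_numpy()
               for c in ("computer", "individual", "group")
               if (human.condition == c).sum() >= 3}
    if len(by_cond) >= 2:
        table, summary = stats.norm_rating_battery(by_cond, rscale=2.0, seed=seed)
        pair_bfs = _pairwise_condition_bfs(by_cond, seed)
        summary.update(pair_bfs)
        out["norm_uncertainty"] = {"summary": summary,
                                   "tests": table.to_dict("records")}
    return out


def _pairwise_condition_bfs(by_cond: Mapping[str, np.ndarray], seed) -> dict:
    labels = list(by_cond)
    n_null = n_alt = n_total = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = by_cond[labels[i]], by_cond[labels[j]]
            for col in range(a.shape[1]):
                try:
                    bf = stats.jzs_bayes_factor(a[:, col], b[:, col], rscale=2.0)
                except (ValueError, ZeroDivisionError):
                    continue
                n_total += 1
                n_null += bf < 1 / 3
                n_alt += bf > 3
    return {"pairwise_bf_total": n_total, "pairwise_bf_favour_null": int(n_null),
            "pairwise_bf_favour_alternative": int(n_alt)}


@_stage("analyze")
def _analyze(outdir: Path, df: pd.DataFrame, norm_ratings, seed: int,
             dic_table: pd.DataFrame | None) -> dict:
    report = analyze_measures(df, norm_ratings, seed)
    if dic_table is not None:
        report["dic"] = dic_table.to_dict("records")
    (outdir / "analysis_report.json").write_text(
        json.dumps(report, indent=2, default=_json_default))
    (outdir / "analysis_summary.txt").write_text(_summarise(report))
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _summarise(report: dict) -> str:
    lines = ["svoconform analysis summary", "=" * 27]
    for key, val in report.items():
        if isinstance(val, dict) and "p_value" in val:
            lines.append(
                f"{key}: {val.get('statistic_name', 'stat')}="
                f"{val['statistic']:.3g}, p={val['p_value']:.4g}, n={val['n']}")
        elif isinstance(val, dict) and "bf10" in val:
            lines.append(f"{key}: BF10={val['bf10']:.3g}")
        elif isinstance(val, dict) and "error" in val:
            lines.append(f"{key}: not computed ({val['error']})")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Identical configs (seed included) produce byte-identical measures.csv.
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    try:
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(config.model_dump(), sort_keys=False))
        log.info("master seed %d", config.seed)
        design = _write_design(outdir, config.seed)
        pop = _simulate(outdir, config.population.to_config(config.seed), design)
        dic_table = None
        best_fit = None
        if config.measures_source == "fit":
            dic_table, fits = _fit(outdir, pop, config.models,
                                   config.mcmc.to_config(config.seed))
            best_fit = fits[dic_table.iloc[0]["model"]]
        df = _measure(outdir, pop, best_fit, config.compliance_threshold)
        norm = pd.read_csv(outdir / "norm_ratings.csv") \
            if (outdir / "norm_ratings.csv").stat().st_size > 1 else None
        _analyze(outdir, df, norm, config.seed, dic_table)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
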