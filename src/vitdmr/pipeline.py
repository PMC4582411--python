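"""End-to-end orchestration: cohorts -> phenotype prep -> scores ->
per-study associations -> meta-analysis (with optional consortium summary
statistics) -> instrumental-variable estimates -> triangulation report.

Two modes:

* ``simulate`` — generate a multi-study collaboration (and, optionally, a
  large external "consortium" cohort contributing only per-SNP summary
  statistics) from a single seed and run the whole analysis;
* ``load`` — start from user-supplied cohort tables, or from pre-pooled
  association tables (the bundled worked example ships pooled coefficients
  so the triangulation runs without any individual-level data).

Every model-selection decision (fixed vs random effects, exclusions,
dropped rows) is appended to a structured decision log written next to the
result tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .iv import IvEstimate, f_statistic, iv_ratio
from .meta import MetaResult, approximate_score_effect, combine_with_consortium, forest_table, meta_analyse
from .phenotypes import percent_per_allele, prepare_cohort
from .regression import (
    AssocResult,
    frame_to_results,
    results_to_frame,
    study_association_battery,
)
from .scores import DEFAULT_PANEL, add_scores_to_table, default_scores, harmonise_table
from .simulate import (
    SimConfig,
    default_multi_study_configs,
    emit_summary_stats,
    generate_cohort,
    generate_multi_study,
    read_cohort,
)

logger = logging.getLogger("vitdmr")

LN_1P1 = float(np.log(1.1))  # Delta ln 25(OH)D for a 10% increase
BP_OUTCOMES = ("sbp", "dbp", "hypertension")


@dataclass
class RunConfig:
    """One pipeline run.

    ``sim_overrides`` feed straight into :class:`~vitdmr.simulate.SimConfig`
    (every generative default is overridable); ``consortium_n`` > 0 adds a
    simulated summary-statistic stratum in simulate mode.  In load mode
    either ``cohort_paths`` (individual-level tables) or
    ``pooled_associations`` (pre-pooled coefficients, as in the worked
    example) must be given.
    """

    mode: str = "simulate"
    out_dir: str = "vitdmr_out"
    seed: int | None = 2014
    alpha_q: float = 0.05
    lipid_adjust: bool = False
    trust_strand: bool = True  # summary files share the panel's strand convention
    n_studies: int = 8
    n_per_study: int = 1500
    consortium_n: int = 20000
    sim_overrides: dict = field(default_factory=dict)
    cohort_paths: list[str] = field(default_factory=list)
    consortium_files: dict = field(default_factory=dict)  # outcome -> path
    pooled_associations: str | None = None
    diagnostics_file: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("seed is mandatory in simulate mode")
        if self.mode == "load" and not self.cohort_paths and not self.pooled_associations:
            raise ValueError("load mode needs cohort_paths or pooled_associations")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def worked_example_paths() -> tuple[Path, Path]:
    """Paths of the bundled pooled-coefficient worked example."""
    base = resources.files("vitdmr") / "data"
    return Path(str(base / "worked_example.tsv")), Path(
        str(base / "worked_example_diagnostics.tsv")
    )


def worked_example_config(out_dir: str = "vitdmr_out") -> RunConfig:
    assoc, diag = worked_example_paths()
    return RunConfig(
        mode="load",
        out_dir=out_dir,
        seed=None,
        pooled_associations=str(assoc),
        diagnostics_file=str(diag),
    )


# ---------------------------------------------------------------------------
# stages


def _stage(log: list[dict], stage: str, **info) -> None:
    entry = {"stage": stage, **info}
    log.append(entry)
    logger.info("%s: %s", stage, info)


def _meta_by_model(
    results: list[AssocResult], alpha_q: float, log: list[dict]
) -> dict[tuple[str, str], MetaResult]:
    pooled: dict[tuple[str, str], MetaResult] = {}
    frame = results_to_frame(results)
    for (exposure, outcome), grp in frame.groupby(["exposure", "outcome"], sort=True):
        ests = frame_to_results(grp)
        res = meta_analyse(ests, alpha_q)
        pooled[(exposure, outcome)] = res
        _stage(
            log,
            "meta",
            exposure=exposure,
            outcome=outcome,
            model=res.model,
            k=res.k,
            q=round(res.q, 4),
            p_q=round(res.p_q, 6),
            i2=round(res.i2, 2),
        )
    return pooled


def _meta_frame(pooled: dict[tuple[str, str], MetaResult]) -> pd.DataFrame:
    rows = []
    for (exposure, outcome), m in sorted(pooled.items()):
        rows.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "beta": m.beta,
                "se": m.se,
                "ci_low": m.ci[0],
                "ci_high": m.ci[1],
                "p": m.p,
                "model": m.model,
                "k": m.k,
                "q": m.q,
                "p_q": m.p_q,
                "i2": m.i2,
                "tau2": m.tau2,
            }
        )
    return pd.DataFrame(rows)


def _phenotypic_per_10pct(res: MetaResult | AssocResult, binary: bool) -> dict:
    """Convert a per-ln-unit phenotypic effect to the per-10% scale.

    A 10% increase in 25(OH)D is ln(1.1) log-units, so the per-10% effect
    is beta * ln(1.1) on the outcome scale (log-odds for binary outcomes).
    """
    beta = res.beta * LN_1P1
    se = res.se * LN_1P1
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    out = {"beta": beta, "se": se, "ci_low": beta - 1.96 * se, "ci_high": beta + 1.96 * se, "p": p}
    if binary:
        out["odds_ratio"] = float(np.exp(beta))
    return out


def _triangulation_frame(
    zx_percent: tuple[float, float],
    genetic: dict[str, tuple[float, float]],
    phenotypic: dict[str, dict],
    iv: dict[str, IvEstimate],
) -> pd.DataFrame:
    rows = []
    for outcome in BP_OUTCOMES:
        if outcome not in iv:
            continue
        est = iv[outcome]
        gen_b, gen_se = genetic[outcome]
        row = {
            "outcome": outcome,
            "phenotypic_beta_per_10pct": phenotypic.get(outcome, {}).get("beta", np.nan),
            "phenotypic_ci_low": phenotypic.get(outcome, {}).get("ci_low", np.nan),
            "phenotypic_ci_high": phenotypic.get(outcome, {}).get("ci_high", np.nan),
            "phenotypic_p": phenotypic.get(outcome, {}).get("p", np.nan),
            "genetic_beta_per_allele": gen_b,
            "genetic_se": gen_se,
            "zx_percent_per_allele": zx_percent[0],
            "zx_percent_se": zx_percent[1],
            "iv_beta_per_10pct": est.ratio,
            "iv_se": est.se,
            "iv_ci_low": est.ci_low,
            "iv_ci_high": est.ci_high,
            "iv_p": est.p,
        }
        if est.binary:
            row["iv_odds_ratio"] = est.odds_ratio
            row["iv_or_ci_low"], row["iv_or_ci_high"] = est.or_ci
            row["phenotypic_odds_ratio"] = phenotypic.get(outcome, {}).get("odds_ratio", np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle and writes TSV/JSON
    outputs (associations, meta-analyses, forest tables, triangulation,
    diagnostics, decision log) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    bundle: dict = {}

    if config.mode == "load" and config.pooled_associations:
        bundle = _run_from_pooled(config, out, log)
    else:
        bundle = _run_from_cohorts(config, out, log)

    with open(out / "decision_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    bundle["decision_log"] = log
    return bundle


def _run_from_cohorts(config: RunConfig, out: Path, log: list[dict]) -> dict:
    panel = DEFAULT_PANEL
    scores = default_scores(panel)

    if config.mode == "simulate":
        sim_configs = default_multi_study_configs(
            config.n_studies, config.n_per_study, int(config.seed), **config.sim_overrides
        )
        cohorts = generate_multi_study(sim_configs)
        _stage(log, "simulate", n_studies=len(cohorts), n_per_study=config.n_per_study)
    else:
        cohorts = [read_cohort(p) for p in config.cohort_paths]
        _stage(log, "load", n_studies=len(cohorts))

    prepared = [add_scores_to_table(prepare_cohort(c)) for c in cohorts]

    all_results: list[AssocResult] = []
    for table in prepared:
        sid = str(table["study_id"].iloc[0])
        try:
            all_results.extend(
                study_association_battery(
                    table, panel, scores, lipid_adjust=config.lipid_adjust
                )
            )
        except Exception as exc:
            raise RuntimeError(f"association stage failed for study {sid!r}: {exc}") from exc
    assoc_frame = results_to_frame(all_results)
    assoc_frame.to_csv(out / "associations.tsv", sep="\t", index=False)
    _stage(log, "associations", n_models=len(all_results))

    pooled = _meta_by_model(all_results, config.alpha_q, log)
    _meta_frame(pooled).to_csv(out / "meta.tsv", sep="\t", index=False)
    for outcome in BP_OUTCOMES:
        forest_table(pooled[("score_synthesis", outcome)]).to_csv(
            out / f"forest_score_synthesis_{outcome}.tsv", sep="\t", index=False
        )

    # consortium stratum: per-SNP summary statistics only
    consortium_files = dict(config.consortium_files)
    if config.mode == "simulate" and config.consortium_n > 0 and not consortium_files:
        base = SimConfig(
            n_individuals=config.consortium_n,
            study_id="consortium",
            seed=int(config.seed) + 1,
            **config.sim_overrides,
        )
        consortium_cohort = prepare_cohort(generate_cohort(base))
        for outcome in BP_OUTCOMES:
            stats_table = emit_summary_stats(consortium_cohort, outcome, panel)
            path = out / f"consortium_{outcome}.tsv"
            stats_table.to_csv(path, sep="\t", index=False)
            consortium_files[outcome] = str(path)
        _stage(log, "consortium_simulated", n=config.consortium_n)

    combined: dict[str, MetaResult] = {}
    genetic: dict[str, tuple[float, float]] = {}
    for outcome in BP_OUTCOMES:
        cohort_pool = pooled[("score_synthesis", outcome)]
        if outcome in consortium_files:
            raw = pd.read_csv(consortium_files[outcome], sep="\t")
            harmonised = harmonise_table(raw, panel, trust_strand=config.trust_strand)
            n_dropped = raw["snp_id"].isin([s.snp_id for s in panel]).sum() - len(harmonised)
            if n_dropped:
                _stage(log, "harmonise", outcome=outcome, excluded_rows=int(n_dropped))
            approx = approximate_score_effect(
                harmonised, scores["synthesis"], outcome=outcome
            )
            combined[outcome] = combine_with_consortium(cohort_pool, approx)
            _stage(
                log,
                "combine_with_consortium",
                outcome=outcome,
                beta=round(combined[outcome].beta, 6),
                i2_between_strata=round(combined[outcome].i2, 2),
            )
        else:
            combined[outcome] = cohort_pool
        genetic[outcome] = (combined[outcome].beta, combined[outcome].se)

    # instrument: score -> ln 25(OH)D, converted to the percent scale
    zx_meta = pooled[("score_synthesis", "ln25ohd")]
    zx_pct = percent_per_allele(zx_meta.beta)
    zx_pct_se = 100.0 * float(np.exp(zx_meta.beta)) * zx_meta.se  # delta method
    _stage(log, "instrument", beta_pct_per_allele=round(zx_pct, 4), se=round(zx_pct_se, 4))

    # instrument-strength diagnostics from the pooled individual-level data
    pool = pd.concat(prepared, ignore_index=True)
    r = np.corrcoef(pool["score_synthesis"], pool["ln25ohd"])[0, 1]
    diag = f_statistic(float(r**2), int(len(pool)))
    _stage(log, "diagnostics", r2=round(diag.r2, 6), f=round(diag.f_stat, 2))

    iv: dict[str, IvEstimate] = {}
    phenotypic: dict[str, dict] = {}
    for outcome in BP_OUTCOMES:
        binary = outcome == "hypertension"
        b, s = genetic[outcome]
        iv[outcome] = iv_ratio(b, s, zx_pct, zx_pct_se, binary=binary, outcome=outcome)
        phenotypic[outcome] = _phenotypic_per_10pct(pooled[("ln25ohd", outcome)], binary)

    tri = _triangulation_frame((zx_pct, zx_pct_se), genetic, phenotypic, iv)
    tri.to_csv(out / "triangulation.tsv", sep="\t", index=False)
    diagnostics = {
        "r2": diag.r2,
        "n": diag.n,
        "f_stat": diag.f_stat,
        "relative_bias": diag.relative_bias,
        "zx_percent_per_allele": zx_pct,
        "zx_percent_se": zx_pct_se,
    }
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=1, sort_keys=True)
    with open(out / "triangulation.json", "w") as fh:
        json.dump(tri.to_dict(orient="records"), fh, indent=1, sort_keys=True)

    return {
        "associations": assoc_frame,
        "meta": _meta_frame(pooled),
        "pooled": pooled,
        "combined": combined,
        "triangulation": tri,
        "diagnostics": diagnostics,
        "iv": iv,
    }


def _run_from_pooled(config: RunConfig, out: Path, log: list[dict]) -> dict:
    """Triangulation from pre-pooled coefficients (worked-example path)."""
    frame = pd.read_csv(config.pooled_associations, sep="\t")
    _stage(log, "load_pooled", path=str(config.pooled_associations), n_rows=len(frame))

    def _row(exposure: str, outcome: str) -> pd.Series:
        sel = frame[(frame["exposure"] == exposure) & (frame["outcome"] == outcome)]
        if len(sel) != 1:
            raise ValueError(f"expected one pooled row for {exposure}->{outcome}, got {len(sel)}")
        return sel.iloc[0]

    zx_row = _row("score_synthesis", "ln25ohd")
    if zx_row["scale"] != "percent_per_allele":
        raise ValueError("pooled score->25(OH)D row must be on the percent_per_allele scale")
    zx_pct, zx_pct_se = float(zx_row["beta"]), float(zx_row["se"])

    genetic: dict[str, tuple[float, float]] = {}
    phenotypic: dict[str, dict] = {}
    iv: dict[str, IvEstimate] = {}
    for outcome in BP_OUTCOMES:
        binary = outcome == "hypertension"
        g = _row("score_synthesis", outcome)
        genetic[outcome] = (float(g["beta"]), float(g["se"]))
        iv[outcome] = iv_ratio(*genetic[outcome], zx_pct, zx_pct_se, binary=binary, outcome=outcome)
        try:
            ph = _row("ln25ohd", outcome)
        except ValueError:
            phenotypic[outcome] = {}
        else:
            b, s = float(ph["beta"]), float(ph["se"])
            entry = {
                "beta": b,
                "se": s,
                "ci_low": b - 1.96 * s,
                "ci_high": b + 1.96 * s,
                "p": float(2.0 * stats.norm.sf(abs(b / s))),
            }
            if binary:
                entry["odds_ratio"] = float(np.exp(b))
            phenotypic[outcome] = entry

    tri = _triangulation_frame((zx_pct, zx_pct_se), genetic, phenotypic, iv)
    tri.to_csv(out / "triangulation.tsv", sep="\t", index=False)
    with open(out / "triangulation.json", "w") as fh:
        json.dump(tri.to_dict(orient="records"), fh, indent=1, sort_keys=True)

    diagnostics: dict = {"zx_percent_per_allele": zx_pct, "zx_percent_se": zx_pct_se}
    if config.diagnostics_file:
        diag_frame = pd.read_csv(config.diagnostics_file, sep="\t")
        for _, row in diag_frame.iterrows():
            diagnostics[str(row["name"])] = float(row["value"])
        if "f_stat" in diagnostics:
            diagnostics["relative_bias"] = 1.0 / diagnostics["f_stat"]
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=1, sort_keys=True)
    _stage(log, "triangulation", outcomes=list(tri["outcome"]))

    return {"triangulation": tri, "diagnostics": diagnostics, "iv": iv}


def run_worked_example(out_dir: str = "vitdmr_out") -> dict:
    """Run the bundled pooled-coefficient worked example."""
    return run_pipeline(worked_example_config(out_dir))
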