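"""Multi-study simulator for the vitamin D / blood-pressure analysis.

Generates per-individual cohort tables and per-SNP summary-statistic tables
with the structure the analysis assumes: genotypes at four independent
vitamin D SNPs in Hardy–Weinberg proportions (no LD — the panel genes sit
on different chromosomal regions); ln 25(OH)D built additively from the
SNPs, a seasonal cosine in month of blood draw, and confounders (age, BMI,
sex); latent blood pressure from confounders plus an optional causal effect
of ln 25(OH)D; antihypertensive treatment assigned by a logistic model on
latent systolic pressure, with observed pressure lowered by a fixed
per-arm constant in treated individuals (so the +15/+10 mm Hg correction
applied downstream is exact in expectation).

Every draw is deterministic given the master seed; per-study streams are
decorrelated by folding a CRC-32 hash of the study label into the seed
sequence.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .phenotypes import prepare_cohort
from .regression import (
    BASE_COVARIATES,
    OHD_EXTRA_COVARIATES,
    fit_linear,
    fit_logistic,
)
from .scores import DEFAULT_PANEL, SnpSpec, add_scores_to_table

# Covariate centring constants: effects in SimConfig multiply the centred
# covariate, so the intercepts below are population means.
AGE_CENTER, AGE_SD = 52.0, 10.0
BMI_CENTER, BMI_SD = 26.5, 4.0
SEX_CENTER = 0.5


class ConfigurationError(ValueError):
    """A simulation parameter is missing or non-finite."""


@dataclass(frozen=True)
class SimConfig:
    """Generative truth for one study cohort.

    Defaults emulate a mid-sized adult cohort of European ancestry: mean
    25(OH)D about 50 nmol/L with ~15% seasonal amplitude, mean blood
    pressure 130/80 mm Hg, and confounding of the biomarker–pressure
    relationship through BMI and age.  ``causal_effect_*`` are mm Hg per
    unit ln 25(OH)D and default to zero (no causal effect); recovery tests
    override them.
    """

    n_individuals: int = 3000
    study_id: str = "study_1"
    seed: int = 2014
    snps: tuple[SnpSpec, ...] = DEFAULT_PANEL
    mu_ln25ohd: float = 3.912  # ln(50 nmol/L)
    seasonal_amplitude: float = 0.15  # log-units, peak-to-mean
    peak_month: int = 8
    confounder_effects: dict = field(
        default_factory=lambda: {"age": -0.003, "bmi": -0.012, "sex": 0.03}
    )
    causal_effect_sbp: float = 0.0  # mm Hg per unit ln 25(OH)D
    causal_effect_dbp: float = 0.0
    mean_sbp: float = 130.0
    mean_dbp: float = 80.0
    confounder_bp_effects: dict = field(
        default_factory=lambda: {
            "sbp": {"age": 0.6, "bmi": 0.8, "sex": 4.0},
            "dbp": {"age": 0.2, "bmi": 0.6, "sex": 3.0},
        }
    )
    sd_ln25ohd: float = 0.35
    sd_sbp: float = 15.0
    sd_dbp: float = 10.0
    treatment_model: dict = field(default_factory=lambda: {"intercept": -2.2, "slope": 0.08})
    treatment_effect_sbp: float = 15.0  # mm Hg lowering when treated
    treatment_effect_dbp: float = 10.0
    n_batches: int = 3

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        for name in ("sd_ln25ohd", "sd_sbp", "sd_dbp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0")
        scalars = [
            self.mu_ln25ohd,
            self.seasonal_amplitude,
            self.causal_effect_sbp,
            self.causal_effect_dbp,
            self.mean_sbp,
            self.mean_dbp,
            self.treatment_effect_sbp,
            self.treatment_effect_dbp,
            *self.confounder_effects.values(),
            *self.treatment_model.values(),
        ]
        for sub in self.confounder_bp_effects.values():
            scalars.extend(sub.values())
        if not np.all(np.isfinite(scalars)):
            raise ConfigurationError("non-finite simulation parameter")
        if self.treatment_effect_sbp < 0 or self.treatment_effect_dbp < 0:
            raise ConfigurationError("treatment effects are BP *lowerings* and must be >= 0")

    def rng(self) -> np.random.Generator:
        entropy = [int(self.seed), zlib.crc32(self.study_id.encode())]
        return np.random.default_rng(np.random.SeedSequence(entropy))


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw one cohort table; byte-identical given (seed, study_id)."""
    rng = config.rng()
    n = config.n_individuals

    age = np.clip(rng.normal(AGE_CENTER, AGE_SD, n), 31, 92)
    sex = rng.binomial(1, SEX_CENTER, n)
    bmi = np.clip(rng.normal(BMI_CENTER, BMI_SD, n), 15, 50)
    month = rng.integers(1, 13, n)
    batch = np.array([f"batch_{i}" for i in rng.integers(1, config.n_batches + 1, n)])

    dosages = {s.snp_id: rng.binomial(2, s.eaf, n).astype(float) for s in config.snps}

    ce = config.confounder_effects
    ln25ohd = (
        config.mu_ln25ohd
        + sum(s.beta_ln_25ohd * dosages[s.snp_id] for s in config.snps)
        + config.seasonal_amplitude * np.cos(2 * np.pi * (month - config.peak_month) / 12.0)
        + ce.get("age", 0.0) * (age - AGE_CENTER)
        + ce.get("bmi", 0.0) * (bmi - BMI_CENTER)
        + ce.get("sex", 0.0) * (sex - SEX_CENTER)
        + rng.normal(0.0, config.sd_ln25ohd, n)
    )

    def _latent_bp(mean: float, causal: float, effects: dict, sd: float) -> np.ndarray:
        return (
            mean
            + causal * (ln25ohd - config.mu_ln25ohd)
            + effects.get("age", 0.0) * (age - AGE_CENTER)
            + effects.get("bmi", 0.0) * (bmi - BMI_CENTER)
            + effects.get("sex", 0.0) * (sex - SEX_CENTER)
            + rng.normal(0.0, sd, n)
        )

    latent_sbp = _latent_bp(
        config.mean_sbp, config.causal_effect_sbp, config.confounder_bp_effects.get("sbp", {}),
        config.sd_sbp,
    )
    latent_dbp = _latent_bp(
        config.mean_dbp, config.causal_effect_dbp, config.confounder_bp_effects.get("dbp", {}),
        config.sd_dbp,
    )

    tm = config.treatment_model
    logit = tm.get("intercept", -2.2) + tm.get("slope", 0.08) * (latent_sbp - 140.0)
    p_treat = 1.0 / (1.0 + np.exp(-logit))
    on_meds = rng.binomial(1, p_treat, n).astype(bool)

    sbp_obs = latent_sbp - np.where(on_meds, config.treatment_effect_sbp, 0.0)
    dbp_obs = latent_dbp - np.where(on_meds, config.treatment_effect_dbp, 0.0)

    table = pd.DataFrame(
        {
            "id": [f"{config.study_id}_{i}" for i in range(n)],
            **dosages,
            "ln25ohd": ln25ohd,
            "sbp_observed": sbp_obs,
            "dbp_observed": dbp_obs,
            "on_meds": on_meds,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "month": month,
            "batch": batch,
            "study_id": config.study_id,
        }
    )
    return table


def generate_multi_study(configs: Sequence[SimConfig]) -> list[pd.DataFrame]:
    """Generate one cohort per config with decorrelated random streams.

    Study labels must be distinct; each study's stream folds the label into
    its seed, so identical parameter sets still yield independent draws.
    """
    if len(configs) == 0:
        raise ValueError("at least one SimConfig required")
    ids = [c.study_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate study_id among {ids}")
    return [generate_cohort(c) for c in configs]


def default_multi_study_configs(
    n_studies: int,
    n_per_study: int,
    seed: int,
    **overrides,
) -> list[SimConfig]:
    """Homogeneous-truth multi-study design with per-study labels."""
    base = SimConfig(n_individuals=n_per_study, seed=seed, **overrides)
    return [replace(base, study_id=f"study_{i + 1}") for i in range(n_studies)]


def emit_summary_stats(
    cohort: pd.DataFrame,
    outcome: str,
    panel: Sequence[SnpSpec] = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Per-SNP summary-statistic table (consortium-style) for one cohort.

    One row per panel SNP: effect/other allele in the 25(OH)D-increasing
    orientation, observed EAF (mean dosage / 2), and the beta/SE/n from the
    same adjusted single-SNP regression the association battery runs.
    """
    if outcome not in ("ln25ohd", "sbp", "dbp", "hypertension"):
        raise ValueError(f"unknown outcome {outcome!r}")
    prepared = cohort if outcome in cohort.columns else prepare_cohort(cohort)
    covs = BASE_COVARIATES + (OHD_EXTRA_COVARIATES if outcome == "ln25ohd" else ())
    rows = []
    for snp in panel:
        if outcome == "hypertension":
            res = fit_logistic(prepared, outcome, snp.snp_id, covs)
        else:
            res = fit_linear(prepared, outcome, snp.snp_id, covs)
        rows.append(
            {
                "snp_id": snp.snp_id,
                "effect_allele": snp.effect_allele,
                "other_allele": snp.other_allele,
                "eaf": float(prepared[snp.snp_id].mean() / 2.0),
                "beta": res.beta,
                "se": res.se,
                "n": res.n,
                "outcome": outcome,
            }
        )
    return pd.DataFrame(rows)


def simulate_prepared_cohort(config: SimConfig) -> pd.DataFrame:
    """Cohort with phenotype prep and allele-score columns applied."""
    return add_scores_to_table(prepare_cohort(generate_cohort(config)))


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_from_yaml(path) -> SimConfig:
    """Load a SimConfig from a YAML mapping; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimConfig:
    allowed = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    if "snps" in raw:
        raw = dict(raw)
        raw["snps"] = tuple(
            s if isinstance(s, SnpSpec) else SnpSpec(**s) for s in raw["snps"]
        )
    return SimConfig(**raw)
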