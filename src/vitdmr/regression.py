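"""Per-study regression engine.

Produces the adjusted associations the meta-analyses consume: ordinary
least squares for continuous outcomes (ln 25(OH)D, treatment-corrected SBP
and DBP) and maximum-likelihood logistic regression (log-odds) for
hypertension.  Continuous-BP and hypertension models share one covariate
set (age, age squared, sex, BMI, plus any user-supplied region/principal-
component columns); 25(OH)D models are additionally adjusted for month of
blood draw and laboratory batch.  All models are complete-case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .scores import ScoreDef, SnpSpec, default_scores

logger = logging.getLogger("vitdmr")

OUTCOMES = ("ln25ohd", "sbp", "dbp", "hypertension")

#: covariates shared by every adjusted model (age squared built from age)
BASE_COVARIATES = ("age", "sex", "bmi")
#: extra adjustment, 25(OH)D models only: month of blood draw, lab batch
OHD_EXTRA_COVARIATES = ("month", "batch")
#: optional lipid adjustment (pleiotropy sensitivity)
LIPID_COVARIATES = ("triglycerides", "total_cholesterol")


class RankDeficientDesignError(ValueError):
    """The regression design matrix is rank deficient (collinear columns)."""


class SeparationError(ValueError):
    """Perfect separation in a logistic fit; the MLE does not exist."""


@dataclass
class AssocResult:
    """One adjusted association: effect of `exposure` on `outcome`.

    ``beta`` is per allele (SNP or score exposures) or per log-unit of
    25(OH)D (phenotypic exposure); log-odds for a binary outcome.  ``scale``
    records the reporting convention so downstream pooling can refuse to
    mix scales.
    """

    study_id: str
    exposure: str
    outcome: str
    beta: float
    se: float
    n: int
    scale: str = "per_allele"
    covariates: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.study_id} {self.exposure}->{self.outcome}: se must be > 0")

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


def _design(
    frame: pd.DataFrame, exposure: str, covariates: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete-case design with intercept; age-squared and categorical
    dummies (month, batch, region...) constructed here."""
    cols = [exposure, *covariates]
    data = frame[list(dict.fromkeys(cols))].copy()
    keep = data.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("complete-case filter dropped %d rows", dropped)
    data = data.loc[keep]
    parts = [pd.Series(1.0, index=data.index, name="const"), data[exposure].astype(float)]
    for cov in covariates:
        if cov == exposure:
            continue
        col = data[cov]
        if cov == "age":
            parts.append(col.astype(float))
            parts.append((col.astype(float) ** 2).rename("age_sq"))
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or cov in ("month", "batch", "region"):
            dummies = pd.get_dummies(col.astype("category"), prefix=cov, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
        else:
            parts.append(col.astype(float))
    X = pd.concat(parts, axis=1)
    return X, data


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for j, name in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise RankDeficientDesignError(f"rank-deficient design; collinear columns: {bad}")


def fit_linear(
    frame: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: tuple[str, ...] = (),
    *,
    study_id: str = "",
    scale: str = "per_allele",
) -> AssocResult:
    """OLS beta and SE for `exposure`, covariates partialled in the same fit."""
    X, data = _design(frame, exposure, covariates)
    y = frame.loc[data.index, outcome].astype(float)
    keep = y.notna()
    X, y = X.loc[keep], y.loc[keep]
    if len(y) <= X.shape[1]:
        raise ValueError(f"n={len(y)} too small for {X.shape[1]} parameters")
    _check_rank(X)
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index(exposure)
    return AssocResult(
        study_id=study_id,
        exposure=exposure,
        outcome=outcome,
        beta=float(fit.params[j]),
        se=float(fit.bse[j]),
        n=int(len(y)),
        scale=scale,
        covariates=tuple(covariates),
    )


def fit_logistic(
    frame: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: tuple[str, ...] = (),
    *,
    study_id: str = "",
    scale: str = "per_allele",
    tol: float = 1e-8,
    maxiter: int = 50,
) -> AssocResult:
    """Maximum-likelihood log-odds beta and SE (Newton/IRLS).

    Perfect separation raises :class:`SeparationError` instead of returning
    an arbitrarily large finite coefficient.
    """
    X, data = _design(frame, exposure, covariates)
    y = frame.loc[data.index, outcome].astype(float)
    keep = y.notna()
    X, y = X.loc[keep], y.loc[keep]
    classes = set(np.unique(y.to_numpy()))
    if not classes <= {0.0, 1.0}:
        raise ValueError(f"binary outcome expected, got values {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    if len(y) <= X.shape[1]:
        raise ValueError(f"n={len(y)} too small for {X.shape[1]} parameters")
    _check_rank(X)
    import warnings as _warnings

    model = sm.Logit(y.to_numpy(), X.to_numpy())
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            fit = model.fit(method="newton", tol=tol, maxiter=maxiter, disp=False)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation in {exposure}->{outcome}") from exc
    fitted = fit.predict()
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        raise SeparationError(f"perfect separation in {exposure}->{outcome}")
    j = list(X.columns).index(exposure)
    return AssocResult(
        study_id=study_id,
        exposure=exposure,
        outcome=outcome,
        beta=float(fit.params[j]),
        se=float(fit.bse[j]),
        n=int(len(y)),
        scale=scale + "_log_odds",
        covariates=tuple(covariates),
    )


def study_association_battery(
    cohort: pd.DataFrame,
    panel: tuple[SnpSpec, ...] | list[SnpSpec],
    scores: dict[str, ScoreDef] | None = None,
    *,
    covariates: tuple[str, ...] = BASE_COVARIATES,
    lipid_adjust: bool = False,
    extra_covariates: tuple[str, ...] = (),
) -> list[AssocResult]:
    """Run the standard per-study analysis plan on one prepared cohort.

    Emits, per study: each single SNP and each allele score against
    ln 25(OH)D (month- and batch-adjusted), SBP, DBP (treatment-corrected)
    and hypertension; plus the phenotypic ln 25(OH)D association with each
    blood-pressure outcome.  Any failed fit aborts the battery naming the
    study and model.
    """
    if scores is None:
        scores = default_scores(tuple(panel))
    study_id = str(cohort["study_id"].iloc[0]) if "study_id" in cohort else ""
    covs = tuple(covariates) + tuple(extra_covariates)
    if lipid_adjust:
        covs = covs + tuple(c for c in LIPID_COVARIATES if c in cohort.columns)
    covs_ohd = covs + tuple(c for c in OHD_EXTRA_COVARIATES if c in cohort.columns)

    exposures = [s.snp_id for s in panel] + [f"score_{name}" for name in scores]
    results: list[AssocResult] = []
    for exposure in exposures + ["ln25ohd"]:
        for outcome in OUTCOMES:
            if exposure == "ln25ohd" and outcome == "ln25ohd":
                continue
            model_covs = covs_ohd if outcome == "ln25ohd" else covs
            scale = "per_allele" if exposure != "ln25ohd" else "per_ln_unit"
            try:
                if outcome == "hypertension":
                    res = fit_logistic(
                        cohort, outcome, exposure, model_covs, study_id=study_id, scale=scale
                    )
                else:
                    res = fit_linear(
                        cohort, outcome, exposure, model_covs, study_id=study_id, scale=scale
                    )
            except Exception as exc:
                raise RuntimeError(
                    f"study {study_id!r}: model {exposure}->{outcome} failed: {exc}"
                ) from exc
            results.append(res)
    return results


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    rows = [
        {
            "study_id": r.study_id,
            "exposure": r.exposure,
            "outcome": r.outcome,
            "beta": r.beta,
            "se": r.se,
            "n": r.n,
            "scale": r.scale,
            "covariates": ",".join(r.covariates),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def frame_to_results(frame: pd.DataFrame) -> list[AssocResult]:
    out = []
    for _, row in frame.iterrows():
        covs = row.get("covariates", "")
        covs_t = tuple(str(covs).split(",")) if isinstance(covs, str) and covs else ()
        out.append(
            AssocResult(
                study_id=str(row.get("study_id", "")),
                exposure=str(row["exposure"]),
                outcome=str(row["outcome"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                n=int(row["n"]),
                scale=str(row.get("scale", "per_allele")),
                covariates=covs_t,
            )
        )
    return out


def write_assoc_table(results: list[AssocResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_assoc_table(path) -> list[AssocResult]:
    return frame_to_results(pd.read_csv(path, sep="\t"))
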