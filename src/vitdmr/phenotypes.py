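"""Phenotype definitions: hypertension classification, antihypertensive
treatment correction, and the log/percent scale for 25(OH)D.

Hypertension is SBP >= 140 mm Hg, DBP >= 90 mm Hg, or current use of
antihypertensive drugs (thresholds inclusive), judged on the observed,
uncorrected pressures.  For continuous blood-pressure outcomes, treated
individuals' observed pressures are corrected upward by a fixed +15 mm Hg
(systolic) / +10 mm Hg (diastolic) to approximate the untreated value.
25(OH)D (nmol/L) is analysed on the natural-log scale; per-allele effects on
that scale are reported as percent differences, 100*(exp(beta)-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("vitdmr")

SBP_TREATMENT_OFFSET = 15.0  # mm Hg added back for treated individuals
DBP_TREATMENT_OFFSET = 10.0
SBP_HYPERTENSION_THRESHOLD = 140.0  # inclusive
DBP_HYPERTENSION_THRESHOLD = 90.0


@dataclass(frozen=True)
class BpRecord:
    """One individual's blood pressure (mm Hg) and treatment flag."""

    sbp: float
    dbp: float
    on_meds: bool

    def __post_init__(self) -> None:
        if self.on_meds is None:
            raise ValueError("on_meds flag is required; no silent default")
        if not (np.isfinite(self.sbp) and np.isfinite(self.dbp)):
            raise ValueError("non-finite blood pressure")
        if not self.sbp > self.dbp >= 0:
            logger.warning(
                "non-physiologic BP record: sbp=%.1f dbp=%.1f", self.sbp, self.dbp
            )


def adjust_bp_for_treatment(record: BpRecord) -> BpRecord:
    """Add 15/10 mm Hg to a treated individual's SBP/DBP; untreated unchanged.

    Not idempotent — apply exactly once per record.
    """
    if not record.on_meds:
        return record
    return replace(
        record,
        sbp=record.sbp + SBP_TREATMENT_OFFSET,
        dbp=record.dbp + DBP_TREATMENT_OFFSET,
    )


def classify_hypertension(record: BpRecord) -> bool:
    """Hypertension: SBP >= 140, DBP >= 90 (observed values), or on treatment."""
    return (
        record.sbp >= SBP_HYPERTENSION_THRESHOLD
        or record.dbp >= DBP_HYPERTENSION_THRESHOLD
        or bool(record.on_meds)
    )


def ln_transform_25ohd(value):
    """Natural log of a 25(OH)D concentration (nmol/L); rejects values <= 0."""
    arr = np.asarray(value, dtype=float)
    bad = ~(arr > 0)
    if np.any(bad):
        idx = np.nonzero(np.atleast_1d(bad))[0]
        raise ValueError(
            f"25(OH)D must be positive for the log transform; offending record(s) {idx.tolist()}"
        )
    out = np.log(arr)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def percent_per_allele(beta_ln: float) -> float:
    """Convert a per-allele effect on ln 25(OH)D to a percent difference.

    Uses 100*(exp(beta)-1); at beta ~ 0.028 this differs from 100*beta by
    under 2%, and the triangulation arithmetic works under either
    convention.  :func:`ln_per_allele` is the exact inverse.
    """
    return 100.0 * (np.exp(beta_ln) - 1.0)


def ln_per_allele(percent: float) -> float:
    """Inverse of :func:`percent_per_allele`."""
    return np.log(1.0 + percent / 100.0)


def prepare_cohort(
    table: pd.DataFrame,
    *,
    sbp_col: str = "sbp_observed",
    dbp_col: str = "dbp_observed",
    meds_col: str = "on_meds",
    ohd_col: str = "ohd_25",
) -> pd.DataFrame:
    """Apply the phenotype definitions to a cohort table (returns a copy).

    Adds ``sbp``/``dbp`` (treatment-corrected continuous outcomes),
    ``hypertension`` (binary, from observed BP or treatment), and
    ``ln25ohd`` when a raw 25(OH)D column is present.  Input columns are
    left untouched.
    """
    if meds_col not in table.columns:
        raise ValueError(f"missing treatment flag column {meds_col!r}")
    out = table.copy()
    treated = out[meds_col].astype(bool)
    if out[meds_col].isna().any():
        raise ValueError("on_meds contains missing values; no silent default")
    out["sbp"] = out[sbp_col] + np.where(treated, SBP_TREATMENT_OFFSET, 0.0)
    out["dbp"] = out[dbp_col] + np.where(treated, DBP_TREATMENT_OFFSET, 0.0)
    out["hypertension"] = (
        (out[sbp_col] >= SBP_HYPERTENSION_THRESHOLD)
        | (out[dbp_col] >= DBP_HYPERTENSION_THRESHOLD)
        | treated
    ).astype(int)
    if ohd_col in out.columns and "ln25ohd" not in out.columns:
        out["ln25ohd"] = ln_transform_25ohd(out[ohd_col].to_numpy())
    return out
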