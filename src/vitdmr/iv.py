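"""Instrumental-variable (Wald ratio) estimation and instrument diagnostics.

The causal effect of 25(OH)D on a blood-pressure outcome is estimated as
the ratio of two genetic associations,

    ratio per 10% increase in 25(OH)D = (beta_ZY / beta_ZX%) * 10,

where beta_ZY is the score–outcome effect per allele (mm Hg, or log-odds
for hypertension) and beta_ZX% the score–25(OH)D effect per allele on the
percent scale.  The ratio variance comes from a first-order Taylor
expansion (delta method) with the numerator–denominator covariance set to
zero; binary outcomes build the confidence interval on the log-odds scale
and exponentiate it to an odds ratio.

Instrument strength is summarised by F = R^2 (n-2) / (1 - R^2) and the
weak-instrument relative bias of the IV estimate versus ordinary least
squares, approximated by 1/F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .regression import AssocResult

Z95 = 1.959963984540054  # normal 97.5% quantile; meta-analytic (not t) reference


@dataclass
class IvEstimate:
    """Causal effect per 10% increase in 25(OH)D.

    ``ratio`` is mm Hg for continuous outcomes, log-odds for binary ones
    (``odds_ratio``/``or_ci`` give the exponentiated form).  The covariance
    between numerator and denominator is taken as zero (flagged here as
    metadata): the two associations come from overlapping samples but no
    covariance is available, matching the standard two-stage ratio.
    """

    ratio: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    binary: bool = False
    outcome: str = ""
    numerator_denominator_cov: float = 0.0

    @property
    def odds_ratio(self) -> float:
        if not self.binary:
            raise ValueError("odds ratio defined only for binary outcomes")
        return float(np.exp(self.ratio))

    @property
    def or_ci(self) -> tuple[float, float]:
        if not self.binary:
            raise ValueError("odds ratio defined only for binary outcomes")
        return (float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))


@dataclass
class InstrumentDiagnostics:
    """Strength of the allele score as an instrument for 25(OH)D."""

    r2: float
    n: int
    f_stat: float
    relative_bias: float


def taylor_se(beta_zy: float, se_zy: float, beta_zx: float, se_zx: float) -> float:
    """Delta-method SE of the ratio beta_zy / beta_zx (per-allele scale).

    First-order expansion with zero numerator–denominator covariance:
    var = se_zy^2/beta_zx^2 + beta_zy^2 se_zx^2 / beta_zx^4.
    """
    if beta_zx == 0:
        raise ZeroDivisionError("beta_zx must be nonzero for the ratio variance")
    if se_zy < 0 or se_zx < 0:
        raise ValueError("standard errors must be non-negative")
    var = se_zy**2 / beta_zx**2 + beta_zy**2 * se_zx**2 / beta_zx**4
    return float(np.sqrt(var))


def iv_ratio(
    beta_zy: float,
    se_zy: float,
    beta_zx_percent: float,
    se_zx_percent: float,
    *,
    binary: bool = False,
    outcome: str = "",
) -> IvEstimate:
    """Wald ratio per 10% increase in 25(OH)D, with delta-method interval.

    ``beta_zx_percent`` must be positive (the score is oriented to increase
    25(OH)D); the per-10% convention divides by the percent-per-allele
    effect and scales by 10, i.e. it is linear in percent.
    """
    if not beta_zx_percent > 0:
        raise ValueError(
            "beta_zx_percent must be > 0: orient the score to the 25(OH)D-increasing allele"
        )
    ratio = beta_zy / beta_zx_percent * 10.0
    se = taylor_se(beta_zy, se_zy, beta_zx_percent, se_zx_percent) * 10.0
    ci_low, ci_high = ratio - Z95 * se, ratio + Z95 * se
    p = float(2.0 * stats.norm.sf(abs(ratio / se))) if se > 0 else (1.0 if ratio == 0 else 0.0)
    return IvEstimate(
        ratio=float(ratio),
        se=float(se),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=p,
        binary=binary,
        outcome=outcome,
    )


def iv_from_assoc(
    score_outcome: AssocResult, beta_zx_percent: float, se_zx_percent: float
) -> IvEstimate:
    """Convenience wrapper taking the score–outcome association object."""
    return iv_ratio(
        score_outcome.beta,
        score_outcome.se,
        beta_zx_percent,
        se_zx_percent,
        binary="log_odds" in score_outcome.scale or score_outcome.outcome == "hypertension",
        outcome=score_outcome.outcome,
    )


def f_statistic(r2: float, n: int) -> InstrumentDiagnostics:
    """Instrument-strength F and relative weak-instrument bias 1/F.

    ``r2`` is the proportion of exposure (ln 25(OH)D) variance explained by
    the allele score in a sample of ``n``.
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must lie in [0, 1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    f = r2 * (n - 2) / (1.0 - r2)
    bias = 1.0 / f if f > 0 else float("inf")
    return InstrumentDiagnostics(r2=float(r2), n=int(n), f_stat=float(f), relative_bias=float(bias))
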