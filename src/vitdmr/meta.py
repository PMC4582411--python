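"""Meta-analysis: inverse-variance pooling, heterogeneity, meta-regression,
and the summary-statistic approximation of allele-score effects.

Per-study associations are pooled with fixed-effect inverse-variance
weights unless Cochran's Q signals heterogeneity (p < alpha_q, default
0.05), in which case a DerSimonian–Laird random-effects model is used.
Consortium results enter as an extra stratum via a second inverse-variance
combination.  When only per-SNP summary statistics are available, the
allele-score effect is approximated by a dosage-variance-weighted average
of the component SNP effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression import AssocResult
from .scores import ScoreDef

logger = logging.getLogger("vitdmr")


@dataclass
class MetaResult:
    """Pooled effect with heterogeneity diagnostics.

    ``q`` is Cochran's Q on ``df = k-1`` degrees of freedom, ``i2`` the
    percent of total variation attributable to between-study heterogeneity
    (max(0, (Q-df)/Q)*100) and ``tau2`` the DerSimonian–Laird between-study
    variance (0 under the fixed-effect model).
    """

    beta: float
    se: float
    model: str  # "fixed" | "random"
    q: float
    df: int
    p_q: float
    i2: float
    tau2: float
    k: int
    inputs: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def p(self) -> float:
        z = self.beta / self.se
        return float(2.0 * stats.norm.sf(abs(z)))


def _unpack(estimates) -> tuple[np.ndarray, np.ndarray, list[str]]:
    betas, ses, labels = [], [], []
    for est in estimates:
        if isinstance(est, AssocResult):
            betas.append(est.beta)
            ses.append(est.se)
            labels.append(est.study_id)
        else:
            b, s = est[0], est[1]
            betas.append(float(b))
            ses.append(float(s))
            labels.append(str(est[2]) if len(est) > 2 else "")
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.any(s <= 0):
        raise ValueError("all standard errors must be > 0")
    return b, s, labels


def _heterogeneity(b: np.ndarray, s: np.ndarray) -> tuple[float, int, float, float]:
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(b) - 1
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p_q, i2


def meta_fixed(estimates) -> MetaResult:
    """Fixed-effect inverse-variance pooling (weights 1/se^2)."""
    b, s, labels = _unpack(estimates)
    if len(b) == 0:
        raise ValueError("meta_fixed needs at least one estimate")
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q, df, p_q, i2 = _heterogeneity(b, s)
    return MetaResult(pooled, se, "fixed", q, df, p_q, i2, 0.0, len(b), list(zip(b, s, labels)))


def dl_tau2(estimates) -> float:
    """DerSimonian–Laird method-of-moments between-study variance."""
    b, s, _ = _unpack(estimates)
    w = 1.0 / s**2
    q, df, _, _ = _heterogeneity(b, s)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, (q - df) / denom)


def meta_random(estimates) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    Fixed-effect weights give Q and tau2; studies are then re-weighted by
    1/(se^2 + tau2).  With tau2 = 0 this reduces exactly to
    :func:`meta_fixed`.
    """
    b, s, labels = _unpack(estimates)
    if len(b) < 2:
        raise ValueError("meta_random needs at least two estimates")
    tau2 = dl_tau2(estimates)
    w_star = 1.0 / (s**2 + tau2)
    pooled = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    q, df, p_q, i2 = _heterogeneity(b, s)
    return MetaResult(pooled, se, "random", q, df, p_q, i2, tau2, len(b), list(zip(b, s, labels)))


def select_model(fixed_result: MetaResult, alpha_q: float = 0.05) -> str:
    """Random effects iff the heterogeneity p-value is strictly below alpha_q."""
    choice = "random" if fixed_result.p_q < alpha_q else "fixed"
    logger.info(
        "model selection: Q=%.3f df=%d p=%.4f -> %s", fixed_result.q, fixed_result.df,
        fixed_result.p_q, choice,
    )
    return choice


def meta_analyse(estimates, alpha_q: float = 0.05) -> MetaResult:
    """Pool with the heterogeneity-driven fixed/random rule."""
    fixed = meta_fixed(estimates)
    if fixed.k >= 2 and select_model(fixed, alpha_q) == "random":
        return meta_random(estimates)
    return fixed


def meta_regression(estimates, covariate) -> tuple[float, float, float]:
    """Univariate random-effects meta-regression of study effects on one
    study-level covariate.

    Method-of-moments residual tau2 from the fixed-weight WLS fit, then a
    re-weighted fit with weights 1/(se^2 + tau2).  Returns
    ``(slope, se, p)``; the p-value uses a normal reference.
    """
    b, s, _ = _unpack(estimates)
    x = np.asarray(covariate, dtype=float)
    k = len(b)
    if k < 3:
        raise ValueError("meta-regression needs at least three studies")
    if x.shape[0] != k:
        raise ValueError("covariate length must match the number of studies")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    X = np.column_stack([np.ones(k), x])
    p = X.shape[1]

    def _wls(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        W = np.diag(weights)
        xtwx_inv = np.linalg.inv(X.T @ W @ X)
        coef = xtwx_inv @ X.T @ W @ b
        return coef, xtwx_inv

    w = 1.0 / s**2
    coef, _ = _wls(w)
    resid = b - X @ coef
    q_res = float(np.sum(w * resid**2))
    # E[Q_res] = (k - p) + tau2 * (tr(W) - tr((X'WX)^-1 X'W^2 X))
    W = np.diag(w)
    xtwx_inv = np.linalg.inv(X.T @ W @ X)
    trace_corr = float(np.trace(W) - np.trace(xtwx_inv @ X.T @ W @ W @ X))
    tau2 = max(0.0, (q_res - (k - p)) / trace_corr) if trace_corr > 0 else 0.0

    w_star = 1.0 / (s**2 + tau2)
    coef, cov = _wls(w_star)
    slope = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    pval = float(2.0 * stats.norm.sf(abs(slope / se)))
    return slope, se, pval


def approximate_score_effect(
    per_snp: pd.DataFrame, score_def: ScoreDef, *, outcome: str = "", study_id: str = "consortium"
) -> AssocResult:
    """Per-allele allele-score effect from harmonised per-SNP summary rows.

    With independent SNPs, the coefficient of an unweighted score on an
    outcome equals the dosage-variance-weighted average of the per-SNP
    coefficients: score effect = sum(v_j b_j) / sum(v_j) with
    v_j = 2*eaf_j*(1-eaf_j), and se = sqrt(sum(v_j^2 se_j^2)) / sum(v_j).
    """
    rows = per_snp.set_index("snp_id") if "snp_id" in per_snp.columns else per_snp
    v, bs, ses, ns = [], [], [], []
    for snp in score_def.snps:
        if snp.snp_id not in rows.index:
            raise KeyError(f"missing summary row for {snp.snp_id}")
        row = rows.loc[snp.snp_id]
        eaf = float(row["eaf"])
        if not np.isfinite(eaf):
            raise ValueError(f"{snp.snp_id}: missing EAF")
        v.append(2.0 * eaf * (1.0 - eaf))
        bs.append(float(row["beta"]))
        ses.append(float(row["se"]))
        ns.append(int(row["n"]) if "n" in row and np.isfinite(float(row["n"])) else 0)
    v_arr = np.asarray(v)
    beta = float(np.sum(v_arr * bs) / np.sum(v_arr))
    se = float(np.sqrt(np.sum(v_arr**2 * np.asarray(ses) ** 2)) / np.sum(v_arr))
    out_label = outcome or (str(rows.iloc[0]["outcome"]) if "outcome" in rows.columns else "")
    return AssocResult(
        study_id=study_id,
        exposure=f"score_{score_def.name}",
        outcome=out_label,
        beta=beta,
        se=se,
        n=max(ns) if ns else 0,
        scale="per_allele",
    )


def combine_with_consortium(
    cohort_meta: MetaResult, consortium: AssocResult, *, scale: str | None = None
) -> MetaResult:
    """Inverse-variance combination of a pooled cohort estimate with an
    external consortium estimate (overlap excluded upstream).

    The two strata are treated as fixed; between-stratum heterogeneity is
    reported in the Q/I2 fields of the returned result.  When ``scale`` is
    given, a consortium row on a different scale is refused.
    """
    if np.isnan(consortium.se) or consortium.se <= 0:
        raise ValueError("consortium se must be > 0")
    if scale is not None and consortium.scale != scale:
        raise ValueError(
            f"scale mismatch: consortium row is {consortium.scale!r}, expected {scale!r}"
        )
    strata = [
        (cohort_meta.beta, cohort_meta.se, "cohort_meta"),
        (consortium.beta, consortium.se, consortium.study_id or "consortium"),
    ]
    return meta_fixed(strata)


def forest_table(meta: MetaResult) -> pd.DataFrame:
    """Per-study table (study, beta, se, weight %) ready for a forest plot."""
    b = np.array([x[0] for x in meta.inputs])
    s = np.array([x[1] for x in meta.inputs])
    w = 1.0 / (s**2 + meta.tau2)
    return pd.DataFrame(
        {
            "study_id": [x[2] for x in meta.inputs],
            "beta": b,
            "se": s,
            "weight_pct": 100.0 * w / w.sum(),
        }
    )
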