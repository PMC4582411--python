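"""SNP panel definitions, unweighted allele scores, and summary-statistic
harmonisation.

The instrument is an unweighted allele score: the per-individual count of
25(OH)D-increasing alleles across a pair of SNPs.  Two scores are defined,

* the *synthesis* score — variants in genes upstream of 25(OH)D production
  (``DHCR7`` rs12785878 and ``CYP2R1`` rs12794714; range 0–4), usable as a
  Mendelian-randomisation instrument, and
* the *metabolism* score — variants in genes downstream of the metabolite
  (``GC`` rs2282679 and ``CYP24A1`` rs6013897; range 0–4), exploratory only
  because of known pleiotropy.

Scores are unweighted (a plain sum of effect-allele dosages): external
per-SNP weights for 25(OH)D were not available to the original analysts and
internal weights can bias instrumental-variable results.

External GWAS summary rows are harmonised to the same 25(OH)D-increasing
effect allele before being combined with cohort results; palindromic (A/T or
C/G) SNPs of unknown strand are excluded rather than silently flipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("vitdmr")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_ALLELES = frozenset(COMPLEMENT)


class HarmonisationError(ValueError):
    """Alleles of a summary row cannot be reconciled with the target SNP."""


class PalindromicSnpWarning(UserWarning):
    """A palindromic (A/T or C/G) SNP was excluded for strand ambiguity."""


@dataclass(frozen=True)
class SnpSpec:
    """One SNP of the vitamin D panel.

    ``effect_allele`` is the 25(OH)D-increasing allele; ``beta_ln_25ohd`` is
    its additive per-allele effect on ln 25(OH)D and is what the simulator
    uses as generative truth.  ``role`` assigns the SNP to the synthesis or
    metabolism score.
    """

    snp_id: str
    gene: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta_ln_25ohd: float
    role: str  # "synthesis" | "metabolism"

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.snp_id}: eaf must lie strictly in (0, 1)")
        if self.role not in ("synthesis", "metabolism"):
            raise ValueError(f"{self.snp_id}: unknown role {self.role!r}")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


# Default panel.  Orientations are the 25(OH)D-increasing alleles with
# round European-ancestry frequencies; per-allele ln-25(OH)D effects are
# defaults chosen so the default simulated synthesis score shows a
# ~2.8%/allele association with 25(OH)D and the metabolism score ~5.4%
# (the magnitudes the score analyses are designed around), not estimates.
DEFAULT_PANEL: tuple[SnpSpec, ...] = (
    SnpSpec("rs12785878", "DHCR7", "T", "G", 0.75, 0.0279, "synthesis"),
    SnpSpec("rs12794714", "CYP2R1", "G", "A", 0.50, 0.0279, "synthesis"),
    SnpSpec("rs2282679", "GC", "T", "G", 0.72, 0.0524, "metabolism"),
    SnpSpec("rs6013897", "CYP24A1", "T", "A", 0.79, 0.0524, "metabolism"),
)


@dataclass(frozen=True)
class ScoreDef:
    """An allele score: the unweighted sum of two effect-allele dosages."""

    name: str
    snps: tuple[SnpSpec, SnpSpec]

    def __post_init__(self) -> None:
        if len(self.snps) != 2:
            raise ValueError("an allele score is built from exactly two SNPs")
        roles = {s.role for s in self.snps}
        if roles != {self.name}:
            raise ValueError(f"score {self.name!r} mixes SNP roles {roles}")

    @property
    def snp_ids(self) -> tuple[str, str]:
        return tuple(s.snp_id for s in self.snps)  # type: ignore[return-value]


def default_scores(panel: Sequence[SnpSpec] = DEFAULT_PANEL) -> dict[str, ScoreDef]:
    """Build the synthesis and metabolism ScoreDefs from a 4-SNP panel."""
    out: dict[str, ScoreDef] = {}
    for role in ("synthesis", "metabolism"):
        members = tuple(s for s in panel if s.role == role)
        if len(members) != 2:
            raise ValueError(f"panel must contain exactly two {role} SNPs")
        out[role] = ScoreDef(role, members)  # type: ignore[arg-type]
    return out


def compute_score(dosages: pd.DataFrame | dict, score_def: ScoreDef) -> pd.Series | float:
    """Sum the two effect-allele dosages of a score.

    ``dosages`` maps SNP id -> dosage in [0, 2] (columns of a DataFrame or a
    plain mapping).  Fractional (imputed) dosages are accepted.  A missing
    component SNP is an error — there is no single-SNP fallback.
    """
    cols = []
    for snp in score_def.snps:
        try:
            col = dosages[snp.snp_id]
        except KeyError as exc:
            raise KeyError(
                f"score {score_def.name!r}: missing dosage column {snp.snp_id!r}"
            ) from exc
        arr = np.asarray(col, dtype=float)
        if np.any((arr < 0) | (arr > 2)):
            raise ValueError(f"{snp.snp_id}: dosages outside [0, 2]")
        cols.append(col)
    total = cols[0] + cols[1]
    return total


def add_scores_to_table(
    table: pd.DataFrame, scores: Iterable[ScoreDef] | None = None
) -> pd.DataFrame:
    """Return a copy of a cohort table with ``score_<name>`` columns added.

    Individuals with a missing component dosage are dropped (complete-case)
    with a logged count.
    """
    if scores is None:
        scores = default_scores().values()
    out = table.copy()
    for sd in scores:
        needed = list(sd.snp_ids)
        missing = out[needed].isna().any(axis=1)
        if missing.any():
            logger.warning(
                "score %s: dropping %d individuals with missing dosages",
                sd.name,
                int(missing.sum()),
            )
            out = out.loc[~missing]
        out[f"score_{sd.name}"] = compute_score(out[needed], sd)
    return out


def harmonise_summary_row(row: dict | pd.Series, target: SnpSpec, *, trust_strand: bool = False) -> dict | None:
    """Orient one external summary row to the target's effect allele.

    Returns the (possibly sign/EAF-flipped) row as a dict, or ``None`` when
    the SNP is palindromic and the strand is not trusted — such rows are
    excluded with a warning rather than guessed at.

    Rules, in order: identical orientation -> unchanged; swapped alleles ->
    beta sign flipped and EAF complemented; same tests on the strand
    complements; anything else -> :class:`HarmonisationError`.
    """
    ea = str(row["effect_allele"]).upper()
    oa = str(row["other_allele"]).upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise HarmonisationError(f"{target.snp_id}: non-ACGT alleles {ea}/{oa}")

    palindromic = COMPLEMENT[ea] == oa
    if palindromic and not trust_strand:
        warnings.warn(
            f"{target.snp_id}: palindromic alleles {ea}/{oa} with unknown strand; excluded",
            PalindromicSnpWarning,
            stacklevel=2,
        )
        logger.warning("harmonise: excluded palindromic SNP %s (%s/%s)", target.snp_id, ea, oa)
        return None

    out = dict(row)

    def _apply(flip: bool) -> dict:
        if flip:
            out["beta"] = -float(row["beta"])
            if "eaf" in out and out["eaf"] is not None and np.isfinite(float(out["eaf"])):
                out["eaf"] = 1.0 - float(row["eaf"])
        out["effect_allele"] = target.effect_allele
        out["other_allele"] = target.other_allele
        return out

    if (ea, oa) == (target.effect_allele, target.other_allele):
        return _apply(False)
    if (ea, oa) == (target.other_allele, target.effect_allele):
        return _apply(True)
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (target.effect_allele, target.other_allele):
        return _apply(False)
    if (cea, coa) == (target.other_allele, target.effect_allele):
        return _apply(True)
    raise HarmonisationError(
        f"{target.snp_id}: alleles {ea}/{oa} match neither orientation of "
        f"{target.effect_allele}/{target.other_allele} nor their complements"
    )


def harmonise_table(
    table: pd.DataFrame, panel: Sequence[SnpSpec] = DEFAULT_PANEL, *, trust_strand: bool = False
) -> pd.DataFrame:
    """Harmonise a per-SNP summary table to the panel's effect alleles.

    Rows for SNPs outside the panel are dropped; palindromic-ambiguous rows
    are excluded per :func:`harmonise_summary_row`.
    """
    by_id = {s.snp_id: s for s in panel}
    kept: list[dict] = []
    for _, row in table.iterrows():
        target = by_id.get(row["snp_id"])
        if target is None:
            continue
        res = harmonise_summary_row(row, target, trust_strand=trust_strand)
        if res is not None:
            kept.append(res)
    return pd.DataFrame(kept, columns=list(table.columns))


def read_summary_stats(path) -> pd.DataFrame:
    """Read a tab-separated per-SNP summary-statistic table."""
    return pd.read_csv(path, sep="\t")


def write_summary_stats(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
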