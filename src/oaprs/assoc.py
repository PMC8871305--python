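"""Per-SNP case-control association under the additive model.

Each SNP is tested by maximum-likelihood logistic regression of case
status on minor-allele dosage (0/1/2) plus covariates; the per-allele odds
ratio is exp(beta) with a Wald 95% interval and Wald p-value.  Samples
with a missing dosage or covariate are dropped per SNP (complete-case),
with the n actually used reported.  ``scan`` applies the screening
threshold (default p < 5e-5) and ``bonferroni_flag`` marks genome-wide
significance at p < 5e-8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotype import MISSING, GenotypeMatrix

P_SCREEN_DEFAULT = 5e-5
GENOMEWIDE_DEFAULT = 5e-8


class DegeneratePredictorError(ValueError):
    """Raised when a SNP's dosage column is constant among usable samples."""


@dataclass(frozen=True)
class AssocResult:
    snp_id: str
    chrom: str
    pos: int
    minor_allele: str
    or_per_allele: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    converged: bool = True
    bonferroni: bool | None = None

    def __post_init__(self) -> None:
        if self.converged and not (self.ci_low <= self.or_per_allele <= self.ci_high):
            raise ValueError(f"{self.snp_id}: CI does not bracket the OR")


def _design(g: GenotypeMatrix, cohort: pd.DataFrame, snp_id: str,
            covariates: list[str],
            missing_policy: str) -> tuple[np.ndarray, np.ndarray, int]:
    dose = g.column(snp_id).astype(float)
    miss = g.column(snp_id) == MISSING
    cohort = cohort.set_index("sample").loc[g.samples]
    y = cohort["case"].to_numpy(float)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    cov = cohort[covariates].to_numpy(float) if covariates else \
        np.empty((len(y), 0))
    usable = np.isfinite(cov).all(axis=1) & np.isfinite(y)
    if missing_policy == "complete":
        usable &= ~miss
    elif missing_policy == "mean":
        if miss.any() and (~miss).any():
            dose = dose.copy()
            dose[miss] = dose[~miss].mean()
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    X = np.column_stack([np.ones(usable.sum()), dose[usable], cov[usable]])
    return X, y[usable], int(usable.sum())


def fit_snp_association(g: GenotypeMatrix, cohort: pd.DataFrame, snp_id: str,
                        covariates: list[str] | None = None,
                        missing_policy: str = "complete") -> AssocResult:
    """Additive-model logistic association for one SNP.

    Non-convergence or separation yields a flagged result (``converged``
    False, p = nan) rather than an exception; a constant dosage column
    raises :class:`DegeneratePredictorError`.
    """
    covariates = covariates or []
    rec = g.snps[g.snp_index(snp_id)]
    X, y, n_used = _design(g, cohort, snp_id, covariates, missing_policy)
    if n_used == 0 or np.ptp(X[:, 1]) == 0:
        raise DegeneratePredictorError(
            f"{snp_id}: dosage is constant among the {n_used} usable samples")
    flagged = AssocResult(snp_id=snp_id, chrom=rec.chrom, pos=rec.pos,
                          minor_allele=rec.minor_allele,
                          or_per_allele=float("nan"), ci_low=float("nan"),
                          ci_high=float("nan"), p=float("nan"),
                          n_used=n_used, converged=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return flagged
    if not fit.mle_retvals.get("converged", False):
        return flagged
    beta = fit.params[1]
    se = fit.bse[1]
    if not np.isfinite(se) or se > 50:  # separation blows the Wald SE up
        return flagged
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    half = 1.959963984540054 * se
    return AssocResult(snp_id=snp_id, chrom=rec.chrom, pos=rec.pos,
                       minor_allele=rec.minor_allele,
                       or_per_allele=float(np.exp(beta)),
                       ci_low=float(np.exp(beta - half)),
                       ci_high=float(np.exp(beta + half)),
                       p=float(p), n_used=n_used)


def scan(g: GenotypeMatrix, cohort: pd.DataFrame,
         covariates: list[str] | None = None,
         p_screen: float = P_SCREEN_DEFAULT,
         missing_policy: str = "complete") -> list[AssocResult]:
    """Test every SNP; return those with p < ``p_screen``, sorted ascending
    by p (ties broken by SNP id).  Untestable SNPs (constant dosage) are
    skipped; flagged non-converged fits never pass the screen."""
    if not 0.0 < p_screen <= 1.0:
        raise ValueError(f"p_screen must lie in (0,1], got {p_screen}")
    out = []
    for rec in g.snps:
        try:
            res = fit_snp_association(g, cohort, rec.id, covariates,
                                      missing_policy)
        except DegeneratePredictorError:
            continue
        if res.converged and res.p < p_screen:
            out.append(res)
    out.sort(key=lambda r: (r.p, r.snp_id))
    return out


def bonferroni_flag(results: list[AssocResult],
                    genomewide: float = GENOMEWIDE_DEFAULT) -> list[AssocResult]:
    """Annotate each result with strict p < ``genomewide`` significance."""
    if not 0.0 < genomewide < 1.0:
        raise ValueError(f"genomewide threshold must lie in (0,1)")
    return [replace(r, bonferroni=bool(r.p < genomewide)) for r in results]


def results_table(results: list[AssocResult]) -> pd.DataFrame:
    """Results as a DataFrame with CHR/SNP/POS/MINOR/OR/L95/U95/P/N columns."""
    return pd.DataFrame(
        [{"CHR": r.chrom, "SNP": r.snp_id, "POS": r.pos, "MINOR": r.minor_allele,
          "OR": r.or_per_allele, "L95": r.ci_low, "U95": r.ci_high,
          "P": r.p, "N": r.n_used,
          **({"BONFERRONI": r.bonferroni} if r.bonferroni is not None else {})}
         for r in results])
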