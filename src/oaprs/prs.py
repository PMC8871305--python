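"""Unweighted polygenic risk score over the SNPs of a selected model.

The risk allele at each model SNP is oriented from its per-allele
association odds ratio: the minor (coded) allele when OR > 1, the major
allele when OR < 1.  Each sample's score is the sum of risk-allele copies
across the model SNPs (0..2k); a genotype missing at one SNP contributes
that SNP's rounded cohort-mean risk count so the cohort size stays stable.
Scores are banded into Low/Medium/High categories (5-SNP model: 0-3 /
4-6 / >6; 6-SNP model: 0-4 / 5-7 / >7 — the bands that label the reported
odds ratios; an alternative 5-SNP banding 0-3 / 4-5 / >=6 is selectable)
and category effects are estimated by covariate-adjusted logistic
regression with Low as the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotype import MISSING, GenotypeMatrix
from .assoc import AssocResult

CATEGORIES = ("Low", "Medium", "High")

# (low_max, medium_max): Low <= low_max < Medium <= medium_max < High
CUTOFF_SETS: dict[str, tuple[int, int]] = {
    "5-SNP": (3, 6),        # 0-3 / 4-6 / >6 (table-footnote banding)
    "6-SNP": (4, 7),        # 0-4 / 5-7 / >7
    "5-SNP-alt": (3, 5),    # 0-3 / 4-5 / >=6 (methods-text banding)
}

# covariate sets for the two adjusted logistic models
MODEL1_COVARIATES = ["sex", "age"]
MODEL2_COVARIATES = MODEL1_COVARIATES + ["energy_pct_eer", "alcohol_g_day",
                                         "exercise_min_week"]


class AmbiguousOrientationError(ValueError):
    """OR exactly 1 gives no direction for the risk allele."""


@dataclass(frozen=True)
class RiskAllele:
    snp_id: str
    allele: str
    risk_is_minor: bool   # True: dosage counts risk copies directly


@dataclass
class PrsAssignment:
    sample_id: str
    risk_allele_count: int
    category: str | None = None
    model_tag: str = ""


def risk_allele_orientation(assoc: list[AssocResult],
                            model_snps: list[str]) -> list[RiskAllele]:
    """Risk allele per model SNP from the association odds ratios.

    OR > 1: the minor (coded) allele raises risk; OR < 1: the major allele
    does (a protective minor allele); OR == 1 is ambiguous and rejected.
    """
    by_id = {r.snp_id: r for r in assoc}
    out = []
    for sid in model_snps:
        if sid not in by_id:
            raise KeyError(f"no association result for model SNP {sid!r}")
        r = by_id[sid]
        if not np.isfinite(r.or_per_allele) or r.or_per_allele == 1.0:
            raise AmbiguousOrientationError(
                f"{sid}: OR of exactly 1 gives no risk-allele direction")
        out.append(RiskAllele(snp_id=sid, allele=r.minor_allele,
                              risk_is_minor=r.or_per_allele > 1.0))
    return out


def compute_prs(g: GenotypeMatrix, risk_alleles: list[RiskAllele],
                model_tag: str = "") -> tuple[list[PrsAssignment], pd.DataFrame]:
    """Per-sample risk-allele count over the model SNPs.

    A missing genotype contributes the rounded cohort-mean risk count at
    that SNP (reported in the imputation log); samples missing at every
    model SNP are excluded and reported.
    """
    if not risk_alleles:
        raise ValueError("no model SNPs given")
    cols = []
    log_rows = []
    for ra in risk_alleles:
        dose = g.column(ra.snp_id).astype(float)
        miss = g.column(ra.snp_id) == MISSING
        risk = dose if ra.risk_is_minor else 2.0 - dose
        if miss.any():
            fill = float(np.round(risk[~miss].mean())) if (~miss).any() else 0.0
            risk = risk.copy()
            risk[miss] = fill
            log_rows.append({"snp": ra.snp_id, "n_missing": int(miss.sum()),
                             "filled_with": int(fill)})
        cols.append(risk)
    risk_mat = np.stack(cols, axis=1)
    all_missing = np.stack(
        [g.column(ra.snp_id) == MISSING for ra in risk_alleles], axis=1
    ).all(axis=1)
    assignments = []
    for i, sid in enumerate(g.samples):
        if all_missing[i]:
            log_rows.append({"snp": "*", "n_missing": len(risk_alleles),
                             "filled_with": -1, "excluded_sample": sid})
            continue
        assignments.append(PrsAssignment(
            sample_id=sid, risk_allele_count=int(round(risk_mat[i].sum())),
            model_tag=model_tag))
    log = pd.DataFrame(log_rows)
    return assignments, log


def categorize_prs(assignments: list[PrsAssignment],
                   model_tag: str | None = None,
                   cutoffs: tuple[int, int] | None = None) -> list[PrsAssignment]:
    """Band counts into Low/Medium/High.

    ``cutoffs`` overrides the named set for ``model_tag``; ``(a, b)`` means
    Low <= a < Medium <= b < High.
    """
    if cutoffs is None:
        tag = model_tag or (assignments[0].model_tag if assignments else "")
        if tag not in CUTOFF_SETS:
            raise KeyError(f"no cutoff set named {tag!r}; pass cutoffs=")
        cutoffs = CUTOFF_SETS[tag]
    lo, mid = cutoffs
    if not lo < mid:
        raise ValueError("cutoffs must satisfy low_max < medium_max")
    out = []
    for a in assignments:
        cat = ("Low" if a.risk_allele_count <= lo
               else "Medium" if a.risk_allele_count <= mid else "High")
        out.append(PrsAssignment(a.sample_id, a.risk_allele_count, cat,
                                 a.model_tag))
    return out


def assignments_frame(assignments: list[PrsAssignment]) -> pd.DataFrame:
    return pd.DataFrame([{"sample": a.sample_id,
                          "risk_allele_count": a.risk_allele_count,
                          "category": a.category,
                          "model": a.model_tag} for a in assignments])


@dataclass(frozen=True)
class OrRow:
    contrast: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    model: str


def fit_or_table(assignments: list[PrsAssignment], cohort: pd.DataFrame,
                 outcome: str = "case",
                 covariates: list[str] | None = None,
                 model_tag: str = "model1") -> pd.DataFrame:
    """Adjusted odds ratios for Medium and High PRS vs the Low reference.

    Logistic regression of the outcome on category indicators plus the
    covariates; an empty category is collapsed into its neighbor with a
    warning.  The reference row carries OR exactly 1.
    """
    covariates = covariates or []
    prs = assignments_frame(assignments)
    if prs["category"].isna().any():
        raise ValueError("categorize_prs must run before fit_or_table")
    df = prs.merge(cohort, on="sample", how="inner")
    y = df[outcome].to_numpy(float)
    if not np.isin(y, [0, 1]).all():
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")

    counts = {c: int((df["category"] == c).sum()) for c in CATEGORIES}
    cats = [c for c in CATEGORIES if counts[c] > 0]
    if len(cats) < len(CATEGORIES):
        warnings.warn(f"empty PRS categories collapsed: "
                      f"{sorted(set(CATEGORIES) - set(cats))}", stacklevel=2)
    if len(cats) < 2:
        raise ValueError("need at least two non-empty PRS categories")
    ref, others = cats[0], cats[1:]

    ind = np.column_stack([(df["category"] == c).to_numpy(float)
                           for c in others])
    cov = df[covariates].to_numpy(float) if covariates else \
        np.empty((len(df), 0))
    X = np.column_stack([np.ones(len(df)), ind, cov])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    rows = [OrRow(contrast=f"{ref}-PRS (ref)", odds_ratio=1.0, ci_low=1.0,
                  ci_high=1.0, p=float("nan"), n=counts[ref], model=model_tag)]
    for j, c in enumerate(others, start=1):
        b, se = fit.params[j], fit.bse[j]
        half = 1.959963984540054 * se
        rows.append(OrRow(
            contrast=f"{c}-PRS", odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - half)), ci_high=float(np.exp(b + half)),
            p=float(2 * stats.norm.sf(abs(b / se))), n=counts[c],
            model=model_tag))
    return pd.DataFrame([r.__dict__ for r in rows])
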