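"""PRS x lifestyle interaction analysis.

Exposures are dichotomized at fixed nutrient cutoffs (energy at 100% of
the estimated energy requirement, carbohydrate 70 en%, protein 13 en%,
fat 15 en%, alcohol 20 g/day, exercise 150 min/week) or at the within-
cohort 70th percentile for dietary-pattern scores; "high" is inclusive of
the cutoff.  Within each exposure stratum, Medium- and High-PRS odds
ratios are estimated against the Low-PRS reference by covariate-adjusted
logistic regression.  The PRS x exposure interaction p-value is a 1-df
likelihood-ratio test with the PRS category entered as an ordinal 0/1/2
term (a 2-df indicator-coded variant is available by flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .prs import CATEGORIES, PrsAssignment, assignments_frame

# value >= cutoff defines the high stratum
DEFAULT_CUTOFFS: dict[str, float] = {
    "energy_pct_eer": 100.0,
    "carb_en_pct": 70.0,
    "protein_en_pct": 13.0,
    "fat_en_pct": 15.0,
    "alcohol_g_day": 20.0,
    "exercise_min_week": 150.0,
}

PATTERN_PERCENTILE = 70.0

_ORDINAL = {c: i for i, c in enumerate(CATEGORIES)}


class DegenerateExposureError(ValueError):
    """All samples fall in one exposure stratum."""


@dataclass(frozen=True)
class ExposureSpec:
    name: str
    cutoff: float | None = None      # None -> percentile rule
    source: str = "nutrient"         # nutrient | pattern-percentile | behavior
    percentile: float = PATTERN_PERCENTILE

    def resolve_cutoff(self, values: np.ndarray) -> float:
        if self.cutoff is not None:
            return float(self.cutoff)
        if self.source != "pattern-percentile":
            raise ValueError(f"{self.name}: no cutoff and not percentile-based")
        return float(np.percentile(values, self.percentile))


def default_spec(name: str) -> ExposureSpec:
    if name in DEFAULT_CUTOFFS:
        return ExposureSpec(name=name, cutoff=DEFAULT_CUTOFFS[name])
    return ExposureSpec(name=name, source="pattern-percentile")


def dichotomize_exposure(cohort: pd.DataFrame,
                         spec: ExposureSpec) -> np.ndarray:
    """Boolean high-exposure indicator; high = value >= cutoff (inclusive,
    also at the percentile cutoff)."""
    if spec.name not in cohort.columns:
        raise KeyError(f"exposure column {spec.name!r} not in cohort")
    values = cohort[spec.name].to_numpy(float)
    if np.ptp(values) == 0:
        raise DegenerateExposureError(
            f"{spec.name}: all samples share the value {values[0]}")
    high = values >= spec.resolve_cutoff(values)
    if high.all() or not high.any():
        raise DegenerateExposureError(
            f"{spec.name}: cutoff leaves a single stratum")
    return high


def _merged(assignments: list[PrsAssignment], cohort: pd.DataFrame,
            outcome: str) -> pd.DataFrame:
    df = assignments_frame(assignments).merge(cohort, on="sample", how="inner")
    if df["category"].isna().any():
        raise ValueError("PRS assignments must be categorized")
    y = df[outcome]
    if not y.isin([0, 1]).all():
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    return df


def stratified_or(assignments: list[PrsAssignment], cohort: pd.DataFrame,
                  spec: ExposureSpec, outcome: str = "case",
                  covariates: list[str] | None = None) -> pd.DataFrame:
    """Medium/High-PRS odds ratios vs Low within each exposure stratum.

    Empty stratum x category cells are flagged with NaN estimates, never
    imputed.
    """
    covariates = covariates or []
    df = _merged(assignments, cohort, outcome)
    high = dichotomize_exposure(df, spec)
    rows = []
    for stratum, mask in [("low", ~high), ("high", high)]:
        sub = df[mask]
        for cat in CATEGORIES:
            n = int((sub["category"] == cat).sum())
            if cat == "Low":
                rows.append({"exposure": spec.name, "stratum": stratum,
                             "category": cat, "odds_ratio": 1.0,
                             "ci_low": 1.0, "ci_high": 1.0,
                             "p": float("nan"), "n": n})
        present = [c for c in CATEGORIES
                   if (sub["category"] == c).sum() > 0]
        if len(present) < 2 or "Low" not in present:
            for cat in ("Medium", "High"):
                rows.append({"exposure": spec.name, "stratum": stratum,
                             "category": cat, "odds_ratio": float("nan"),
                             "ci_low": float("nan"), "ci_high": float("nan"),
                             "p": float("nan"),
                             "n": int((sub["category"] == cat).sum())})
            continue
        others = [c for c in present if c != "Low"]
        ind = np.column_stack([(sub["category"] == c).to_numpy(float)
                               for c in others])
        cov = sub[covariates].to_numpy(float) if covariates else \
            np.empty((len(sub), 0))
        X = np.column_stack([np.ones(len(sub)), ind, cov])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(sub[outcome].to_numpy(float), X).fit(disp=0,
                                                                maxiter=200)
        est = {c: (fit.params[j], fit.bse[j])
               for j, c in enumerate(others, start=1)}
        for cat in ("Medium", "High"):
            n = int((sub["category"] == cat).sum())
            if cat in est:
                b, se = est[cat]
                half = 1.959963984540054 * se
                rows.append({"exposure": spec.name, "stratum": stratum,
                             "category": cat,
                             "odds_ratio": float(np.exp(b)),
                             "ci_low": float(np.exp(b - half)),
                             "ci_high": float(np.exp(b + half)),
                             "p": float(2 * stats.norm.sf(abs(b / se))),
                             "n": n})
            else:
                rows.append({"exposure": spec.name, "stratum": stratum,
                             "category": cat, "odds_ratio": float("nan"),
                             "ci_low": float("nan"), "ci_high": float("nan"),
                             "p": float("nan"), "n": n})
    return pd.DataFrame(rows)


def interaction_pvalue(assignments: list[PrsAssignment], cohort: pd.DataFrame,
                       spec: ExposureSpec, outcome: str = "case",
                       covariates: list[str] | None = None,
                       ordinal: bool = True) -> float:
    """Likelihood-ratio p-value for PRS x exposure interaction.

    The full model adds (PRS x exposure) to main effects and covariates;
    with ``ordinal`` the PRS enters the interaction as 0/1/2 (1 df),
    otherwise as category indicators (2 df).
    """
    covariates = covariates or []
    df = _merged(assignments, cohort, outcome)
    high = dichotomize_exposure(df, spec).astype(float)
    y = df[outcome].to_numpy(float)
    ord_prs = df["category"].map(_ORDINAL).to_numpy(float)
    ind = np.column_stack([(df["category"] == c).to_numpy(float)
                           for c in ("Medium", "High")])
    cov = df[covariates].to_numpy(float) if covariates else \
        np.empty((len(df), 0))
    base = np.column_stack([np.ones(len(df)), ind, high, cov])
    if ordinal:
        inter = (ord_prs * high)[:, None]
    else:
        inter = ind * high[:, None]
    full = np.column_stack([base, inter])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit0 = sm.Logit(y, base).fit(disp=0, maxiter=200)
        fit1 = sm.Logit(y, full).fit(disp=0, maxiter=200)
    if not (fit0.mle_retvals.get("converged", False)
            and fit1.mle_retvals.get("converged", False)):
        raise RuntimeError(
            f"{spec.name}: interaction model fit did not converge")
    lr = 2.0 * (fit1.llf - fit0.llf)
    df_diff = inter.shape[1]
    return float(stats.chi2.sf(max(lr, 0.0), df_diff))


def interaction_table(assignments: list[PrsAssignment], cohort: pd.DataFrame,
                      specs: list[ExposureSpec], outcome: str = "case",
                      covariates: list[str] | None = None) -> pd.DataFrame:
    """Stratified OR grid plus interaction p per exposure (long format)."""
    frames = []
    for spec in specs:
        grid = stratified_or(assignments, cohort, spec, outcome, covariates)
        grid["p_interaction"] = interaction_pvalue(
            assignments, cohort, spec, outcome, covariates)
        frames.append(grid)
    return pd.concat(frames, ignore_index=True)
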