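"""Semi-quantitative FFQ processing, dietary patterns, and derived clinical
variables.

Frequency categories are converted to times/day at the midpoint of the
category's range over the period length (week = 7 d, month = 30.4375 d):
e.g. "five-six per week" is 5.5/7 ~= 0.79 times/day.  Daily food intake is
frequency/day x reference portion x a portion multiplier (less 0.5, equal
1.0, more 1.5).  Nutrients follow from a per-100 g composition matrix, with
macronutrient energy shares at 4/9/4 kcal per g of protein/fat/carbohydrate
and energy intake expressed as a percentage of the age- and sex-specific
estimated energy requirement (EER).

Dietary patterns are extracted by PCA on the correlation matrix of the
food-group intakes, retaining components with eigenvalue > 1.5, applying a
varimax (orthogonal) rotation, and scoring samples by the regression
method; loadings >= 0.40 in absolute value are flagged as significant and a
high/low indicator is set at the 70th percentile of each pattern score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DAYS_PER_WEEK = 7.0
DAYS_PER_MONTH = 30.4375  # 365.25 / 12

FREQUENCY_LEVELS: tuple[str, ...] = (
    "never or seldom",
    "1/month",
    "2-3/month",
    "1-2/week",
    "3-4/week",
    "5-6/week",
    "1/day",
    "2/day",
    ">=3/day",
)

# midpoint of the category's count range divided by the period in days
_FREQ_PER_DAY: dict[str, float] = {
    "never or seldom": 0.0,
    "1/month": 1.0 / DAYS_PER_MONTH,
    "2-3/month": 2.5 / DAYS_PER_MONTH,
    "1-2/week": 1.5 / DAYS_PER_WEEK,
    "3-4/week": 3.5 / DAYS_PER_WEEK,
    "5-6/week": 5.5 / DAYS_PER_WEEK,
    "1/day": 1.0,
    "2/day": 2.0,
    ">=3/day": 3.0,
}

PORTION_LEVELS: tuple[str, ...] = ("less", "equal", "more")
PORTION_MULTIPLIER: dict[str, float] = {"less": 0.5, "equal": 1.0, "more": 1.5}

# kcal per gram for protein / fat / carbohydrate energy shares
ATWATER = {"protein": 4.0, "fat": 9.0, "carbohydrate": 4.0}

# Estimated energy requirement (kcal/day) by sex and adult age band;
# Korean Dietary Reference Intake adult values, config-replaceable.
DEFAULT_EER = pd.DataFrame(
    [("M", 19, 29, 2600), ("M", 30, 49, 2400), ("M", 50, 64, 2200),
     ("M", 65, 74, 2000), ("M", 75, 120, 1900),
     ("F", 19, 29, 2100), ("F", 30, 49, 1900), ("F", 50, 64, 1800),
     ("F", 65, 74, 1600), ("F", 75, 120, 1500)],
    columns=["sex", "age_lo", "age_hi", "eer_kcal"],
)


def frequency_to_daily(category: str) -> float:
    """Times/day for one of the nine FFQ frequency categories."""
    try:
        return _FREQ_PER_DAY[category]
    except KeyError:
        raise ValueError(
            f"unknown frequency category {category!r}; "
            f"expected one of {FREQUENCY_LEVELS}") from None


def daily_food_intake(ffq: pd.DataFrame, portion_sizes: pd.Series) -> pd.DataFrame:
    """Grams/day per item from an FFQ response table.

    ``ffq`` holds, per item ``X``, columns ``X_freq`` (frequency label) and
    ``X_portion`` (less/equal/more); ``portion_sizes`` maps item -> grams of
    a reference portion.
    """
    items = sorted(c[:-5] for c in ffq.columns if c.endswith("_freq"))
    missing = [it for it in items if it not in portion_sizes.index]
    if missing:
        raise ValueError(f"no reference portion size for items: {missing[:5]}")
    out = {}
    for it in items:
        freq = ffq[f"{it}_freq"].map(_FREQ_PER_DAY)
        if freq.isna().any():
            bad = ffq.loc[freq.isna(), f"{it}_freq"].iloc[0]
            raise ValueError(f"unknown frequency category {bad!r} for {it}")
        mult = ffq[f"{it}_portion"].map(PORTION_MULTIPLIER)
        if mult.isna().any():
            bad = ffq.loc[mult.isna(), f"{it}_portion"].iloc[0]
            raise ValueError(f"unknown portion level {bad!r} for {it}")
        out[it] = freq.to_numpy() * mult.to_numpy() * float(portion_sizes[it])
    idx = ffq["sample"] if "sample" in ffq.columns else ffq.index
    return pd.DataFrame(out, index=pd.Index(idx, name="sample"))


def group_intakes(intake: pd.DataFrame, item_map: pd.DataFrame) -> pd.DataFrame:
    """Sum item g/day into food-group g/day using an item -> group map."""
    mapping = item_map.set_index("item")["group"]
    gaps = [c for c in intake.columns if c not in mapping.index]
    if gaps:
        raise ValueError(f"items without a food-group assignment: {gaps[:5]}")
    return intake.T.groupby(mapping).sum().T


def nutrient_intake(foods: pd.DataFrame, composition: pd.DataFrame,
                    cohort: pd.DataFrame | None = None,
                    eer_table: pd.DataFrame = DEFAULT_EER) -> pd.DataFrame:
    """Daily nutrients from g/day food intakes and a per-100 g composition
    matrix (items x nutrients).

    When the composition provides ``energy_kcal``, ``protein_g``, ``fat_g``
    and ``carbohydrate_g``, macronutrient energy percentages are added
    (4/9/4 kcal/g); when ``cohort`` with age and sex is given, energy is
    also expressed as % of the estimated energy requirement.
    """
    gaps = [c for c in foods.columns if c not in composition.index]
    if gaps:
        raise ValueError(f"composition matrix missing items: {gaps[:5]}")
    nutr = foods @ composition.loc[foods.columns] / 100.0
    have = set(nutr.columns)
    if {"energy_kcal", "protein_g", "fat_g", "carbohydrate_g"} <= have:
        with np.errstate(invalid="ignore", divide="ignore"):
            energy = nutr["energy_kcal"].to_numpy()
            for macro, col in [("protein", "protein_g"), ("fat", "fat_g"),
                               ("carbohydrate", "carbohydrate_g")]:
                share = np.where(energy > 0,
                                 ATWATER[macro] * nutr[col] / energy * 100.0, 0.0)
                nutr[f"{macro}_en_pct"] = share
    if cohort is not None and "energy_kcal" in have:
        eer = lookup_eer(cohort["age"], cohort["sex"], eer_table)
        nutr["energy_pct_eer"] = nutr["energy_kcal"].to_numpy() / eer * 100.0
    return nutr


def lookup_eer(age: pd.Series, sex: pd.Series,
               eer_table: pd.DataFrame = DEFAULT_EER) -> np.ndarray:
    """kcal/day EER per sample; ``sex`` coded 0/'M' male, 1/'F' female."""
    sex_code = np.where(pd.Series(sex).astype(str).isin(["1", "F", "f"]), "F", "M")
    out = np.empty(len(age))
    for i, (a, s) in enumerate(zip(np.asarray(age, float), sex_code)):
        row = eer_table[(eer_table["sex"] == s)
                        & (eer_table["age_lo"] <= a)
                        & (a <= eer_table["age_hi"])]
        if row.empty:
            raise ValueError(f"no EER entry for sex={s}, age={a}")
        out[i] = float(row["eer_kcal"].iloc[0])
    return out


# ---------------------------------------------------------------------------
# dietary patterns
# ---------------------------------------------------------------------------

@dataclass
class DietPattern:
    loadings: pd.DataFrame          # groups x retained factors (rotated)
    eigenvalues: np.ndarray         # all eigenvalues, descending
    scores: pd.DataFrame            # samples x retained factors
    high: pd.DataFrame              # boolean, >= 70th percentile per factor
    significant: pd.DataFrame       # |loading| >= 0.40


def _varimax(loadings: np.ndarray, max_iter: int = 200,
             tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation matrix for a loading matrix (columns = factors)."""
    p, k = loadings.shape
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam ** 3 - lam @ np.diag((lam ** 2).sum(0)) / p))
        rot = u @ vt
        new = s.sum()
        if new <= var * (1 + tol):
            break
        var = new
    return rot


def extract_patterns(groups: pd.DataFrame, eigen_min: float = 1.5,
                     loading_sig: float = 0.40,
                     high_percentile: float = 70.0) -> DietPattern:
    """PCA on the correlation matrix of food-group intakes with varimax
    rotation; factors retained at eigenvalue > ``eigen_min``."""
    X = groups.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant food-group column(s): "
                         f"{list(groups.columns[sd == 0])[:5]}")
    Z = (X - X.mean(0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    if np.linalg.matrix_rank(corr) < corr.shape[0]:
        warnings.warn("food-group intake matrix is rank-deficient "
                      "(duplicated or collinear groups)", stacklevel=2)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > eigen_min
    if not keep.any():
        raise ValueError(
            f"no component has eigenvalue > {eigen_min}; the intake matrix "
            "carries no pattern structure at this threshold")
    k = int(keep.sum())
    load = eigvec[:, :k] * np.sqrt(eigval[:k])
    load = load @ _varimax(load)
    # deterministic sign: largest-|loading| entry positive per factor
    for j in range(k):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    # regression-method scores: Z . corr^-1 . loadings
    scores = Z @ np.linalg.solve(corr, load)
    names = [f"pattern{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(load, index=groups.columns, columns=names)
    score_df = pd.DataFrame(scores, index=groups.index, columns=names)
    cuts = np.percentile(scores, high_percentile, axis=0)
    high = pd.DataFrame(scores >= cuts, index=groups.index, columns=names)
    return DietPattern(loadings=loadings, eigenvalues=eigval,
                       scores=score_df, high=high,
                       significant=loadings.abs() >= loading_sig)


# ---------------------------------------------------------------------------
# derived clinical variables
# ---------------------------------------------------------------------------

def homa_ir(insulin_uU_ml: float, glucose_mmol_l: float) -> float:
    """Insulin-resistance index: fasting insulin (uU/mL) x fasting glucose
    (mmol/L) / 22.5."""
    if insulin_uU_ml < 0 or glucose_mmol_l < 0:
        raise ValueError("insulin and glucose must be non-negative")
    return insulin_uU_ml * glucose_mmol_l / 22.5


def homa_b(insulin_uU_ml: float, glucose_mmol_l: float) -> float:
    """Beta-cell-function index: 20 x insulin / (glucose - 3.5); undefined
    at glucose <= 3.5 mmol/L."""
    if insulin_uU_ml < 0:
        raise ValueError("insulin must be non-negative")
    if glucose_mmol_l <= 3.5:
        raise ValueError("HOMA-B is undefined for glucose <= 3.5 mmol/L")
    return 20.0 * insulin_uU_ml / (glucose_mmol_l - 3.5)


def egfr(creatinine_mg_dl: float, age_yr: float, female: bool) -> float:
    """MDRD-style estimated glomerular filtration rate, mL/min/1.73 m^2:
    175 x creatinine^-1.154 x age^-0.203, x 0.742 for women."""
    if creatinine_mg_dl <= 0:
        raise ValueError("creatinine must be positive")
    if age_yr <= 0:
        raise ValueError("age must be positive")
    out = 175.0 * creatinine_mg_dl ** -1.154 * age_yr ** -0.203
    return out * 0.742 if female else out


def alcohol_category(g_per_day: float) -> str:
    """Non (0), light (>0-15], moderate (16-30], heavy (>30) g/day."""
    if g_per_day < 0:
        raise ValueError("alcohol intake cannot be negative")
    if g_per_day == 0:
        return "non"
    if g_per_day <= 15:
        return "light"
    if g_per_day <= 30:
        return "moderate"
    return "heavy"


def obesity_flag(bmi: float) -> bool:
    """Asian-population obesity: BMI >= 25 kg/m^2 (inclusive)."""
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    return bmi >= 25.0


def mets_flag(waist_cm: float, triglyceride_mg_dl: float, hdl_mg_dl: float,
              sbp_mm_hg: float, dbp_mm_hg: float, glucose_mg_dl: float,
              female: bool) -> bool:
    """Metabolic syndrome: >= 3 of the 2005-revised NCEP-ATP III criteria
    for Asians (waist M >= 90 / F >= 85 cm; TG >= 150; HDL M < 40 / F < 50;
    BP >= 130/85; fasting glucose >= 100 mg/dL)."""
    vals = [waist_cm, triglyceride_mg_dl, hdl_mg_dl, sbp_mm_hg,
            dbp_mm_hg, glucose_mg_dl]
    if any(v < 0 for v in vals):
        raise ValueError("clinical measurements cannot be negative")
    n = 0
    n += waist_cm >= (85.0 if female else 90.0)
    n += triglyceride_mg_dl >= 150.0
    n += hdl_mg_dl < (50.0 if female else 40.0)
    n += sbp_mm_hg >= 130.0 or dbp_mm_hg >= 85.0
    n += glucose_mg_dl >= 100.0
    return n >= 3


def exercise_flag(minutes_per_week: float) -> bool:
    """Regular exercise: >= 150 min of moderate activity per week."""
    if minutes_per_week < 0:
        raise ValueError("exercise minutes cannot be negative")
    return minutes_per_week >= 150.0


def categorical_codings(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized lifestyle/clinical codings for the columns present.

    Adds ``alcohol_cat``, ``obese``, ``regular_exercise`` and, when the
    five component measurements exist, ``mets``.
    """
    out = cohort.copy()
    if "alcohol_g_day" in out:
        if (out["alcohol_g_day"] < 0).any():
            raise ValueError("alcohol intake cannot be negative")
        out["alcohol_cat"] = [alcohol_category(v) for v in out["alcohol_g_day"]]
    if "bmi" in out:
        out["obese"] = out["bmi"] >= 25.0
    if "exercise_min_week" in out:
        out["regular_exercise"] = out["exercise_min_week"] >= 150.0
    needed = {"waist_cm", "tg_mg_dl", "hdl_mg_dl", "sbp", "dbp", "glucose_mg_dl"}
    if needed <= set(out.columns):
        female = out["sex"].astype(int) == 1 if "sex" in out else False
        out["mets"] = [
            mets_flag(w, t, h, s, d, g, bool(f))
            for w, t, h, s, d, g, f in zip(
                out["waist_cm"], out["tg_mg_dl"], out["hdl_mg_dl"],
                out["sbp"], out["dbp"], out["glucose_mg_dl"],
                np.broadcast_to(female, len(out)))
        ]
    return out
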