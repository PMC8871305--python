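"""Generalized multifactor dimensionality reduction (GMDR).

The method searches SNP subsets for joint (epistatic) effects on a binary
outcome.  Each sample carries a score s_i = y_i - p_hat_i, the residual of
a covariates-only logistic null model (with no covariates, p_hat is the
case prevalence).  For a k-SNP subset, samples fall into at most 3^k
multilocus genotype cells; a cell is labeled high-risk when its mean
training score is >= 0 (the mean score over all samples is 0 by the
logistic score equation, so 0 is the natural split; boundary cells go to
high-risk).  Classifying "in a high cell" as predicted-case yields a
trained balanced accuracy (TRBA) on the training folds and a testing
balanced accuracy (TEBA) on the held-out fold; cells unseen in training
default to low-risk.  Ten-fold stratified cross-validation produces, per
subset, mean TRBA/TEBA, an exact one-sided sign test on the number of
folds with TEBA > 1/2, and the cross-validation consistency (CVC): the
number of folds in which the subset attains the fold-best TRBA among the
subsets searched.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

MAX_CANDIDATES = 60


@dataclass(frozen=True)
class ScoreVector:
    """Per-sample GMDR scores y - p_hat plus the outcome they derive from."""

    sample_ids: tuple[str, ...]
    scores: np.ndarray
    y: np.ndarray
    covariates: tuple[str, ...]
    null_converged: bool = True

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.y) or len(self.scores) != len(self.sample_ids):
            raise ValueError("scores, outcome and sample ids must align")


@dataclass
class GmdrResult:
    snp_ids: tuple[str, ...]
    trba: np.ndarray            # per fold
    teba: np.ndarray            # per fold
    mean_trba: float
    mean_teba: float
    cvc: int
    sign_test_p: float
    cell_labels: dict[tuple[int, ...], str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.snp_ids)


def compute_scores(cohort: pd.DataFrame,
                   covariates: list[str] | None = None) -> ScoreVector:
    """Residual scores from the covariates-only logistic null model.

    With an empty covariate list the fitted probability is the case
    prevalence.  If the null fit separates or fails to converge, the
    prevalence-only score is used with a warning (the score stays usable;
    only the covariate adjustment is lost).
    """
    covariates = covariates or []
    y = cohort["case"].to_numpy(float)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    ids = tuple(cohort["sample"].astype(str))
    if not covariates:
        p_hat = np.full(len(y), y.mean())
        return ScoreVector(ids, y - p_hat, y, ())
    X = sm.add_constant(cohort[covariates].to_numpy(float))
    if not np.isfinite(X).all():
        raise ValueError("covariates must be complete-case for the null model")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        ok = fit.mle_retvals.get("converged", False) and np.isfinite(fit.bse).all()
    except Exception:
        ok = False
    if not ok:
        warnings.warn("null logistic model did not converge; falling back to "
                      "prevalence-only scores", stacklevel=2)
        p_hat = np.full(len(y), y.mean())
        return ScoreVector(ids, y - p_hat, y, tuple(covariates),
                           null_converged=False)
    return ScoreVector(ids, y - fit.predict(X), y, tuple(covariates))


def make_folds(cohort: pd.DataFrame, n_folds: int = 10,
               seed: int = 0) -> np.ndarray:
    """Case/control-stratified fold assignment (0..n_folds-1 per sample).

    Within each outcome class, samples are shuffled and dealt round-robin,
    so fold sizes differ by at most one per class.
    """
    y = cohort["case"].to_numpy(int)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples for {n_folds} folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    for f in range(n_folds):
        if (y[folds == f] == 1).sum() == 0:
            raise ValueError(
                f"fold {f} has no cases; use fewer folds for this cohort")
    return folds


def _balanced_accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    """0.5 * (sensitivity + specificity); an empty class contributes 0.5."""
    pos = y == 1
    sens = pred[pos].mean() if pos.any() else 0.5
    spec = (~pred[~pos]).mean() if (~pos).any() else 0.5
    return 0.5 * (sens + spec)


def _cells_for(g, snp_ids: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Multilocus cell index per sample (base-3 over dosages) and the mask
    of samples complete at every subset SNP."""
    from .genotype import MISSING
    k = len(snp_ids)
    dos = np.stack([g.column(s) for s in snp_ids], axis=1)
    complete = (dos != MISSING).all(axis=1)
    cells = np.zeros(g.n_samples, dtype=np.int64)
    for j in range(k):
        cells = cells * 3 + np.where(complete, dos[:, j], 0)
    return cells, complete


def evaluate_combination(snp_ids, g, scores: ScoreVector,
                         folds: np.ndarray, threshold: float = 0.0,
                         weighted_ba: bool = False) -> GmdrResult:
    """Cross-validated GMDR evaluation of one SNP subset.

    Samples missing a dosage at any subset SNP are excluded from this
    combination.  Per fold, cells are labeled from the nine training
    folds (mean score >= ``threshold`` -> high; empty cell -> low), TRBA is
    the balanced accuracy on training samples, TEBA on the held-out fold
    with unseen cells low.  ``weighted_ba`` replaces the hard case/control
    counts by score-weighted sums (a GMDR variant; off by default).
    """
    snp_ids = tuple(snp_ids)
    if len(snp_ids) < 1:
        raise ValueError("need at least one SNP")
    if len(snp_ids) > g.n_snps:
        raise ValueError("subset larger than the number of SNPs")
    cells, complete = _cells_for(g, snp_ids)
    if len(folds) != g.n_samples or len(scores.scores) != g.n_samples:
        raise ValueError("folds and scores must align with the genotype matrix")
    n_folds = int(folds.max()) + 1
    n_cells = 3 ** len(snp_ids)

    s = scores.scores
    y = scores.y
    trba = np.empty(n_folds)
    teba = np.empty(n_folds)
    for f in range(n_folds):
        train = complete & (folds != f)
        test = complete & (folds == f)
        csum = np.bincount(cells[train], weights=s[train], minlength=n_cells)
        cnum = np.bincount(cells[train], minlength=n_cells)
        with np.errstate(invalid="ignore"):
            mean = np.divide(csum, cnum, out=np.full(n_cells, -np.inf),
                             where=cnum > 0)
        high = mean >= threshold  # empty cells are -inf -> low
        if weighted_ba:
            pos_w = np.clip(s, 0, None)
            neg_w = np.clip(-s, 0, None)
            pred_tr = high[cells[train]]
            sens = _wmean(pred_tr, pos_w[train])
            spec = _wmean(~pred_tr, neg_w[train])
            trba[f] = 0.5 * (sens + spec)
            pred_te = high[cells[test]]
            teba[f] = 0.5 * (_wmean(pred_te, pos_w[test])
                             + _wmean(~pred_te, neg_w[test]))
        else:
            trba[f] = _balanced_accuracy(high[cells[train]], y[train])
            teba[f] = _balanced_accuracy(high[cells[test]], y[test])

    m = int((teba > 0.5).sum())
    sign_p = float(stats.binom.sf(m - 1, n_folds, 0.5))

    # audit labels from the full complete-case data
    csum = np.bincount(cells[complete], weights=s[complete], minlength=n_cells)
    cnum = np.bincount(cells[complete], minlength=n_cells)
    labels: dict[tuple[int, ...], str] = {}
    for c in range(n_cells):
        if cnum[c] == 0:
            continue
        geno = tuple((c // 3 ** j) % 3 for j in reversed(range(len(snp_ids))))
        labels[geno] = "high" if csum[c] / cnum[c] >= threshold else "low"

    return GmdrResult(snp_ids=snp_ids, trba=trba, teba=teba,
                      mean_trba=float(trba.mean()), mean_teba=float(teba.mean()),
                      cvc=n_folds, sign_test_p=sign_p, cell_labels=labels)


def _wmean(flags: np.ndarray, w: np.ndarray) -> float:
    tot = w.sum()
    return float((flags * w).sum() / tot) if tot > 0 else 0.5


def sign_rank_test(teba: np.ndarray, mu: float = 0.5) -> float:
    """One-sided Wilcoxon signed-rank p-value for TEBA > mu (alternative to
    the exact sign test; offered for sensitivity checks)."""
    diff = np.asarray(teba) - mu
    if np.all(diff == 0):
        return 1.0
    return float(stats.wilcoxon(diff, alternative="greater",
                                zero_method="wilcox").pvalue)


def search_best_models(candidate_snps, g, scores: ScoreVector,
                       k_range, folds: np.ndarray,
                       sign_alpha: float = 0.05, cvc_min: int = 9,
                       top_n: int = 10,
                       threshold: float = 0.0) -> dict:
    """Exhaustive GMDR search over all k-subsets for each k in ``k_range``.

    Subsets are ranked by mean TEBA (ties: higher CVC, then lexicographic
    SNP ids).  CVC of a subset is the number of folds in which it attains
    the fold-best TRBA among all subsets of the same k.  The global best
    model is the highest-mean-TEBA subset with sign-test p < ``sign_alpha``
    and CVC >= ``cvc_min``.

    Returns ``{"per_k": {k: best GmdrResult}, "top": [GmdrResult], "best":
    GmdrResult | None}``.
    """
    candidate_snps = list(candidate_snps)
    if len(candidate_snps) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(candidate_snps)} candidates exceed the exhaustive-search "
            f"guard of {MAX_CANDIDATES}; prune the list first")
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 1:
        raise ValueError("k_range must contain positive subset sizes")
    if k_range[-1] > len(candidate_snps):
        raise ValueError("k exceeds the number of candidate SNPs")

    n_folds = int(folds.max()) + 1
    per_k: dict[int, GmdrResult] = {}
    all_results: list[GmdrResult] = []
    for k in k_range:
        results = [evaluate_combination(combo, g, scores, folds, threshold)
                   for combo in itertools.combinations(sorted(candidate_snps), k)]
        # fold-best TRBA bookkeeping -> CVC
        trba_mat = np.stack([r.trba for r in results])  # combos x folds
        fold_best = trba_mat.max(axis=0)
        for i, r in enumerate(results):
            results[i] = replace(
                r, cvc=int((trba_mat[i] >= fold_best - 1e-12).sum()))
        results.sort(key=lambda r: (-r.mean_teba, -r.cvc, r.snp_ids))
        per_k[k] = results[0]
        all_results.extend(results)

    all_results.sort(key=lambda r: (-r.mean_teba, -r.cvc, r.snp_ids))
    top = all_results[:top_n]
    best = next((r for r in all_results
                 if r.sign_test_p < sign_alpha and r.cvc >= cvc_min), None)
    return {"per_k": per_k, "top": top, "best": best, "n_folds": n_folds}


def top_models_table(search: dict) -> pd.DataFrame:
    """Top-models summary (k, SNPs, mean TRBA/TEBA, CVC, sign p)."""
    return pd.DataFrame(
        [{"k": r.k, "SNPs": ",".join(r.snp_ids),
          "mean_TRBA": r.mean_trba, "mean_TEBA": r.mean_teba,
          "CVC": r.cvc, "sign_p": r.sign_test_p}
         for r in search["top"]])
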