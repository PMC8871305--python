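"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies are estimated by expectation-maximization over the
double-heterozygote phase ambiguity (the only genotype class whose
haplotype decomposition is not determined).  At convergence,
D = p_AB - p_A p_B and D' = |D| / D_max, where D_max is
min(p_A p_b, p_a p_B) for D > 0 and min(p_A p_B, p_a p_b) for D < 0;
D = 0 gives D' = 0.  Candidate lists are pruned greedily: keep the SNP
with the smallest association p, drop any later same-chromosome SNP in
high LD (D' above the threshold, 0.3 by default) with a retained one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .assoc import AssocResult

DPRIME_PRUNE_DEFAULT = 0.3


class MonomorphicSnpError(ValueError):
    """LD is undefined when either locus has a single allele."""


@dataclass(frozen=True)
class LdEstimate:
    snp_a: str
    snp_b: str
    hap_freqs: tuple[float, float, float, float]  # AB, Ab, aB, ab (A,B = minor)
    p_ab: float
    d: float
    d_prime: float
    n_iter: int
    converged: bool
    n_used: int


def _pair_counts(g: GenotypeMatrix, snp_a: str, snp_b: str) -> np.ndarray:
    """3x3 joint genotype counts (rows: dosage at A, cols: dosage at B)
    over samples complete at both loci."""
    a = g.column(snp_a)
    b = g.column(snp_b)
    ok = (a != MISSING) & (b != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (a[ok].astype(int), b[ok].astype(int)), 1)
    return counts


def em_haplotype_freqs(g: GenotypeMatrix, snp_a: str, snp_b: str,
                       tol: float = 1e-8, max_iter: int = 1000) -> LdEstimate:
    """EM estimate of the four haplotype frequencies for a SNP pair.

    Initialized at linkage equilibrium; iterates the standard two-locus EM
    in which each double heterozygote contributes its two possible phase
    resolutions in proportion to their current haplotype-product weights.
    """
    counts = _pair_counts(g, snp_a, snp_b)
    n = counts.sum()
    if n == 0:
        raise MonomorphicSnpError(f"no complete observations for {snp_a},{snp_b}")
    p_a = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
    p_b = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicSnpError(
            f"LD undefined: {snp_a} or {snp_b} monomorphic in complete cases")

    # fixed haplotype contributions from unambiguous genotype classes;
    # order: AB, Ab, aB, ab (capital = minor allele present on haplotype)
    fixed = np.zeros(4)
    _idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}
    for ga in range(3):
        for gb in range(3):
            c = counts[ga, gb]
            if c == 0 or (ga == 1 and gb == 1):
                continue
            # phase is determined whenever at most one locus is heterozygous
            if ga != 1 and gb != 1:
                fixed[_idx[(ga // 2, gb // 2)]] += 2 * c
            elif ga == 1:  # het at A, hom at B: haplotypes (A,b?) and (a,b?)
                fixed[_idx[(1, gb // 2)]] += c
                fixed[_idx[(0, gb // 2)]] += c
            else:  # hom at A, het at B
                fixed[_idx[(ga // 2, 1)]] += c
                fixed[_idx[(ga // 2, 0)]] += c
    n_dh = counts[1, 1]

    freqs = np.array([p_a * p_b, p_a * (1 - p_b),
                      (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between AB/ab and Ab/aB phases
        w_cis = freqs[0] * freqs[3]
        w_trans = freqs[1] * freqs[2]
        tot = w_cis + w_trans
        frac_cis = 0.5 if tot == 0 else w_cis / tot
        hap = fixed.copy()
        hap[0] += n_dh * frac_cis
        hap[3] += n_dh * frac_cis
        hap[1] += n_dh * (1 - frac_cis)
        hap[2] += n_dh * (1 - frac_cis)
        new = hap / (2 * n)
        if np.abs(new - freqs).max() < tol:
            freqs = new
            converged = True
            break
        freqs = new

    p_ab = float(freqs[0])
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        d_max = 1.0
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    return LdEstimate(snp_a=snp_a, snp_b=snp_b,
                      hap_freqs=tuple(float(f) for f in freqs),
                      p_ab=p_ab, d=float(d),
                      d_prime=float(min(d_prime, 1.0)),
                      n_iter=it, converged=converged, n_used=int(n))


def prune_by_dprime(candidates: list[AssocResult], g: GenotypeMatrix,
                    threshold: float = DPRIME_PRUNE_DEFAULT,
                    tol: float = 1e-8, max_iter: int = 1000
                    ) -> tuple[list[str], pd.DataFrame]:
    """Greedy D' pruning of an association-ranked candidate list.

    ``candidates`` must be sorted ascending by p; the best-p SNP is always
    kept and any later SNP with D' > ``threshold`` against a retained SNP
    on the same chromosome is dropped.  Cross-chromosome pairs are never
    pruned.  Returns the retained SNP ids and the pairwise-LD table of the
    comparisons made.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"D' threshold must lie in [0,1], got {threshold}")
    ps = [c.p for c in candidates]
    if any(ps[i] > ps[i + 1] for i in range(len(ps) - 1)):
        raise ValueError("candidates must be sorted ascending by p")
    retained: list[AssocResult] = []
    rows = []
    for cand in candidates:
        keep = True
        for kept in retained:
            if kept.chrom != cand.chrom:
                continue
            try:
                est = em_haplotype_freqs(g, kept.snp_id, cand.snp_id,
                                         tol=tol, max_iter=max_iter)
            except MonomorphicSnpError:
                continue
            rows.append({"SNP_A": kept.snp_id, "SNP_B": cand.snp_id,
                         "D": est.d, "DPRIME": est.d_prime,
                         "N_ITER": est.n_iter, "N": est.n_used})
            if est.d_prime > threshold:
                keep = False
                break
        if keep:
            retained.append(cand)
    table = pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "D",
                                        "DPRIME", "N_ITER", "N"])
    return [c.snp_id for c in retained], table
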