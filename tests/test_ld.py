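"""EM haplotype-frequency estimation, D' and greedy pruning."""

import itertools

import numpy as np
import pytest

from oaprs.assoc import AssocResult
from oaprs.genotype import MISSING
from oaprs.ld import (MonomorphicSnpError, em_haplotype_freqs,
                      prune_by_dprime)
from oaprs.synthetic import LdBlock, SimulationConfig, SnpSpec, \
    generate_genotypes
from .conftest import make_matrix


def _grid_loglik_pab(counts: np.ndarray, p_a: float, p_b: float,
                     step: float = 1e-5) -> float:
    """Brute-force maximizer of the multinomial likelihood over p_AB.

    With allele frequencies fixed at their sample values, the four
    haplotype frequencies are determined by p_AB alone; the genotype-class
    probabilities follow by pairing haplotypes independently, with the
    double heterozygote collecting both phase resolutions.
    """
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.arange(lo, hi + step, step)
    pab = grid
    pAb = p_a - pab
    paB = p_b - pab
    pab_ = 1.0 - p_a - p_b + pab
    probs = np.stack([pab, pAb, paB, pab_])  # AB, Ab, aB, ab
    probs = np.clip(probs, 1e-300, None)
    ll = np.zeros(len(grid))
    for ga in range(3):
        for gb in range(3):
            c = counts[ga, gb]
            if c == 0:
                continue
            if ga == 1 and gb == 1:
                cell = 2 * probs[0] * probs[3] + 2 * probs[1] * probs[2]
            else:
                hap_a = [(1, 1), (1, 0)] if ga == 2 else \
                        [(0, 1), (0, 0)] if ga == 0 else None
                # build the cell probability from the determined haplotypes
                idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}
                if ga != 1 and gb != 1:
                    h = idx[(ga // 2, gb // 2)]
                    cell = probs[h] ** 2
                elif ga == 1:
                    cell = 2 * probs[idx[(1, gb // 2)]] * probs[idx[(0, gb // 2)]]
                else:
                    cell = 2 * probs[idx[(ga // 2, 1)]] * probs[idx[(ga // 2, 0)]]
            ll += c * np.log(np.clip(cell, 1e-300, None))
    return float(grid[np.argmax(ll)])


def _pair_counts(g, a, b):
    ga, gb = g.column(a), g.column(b)
    ok = (ga != MISSING) & (gb != MISSING)
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (ga[ok].astype(int), gb[ok].astype(int)), 1)
    return counts


class TestEm:
    def test_complete_ld_gives_dprime_one(self):
        # only AB/ab haplotypes present: dosages always equal
        col = np.array([0, 1, 2, 0, 1, 2, 0, 0, 2, 1], dtype=np.int8)
        g = make_matrix(np.column_stack([col, col]))
        est = em_haplotype_freqs(g, "rs0", "rs1")
        assert est.d_prime == pytest.approx(1.0, abs=1e-9)

    def test_independent_loci_near_zero(self):
        cfg = SimulationConfig(
            n_samples=10000,
            snp_specs=[SnpSpec("a", 0.3, pos=1), SnpSpec("b", 0.3, pos=2)],
            seed=13)
        est = em_haplotype_freqs(generate_genotypes(cfg), "a", "b")
        assert est.d_prime < 0.05

    def test_monomorphic_raises(self):
        g = make_matrix(np.column_stack([np.zeros(10), np.tile([0, 1], 5)]))
        with pytest.raises(MonomorphicSnpError):
            em_haplotype_freqs(g, "rs0", "rs1")

    def test_no_double_het_equals_direct_counting(self, rng):
        # without double heterozygotes every haplotype is determined, so
        # EM must equal the closed-form count in one pass
        for _ in range(20):
            while True:
                dos = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
                dos[(dos[:, 0] == 1) & (dos[:, 1] == 1), 1] = 0
                if len(set(dos[:, 0])) > 1 and len(set(dos[:, 1])) > 1:
                    break
            g = make_matrix(dos)
            est = em_haplotype_freqs(g, "rs0", "rs1")
            # direct count
            hap = np.zeros(4)
            idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}
            for ga, gb in dos:
                if ga != 1 and gb != 1:
                    hap[idx[(ga // 2, gb // 2)]] += 2
                elif ga == 1:
                    hap[idx[(1, gb // 2)]] += 1
                    hap[idx[(0, gb // 2)]] += 1
                else:
                    hap[idx[(ga // 2, 1)]] += 1
                    hap[idx[(ga // 2, 0)]] += 1
            assert np.allclose(est.hap_freqs, hap / hap.sum(), atol=1e-12)

    def test_em_matches_likelihood_grid_on_random_data(self, rng):
        """EM p_AB agrees with the brute-force likelihood maximizer to
        1e-4 on 100 random small datasets."""
        checked = 0
        while checked < 100:
            n = int(rng.integers(20, 60))
            dos = rng.integers(0, 3, size=(n, 2)).astype(np.int8)
            g = make_matrix(dos)
            try:
                est = em_haplotype_freqs(g, "rs0", "rs1")
            except MonomorphicSnpError:
                continue
            counts = _pair_counts(g, "rs0", "rs1")
            nn = counts.sum()
            p_a = (2 * counts[2].sum() + counts[1].sum()) / (2 * nn)
            p_b = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * nn)
            best = _grid_loglik_pab(counts, p_a, p_b)
            assert est.p_ab == pytest.approx(best, abs=1e-4)
            checked += 1

    def test_allele_swap_invariance(self, rng):
        for _ in range(20):
            dos = rng.integers(0, 3, size=(50, 2)).astype(np.int8)
            g = make_matrix(dos)
            swapped = dos.copy()
            swapped[:, 0] = 2 - swapped[:, 0]
            g2 = make_matrix(swapped)
            try:
                d1 = em_haplotype_freqs(g, "rs0", "rs1").d_prime
                d2 = em_haplotype_freqs(g2, "rs0", "rs1").d_prime
            except MonomorphicSnpError:
                continue
            assert d1 == pytest.approx(d2, abs=1e-10)

    def test_em_loglik_nondecreasing(self):
        # monitor the multinomial log-likelihood along the EM path
        rng = np.random.default_rng(77)
        dos = rng.integers(0, 3, size=(40, 2)).astype(np.int8)
        g = make_matrix(dos)
        counts = _pair_counts(g, "rs0", "rs1")
        n = counts.sum()
        p_a = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
        p_b = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)

        def loglik(pab):
            lo = max(0.0, p_a + p_b - 1.0)
            probs = np.array([pab, p_a - pab, p_b - pab,
                              1 - p_a - p_b + pab]).clip(1e-12)
            ll = 0.0
            idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}
            for ga in range(3):
                for gb in range(3):
                    c = counts[ga, gb]
                    if c == 0:
                        continue
                    if ga == 1 and gb == 1:
                        cell = 2 * probs[0] * probs[3] + 2 * probs[1] * probs[2]
                    elif ga != 1 and gb != 1:
                        cell = probs[idx[(ga // 2, gb // 2)]] ** 2
                    elif ga == 1:
                        cell = 2 * probs[idx[(1, gb // 2)]] * probs[idx[(0, gb // 2)]]
                    else:
                        cell = 2 * probs[idx[(ga // 2, 1)]] * probs[idx[(ga // 2, 0)]]
                    ll += c * np.log(cell)
            return ll

        lls = [loglik(em_haplotype_freqs(g, "rs0", "rs1", max_iter=i).p_ab)
               for i in range(1, 12)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def _cand(snp_id, p, chrom="1"):
    return AssocResult(snp_id, chrom, 1, "A", 1.5, 1.2, 1.9, p, 100)


class TestPrune:
    def test_perfect_ld_pair_keeps_best_p(self):
        col = np.array([0, 1, 2] * 10, dtype=np.int8)
        g = make_matrix(np.column_stack([col, col]))
        kept, table = prune_by_dprime([_cand("rs0", 1e-8), _cand("rs1", 1e-6)],
                                      g, 0.3)
        assert kept == ["rs0"]
        assert table["DPRIME"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(20)
        g = make_matrix(rng.integers(0, 3, size=(3000, 3)))
        cands = [_cand(f"rs{j}", 10 ** -(8 - j)) for j in range(3)]
        kept, _ = prune_by_dprime(cands, g, 0.3)
        assert kept == ["rs0", "rs1", "rs2"]

    def test_greedy_chain_keeps_ends(self):
        # A-B and B-C in high LD, A-C independent, pA < pB < pC:
        # greedy keeps A, drops B (LD with A), keeps C (independent of A)
        rng = np.random.default_rng(21)
        n = 4000
        hapA = rng.random((n, 2)) < 0.4
        # B correlated with A, C anti-structured so that A-C are independent
        flip = rng.random((n, 2)) < 0.25
        hapB = np.where(flip, rng.random((n, 2)) < 0.4, hapA)
        flip2 = rng.random((n, 2)) < 0.25
        hapC = np.where(flip2, rng.random((n, 2)) < 0.4,
                        rng.random((n, 2)) < 0.4)
        dos = np.column_stack([hapA.sum(1), hapB.sum(1), hapC.sum(1)])
        g = make_matrix(dos.astype(np.int8), snp_ids=["A", "B", "C"])
        cands = [_cand("A", 1e-9), _cand("B", 1e-8), _cand("C", 1e-7)]
        kept, table = prune_by_dprime(cands, g, 0.3)
        assert kept == ["A", "C"]

    def test_cross_chromosome_never_pruned(self):
        col = np.array([0, 1, 2] * 10, dtype=np.int8)
        g = make_matrix(np.column_stack([col, col]), chroms=["1", "2"])
        kept, _ = prune_by_dprime([_cand("rs0", 1e-8, "1"),
                                   _cand("rs1", 1e-6, "2")], g, 0.3)
        assert kept == ["rs0", "rs1"]

    def test_unsorted_candidates_rejected(self):
        g = make_matrix(np.tile([0, 1, 2], (10, 2)).reshape(10, -1)[:, :2])
        with pytest.raises(ValueError, match="sorted"):
            prune_by_dprime([_cand("rs0", 1e-6), _cand("rs1", 1e-8)], g)
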