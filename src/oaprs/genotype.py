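"""Genotype containers, PLINK binary input/output, and quality control.

Genotypes are held as a sample x SNP matrix of minor-allele dosages in
{0, 1, 2} with ``MISSING`` (-1) as the sentinel for a failed call.  All
downstream code branches on the sentinel explicitly; it never enters an
arithmetic path by accident because comparisons against ``MISSING`` are
exact integer checks.

The PLINK .bed codec implements the SNP-major 2-bit layout (magic bytes
``6c 1b`` followed by mode byte ``01``): within each SNP's byte block the
two-bit codes are, from the low bits up, ``00`` = homozygous for allele 1
of the .bim record, ``01`` = missing, ``10`` = heterozygous, ``11`` =
homozygous allele 2.  On read, dosages are re-oriented so that they always
count the cohort-empirical minor allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit code -> dosage of .bim allele-1 (the coded allele)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported PLINK binary files."""


class EmptyCohortError(ValueError):
    """Raised when quality control removes every sample."""


@dataclass(frozen=True)
class SnpRecord:
    """Per-SNP metadata; ``minor_allele`` is the allele the dosages count."""

    id: str
    chrom: str
    pos: int
    minor_allele: str
    major_allele: str
    maf: float = float("nan")
    hwe_p: float = float("nan")
    call_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Sample x SNP minor-allele dosage matrix with metadata.

    ``dosages[i, j]`` is the number of copies of ``snps[j].minor_allele``
    carried by ``samples[i]``, or ``MISSING``.
    """

    dosages: np.ndarray
    snps: list[SnpRecord]
    samples: list[str]
    sample_sex: np.ndarray = field(default=None)  # 1=male, 2=female, 0=unknown
    sample_phenotype: np.ndarray = field(default=None)  # .fam slot, -9 = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D sample x SNP array")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNP records for {m} columns")
        if len(set(self.samples)) != n:
            raise ValueError("sample ids must be unique")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != m:
            raise ValueError("SNP ids must be unique")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")
        if self.sample_sex is None:
            self.sample_sex = np.zeros(n, dtype=np.int8)
        if self.sample_phenotype is None:
            self.sample_phenotype = np.full(n, -9, dtype=np.int32)
        self._index = {sid: j for j, sid in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            self.dosages[:, idx].copy(),
            [self.snps[j] for j in idx],
            list(self.samples),
            self.sample_sex.copy(),
            self.sample_phenotype.copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.dosages[keep].copy(),
            list(self.snps),
            [self.samples[i] for i in keep],
            self.sample_sex[keep].copy(),
            self.sample_phenotype[keep].copy(),
        )

    def with_snp_stats(self) -> "GenotypeMatrix":
        """Return a copy whose SnpRecords carry maf, hwe_p and call_rate."""
        out_snps = []
        for j, rec in enumerate(self.snps):
            col = self.dosages[:, j]
            obs = col[col != MISSING]
            call = obs.size / col.size if col.size else 0.0
            if obs.size == 0:
                out_snps.append(replace(rec, maf=float("nan"),
                                        hwe_p=float("nan"), call_rate=call))
                continue
            maf = float(obs.mean() / 2.0)
            n2 = int((obs == 2).sum())
            n1 = int((obs == 1).sum())
            n0 = int((obs == 0).sum())
            p = hwe_exact_test(n2, n1, n0)
            out_snps.append(replace(rec, maf=maf, hwe_p=p, call_rate=call))
        return GenotypeMatrix(self.dosages.copy(), out_snps, list(self.samples),
                              self.sample_sex.copy(), self.sample_phenotype.copy())


def orient_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip SNP columns so dosages count the cohort-empirical minor allele.

    Ties at allele frequency 0.5 are broken toward the lexicographically
    smaller allele label so orientation is deterministic.
    """
    dos = g.dosages.copy()
    snps = []
    for j, rec in enumerate(g.snps):
        col = dos[:, j]
        obs = col[col != MISSING]
        freq = obs.mean() / 2.0 if obs.size else 0.0
        flip = freq > 0.5 or (
            obs.size and math.isclose(freq, 0.5)
            and rec.major_allele < rec.minor_allele
        )
        if flip:
            mask = col != MISSING
            col[mask] = 2 - col[mask]
            rec = replace(rec, minor_allele=rec.major_allele,
                          major_allele=rec.minor_allele)
        snps.append(rec)
    return GenotypeMatrix(dos, snps, list(g.samples),
                          g.sample_sex.copy(), g.sample_phenotype.copy())


# ---------------------------------------------------------------------------
# PLINK binary codec
# ---------------------------------------------------------------------------

def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a .bed/.bim/.fam triple; allele 1 of the .bim is the minor allele."""
    prefix = Path(prefix)
    n = g.n_samples
    bed = bytearray(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
    n_bytes = (n + 3) // 4
    for j in range(g.n_snps):
        block = bytearray(n_bytes)
        col = g.dosages[:, j]
        for i in range(n):
            code = _DOSAGE_TO_CODE[int(col[i])]
            block[i >> 2] |= code << ((i & 3) * 2)
        bed.extend(block)
    prefix.with_suffix(".bed").write_bytes(bytes(bed))

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for rec in g.snps:
            fh.write(f"{rec.chrom}\t{rec.id}\t0\t{rec.pos}\t"
                     f"{rec.minor_allele}\t{rec.major_allele}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, sid in enumerate(g.samples):
            fh.write(f"{sid}\t{sid}\t0\t0\t{int(g.sample_sex[i])}\t"
                     f"{int(g.sample_phenotype[i])}\n")


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triple into a minor-allele-oriented matrix."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "phe"],
                      dtype={"iid": str})
    raw = prefix.with_suffix(".bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _BED_SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: individual-major mode (byte 0x{raw[2]:02x}) "
            "is not supported; re-export in SNP-major mode")
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    if len(raw) - 3 != n_bytes * m:
        raise PlinkFormatError(
            f"{prefix}.bed: expected {n_bytes * m} payload bytes for "
            f"{n} samples x {m} SNPs, found {len(raw) - 3}")
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    # unpack 2-bit fields, low bits first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (payload[:, :, None] >> shifts) & 0b11  # (m, n_bytes, 4)
    codes = codes.reshape(m, n_bytes * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.astype(np.int8)  # sample x SNP, counts a1

    snps = [SnpRecord(id=r.id, chrom=str(r.chrom), pos=int(r.pos),
                      minor_allele=str(r.a1), major_allele=str(r.a2))
            for r in bim.itertuples()]
    g = GenotypeMatrix(dosages, snps, fam["iid"].tolist(),
                       fam["sex"].to_numpy(np.int8),
                       fam["phe"].to_numpy(np.int32))
    return orient_to_minor(g)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def sample_qc(
    g: GenotypeMatrix,
    missing_max: float = 0.04,
    het_max: float = 0.30,
    accuracy: np.ndarray | None = None,
    accuracy_min: float = 0.98,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples with missing call rate >= ``missing_max`` or
    heterozygosity (het calls / non-missing calls) > ``het_max``.

    Genotyping accuracy is a chip-level metric that cannot be derived from
    dosages; if a per-sample ``accuracy`` vector is supplied, samples below
    ``accuracy_min`` are dropped as well.
    """
    if g.n_samples == 0:
        raise EmptyCohortError("no samples to QC")
    dos = g.dosages
    n_snps = dos.shape[1]
    miss = (dos == MISSING).sum(axis=1) / max(n_snps, 1)
    nonmiss = (dos != MISSING).sum(axis=1)
    het = np.divide((dos == 1).sum(axis=1), nonmiss,
                    out=np.zeros(len(nonmiss)), where=nonmiss > 0)
    rows = []
    for i, sid in enumerate(g.samples):
        reasons = []
        if miss[i] >= missing_max:
            reasons.append(f"missing>={missing_max:.0%}")
        if het[i] > het_max:
            reasons.append(f"heterozygosity>{het_max:.0%}")
        if accuracy is not None and accuracy[i] < accuracy_min:
            reasons.append(f"accuracy<{accuracy_min:.0%}")
        if reasons:
            rows.append({"sample": sid, "reason": ";".join(reasons),
                         "missing_rate": miss[i], "heterozygosity": het[i]})
    report = pd.DataFrame(rows, columns=["sample", "reason",
                                         "missing_rate", "heterozygosity"])
    keep = ~np.isin(g.samples, report["sample"].tolist())
    if not keep.any():
        raise EmptyCohortError("sample QC excluded every sample")
    return g.subset_samples(keep), report


def snp_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_min: float = 1e-6,
    call_min: float = 0.95,
    controls: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs with MAF < ``maf_min``, HWE exact p < ``hwe_min``
    (computed on controls when a control mask is given), or call rate
    < ``call_min``."""
    for name, v in [("maf_min", maf_min), ("hwe_min", hwe_min),
                    ("call_min", call_min)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0,1], got {v}")
    dos = g.dosages
    hwe_src = dos[np.asarray(controls, bool)] if controls is not None else dos
    rows, keep_ids = [], []
    for j, rec in enumerate(g.snps):
        col = dos[:, j]
        obs = col[col != MISSING]
        call = obs.size / col.size if col.size else 0.0
        maf = float(obs.mean() / 2.0) if obs.size else 0.0
        maf = min(maf, 1.0 - maf)
        hcol = hwe_src[:, j]
        hobs = hcol[hcol != MISSING]
        hwe_p = hwe_exact_test(int((hobs == 2).sum()), int((hobs == 1).sum()),
                               int((hobs == 0).sum())) if hobs.size else 1.0
        reasons = []
        if maf < maf_min:
            reasons.append(f"maf<{maf_min}")
        if hwe_p < hwe_min:
            reasons.append(f"hwe_p<{hwe_min}")
        if call < call_min:
            reasons.append(f"call_rate<{call_min}")
        if reasons:
            rows.append({"snp": rec.id, "reason": ";".join(reasons),
                         "maf": maf, "hwe_p": hwe_p, "call_rate": call})
        else:
            keep_ids.append(rec.id)
    report = pd.DataFrame(rows, columns=["snp", "reason", "maf",
                                         "hwe_p", "call_rate"])
    return g.subset_snps(keep_ids).with_snp_stats(), report


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, heterozygote counts follow
    the HWE sampling distribution; the p-value sums the probabilities of
    all heterozygote counts no more probable than the one observed
    (Wigginton-style mid-less convention, capped at 1).
    """
    if min(n_hom_minor, n_het, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_minor + n_het + n_hom_major
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_hom_minor, n_hom_major) + n_het
    if n_rare == 0:
        return 1.0
    # het counts share the parity of the rare-allele count
    het_possible = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalized log-probabilities of each het count given allele counts
    n_common = 2 * n - n_rare
    logp = np.empty(len(het_possible))
    for idx, h in enumerate(het_possible):
        r_hom = (n_rare - h) // 2
        c_hom = n - h - r_hom
        logp[idx] = (h * math.log(2)
                     - math.lgamma(r_hom + 1) - math.lgamma(h + 1)
                     - math.lgamma(c_hom + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.searchsorted(het_possible, n_het)]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))
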