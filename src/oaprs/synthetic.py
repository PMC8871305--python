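"""Synthetic cohort generator.

Produces genotype, phenotype/covariate, and food-frequency data with the
statistical structure the downstream analysis assumes:

* biallelic SNPs in Hardy-Weinberg proportions at configurable MAF;
* optional haplotype-block LD at a target D' (haplotype frequencies built
  as p_AB = p_A p_B + D' * D_max, which is unique and always feasible for
  D' in [0, 1]);
* a binary outcome from an additive logistic model with optional main
  effects, one planted pure SNP-SNP interaction (a joint log-odds bump for
  carrying at least one risk allele at both loci), covariate effects, and
  an exposure-modified genetic effect;
* semi-quantitative FFQ responses (9 frequency levels x 3 portion levels)
  driven by latent dietary-pattern scores so principal-component pattern
  extraction has planted truth to recover.

Everything is driven by a ``SimulationConfig`` and a single seed; the same
config yields bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix, SnpRecord, write_plink
from .diet import FREQUENCY_LEVELS, PORTION_LEVELS


@dataclass(frozen=True)
class SnpSpec:
    id: str
    maf: float
    chrom: str = "1"
    pos: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.id}: MAF must lie in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class LdBlock:
    """A pair (or chain) of SNPs sharing haplotype structure at target D'."""

    snp_ids: tuple[str, ...]
    d_prime: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.d_prime <= 1.0:
            raise ValueError(f"target D' must lie in [0,1], got {self.d_prime}")
        if len(self.snp_ids) < 2:
            raise ValueError("an LD block needs at least two SNPs")


@dataclass(frozen=True)
class GxeSpec:
    """Exposure-stratified genetic effect: per-allele log-OR at ``snp_id``
    is ``log_or_low`` in the low-exposure stratum and ``log_or_high`` in
    the high-exposure stratum."""

    exposure: str
    snp_id: str
    log_or_low: float
    log_or_high: float


@dataclass
class SimulationConfig:
    n_samples: int = 2000
    snp_specs: list[SnpSpec] = field(default_factory=list)
    ld_blocks: list[LdBlock] = field(default_factory=list)
    baseline_logit: float = 0.0
    main_effects: dict[str, float] = field(default_factory=dict)
    # (snp_a, snp_b, joint log-OR for carrying >=1 risk allele at both)
    interaction: tuple[str, str, float] | None = None
    covariate_effects: dict[str, float] = field(default_factory=dict)
    gxe: GxeSpec | None = None
    missing_rate: float = 0.0
    seed: int = 0
    # covariate / exposure distribution parameters (documented defaults)
    age_range: tuple[float, float] = (40.0, 75.0)
    bmi_mean_sd: tuple[float, float] = (24.5, 3.0)
    bmi_bounds: tuple[float, float] = (16.0, 40.0)
    energy_pct_eer_lognorm: tuple[float, float] = (0.0, 0.25)  # x100 -> %EER
    alcohol_lognorm: tuple[float, float] = (1.5, 1.2)  # g/day among drinkers
    drinker_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not 0.0 <= self.missing_rate <= 0.05:
            raise ValueError("missing_rate must lie in [0, 0.05]")
        ids = [s.id for s in self.snp_specs]
        if len(set(ids)) != len(ids):
            raise ValueError("snp ids must be unique")
        known = set(ids)
        for sid in self.main_effects:
            if sid not in known:
                raise ValueError(f"main effect on unknown SNP {sid!r}")
        if self.interaction is not None:
            a, b, _ = self.interaction
            for sid in (a, b):
                if sid not in known:
                    raise ValueError(f"interaction on unknown SNP {sid!r}")
        for blk in self.ld_blocks:
            for sid in blk.snp_ids:
                if sid not in known:
                    raise ValueError(f"LD block names unknown SNP {sid!r}")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _pair_haplotype_table(p_a: float, p_b: float, d_prime: float) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) for minor-allele freqs
    ``p_a``, ``p_b`` and target D' (positive-D convention).

    D_max = min(p_A (1-p_B), (1-p_A) p_B), so any D' in [0,1] is feasible.
    """
    d = d_prime * min(p_a * (1 - p_b), (1 - p_a) * p_b)
    tab = np.array([
        p_a * p_b + d,
        p_a * (1 - p_b) - d,
        (1 - p_a) * p_b - d,
        (1 - p_a) * (1 - p_b) + d,
    ])
    tab = np.clip(tab, 0.0, 1.0)
    return tab / tab.sum()


def generate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw genotypes: unlinked SNPs from HWE proportions, LD-block SNPs by
    sampling two haplotypes per person from the target-D' haplotype table."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_samples
    specs = {s.id: s for s in config.snp_specs}
    dosages = np.empty((n, len(config.snp_specs)), dtype=np.int8)
    col_of = {s.id: j for j, s in enumerate(config.snp_specs)}

    in_block: set[str] = set()
    for blk in config.ld_blocks:
        ids = list(blk.snp_ids)
        # chain structure: each SNP linked to the previous at the target D'
        first = specs[ids[0]]
        hap_prev = rng.random((n, 2)) < first.maf  # minor-allele indicator
        dosages[:, col_of[first.id]] = hap_prev.sum(axis=1)
        for sid in ids[1:]:
            spec = specs[sid]
            tab = _pair_haplotype_table(specs[ids[0]].maf, spec.maf, blk.d_prime)
            # conditional P(B minor | A state) from the pair table
            p_b_given_a = tab[0] / (tab[0] + tab[1])
            p_b_given_not_a = tab[2] / (tab[2] + tab[3])
            cond = np.where(hap_prev, p_b_given_a, p_b_given_not_a)
            hap_b = rng.random((n, 2)) < cond
            dosages[:, col_of[sid]] = hap_b.sum(axis=1)
            in_block.update(blk.snp_ids)

    for spec in config.snp_specs:
        if spec.id in in_block:
            continue
        g = (rng.random((n, 2)) < spec.maf).sum(axis=1)
        dosages[:, col_of[spec.id]] = g

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    snps = [SnpRecord(id=s.id, chrom=s.chrom,
                      pos=s.pos if s.pos >= 1 else j + 1,
                      minor_allele="A", major_allele="G")
            for j, s in enumerate(config.snp_specs)]
    samples = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages, snps, samples)


# ---------------------------------------------------------------------------
# phenotype & covariates
# ---------------------------------------------------------------------------

def _effect_dosage(col: np.ndarray) -> np.ndarray:
    """Dosage with missing entries replaced by the observed mean (simulation
    only; the analysis modules never impute this way)."""
    out = col.astype(float)
    miss = col == MISSING
    if miss.any():
        out[miss] = out[~miss].mean() if (~miss).any() else 0.0
    return out


def generate_phenotype(genotypes: GenotypeMatrix,
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw covariates, exposures and the binary outcome.

    The outcome is Bernoulli with logit = baseline + sum(beta_j * dosage_j)
    + joint-interaction bump + covariate terms (+ exposure-stratified
    genetic term if a G x E spec is present).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = genotypes.n_samples

    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n)  # 1 = female
    mu, sd = config.bmi_mean_sd
    lo, hi = config.bmi_bounds
    bmi = np.clip(rng.normal(mu, sd, size=n), lo, hi)
    energy_pct_eer = 100.0 * rng.lognormal(*config.energy_pct_eer_lognorm, size=n)
    # macronutrient energy shares roughly Korean-cohort-like
    protein_en = np.clip(rng.normal(13.5, 2.5, size=n), 5, 30)
    fat_en = np.clip(rng.normal(15.0, 4.0, size=n), 3, 45)
    carb_en = np.clip(100.0 - protein_en - fat_en
                      + rng.normal(0, 2.0, size=n), 30, 90)
    drinks = rng.random(n) < config.drinker_fraction
    alcohol = np.where(drinks, rng.lognormal(*config.alcohol_lognorm, size=n), 0.0)
    smoking = rng.choice(["never", "past", "current"], size=n, p=[0.6, 0.15, 0.25])
    exercise_min = np.clip(rng.exponential(120.0, size=n), 0, 1000)

    logit = np.full(n, config.baseline_logit, dtype=float)
    for sid, beta in config.main_effects.items():
        logit += beta * _effect_dosage(genotypes.column(sid))
    if config.interaction is not None:
        a, b, joint = config.interaction
        ca = _effect_dosage(genotypes.column(a)) >= 1
        cb = _effect_dosage(genotypes.column(b)) >= 1
        logit += joint * (ca & cb)

    cov_values = {
        "age": (age - np.mean(config.age_range)) / 10.0,
        "sex": sex.astype(float),
        "bmi": (bmi - mu) / sd,
    }
    for name, beta in config.covariate_effects.items():
        if name not in cov_values:
            raise ValueError(f"unknown covariate {name!r} in covariate_effects")
        logit += beta * cov_values[name]

    exposures = {
        "energy_pct_eer": energy_pct_eer,
        "protein_en_pct": protein_en,
        "fat_en_pct": fat_en,
        "carb_en_pct": carb_en,
        "alcohol_g_day": alcohol,
        "exercise_min_week": exercise_min,
    }
    if config.gxe is not None:
        gx = config.gxe
        expo = exposures[gx.exposure]
        # dichotomize at the analysis cutoff so the planted truth matches
        from .gxe import DEFAULT_CUTOFFS
        cutoff = DEFAULT_CUTOFFS.get(gx.exposure)
        if cutoff is None:
            cutoff = float(np.median(expo))
        high = expo >= cutoff
        dose = _effect_dosage(genotypes.column(gx.snp_id))
        logit += np.where(high, gx.log_or_high, gx.log_or_low) * dose

    prob = 1.0 / (1.0 + np.exp(-logit))
    case = (rng.random(n) < prob).astype(int)

    return pd.DataFrame({
        "sample": genotypes.samples,
        "case": case,
        "age": age,
        "sex": sex,
        "bmi": bmi,
        "smoking": smoking,
        **exposures,
    })


# ---------------------------------------------------------------------------
# FFQ
# ---------------------------------------------------------------------------

# latent-intensity thresholds mapping a standard-normal score to the nine
# frequency categories (monotone; higher latent -> more frequent intake)
_FREQ_CUTS = np.array([-1.2, -0.7, -0.2, 0.3, 0.8, 1.3, 1.8, 2.3])


def generate_ffq(cohort: pd.DataFrame, n_items: int = 106,
                 n_groups: int = 29, n_patterns: int = 2,
                 pattern_strength: float = 1.5,
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Generate FFQ responses driven by latent dietary-pattern scores.

    Items are assigned round-robin to ``n_groups`` food groups; each
    pattern loads on a disjoint set of groups so planted loadings are
    orthogonal.  Returns ``(responses, item_to_group, planted_loadings)``
    where ``responses`` has two columns per item (frequency label, portion
    label) and ``planted_loadings`` is groups x patterns.
    """
    if n_items < 2:
        raise ValueError("need at least two FFQ items")
    rng = np.random.default_rng(seed)
    n = len(cohort)

    groups = np.arange(n_items) % n_groups
    loadings = np.zeros((n_groups, n_patterns))
    per = n_groups // n_patterns
    for k in range(n_patterns):
        loadings[k * per:(k + 1) * per, k] = 1.0

    scores = rng.standard_normal((n, n_patterns))
    latent_group = pattern_strength * scores @ loadings.T  # n x groups
    latent_item = latent_group[:, groups] + rng.standard_normal((n, n_items))
    latent_item = (latent_item - latent_item.mean(0)) / latent_item.std(0)

    freq_idx = np.searchsorted(_FREQ_CUTS, latent_item)  # 0..8
    portion_idx = rng.integers(0, len(PORTION_LEVELS), size=(n, n_items))

    data = {"sample": cohort["sample"].to_numpy()}
    for j in range(n_items):
        data[f"item{j:03d}_freq"] = [FREQUENCY_LEVELS[k] for k in freq_idx[:, j]]
        data[f"item{j:03d}_portion"] = [PORTION_LEVELS[k] for k in portion_idx[:, j]]
    responses = pd.DataFrame(data)
    item_map = pd.DataFrame({"item": [f"item{j:03d}" for j in range(n_items)],
                             "group": [f"group{g:02d}" for g in groups]})
    return responses, item_map, loadings


# ---------------------------------------------------------------------------
# cohort bundle + provenance
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig,
                    with_ffq: bool = False) -> dict:
    """Run the full generator; returns genotypes, cohort table and
    (optionally) FFQ artifacts keyed by name."""
    rng = np.random.default_rng(config.seed)
    g = generate_genotypes(config, rng)
    cohort = generate_phenotype(g, config, rng)
    out = {"genotypes": g, "cohort": cohort}
    if with_ffq:
        ffq, item_map, loadings = generate_ffq(cohort, seed=config.seed + 2)
        out.update(ffq=ffq, item_map=item_map, planted_loadings=loadings)
    return out


def write_cohort(bundle: dict, config: SimulationConfig, outdir: str | Path) -> None:
    """Persist a simulated cohort: PLINK triple, cohort TSV, FFQ TSV and a
    provenance JSON recording the config and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(bundle["genotypes"], outdir / "genotypes")
    bundle["cohort"].to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    if "ffq" in bundle:
        bundle["ffq"].to_csv(outdir / "ffq.tsv", sep="\t", index=False)
        bundle["item_map"].to_csv(outdir / "item_groups.tsv", sep="\t", index=False)
    prov = asdict(config)
    prov["snp_specs"] = [asdict(s) for s in config.snp_specs]
    prov["ld_blocks"] = [{"snp_ids": list(b.snp_ids), "d_prime": b.d_prime}
                         for b in config.ld_blocks]
    if config.gxe is not None:
        prov["gxe"] = asdict(config.gxe)
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
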