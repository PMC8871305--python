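"""Config-driven orchestration of the full discovery flow.

Stages: sample/SNP quality control -> per-SNP association screen ->
D'-based pruning -> optional gene allow-list filter -> exhaustive GMDR
model search -> unweighted PRS construction and adjusted odds ratios ->
PRS x exposure interaction tables.  Every stage persists its output under
the run directory and a manifest records seeds, thresholds, per-stage
candidate counts (a monotone funnel) and content hashes, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, gmdr, gxe, ld, prs
from .genotype import GenotypeMatrix, read_plink, sample_qc, snp_qc
from .synthetic import (GxeSpec, LdBlock, SimulationConfig, SnpSpec,
                        simulate_cohort)

log = logging.getLogger("oaprs")


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""


@dataclass
class PipelineConfig:
    # either file inputs ...
    genotype_prefix: str | None = None
    cohort_path: str | None = None
    snp_gene_map: str | None = None       # TSV snp\tgene
    gene_allowlist: list[str] | None = None
    # ... or a simulation block
    simulation: SimulationConfig | None = None
    # thresholds
    p_screen: float = assoc.P_SCREEN_DEFAULT
    genomewide: float = assoc.GENOMEWIDE_DEFAULT
    dprime: float = ld.DPRIME_PRUNE_DEFAULT
    k_range: tuple[int, ...] = (2,)
    n_folds: int = 10
    cvc_min: int = 9
    sign_alpha: float = 0.05
    # QC; the sample thresholds assume a genome-wide panel — on a small
    # synthetic panel the heterozygosity rule bites at common-MAF SNPs,
    # so demos may relax them explicitly
    maf_min: float = 0.01
    hwe_min: float = 1e-6
    call_min: float = 0.95
    sample_missing_max: float = 0.04
    sample_het_max: float = 0.30
    # PRS / models
    prs_cutoffs: tuple[int, int] | None = None
    scan_covariates: list[str] = field(default_factory=list)
    gmdr_covariates: list[str] = field(default_factory=list)
    or_covariates_model1: list[str] = field(default_factory=lambda: ["sex", "age"])
    or_covariates_model2: list[str] = field(
        default_factory=lambda: ["sex", "age", "energy_pct_eer",
                                 "alcohol_g_day", "exercise_min_week"])
    exposures: list[str] = field(
        default_factory=lambda: ["energy_pct_eer", "carb_en_pct",
                                 "protein_en_pct", "fat_en_pct",
                                 "alcohol_g_day", "exercise_min_week"])
    out_dir: str = "oaprs_run"
    seed: int = 0

    _KNOWN = None  # populated below


PipelineConfig._KNOWN = set(PipelineConfig.__dataclass_fields__)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems (empty = valid)."""
    errs = []
    for name in ("p_screen", "genomewide", "sign_alpha"):
        v = getattr(config, name)
        if not 0.0 < v <= 1.0:
            errs.append(f"{name} must lie in (0,1], got {v}")
    if not 0.0 <= config.dprime <= 1.0:
        errs.append(f"dprime must lie in [0,1], got {config.dprime}")
    if config.simulation is None and config.genotype_prefix is None:
        errs.append("either a genotype_prefix/cohort_path pair or a "
                    "simulation block is required")
    if config.genotype_prefix is not None and config.cohort_path is None:
        errs.append("cohort_path is required with genotype_prefix")
    ks = list(config.k_range)
    if not ks or any(k < 1 or k > 10 for k in ks):
        errs.append(f"k_range must be subset sizes within [1,10], got {ks}")
    if config.n_folds < 2:
        errs.append("n_folds must be at least 2")
    if not 0 <= config.cvc_min <= config.n_folds:
        errs.append("cvc_min must lie in [0, n_folds]")
    return errs


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a parsed YAML/JSON mapping; unknown keys
    are rejected."""
    raw = dict(raw)
    unknown = set(raw) - PipelineConfig._KNOWN
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim = raw.pop("simulation", None)
    if sim is not None:
        sim = dict(sim)
        sim["snp_specs"] = [SnpSpec(**s) for s in sim.get("snp_specs", [])]
        sim["ld_blocks"] = [LdBlock(tuple(b["snp_ids"]), b["d_prime"])
                            for b in sim.get("ld_blocks", [])]
        if sim.get("interaction") is not None:
            sim["interaction"] = tuple(sim["interaction"])
        if sim.get("gxe") is not None:
            sim["gxe"] = GxeSpec(**sim["gxe"])
        sim = SimulationConfig(**sim)
    cfg = PipelineConfig(simulation=sim, **raw)
    if "k_range" in raw:
        cfg.k_range = tuple(raw["k_range"])
    errs = validate_config(cfg)
    if errs:
        raise ConfigError("; ".join(errs))
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    errs = validate_config(config)
    if errs:
        raise ConfigError("; ".join(errs))
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "thresholds": {"p_screen": config.p_screen,
                                     "genomewide": config.genomewide,
                                     "dprime": config.dprime,
                                     "sign_alpha": config.sign_alpha,
                                     "cvc_min": config.cvc_min},
                      "counts": {}, "outputs": {}}

    # --- inputs ---------------------------------------------------------
    stage = "input"
    try:
        if config.simulation is not None:
            bundle = simulate_cohort(config.simulation)
            g: GenotypeMatrix = bundle["genotypes"]
            cohort: pd.DataFrame = bundle["cohort"]
        else:
            g = read_plink(config.genotype_prefix)
            cohort = pd.read_csv(config.cohort_path, sep="\t",
                                 dtype={"sample": str})
        manifest["counts"]["input_snps"] = g.n_snps
        manifest["counts"]["input_samples"] = g.n_samples

        # --- QC ---------------------------------------------------------
        stage = "qc"
        g, sample_report = sample_qc(g, config.sample_missing_max,
                                     config.sample_het_max)
        keep = set(g.samples)
        cohort = cohort[cohort["sample"].isin(keep)].reset_index(drop=True)
        controls = cohort.set_index("sample").loc[g.samples, "case"].to_numpy() == 0
        g, snp_report = snp_qc(g, config.maf_min, config.hwe_min,
                               config.call_min, controls=controls)
        _write(sample_report, outdir / "sample_qc.tsv")
        _write(snp_report, outdir / "snp_qc.tsv")
        manifest["counts"]["qc_samples"] = g.n_samples
        manifest["counts"]["qc_snps"] = g.n_snps

        # --- association screen -----------------------------------------
        stage = "scan"
        hits = assoc.scan(g, cohort, config.scan_covariates, config.p_screen)
        hits = assoc.bonferroni_flag(hits, config.genomewide)
        _write(assoc.results_table(hits), outdir / "assoc.tsv")
        manifest["counts"]["screen_hits"] = len(hits)
        if not hits:
            log.warning("no candidates pass the screen at p < %g",
                        config.p_screen)
            manifest["status"] = "no-candidates"
            _finalize(manifest, outdir)
            return manifest

        # --- optional gene allow-list filter ----------------------------
        stage = "gene-filter"
        if config.snp_gene_map is not None and config.gene_allowlist:
            gmap = pd.read_csv(config.snp_gene_map, sep="\t",
                               names=["snp", "gene"], header=0)
            allowed = set(config.gene_allowlist)
            ok_snps = set(gmap.loc[gmap["gene"].isin(allowed), "snp"])
            hits = [h for h in hits if h.snp_id in ok_snps]
        manifest["counts"]["after_gene_filter"] = len(hits)

        # --- LD pruning --------------------------------------------------
        stage = "prune"
        retained, ld_table = ld.prune_by_dprime(hits, g, config.dprime)
        _write(ld_table, outdir / "ld_pairs.tsv")
        (outdir / "retained_snps.txt").write_text("\n".join(retained) + "\n")
        manifest["counts"]["after_prune"] = len(retained)

        # --- GMDR --------------------------------------------------------
        stage = "gmdr"
        retained = retained[:gmdr.MAX_CANDIDATES]
        scores = gmdr.compute_scores(cohort, config.gmdr_covariates)
        folds = gmdr.make_folds(cohort, config.n_folds, config.seed)
        ks = [k for k in config.k_range if k <= len(retained)]
        if not ks:
            raise RuntimeError(f"only {len(retained)} SNPs survive pruning; "
                               f"k_range {config.k_range} is infeasible")
        search = gmdr.search_best_models(retained, g, scores, ks, folds,
                                         config.sign_alpha, config.cvc_min)
        _write(gmdr.top_models_table(search), outdir / "gmdr_top.tsv")
        best = search["best"] or search["top"][0]
        chosen = {"snp_ids": list(best.snp_ids),
                  "mean_trba": best.mean_trba, "mean_teba": best.mean_teba,
                  "cvc": best.cvc, "sign_test_p": best.sign_test_p,
                  "cell_labels": {"/".join(map(str, k)): v
                                  for k, v in best.cell_labels.items()},
                  "passed_selection_bar": search["best"] is not None}
        (outdir / "gmdr_best.json").write_text(json.dumps(chosen, indent=2))
        manifest["counts"]["best_model_snps"] = len(best.snp_ids)

        # --- PRS ---------------------------------------------------------
        stage = "prs"
        tag = f"{len(best.snp_ids)}-SNP"
        risk = prs.risk_allele_orientation(hits, list(best.snp_ids))
        assignments, prs_log = prs.compute_prs(g, risk, tag)
        cutoffs = config.prs_cutoffs
        if cutoffs is None and tag not in prs.CUTOFF_SETS:
            counts = np.array([a.risk_allele_count for a in assignments])
            cutoffs = (int(np.percentile(counts, 40)),
                       int(np.percentile(counts, 80)))
        assignments = prs.categorize_prs(assignments, tag, cutoffs)
        _write(prs.assignments_frame(assignments), outdir / "prs.tsv")
        or_tables = [prs.fit_or_table(assignments, cohort, "case",
                                      config.or_covariates_model1, "model1"),
                     prs.fit_or_table(assignments, cohort, "case",
                                      config.or_covariates_model2, "model2")]
        _write(pd.concat(or_tables, ignore_index=True), outdir / "prs_or.tsv")

        # --- G x E -------------------------------------------------------
        stage = "gxe"
        specs = [gxe.default_spec(e) for e in config.exposures
                 if e in cohort.columns]
        if specs:
            table = gxe.interaction_table(assignments, cohort, specs,
                                          covariates=config.or_covariates_model2)
            _write(table, outdir / "gxe.tsv")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        _finalize(manifest, outdir)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _finalize(manifest, outdir)
    return manifest


def _finalize(manifest: dict, outdir: Path) -> None:
    for f in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.json")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
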