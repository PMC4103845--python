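"""End-to-end orchestration: simulate or load a study, apply the sample
exclusion filter, residualize traits on covariates, run single-SNP
family-based tests, combine p-values at gene and gene-family level against
a Monte Carlo null, attach Storey q-values, and write the report tables.

The published sensitivity analyses are expressed as configuration variants:
excluding participants with diabetes, toggling the smoking covariate,
additionally adjusting for BMI, and removing the most significant SNP.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fbat, fixtures, genio, qvalue
from .combine import CombineConfig, FamilyResult, GeneResult, combine_trait, \
    estimate_ld_correlation, mc_null_ensemble
from .simulate import SimConfig, simulate_study

logger = logging.getLogger("famassoc")


@dataclass
class RunConfig:
    sim: SimConfig | None = None
    ped_path: str | None = None
    map_path: str | None = None
    pheno_path: str | None = None
    manifest_path: str | None = None
    traits: tuple[str, ...] = fixtures.TRAITS
    covariates: tuple[str, ...] = genio.DEFAULT_COVARIATES
    log_transform: bool = True
    exclude_diabetes: bool = False
    adjust_smoking: bool = True
    adjust_bmi: bool = False
    drop_snp: str | None = None
    min_informative: int = fbat.DEFAULT_MIN_INFORMATIVE
    combine: CombineConfig = field(default_factory=CombineConfig)
    correction_scope: str = "per_trait"  # {"per_trait", "joint"}
    outdir: str | None = None
    seed: int = 0

    def covariates_for(self, trait: str) -> list[str]:
        covs = list(self.covariates)
        if not self.adjust_smoking and "smoking" in covs:
            covs.remove("smoking")
        if self.exclude_diabetes and "diabetes" in covs:
            covs.remove("diabetes")  # constant after the exclusion
        if self.adjust_bmi and trait != "BMI" and "BMI" not in covs:
            covs.append("BMI")
        return covs


@dataclass
class RunResult:
    config: RunConfig
    pedigree: genio.Pedigree
    genotypes: genio.GenotypeMatrix
    phenotypes: pd.DataFrame
    exclusion_log: genio.ExclusionLog
    snp_results: pd.DataFrame  # tidy: snp, trait, U, V, Z, p, b, n_informative
    snp_table: pd.DataFrame  # per-SNP, one p column per trait, with q
    gene_results: dict  # trait -> list[GeneResult]
    family_results: dict  # trait -> FamilyResult
    gene_table: pd.DataFrame  # genes x traits (+ gene-family row)
    manifest: pd.DataFrame


def _load_inputs(cfg: RunConfig):
    if cfg.sim is not None:
        sim = replace(cfg.sim, seed=cfg.seed)
        ped, geno, pheno = simulate_study(sim)
        manifest = pd.DataFrame(
            [(s, b.gene) for b in sim.ld_blocks for s in b.snps],
            columns=["snp", "gene"],
        )
        return ped, geno, pheno, manifest
    for name in ("ped_path", "map_path", "pheno_path", "manifest_path"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"{name} missing or does not exist: {p}")
    ped, geno, _ = genio.read_pedmap(cfg.ped_path, cfg.map_path)
    pheno = genio.read_phenotypes(cfg.pheno_path)
    manifest = genio.read_manifest(cfg.manifest_path)
    missing = set(manifest["snp"]) - set(geno.snps)
    if missing:
        raise ValueError(f"manifest SNPs absent from genotypes: {sorted(missing)}")
    return ped, geno, pheno, manifest


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full analysis; write tables when an output directory is
    configured.  Fixed config + seed reproduces every output byte for byte."""
    stage = "load"
    try:
        ped, geno, pheno, manifest = _load_inputs(cfg)

        stage = "exclusions"
        required = [c for c in cfg.covariates if c in pheno.columns]
        pheno_kept, excl = genio.apply_exclusions(pheno, required)
        if cfg.exclude_diabetes:
            if "diabetes" not in pheno_kept.columns:
                raise ValueError("no diabetes column; cannot exclude diabetes cases")
            n0 = len(pheno_kept)
            pheno_kept = pheno_kept[pheno_kept["diabetes"] == 0]
            excl.counts["diabetes"] = n0 - len(pheno_kept)
            excl.n_final = len(pheno_kept)

        stage = "drop_snp"
        if cfg.drop_snp is not None:
            if cfg.drop_snp not in set(manifest["snp"]):
                raise ValueError(f"--drop-snp {cfg.drop_snp}: not in manifest")
            manifest = manifest[manifest["snp"] != cfg.drop_snp].reset_index(drop=True)

        stage = "residualize"
        residuals = {}
        for trait in cfg.traits:
            covs = [c for c in cfg.covariates_for(trait) if c in pheno_kept.columns]
            residuals[trait] = fbat.adjust_covariates(
                pheno_kept, trait, covs, log_transform=cfg.log_transform
            )
            if residuals[trait].residuals.notna().sum() == 0:
                raise ValueError(f"trait {trait}: no non-missing values after exclusion")

        stage = "single_snp_tests"
        geno_used = geno
        if cfg.drop_snp is not None or len(manifest) != len(geno.snps):
            keep = [s for s in geno.snps if s in set(manifest["snp"])]
            meta = [m for m in geno.meta if m.snp in set(keep)]
            geno_used = genio.GenotypeMatrix(geno.values[keep], meta)
        snp_results = fbat.run_snp_tests(ped, geno_used, residuals, cfg.min_informative)

        stage = "null_ensemble"
        ccfg = replace(cfg.combine, seed=cfg.seed)
        if ccfg.null_mode == "ld_mvn":
            chrom = {m.snp: m.chrom for m in geno_used.meta}
            ld = estimate_ld_correlation(
                geno_used, founder_ids=ped.founder_ids, chrom_by_snp=chrom
            )
            ensemble = mc_null_ensemble(ld, ccfg)
        else:
            ensemble = mc_null_ensemble(None, ccfg, snps=geno_used.snps)

        stage = "combination"
        gene_results: dict[str, list[GeneResult]] = {}
        family_results: dict[str, FamilyResult] = {}
        for trait in cfg.traits:
            sub = snp_results[snp_results["trait"] == trait]
            gres, fres = combine_trait(sub, manifest, ensemble, ccfg)
            gene_results[trait] = gres
            family_results[trait] = fres

        stage = "multiple_testing"
        by = "trait" if cfg.correction_scope == "per_trait" else None
        snp_q = qvalue.add_qvalues(snp_results, p_col="p", by=by)
        snp_table = _snp_table(snp_q, manifest, cfg.traits)
        gene_table = _gene_table(gene_results, family_results, cfg.traits)

        stage = "write"
        result = RunResult(
            config=cfg, pedigree=ped, genotypes=geno_used, phenotypes=pheno_kept,
            exclusion_log=excl, snp_results=snp_q, snp_table=snp_table,
            gene_results=gene_results, family_results=family_results,
            gene_table=gene_table, manifest=manifest,
        )
        if cfg.outdir is not None:
            _write_outputs(result)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _snp_table(snp_q: pd.DataFrame, manifest: pd.DataFrame, traits) -> pd.DataFrame:
    wide_p = snp_q.pivot(index="snp", columns="trait", values="p")
    wide_q = snp_q.pivot(index="snp", columns="trait", values="q")
    out = manifest.copy()
    for t in traits:
        out[t] = wide_p.reindex(manifest["snp"])[t].values
        out[f"{t}_q"] = wide_q.reindex(manifest["snp"])[t].values
    return out


def _gene_table(gene_results, family_results, traits) -> pd.DataFrame:
    genes = [gr.gene for gr in next(iter(gene_results.values()))]
    rows = {}
    for g in genes:
        rows[g] = {}
    for trait in traits:
        qres = qvalue.qvalues(np.array([gr.p for gr in gene_results[trait]]))
        for gr, q in zip(gene_results[trait], qres.qvalues):
            rows[gr.gene][trait] = gr.p
            rows[gr.gene][f"{trait}_q"] = q
            rows[gr.gene][f"{trait}_flag"] = "*" if q < 0.05 else ""
    fam_row = {}
    for trait in traits:
        fam_row[trait] = family_results[trait].p
        fam_row[f"{trait}_q"] = np.nan
        fam_row[f"{trait}_flag"] = "*" if family_results[trait].p < 0.05 else ""
    rows["gene-family"] = fam_row
    table = pd.DataFrame(rows).T
    table.index.name = "gene"
    return table.reset_index()


def run_manifest(cfg: RunConfig, excl: genio.ExclusionLog) -> dict:
    """Machine-readable record of everything needed to reproduce the run."""
    sim = None
    if cfg.sim is not None:
        sim = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(cfg.sim).items()
            if k not in ("ld_blocks",)
        }
        sim["ld_blocks"] = [
            {"gene": b.gene, "snps": b.snps, "r": b.r} for b in cfg.sim.ld_blocks
        ]
    return {
        "seed": cfg.seed,
        "traits": list(cfg.traits),
        "covariates": list(cfg.covariates),
        "covariates_by_trait": {t: cfg.covariates_for(t) for t in cfg.traits},
        "log_transform": cfg.log_transform,
        "exclude_diabetes": cfg.exclude_diabetes,
        "adjust_smoking": cfg.adjust_smoking,
        "adjust_bmi": cfg.adjust_bmi,
        "drop_snp": cfg.drop_snp,
        "min_informative": cfg.min_informative,
        "tau": cfg.combine.tau,
        "weight_mode": cfg.combine.weight_mode,
        "B": cfg.combine.B,
        "null_mode": cfg.combine.null_mode,
        "correction_scope": cfg.correction_scope,
        "exclusions": {"counts": excl.counts, "n_initial": excl.n_initial,
                       "n_final": excl.n_final},
        "simulation": sim,
    }


def _write_outputs(result: RunResult) -> None:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    result.snp_table.to_csv(outdir / "snp_results.tsv", sep="\t", index=False,
                            float_format=fmt)
    result.gene_table.to_csv(outdir / "gene_results.tsv", sep="\t", index=False,
                             float_format=fmt)
    result.snp_results.to_csv(outdir / "snp_results_tidy.tsv", sep="\t", index=False,
                              float_format=fmt)
    (outdir / "exclusion_log.txt").write_text(result.exclusion_log.render() + "\n")
    manifest = run_manifest(result.config, result.exclusion_log)
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# Sensitivity analyses

SENSITIVITY_VARIANTS = (
    "exclude_diabetes",
    "no_smoking_adjustment",
    "adjust_bmi",
    "drop_top_snp",
)


def sensitivity_suite(cfg: RunConfig, base: RunResult | None = None) -> dict:
    """Run the four published sensitivity variants and tabulate gene-family
    p-values side by side with the base analysis.

    Returns {"base": RunResult, variant_name: RunResult..., "comparison":
    DataFrame}.  An infeasible variant (e.g. no diabetes column) is skipped
    with a warning.
    """
    if base is None:
        base = run_pipeline(replace(cfg, outdir=None))
    runs: dict[str, RunResult] = {"base": base}

    variants: dict[str, RunConfig] = {}
    if "diabetes" in base.phenotypes.columns:
        variants["exclude_diabetes"] = replace(cfg, exclude_diabetes=True, outdir=None)
    else:
        logger.warning("sensitivity: no diabetes column; variant skipped")
    if "smoking" in cfg.covariates:
        variants["no_smoking_adjustment"] = replace(cfg, adjust_smoking=False, outdir=None)
    else:
        logger.warning("sensitivity: smoking not a covariate; variant skipped")
    variants["adjust_bmi"] = replace(cfg, adjust_bmi=True, outdir=None)
    top = base.snp_results.loc[base.snp_results["p"].idxmin()]
    variants["drop_top_snp"] = replace(cfg, drop_snp=top["snp"], outdir=None)
    logger.info("sensitivity: most significant SNP is %s (%s, p=%.4g)",
                top["snp"], top["trait"], top["p"])

    for name, vcfg in variants.items():
        try:
            runs[name] = run_pipeline(vcfg)
        except RuntimeError as exc:
            logger.warning("sensitivity variant %s failed: %s", name, exc)

    rows = []
    for name, res in runs.items():
        for trait in cfg.traits:
            row = {"variant": name, "trait": trait,
                   "family_p": res.family_results[trait].p}
            for gr in res.gene_results[trait]:
                row[gr.gene] = gr.p
            rows.append(row)
    comparison = pd.DataFrame(rows)
    runs["comparison"] = comparison
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        comparison.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False,
                          float_format="%.6g")
    return runs


# ---------------------------------------------------------------------------
# Config file support

def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML key-value file.

    Top-level keys mirror RunConfig fields; ``combine`` and ``sim`` nest
    their own fields (``sim: default`` requests the packaged study design).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    combine = CombineConfig(**raw.pop("combine", {}))
    sim_raw = raw.pop("sim", None)
    sim = None
    if sim_raw == "default":
        sim = SimConfig()
    elif isinstance(sim_raw, dict):
        sim = SimConfig(**sim_raw)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "traits" in raw:
        raw["traits"] = tuple(raw["traits"])
    if "covariates" in raw:
        raw["covariates"] = tuple(raw["covariates"])
    return RunConfig(sim=sim, combine=combine, **raw)
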