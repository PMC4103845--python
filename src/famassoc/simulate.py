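"""Synthetic multiplex-family study generator.

Emulates the design of a family-based genetic study of obesity traits:
~94 extended (multiplex) families, 61 biallelic tagSNPs in 7 gene blocks
with within-block linkage disequilibrium, and four right-skewed, correlated
quantitative traits (BMI, waist circumference, waist-to-hip ratio, percent
body fat) with covariate effects and a shared family random effect.

The generator works in three stages, each reproducible from one seed via
deterministic sub-streams:

1. founder haplotypes — a latent multivariate-normal vector with a
   block-banded (AR-chain) correlation structure is thresholded at the
   quantile of each SNP's target minor-allele frequency, producing 0/1
   haplotypes whose allelic correlation matches a target ``r`` per adjacent
   pair (the latent correlation needed for a given allelic correlation is
   solved numerically from the bivariate-normal orthant probability);
2. gene drop — founders receive two pool haplotypes, every meiosis
   transmits a recombinant with per-interval crossover probability equal to
   the recombination fraction, genotypes are additive 0/1/2 counts;
3. phenotypes — trait = covariate term + sum of per-SNP additive effects +
   family random effect + residual noise, exponentiated when ``log_scale``
   is set so the observed trait is right-skewed and a log transformation
   downstream recovers linearity.

Extended families are collections of linked nuclear units spanning three
generations: a grandparental couple whose children each marry in a founder
spouse and have children of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import fixtures
from .genio import FOUNDER, GenotypeMatrix, Pedigree, SnpMeta

# sub-stream labels hashed off the master seed, one per stage
_STREAMS = {"haplotypes": 0, "segregation": 1, "covariates": 2, "noise": 3, "pedigree": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stage],)))


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class LdBlock:
    """A gene block: ordered member SNPs sharing LD, with a target allelic
    correlation ``r`` for each adjacent pair (AR-chain within the block)."""

    gene: str
    snps: list[str]
    r: float = 0.6


@dataclass
class SimConfig:
    n_families: int = 94
    units_per_family: tuple[int, int] = (5, 7)  # nuclear units per extended family
    offspring_per_family: tuple[int, int] = (4, 7)  # offspring per nuclear unit
    snp_freqs: np.ndarray = None  # minor-allele frequencies, (0, 0.5]
    ld_blocks: list[LdBlock] = None
    recomb_fractions: np.ndarray = None  # per adjacent SNP pair, [0, 0.5]
    trait_effects: dict = field(default_factory=dict)  # trait -> per-SNP beta
    covariate_spec: dict = None  # covariate -> coefficient (or level -> coef)
    family_effect_var: float = 0.02
    noise_var: float = 0.04
    log_scale: bool = True
    traits: tuple[str, ...] = fixtures.TRAITS
    n_missing_smoking: int = 0
    n_missing_covariate: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.ld_blocks is None:
            manifest = fixtures.default_manifest()
            self.ld_blocks = [
                LdBlock(gene, list(grp["snp"]))
                for gene, grp in manifest.groupby("gene", sort=False)
            ]
        n = sum(len(b.snps) for b in self.ld_blocks)
        if self.snp_freqs is None:
            # frequencies similar within a block (as in real LD blocks, and
            # required for the target allelic correlation to be attainable)
            block_base = [0.15, 0.30, 0.22, 0.38, 0.18, 0.27, 0.33]
            jitter = [0.0, 0.02, -0.02, 0.04, -0.04, 0.01, -0.01, 0.03, -0.03]
            freqs = []
            for i, b in enumerate(self.ld_blocks):
                base = block_base[i % len(block_base)]
                freqs += [base + jitter[k % len(jitter)] for k in range(len(b.snps))]
            self.snp_freqs = np.array(freqs)
        self.snp_freqs = np.asarray(self.snp_freqs, dtype=float)
        if self.recomb_fractions is None:
            # tight within blocks, free recombination across block boundaries
            theta = np.full(max(n - 1, 0), 0.5)
            pos = 0
            for b in self.ld_blocks:
                L = len(b.snps)
                theta[pos : pos + L - 1] = 0.01
                pos += L
            self.recomb_fractions = theta
        self.recomb_fractions = np.asarray(self.recomb_fractions, dtype=float)
        if self.covariate_spec is None:
            self.covariate_spec = default_covariate_spec()
        self._validate(n)

    def _validate(self, n: int) -> None:
        if len(self.snp_freqs) != n:
            raise ValueError(f"snp_freqs length {len(self.snp_freqs)} != {n} SNPs")
        if np.any(self.snp_freqs <= 0) or np.any(self.snp_freqs > 0.5):
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")
        for b in self.ld_blocks:
            if not -1.0 <= b.r <= 1.0:
                raise ValueError(f"block {b.gene}: target correlation {b.r} outside [-1, 1]")
        if len(self.recomb_fractions) != max(n - 1, 0):
            raise ValueError("recomb_fractions must have one entry per adjacent SNP pair")
        if np.any(self.recomb_fractions < 0) or np.any(self.recomb_fractions > 0.5):
            raise ValueError("recombination fractions must lie in [0, 0.5]")
        if self.family_effect_var < 0 or self.noise_var < 0:
            raise ValueError("variances must be non-negative")
        for trait, beta in self.trait_effects.items():
            if len(np.atleast_1d(beta)) != n:
                raise ValueError(
                    f"trait_effects[{trait!r}] length != {n} SNPs"
                )

    @property
    def snp_ids(self) -> list[str]:
        return [s for b in self.ld_blocks for s in b.snps]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_meta(self) -> list[SnpMeta]:
        meta = []
        counter: dict[int, int] = {}
        for b in self.ld_blocks:
            chrom = fixtures.GENE_CHROMOSOMES.get(b.gene, 1)
            for snp in b.snps:
                counter[chrom] = counter.get(chrom, 0) + 1
                meta.append(SnpMeta(snp, chrom, 100_000 * counter[chrom], "A", "G"))
        return meta


def default_covariate_spec() -> dict:
    """Modest covariate effects on the log-trait scale."""
    return {
        "age": 0.003,  # per year, centered
        "sex": {1: 0.0, 2: 0.04},  # female vs male
        "center": {"AZ": 0.0, "DK": -0.02, "OK": 0.01},
        "smoking": {"never": 0.0, "former": -0.01, "current": -0.03},
        "alcohol": {"never": 0.0, "former": 0.0, "current": -0.01},
        "activity": -0.000002,  # per step/day, centered
        "energy": 0.00002,  # per kcal/day, centered
        "ses": {1: 0.0, 2: -0.01, 3: -0.02},
        "diabetes": {0: 0.0, 1: 0.08},
    }


# ---------------------------------------------------------------------------
# Founder haplotypes via latent-Gaussian thresholding

@dataclass
class HaplotypePool:
    """Founder haplotypes (haplotype x SNP, alleles 0/1, 1 = minor)."""

    haplotypes: np.ndarray
    snps: list[str]
    freqs: np.ndarray  # realized allele frequencies
    adjacent_corr: np.ndarray  # realized correlation per adjacent pair

    def __len__(self) -> int:
        return len(self.haplotypes)


def allelic_correlation(rho: float, p1: float, p2: float) -> float:
    """Correlation of the two 0/1 allele indicators induced by latent normal
    correlation ``rho`` with marginal frequencies ``p1``, ``p2``."""
    z1 = stats.norm.ppf(1.0 - p1)
    z2 = stats.norm.ppf(1.0 - p2)
    p11 = stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([-z1, -z2])
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return float((p11 - p1 * p2) / denom)


def latent_correlation(r: float, p1: float, p2: float) -> float:
    """Invert :func:`allelic_correlation`: the latent-normal correlation that
    yields allelic correlation ``r`` at the given frequencies.

    Raises ``ValueError`` when no latent correlation in (-1, 1) attains the
    target (possible when frequencies differ and |r| is large).
    """
    if r == 0.0:
        return 0.0
    f = lambda rho: allelic_correlation(rho, p1, p2) - r
    lo, hi = -0.9999, 0.9999
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"allelic correlation {r} unattainable at frequencies ({p1}, {p2})"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def latent_block_matrix(cfg: SimConfig) -> np.ndarray:
    """Latent correlation matrix over all SNPs: AR chains within each block
    (correlation between SNPs i<j is the product of adjacent latent
    correlations along the chain), zero across blocks."""
    n = cfg.n_snps
    R = np.eye(n)
    pos = 0
    for b in cfg.ld_blocks:
        L = len(b.snps)
        rhos = []
        for k in range(L - 1):
            p1 = cfg.snp_freqs[pos + k]
            p2 = cfg.snp_freqs[pos + k + 1]
            try:
                rhos.append(latent_correlation(b.r, p1, p2))
            except ValueError as exc:
                raise ValueError(f"block {b.gene}: {exc}") from exc
        for i in range(L):
            acc = 1.0
            for j in range(i + 1, L):
                acc *= rhos[j - 1]
                R[pos + i, pos + j] = R[pos + j, pos + i] = acc
        pos += L
    eigmin = np.linalg.eigvalsh(R).min() if n else 1.0
    if eigmin < -1e-10:
        bad = max(cfg.ld_blocks, key=lambda b: abs(b.r)).gene
        raise ValueError(
            f"latent correlation matrix not positive semidefinite "
            f"(min eigenvalue {eigmin:.3g}); check block {bad}"
        )
    return R


def simulate_founder_haplotypes(
    cfg: SimConfig, n_haplotypes: int, rng: np.random.Generator | None = None
) -> HaplotypePool:
    """Draw founder haplotypes by thresholding latent multivariate normals.

    Allele 1 (minor) is emitted when the latent variable exceeds the
    ``1 - freq`` quantile, so alleles within a block are correlated and
    across blocks independent.
    """
    if rng is None:
        rng = _stage_rng(cfg.seed, "haplotypes")
    n_snps = cfg.n_snps
    if n_haplotypes == 0:
        return HaplotypePool(
            np.zeros((0, n_snps), dtype=np.int8),
            cfg.snp_ids,
            np.full(n_snps, np.nan),
            np.full(max(n_snps - 1, 0), np.nan),
        )
    R = latent_block_matrix(cfg)
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(n_snps))
    Z = rng.standard_normal((n_haplotypes, n_snps)) @ chol.T
    thresholds = stats.norm.ppf(1.0 - cfg.snp_freqs)
    H = (Z > thresholds).astype(np.int8)
    freqs = H.mean(axis=0)
    with np.errstate(invalid="ignore"):
        adj = np.array(
            [
                np.corrcoef(H[:, j], H[:, j + 1])[0, 1]
                if H[:, j].std() > 0 and H[:, j + 1].std() > 0
                else np.nan
                for j in range(n_snps - 1)
            ]
        )
    return HaplotypePool(H, cfg.snp_ids, freqs, adj)


# ---------------------------------------------------------------------------
# Pedigree construction

def build_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Three-generation multiplex families: a grandparental couple whose
    children each pair with a marry-in founder and have children."""
    if rng is None:
        rng = _stage_rng(cfg.seed, "pedigree")
    rows = []
    lo_u, hi_u = cfg.units_per_family
    lo_k, hi_k = cfg.offspring_per_family
    for f in range(1, cfg.n_families + 1):
        fid = f"F{f:03d}"
        n_units = int(rng.integers(lo_u, hi_u + 1))
        gf, gm = f"{fid}_G1_1", f"{fid}_G1_2"
        rows.append((fid, gf, FOUNDER, FOUNDER, 1))
        rows.append((fid, gm, FOUNDER, FOUNDER, 2))
        n_children = max(n_units - 1, 1)
        for c in range(1, n_children + 1):
            sex = 1 if c % 2 == 1 else 2
            child = f"{fid}_G2_{c}"
            rows.append((fid, child, gf, gm, sex))
            spouse = f"{fid}_G2S_{c}"
            rows.append((fid, spouse, FOUNDER, FOUNDER, 3 - sex))
            k = int(rng.integers(lo_k, hi_k + 1))
            father, mother = (child, spouse) if sex == 1 else (spouse, child)
            for g in range(1, k + 1):
                rows.append(
                    (fid, f"{fid}_G3_{c}_{g}", father, mother, int(rng.integers(1, 3)))
                )
    members = pd.DataFrame(rows, columns=["fid", "iid", "pat", "mat", "sex"])
    return Pedigree(members)


# ---------------------------------------------------------------------------
# Gene drop

def _topological_levels(ped: Pedigree) -> list[np.ndarray]:
    """Individual row positions grouped by generation depth (parents first)."""
    iid = ped.members["iid"].values
    pos = {x: i for i, x in enumerate(iid)}
    pat = ped.members["pat"].values
    mat = ped.members["mat"].values
    level = np.zeros(len(iid), dtype=int)
    changed = True
    while changed:
        changed = False
        for i in range(len(iid)):
            if pat[i] != FOUNDER:
                depth = max(level[pos[pat[i]]], level[pos[mat[i]]]) + 1
                if depth != level[i]:
                    level[i] = depth
                    changed = True
    return [np.where(level == d)[0] for d in range(level.max() + 1)]


def _meiosis(
    parent_haps: np.ndarray, theta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Transmit one recombinant haplotype per parent.

    ``parent_haps`` is (n, 2, L); crossover occurs between SNP j and j+1
    with probability ``theta[j]``.
    """
    n, _, L = parent_haps.shape
    start = rng.integers(0, 2, size=n)
    if L > 1:
        switches = (rng.random((n, L - 1)) < theta).astype(np.int8)
        pattern = (start[:, None] + np.cumsum(switches, axis=1)) % 2
        pattern = np.concatenate([start[:, None] % 2, pattern], axis=1)
    else:
        pattern = start[:, None] % 2
    return np.where(pattern == 0, parent_haps[:, 0, :], parent_haps[:, 1, :])


def gene_drop(
    ped: Pedigree,
    pool: HaplotypePool,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Drop founder haplotypes down the pedigree.

    Founders receive consecutive haplotype pairs from the pool; each meiosis
    transmits a recombinant of the parent's two haplotypes.  Output is the
    additive minor-allele count per individual and SNP.
    """
    if rng is None:
        rng = _stage_rng(cfg.seed, "segregation")
    haps = gene_drop_haplotypes(ped, pool, cfg, rng)
    values = pd.DataFrame(
        haps.sum(axis=1, dtype=np.int16).astype(float),
        index=ped.members["iid"].values,
        columns=cfg.snp_ids,
    )
    return GenotypeMatrix(values, cfg.snp_meta())


def gene_drop_haplotypes(
    ped: Pedigree,
    pool: HaplotypePool,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_individuals, 2, n_snps) haplotype array; paternal copy first."""
    n = len(ped)
    L = cfg.n_snps
    founder_mask = ped.is_founder().values
    n_founders = int(founder_mask.sum())
    if len(pool) < 2 * n_founders:
        raise ValueError(
            f"haplotype pool has {len(pool)} haplotypes; {2 * n_founders} needed"
        )
    iid = ped.members["iid"].values
    pos = {x: i for i, x in enumerate(iid)}
    pat_idx = np.array([pos[p] if p != FOUNDER else -1 for p in ped.members["pat"]])
    mat_idx = np.array([pos[p] if p != FOUNDER else -1 for p in ped.members["mat"]])

    haps = np.zeros((n, 2, L), dtype=np.int8)
    founder_rows = np.where(founder_mask)[0]
    haps[founder_rows, 0, :] = pool.haplotypes[0 : 2 * n_founders : 2]
    haps[founder_rows, 1, :] = pool.haplotypes[1 : 2 * n_founders : 2]

    for idx in _topological_levels(ped)[1:]:
        haps[idx, 0, :] = _meiosis(haps[pat_idx[idx]], cfg.recomb_fractions, rng)
        haps[idx, 1, :] = _meiosis(haps[mat_idx[idx]], cfg.recomb_fractions, rng)
    return haps


# ---------------------------------------------------------------------------
# Phenotypes and covariates

_TRAIT_INTERCEPTS = {"BMI": np.log(31.0), "WC": np.log(103.0), "WHR": np.log(0.91), "PBF": np.log(37.0)}

_AGE_BY_LEVEL = {0: (58.0, 8.0), 1: (34.0, 7.0)}  # deeper levels fall back to (19, 3)


def simulate_covariates(
    ped: Pedigree, rng: np.random.Generator | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Draw the covariate table: age (by generation), sex (from the
    pedigree), study center (per family), smoking, pack-years, alcohol,
    steps/day, energy intake, a 3-level ordinal socioeconomic score, and
    diabetes status."""
    if rng is None:
        rng = _stage_rng(seed if seed is not None else 0, "covariates")
    n = len(ped)
    levels = np.zeros(n, dtype=int)
    for d, idx in enumerate(_topological_levels(ped)):
        levels[idx] = d
    mu = np.array([_AGE_BY_LEVEL.get(d, (19.0, 3.0))[0] for d in levels])
    sd = np.array([_AGE_BY_LEVEL.get(d, (19.0, 3.0))[1] for d in levels])
    age = np.clip(rng.normal(mu, sd), 14.0, 93.0)

    fids = ped.members["fid"].values
    uniq_fids = pd.unique(fids)
    center_by_fam = dict(
        zip(uniq_fids, rng.choice(["AZ", "DK", "OK"], size=len(uniq_fids)))
    )
    smoking = rng.choice(SMOKING := ["current", "former", "never"], size=n, p=[0.30, 0.28, 0.42])
    pack_years = np.where(
        np.isin(smoking, ["current", "former"]), rng.lognormal(2.2, 0.8, size=n), 0.0
    )
    return pd.DataFrame(
        {
            "fid": fids,
            "age": np.round(age, 1),
            "sex": ped.members["sex"].values,
            "center": [center_by_fam[f] for f in fids],
            "smoking": smoking,
            "pack_years": np.round(pack_years, 1),
            "alcohol": rng.choice(["current", "former", "never"], size=n, p=[0.45, 0.20, 0.35]),
            "activity": np.round(rng.lognormal(8.6, 0.5, size=n)),
            "energy": np.round(np.clip(rng.normal(2100.0, 550.0, size=n), 800.0, None)),
            "ses": rng.choice([1, 2, 3], size=n, p=[0.3, 0.4, 0.3]),
            "diabetes": (rng.random(n) < 0.23).astype(int),
        },
        index=pd.Index(ped.members["iid"].values, name="iid"),
    )


def _covariate_term(cov: pd.DataFrame, spec: dict) -> np.ndarray:
    term = np.zeros(len(cov))
    for name, eff in spec.items():
        if name not in cov.columns:
            continue
        x = cov[name]
        if isinstance(eff, dict):
            term += x.map(eff).fillna(0.0).values
        else:
            xv = x.values.astype(float)
            term += eff * (xv - xv.mean())
    return term


def simulate_phenotypes(
    geno: GenotypeMatrix,
    ped: Pedigree,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the phenotype/covariate table.

    Each trait is covariate term + per-SNP additive genetic effects + a
    family random effect shared within the extended family + residual
    noise, exponentiated when ``cfg.log_scale``.  Raw anthropometric fields
    (weight, height, waist, hip) are emitted so BMI and WHR are recomputable.
    """
    if list(geno.ids) != list(ped.ids):
        raise ValueError("genotype and pedigree individuals do not match")
    if rng is None:
        rng = _stage_rng(cfg.seed, "noise")
    if covariates is None:
        covariates = simulate_covariates(ped, rng=_stage_rng(cfg.seed, "covariates"))
    n = len(ped)
    G = np.nan_to_num(geno.values.values)

    fids = ped.members["fid"].values
    uniq = pd.unique(fids)
    fam_pos = pd.Series(np.arange(len(uniq)), index=uniq)

    out = covariates.copy()
    cov_term = _covariate_term(covariates, cfg.covariate_spec)
    for trait in cfg.traits:
        beta = np.asarray(cfg.trait_effects.get(trait, np.zeros(cfg.n_snps)), dtype=float)
        fam_eff = rng.normal(0.0, np.sqrt(cfg.family_effect_var), size=len(uniq))
        lp = (
            _TRAIT_INTERCEPTS.get(trait, 0.0)
            + cov_term
            + G @ beta
            + fam_eff[fam_pos[fids].values]
            + rng.normal(0.0, np.sqrt(cfg.noise_var), size=n)
        )
        out[trait] = np.exp(lp) if cfg.log_scale else lp

    # raw anthropometrics consistent with the derived indices
    if "BMI" in out.columns:
        height = np.round(
            rng.normal(np.where(out["sex"] == 1, 1.72, 1.60), 0.06), 3
        )
        out["height"] = height
        out["weight"] = np.round(out["BMI"] * height**2, 1)
    if "WC" in out.columns and "WHR" in out.columns:
        out["waist"] = np.round(out["WC"], 1)
        out["hip"] = np.round(out["WC"] / out["WHR"], 1)

    if cfg.n_missing_smoking or cfg.n_missing_covariate:
        out = inject_missingness(
            out, cfg.n_missing_smoking, cfg.n_missing_covariate, rng=rng
        )
    return out


def inject_missingness(
    pheno: pd.DataFrame,
    n_smoking: int,
    n_covariate: int,
    covariate: str = "alcohol",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Blank smoking status in ``n_smoking`` rows and ``covariate`` in a
    further (disjoint) ``n_covariate`` rows, emulating reported sample
    accounting."""
    if rng is None:
        rng = np.random.default_rng(0)
    if n_smoking + n_covariate > len(pheno):
        raise ValueError("more missing rows requested than rows available")
    out = pheno.copy()
    idx = rng.choice(len(out), size=n_smoking + n_covariate, replace=False)
    out.iloc[idx[:n_smoking], out.columns.get_loc("smoking")] = np.nan
    out.iloc[idx[n_smoking:], out.columns.get_loc(covariate)] = np.nan
    return out


# ---------------------------------------------------------------------------
# One-call study generation

def simulate_study(
    cfg: SimConfig,
) -> tuple[Pedigree, GenotypeMatrix, pd.DataFrame]:
    """Generate pedigree, genotypes and phenotypes for one study replicate.

    All randomness derives from ``cfg.seed`` through per-stage sub-streams,
    so a fixed seed yields byte-identical output and each stage can be
    regenerated independently.
    """
    ped = build_pedigree(cfg)
    n_founders = int(ped.is_founder().sum())
    pool = simulate_founder_haplotypes(cfg, 2 * n_founders)
    geno = gene_drop(ped, pool, cfg)
    pheno = simulate_phenotypes(geno, ped, cfg)
    return ped, geno, pheno
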