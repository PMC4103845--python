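"""Gene- and gene-family-level p-value combination by the (weighted)
truncated product method (TPM) with a Monte Carlo null that respects LD.

The truncated product statistic over L p-values with non-negative weights
``w`` (normalized to mean 1 within the combining set) and truncation
threshold ``tau`` is

    W = prod_i p_i ^ ( w_i * I(p_i <= tau) )

i.e. the weighted product of the p-values at or below ``tau``; an empty
product is 1.  Small W is evidence against the joint null.  Because the
per-SNP tests within a gene are correlated through linkage disequilibrium,
significance is assessed against a simulated null: draw Z ~ MVN(0, R) with
R the genotype LD correlation matrix, convert to two-sided p-values, form
the null W, and report the add-one Monte Carlo estimate
``p = (1 + #{W_null <= W_obs}) / (B + 1)``.

The gene-family (second) stage reuses the same SNP-level ensemble: each
draw's gene-level statistic is converted to a null gene p-value by ranking
it within the ensemble, and the TPM is applied again across genes.  This
avoids nested Monte Carlo while preserving the between-gene correlation of
genes residing in the same genomic cluster.

All product statistics are computed in the log domain, so 61 p-values of
1e-300 combine without underflow.

For the unweighted, independent-null case a closed-form distribution
(Zaykin's formula) is provided as an analytic cross-check of the Monte
Carlo machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .genio import GenotypeMatrix

logger = logging.getLogger("famassoc")

DEFAULT_TAU = 0.05
DEFAULT_B = 50_000


@dataclass
class CombineConfig:
    tau: float = DEFAULT_TAU
    weight_mode: str = "abs_effect"  # {"uniform", "abs_effect"}
    B: int = DEFAULT_B
    seed: int = 0
    null_mode: str = "ld_mvn"  # {"independent", "ld_mvn"}

    def __post_init__(self):
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("truncation threshold tau must lie in (0, 1]")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.weight_mode not in ("uniform", "abs_effect"):
            raise ValueError(f"unknown weight mode {self.weight_mode!r}")
        if self.null_mode not in ("independent", "ld_mvn"):
            raise ValueError(f"unknown null mode {self.null_mode!r}")


# ---------------------------------------------------------------------------
# Statistic

def normalize_weights(weights: np.ndarray) -> np.ndarray:
    """Scale non-negative weights to mean 1; an all-zero (or degenerate)
    vector falls back to uniform."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.all(np.isfinite(w)) or w.sum() == 0:
        return np.ones_like(w)
    return w / w.mean()


def tpm_log_statistic(
    pvals: np.ndarray,
    weights: np.ndarray | None = None,
    tau: float = DEFAULT_TAU,
    floor: float | None = None,
) -> float:
    """ln W of the weighted truncated product statistic.

    ``pvals`` must lie in (0, 1]; zeros are clamped to ``floor`` (with a
    warning) when one is supplied, otherwise rejected.  Weights are used as
    given (``None`` means uniform); callers that derive weights from effect
    sizes normalize them to mean 1 first (see :func:`normalize_weights`).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        if floor is None:
            raise ValueError("p-value of 0 cannot be combined without a floor")
        logger.warning("clamping %d zero p-value(s) to %g", int((p == 0).sum()), floor)
        p = np.maximum(p, floor)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    mask = p <= tau
    return float(np.sum(w[mask] * np.log(p[mask])))


def tpm_statistic(
    pvals: np.ndarray,
    weights: np.ndarray | None = None,
    tau: float = DEFAULT_TAU,
    floor: float | None = None,
) -> float:
    """W itself (may underflow to 0 for extreme inputs; comparisons should
    use :func:`tpm_log_statistic`)."""
    return float(np.exp(tpm_log_statistic(pvals, weights, tau, floor)))


def _tpm_log_statistic_rows(P: np.ndarray, w: np.ndarray, tau: float) -> np.ndarray:
    """ln W for each row of a (B, L) matrix of p-values.

    ``w`` is either a length-L weight vector (fixed weights) or a (B, L)
    matrix of per-draw weights.
    """
    mask = P <= tau
    with np.errstate(divide="ignore"):
        lp = np.where(mask, np.log(np.maximum(P, 1e-320)), 0.0)
    if w.ndim == 2:
        return (lp * w).sum(axis=1)
    return lp @ w


def _null_weight_rows(P: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Per-draw effect-size weights for the null ensemble.

    The observed weight of SNP i is |b_i| = |U_i/V_i| = |Z_i| / sqrt(V_i),
    a function of the test's Z-score and its (fixed) variance.  The same
    function applied to each null draw, |Z_bi| = Phi^{-1}(1 - p_bi / 2),
    gives the draw's own weights, normalized to mean 1 row-wise.  Weights
    must be re-estimated per draw: the observed weights are correlated with
    the observed p-values, and freezing them makes the null statistic
    stochastically larger than the observed one, inflating type-I error.
    """
    Z = stats.norm.isf(np.minimum(P, 1.0) / 2.0)
    W = Z / np.sqrt(V)[None, :]
    means = W.mean(axis=1, keepdims=True)
    means[means == 0] = 1.0
    return W / means


# ---------------------------------------------------------------------------
# Closed-form null distribution (unweighted, independent case)

def tpm_pvalue_closedform(W: float, L: int, tau: float = DEFAULT_TAU) -> float:
    """P(W_null <= W) for the unweighted TPM of L independent uniform
    p-values — the analytic reference distribution.

    Conditioning on k of the L p-values falling at or below tau,

        P = sum_{k=1}^{L} C(L,k) (1-tau)^{L-k} *
            [ W * sum_{s=0}^{k-1} (k ln tau - ln W)^s / s!   if W <= tau^k
              tau^k                                          otherwise ]

    evaluated in the log domain.  ``W`` must lie in (0, 1]; W = 1 gives 1.
    """
    return float(np.exp(tpm_log_pvalue_closedform(np.log(_check_w(W)), L, tau)))


def _check_w(W: float) -> float:
    if not 0.0 < W <= 1.0:
        raise ValueError(f"W must lie in (0, 1], got {W}")
    return W


def tpm_log_pvalue_closedform(log_w: float, L: int, tau: float = DEFAULT_TAU) -> float:
    """ln P(W_null <= W) given ln W (log-domain form of
    :func:`tpm_pvalue_closedform`)."""
    if log_w > 0:
        raise ValueError("ln W must be <= 0")
    if log_w == 0.0:
        return 0.0
    log1mtau = np.log1p(-tau) if tau < 1.0 else -np.inf
    terms = []
    for k in range(1, L + 1):
        log_coef = (
            gammaln(L + 1) - gammaln(k + 1) - gammaln(L - k + 1)
            + (L - k) * (log1mtau if L > k else 0.0)
        )
        if tau >= 1.0 and L > k:
            continue  # (1-tau)^{L-k} = 0
        k_log_tau = k * np.log(tau)
        if log_w <= k_log_tau:
            # W * sum_s (k ln tau - ln W)^s / s!
            x = k_log_tau - log_w  # >= 0
            s = np.arange(k)
            with np.errstate(divide="ignore"):
                log_terms = s * np.log(x) if x > 0 else np.where(s == 0, 0.0, -np.inf)
            log_sum = logsumexp(log_terms - gammaln(s + 1))
            terms.append(log_coef + log_w + log_sum)
        else:
            terms.append(log_coef + k_log_tau)
    if not terms:
        return -np.inf
    return float(min(logsumexp(terms), 0.0))


# ---------------------------------------------------------------------------
# LD estimation and the Monte Carlo null ensemble

@dataclass
class LdMatrix:
    snps: list[str]
    R: np.ndarray
    repaired: bool = False
    monomorphic: list[str] = field(default_factory=list)


def nearest_psd(R: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipped projection to the PSD cone, rescaled to unit
    diagonal.  Returns (matrix, whether clipping was needed)."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= -tol:
        return R, False
    clipped = (vecs * np.maximum(vals, 0.0)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    d[d == 0] = 1.0
    out = clipped / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out, True


def estimate_ld_correlation(
    geno: GenotypeMatrix,
    snps: list[str] | None = None,
    founder_ids: list[str] | None = None,
    chrom_by_snp: dict[str, int] | None = None,
    min_founders: int = 30,
) -> LdMatrix:
    """Pairwise correlation of additive genotype codes over founders.

    Missing genotypes are handled pairwise-complete.  Monomorphic SNPs get
    an identity row/column (with a warning).  When chromosome assignments
    are supplied, cross-chromosome entries are zeroed by construction.  The
    result is repaired to the nearest PSD correlation matrix (eigenvalue
    clipping) when sampling noise pushes it outside the cone.
    """
    snps = list(snps) if snps is not None else geno.snps
    sub = geno.values[snps]
    if founder_ids is not None:
        sub = sub.loc[founder_ids]
    if len(sub) < min_founders:
        raise ValueError(f"need >= {min_founders} founders to estimate LD, got {len(sub)}")
    R = sub.corr(min_periods=2).values
    mono = [s for s, sd in zip(snps, sub.std(ddof=0)) if not sd > 0]
    for s in mono:
        j = snps.index(s)
        R[j, :] = 0.0
        R[:, j] = 0.0
        R[j, j] = 1.0
        logger.warning("SNP %s monomorphic among founders; LD row set to identity", s)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    if chrom_by_snp is not None:
        chroms = np.array([chrom_by_snp[s] for s in snps])
        cross = chroms[:, None] != chroms[None, :]
        R[cross] = 0.0
    R = (R + R.T) / 2.0
    R, repaired = nearest_psd(R)
    return LdMatrix(snps=snps, R=R, repaired=repaired, monomorphic=mono)


@dataclass
class NullEnsemble:
    """B x L matrix of null p-values shared by both combination stages."""

    pvals: np.ndarray
    snps: list[str]
    seed: int
    null_mode: str

    @property
    def B(self) -> int:
        return self.pvals.shape[0]

    def columns(self, snps: list[str]) -> np.ndarray:
        idx = [self.snps.index(s) for s in snps]
        return self.pvals[:, idx]


def mc_null_ensemble(R: LdMatrix | np.ndarray | None, cfg: CombineConfig,
                     snps: list[str] | None = None) -> NullEnsemble:
    """Simulate the null p-value ensemble.

    Each draw b: Z_b ~ MVN(0, R); p_bi = 2(1 - Phi(|Z_bi|)).  In
    ``independent`` mode R is the identity.  Fixed seed => identical
    ensemble.
    """
    if isinstance(R, LdMatrix):
        snps = R.snps if snps is None else snps
        Rm = R.R
    else:
        Rm = R
    if snps is None:
        raise ValueError("SNP ids required when R is a bare matrix")
    L = len(snps)
    rng = np.random.default_rng(cfg.seed)
    if cfg.null_mode == "independent" or Rm is None:
        Z = rng.standard_normal((cfg.B, L))
    else:
        eigmin = np.linalg.eigvalsh(Rm).min()
        if eigmin < -1e-8:
            raise ValueError(f"null correlation matrix not PSD (min eig {eigmin:.3g})")
        chol = np.linalg.cholesky(Rm + 1e-10 * np.eye(L))
        Z = rng.standard_normal((cfg.B, L)) @ chol.T
    P = 2.0 * stats.norm.sf(np.abs(Z))
    np.clip(P, 1e-320, 1.0, out=P)
    return NullEnsemble(pvals=P, snps=list(snps), seed=cfg.seed, null_mode=cfg.null_mode)


# ---------------------------------------------------------------------------
# Gene-level and gene-family-level tests

@dataclass
class GeneResult:
    gene: str
    trait: str
    log_w: float
    p: float
    weights: dict
    snps: list[str]
    weight_mode: str = "uniform"
    snp_variances: dict = field(default_factory=dict)  # V_i, for null weights

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def W(self) -> float:
        return float(np.exp(self.log_w))


@dataclass
class FamilyResult:
    trait: str
    log_w: float
    p: float
    gene_pvalues: dict


def _gene_weights(sub: pd.DataFrame, cfg: CombineConfig) -> np.ndarray:
    if cfg.weight_mode == "uniform":
        return np.ones(len(sub))
    return normalize_weights(np.abs(sub["b"].fillna(0.0).values))


def gene_based_test(
    snp_results: pd.DataFrame,
    gene: str,
    manifest: pd.DataFrame,
    ensemble: NullEnsemble,
    cfg: CombineConfig,
) -> GeneResult:
    """Combine one gene's SNP p-values against the Monte Carlo null.

    ``snp_results`` is the single-trait tidy table (columns snp, p and — for
    effect-size weighting — b and V).  Observed weights come from the
    observed effect sizes; under ``abs_effect`` weighting the null draws get
    their own per-draw weights through the same |Z|/sqrt(V) map (see
    :func:`_null_weight_rows`), since weights estimated from the data are
    correlated with the data's p-values.  The Monte Carlo p-value uses the
    add-one estimator, so it is never smaller than 1/(B+1).
    """
    gene_snps = [
        s for s in manifest.loc[manifest["gene"] == gene, "snp"]
        if s in set(snp_results["snp"])
    ]
    sub = snp_results.set_index("snp").loc[gene_snps].reset_index()
    sub = sub[sub["p"].notna()]
    if sub.empty:
        raise ValueError(f"gene {gene}: no testable SNPs")
    snps = list(sub["snp"])
    missing = [s for s in snps if s not in ensemble.snps]
    if missing:
        raise ValueError(f"gene {gene}: SNPs absent from null ensemble: {missing}")
    w = _gene_weights(sub, cfg)
    floor = 1.0 / (ensemble.B + 1)
    log_w_obs = tpm_log_statistic(sub["p"].values, w, cfg.tau, floor=floor)
    if log_w_obs == 0.0:
        logger.info("gene %s (%s): no p-value at or below tau; p = 1", gene,
                    snp_results["trait"].iloc[0] if "trait" in snp_results else "?")
    P_null = ensemble.columns(snps)
    variances = {}
    if cfg.weight_mode == "abs_effect":
        if "V" not in sub.columns:
            raise ValueError("abs_effect weighting needs the V column of SNP results")
        V = sub["V"].values.astype(float)
        variances = dict(zip(snps, V))
        w_null = _null_weight_rows(P_null, V)
    else:
        w_null = w
    null_log_w = _tpm_log_statistic_rows(P_null, w_null, cfg.tau)
    count = int(np.sum(null_log_w <= log_w_obs))
    p = (1 + count) / (ensemble.B + 1)
    trait = snp_results["trait"].iloc[0] if "trait" in snp_results.columns else ""
    return GeneResult(
        gene=gene, trait=trait, log_w=log_w_obs, p=p,
        weights=dict(zip(snps, w)), snps=snps,
        weight_mode=cfg.weight_mode, snp_variances=variances,
    )


def _gene_null_pvalues(
    gene_results: list[GeneResult], ensemble: NullEnsemble, cfg: CombineConfig
) -> np.ndarray:
    """(B, n_genes) matrix of null gene-level p-values obtained by ranking
    each draw's gene statistic within the ensemble (per-draw weights under
    effect-size weighting, matching the gene stage)."""
    cols = []
    for gr in gene_results:
        P_null = ensemble.columns(gr.snps)
        if gr.weight_mode == "abs_effect":
            V = np.array([gr.snp_variances[s] for s in gr.snps])
            w = _null_weight_rows(P_null, V)
        else:
            w = np.array([gr.weights[s] for s in gr.snps])
        null_log_w = _tpm_log_statistic_rows(P_null, w, cfg.tau)
        ranks = stats.rankdata(null_log_w, method="max")
        cols.append(ranks / ensemble.B)
    return np.column_stack(cols)


def gene_family_test(
    gene_results: list[GeneResult],
    ensemble: NullEnsemble,
    manifest: pd.DataFrame,
    cfg: CombineConfig,
) -> FamilyResult:
    """Second-stage combination of gene-level p-values (uniform weights).

    The null is derived from the SAME SNP-level ensemble: for each draw,
    every gene's statistic is converted to a null gene p-value by its rank
    among all B null statistics for that gene, and the TPM is applied
    across genes draw by draw.
    """
    if len(gene_results) < 2:
        raise ValueError("gene-family test needs >= 2 genes")
    obs_p = np.array([gr.p for gr in gene_results])
    log_w_obs = tpm_log_statistic(obs_p, None, cfg.tau)
    null_gene_p = _gene_null_pvalues(gene_results, ensemble, cfg)
    null_log_w = _tpm_log_statistic_rows(null_gene_p, np.ones(len(gene_results)), cfg.tau)
    count = int(np.sum(null_log_w <= log_w_obs))
    p = (1 + count) / (ensemble.B + 1)
    return FamilyResult(
        trait=gene_results[0].trait,
        log_w=log_w_obs,
        p=p,
        gene_pvalues={gr.gene: gr.p for gr in gene_results},
    )


def combine_trait(
    snp_results: pd.DataFrame,
    manifest: pd.DataFrame,
    ensemble: NullEnsemble,
    cfg: CombineConfig,
) -> tuple[list[GeneResult], FamilyResult]:
    """Run the gene stage for every gene in the manifest, then the
    gene-family stage, for one trait's SNP results."""
    gene_results = []
    for gene in manifest["gene"].unique():
        try:
            gene_results.append(
                gene_based_test(snp_results, gene, manifest, ensemble, cfg)
            )
        except ValueError as exc:
            logger.warning("skipping gene %s: %s", gene, exc)
    fam = gene_family_test(gene_results, ensemble, manifest, cfg)
    return gene_results, fam


def leave_one_snp_out(
    snp_results: pd.DataFrame,
    manifest: pd.DataFrame,
    ensemble: NullEnsemble,
    cfg: CombineConfig,
    snp_to_drop: str,
) -> tuple[list[GeneResult], FamilyResult]:
    """Recompute gene and gene-family results with one SNP removed.

    A gene reduced to zero SNPs is omitted with a warning (the family stage
    then combines the remaining genes).
    """
    if snp_to_drop not in set(manifest["snp"]):
        raise ValueError(f"SNP {snp_to_drop} not in manifest")
    reduced = manifest[manifest["snp"] != snp_to_drop]
    results = snp_results[snp_results["snp"] != snp_to_drop]
    return combine_trait(results, reduced, ensemble, cfg)
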