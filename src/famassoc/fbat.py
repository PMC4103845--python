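"""Single-SNP family-based association tests for quantitative traits.

The statistic is the classic family-based score test: within each nuclear
family, offspring genotypes are compared with their Mendelian expectation
given the parental genotypes, weighted by the offspring's covariate-adjusted
trait residual.  Writing ``X_j`` for the additive minor-allele count of
offspring ``j`` and ``T_j`` for the residual,

    U = sum_families sum_j T_j * (X_j - E[X_j | parents])
    V = sum_families sum_j T_j^2 * Var(X_j | parents)
    Z = U / sqrt(V),   p = 2 * (1 - Phi(|Z|))

Transmissions are conditioned on parental genotypes, which makes the test
robust to population stratification; offspring within a family are treated
as independent given the parents (the same first-order treatment the FBAT
program applies).  Families with a missing parental genotype are skipped
rather than reconstructed.  Under additive coding the conditional moments
are ``E[X|f,m] = f/2 + m/2`` and
``Var(X|f,m) = (f/2)(1-f/2) + (m/2)(1-m/2)``.

An effect-size proxy ``b = U / V`` is exported per SNP for use as a weight
in downstream p-value combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genio import GenotypeMatrix, NuclearFamily, Pedigree

DEFAULT_MIN_INFORMATIVE = 10


# ---------------------------------------------------------------------------
# Covariate adjustment

@dataclass
class TraitResiduals:
    """Covariate-adjusted (optionally log-transformed) trait residuals."""

    trait: str
    residuals: pd.Series  # iid -> T
    offset: float  # fitted mean subtracted
    log_transformed: bool


def _design_matrix(pheno: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cols = []
    for cov in covariates:
        x = pheno[cov]
        if x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(x, prefix=cov, drop_first=True, dtype=float)
            cols.append(d)
        else:
            cols.append(x.astype(float).rename(cov))
    X = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=pheno.index)
    return sm.add_constant(X, has_constant="add")


def adjust_covariates(
    pheno: pd.DataFrame,
    trait: str,
    covariates: list[str],
    log_transform: bool = True,
) -> TraitResiduals:
    """OLS residuals of (log-)trait on the covariate design.

    Categorical covariates are expanded to indicator columns.  Rows with a
    missing trait or covariate are dropped from the regression sample;
    residuals over that sample have mean zero.  A rank-deficient design is
    rejected, naming the collinear columns.
    """
    cols = [trait] + covariates
    sub = pheno[cols].dropna()
    y = sub[trait].astype(float)
    if log_transform:
        if (y <= 0).any():
            raise ValueError(f"trait {trait!r} must be strictly positive to log-transform")
        y = np.log(y)
    X = _design_matrix(sub, covariates)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.values[:, 1:], rowvar=False) if X.shape[1] > 2 else None
        suspects = []
        if corr is not None:
            names = list(X.columns[1:])
            ii, jj = np.where(np.triu(np.abs(corr) > 1 - 1e-10, k=1))
            suspects = [f"{names[i]}~{names[j]}" for i, j in zip(ii, jj)]
        raise ValueError(
            f"rank-deficient covariate design for {trait!r}"
            + (f": collinear {suspects}" if suspects else "")
        )
    fit = sm.OLS(y, X).fit()
    return TraitResiduals(
        trait=trait,
        residuals=pd.Series(fit.resid, index=sub.index),
        offset=float(y.mean()),
        log_transformed=log_transform,
    )


# ---------------------------------------------------------------------------
# Mendelian conditional distribution

def offspring_genotype_distribution(father: float, mother: float) -> np.ndarray:
    """Exact conditional distribution of the offspring's minor-allele count
    given both parental genotypes (additive 0/1/2 coding)."""
    if np.isnan(father) or np.isnan(mother):
        raise ValueError("offspring distribution requires both parental genotypes")
    if father not in (0.0, 1.0, 2.0) or mother not in (0.0, 1.0, 2.0):
        raise ValueError(f"invalid parental genotypes ({father}, {mother})")
    pf, pm = father / 2.0, mother / 2.0
    return np.array(
        [
            (1 - pf) * (1 - pm),
            pf * (1 - pm) + (1 - pf) * pm,
            pf * pm,
        ]
    )


# ---------------------------------------------------------------------------
# Family contributions and the test

def family_contribution(
    family: NuclearFamily,
    geno: GenotypeMatrix,
    resid: TraitResiduals,
    snp: str,
) -> tuple[float, float]:
    """(U_i, V_i) for one nuclear family at one SNP.

    Requires both parents genotyped; offspring enter if genotyped and
    phenotyped.  A family that cannot segregate (conditional variance zero)
    or has no usable offspring contributes (0, 0).
    """
    vals = geno.values[snp]
    for parent in (family.father, family.mother):
        if parent not in vals.index or np.isnan(vals[parent]):
            raise ValueError(f"family {family.family_id}: parent {parent} not genotyped")
    gf, gm = vals[family.father], vals[family.mother]
    e = gf / 2.0 + gm / 2.0
    var = (gf / 2.0) * (1 - gf / 2.0) + (gm / 2.0) * (1 - gm / 2.0)
    U = V = 0.0
    for child in family.offspring:
        if child not in vals.index or np.isnan(vals[child]):
            continue
        if child not in resid.residuals.index:
            continue
        T = resid.residuals[child]
        U += T * (vals[child] - e)
        V += T * T * var
    return U, V


@dataclass
class SnpResult:
    snp: str
    trait: str
    U: float
    V: float
    Z: float
    p: float
    b: float  # effect-size proxy U/V
    n_informative: int
    reason: str | None = None  # set when p is not computable


def fbat_test(
    families: list[NuclearFamily],
    geno: GenotypeMatrix,
    resid: TraitResiduals,
    snp: str,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> SnpResult:
    """Sum family contributions at one SNP and form Z = U/sqrt(V).

    Families with an ungenotyped parent are skipped; a family is counted
    informative when its variance contribution is positive.  With fewer
    than ``min_informative`` informative families, or V = 0, the p-value is
    reported missing with a reason.
    """
    U = V = 0.0
    n_inf = 0
    for fam in families:
        try:
            u_i, v_i = family_contribution(fam, geno, resid, snp)
        except ValueError:
            continue
        U += u_i
        V += v_i
        if v_i > 0:
            n_inf += 1
    if V <= 0 or n_inf < min_informative:
        return SnpResult(
            snp, resid.trait, U, V, np.nan, np.nan, np.nan, n_inf,
            reason="uninformative" if V <= 0 else "too few informative families",
        )
    Z = U / np.sqrt(V)
    p = 2.0 * stats.norm.sf(abs(Z))
    return SnpResult(snp, resid.trait, U, V, Z, p, U / V, n_inf)


# ---------------------------------------------------------------------------
# Vectorized engine over all SNPs (used by the pipeline and simulations)

class FamilyIndex:
    """Precomputed row positions of parents and offspring for fast
    evaluation of the statistic across all SNPs at once."""

    def __init__(self, ped: Pedigree, geno_ids: list[str]):
        pos = {x: i for i, x in enumerate(geno_ids)}
        fa, mo, ch, unit = [], [], [], []
        units = [f for f in ped.nuclear_families()]
        self.units = units
        for u, fam in enumerate(units):
            if fam.father not in pos or fam.mother not in pos:
                continue
            for child in fam.offspring:
                if child not in pos:
                    continue
                fa.append(pos[fam.father])
                mo.append(pos[fam.mother])
                ch.append(pos[child])
                unit.append(u)
        self.father_pos = np.asarray(fa, dtype=int)
        self.mother_pos = np.asarray(mo, dtype=int)
        self.child_pos = np.asarray(ch, dtype=int)
        self.unit_id = np.asarray(unit, dtype=int)
        self.n_units = len(units)


def fbat_all_snps(
    G: np.ndarray,
    resid_vec: np.ndarray,
    index: FamilyIndex,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> dict[str, np.ndarray]:
    """Score test at every SNP simultaneously.

    ``G`` is the (n_individuals, n_snps) additive genotype array (NaN =
    missing) in the same row order used to build ``index``; ``resid_vec``
    holds trait residuals (NaN for unphenotyped individuals).  Returns
    arrays U, V, Z, p, b, n_informative of length n_snps.
    """
    Gf = G[index.father_pos]
    Gm = G[index.mother_pos]
    Gc = G[index.child_pos]
    T = resid_vec[index.child_pos][:, None]
    valid = ~np.isnan(Gf) & ~np.isnan(Gm) & ~np.isnan(Gc) & ~np.isnan(T)
    e = np.where(valid, Gf / 2.0 + Gm / 2.0, 0.0)
    var = np.where(
        valid, (Gf / 2.0) * (1 - Gf / 2.0) + (Gm / 2.0) * (1 - Gm / 2.0), 0.0
    )
    Tm = np.where(valid, T, 0.0)
    u_off = Tm * np.where(valid, np.nan_to_num(Gc) - e, 0.0)
    v_off = Tm * Tm * var

    n_snps = G.shape[1]
    Vu = np.zeros((index.n_units, n_snps))
    np.add.at(Vu, index.unit_id, v_off)
    U = u_off.sum(axis=0)
    V = v_off.sum(axis=0)
    n_inf = (Vu > 0).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(V > 0, U / np.sqrt(np.where(V > 0, V, 1.0)), np.nan)
        b = np.where(V > 0, U / np.where(V > 0, V, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(Z))
    bad = (V <= 0) | (n_inf < min_informative)
    Z = np.where(bad, np.nan, Z)
    p = np.where(bad, np.nan, p)
    b = np.where(bad, np.nan, b)
    return {"U": U, "V": V, "Z": Z, "p": p, "b": b, "n_informative": n_inf}


def run_snp_tests(
    ped: Pedigree,
    geno: GenotypeMatrix,
    residuals: dict[str, TraitResiduals],
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> pd.DataFrame:
    """All SNPs x all traits: tidy results table with one row per pair.

    Columns: snp, trait, U, V, Z, p, b, n_informative.
    """
    index = FamilyIndex(ped, geno.ids)
    G = geno.values.values.astype(float)
    id_index = geno.values.index
    frames = []
    for trait, resid in residuals.items():
        rv = resid.residuals.reindex(id_index).values.astype(float)
        res = fbat_all_snps(G, rv, index, min_informative)
        frames.append(
            pd.DataFrame(
                {
                    "snp": geno.snps,
                    "trait": trait,
                    "U": res["U"],
                    "V": res["V"],
                    "Z": res["Z"],
                    "p": res["p"],
                    "b": res["b"],
                    "n_informative": res["n_informative"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def snp_pvalue_table(results: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy results into a per-SNP table with one p column per trait,
    annotated with the gene label (the shape of a published summary table)."""
    wide = results.pivot(index="snp", columns="trait", values="p")
    wide = wide.reindex(manifest["snp"])
    out = manifest.merge(wide, left_on="snp", right_index=True, how="left")
    return out
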