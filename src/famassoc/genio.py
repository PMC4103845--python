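"""Reading, writing and screening of pedigree, genotype and phenotype data.

Formats are deliberately plain: PLINK-style text PED/MAP for genotypes with
pedigree structure, tab-separated tables for phenotypes/covariates and the
gene manifest.  Genotypes are held in additive coding — the count of minor
alleles, 0/1/2, with the minor allele determined from founders only so that
offspring transmissions (the random quantity the association test conditions
on) cannot influence the coding.

Mendelian inconsistencies found on read are soft errors: the offending child
genotype is set missing and counted, the file is not rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("famassoc")

FOUNDER = "0"  # sentinel parent id
MISSING_ALLELE = "0"

SMOKING_LEVELS = ("current", "former", "never")
ALCOHOL_LEVELS = ("current", "former", "never")

#: covariates used in the published single-SNP analysis
DEFAULT_COVARIATES = (
    "age",
    "sex",
    "center",
    "smoking",
    "alcohol",
    "activity",
    "energy",
    "ses",
    "diabetes",
)


# ---------------------------------------------------------------------------
# Pedigree

@dataclass(frozen=True)
class NuclearFamily:
    """One father-mother pair and their common offspring."""

    family_id: str
    father: str
    mother: str
    offspring: tuple[str, ...]


class Pedigree:
    """Family structure: members with parent pointers, decomposed into
    nuclear families.

    Parameters
    ----------
    members : DataFrame with columns fid, iid, pat, mat, sex.  ``pat``/``mat``
        equal to ``"0"`` mark a founder.  Individual ids must be globally
        unique (the simulator guarantees this; PED files that reuse ids
        across families are rejected).
    """

    def __init__(self, members: pd.DataFrame):
        required = ["fid", "iid", "pat", "mat", "sex"]
        missing = [c for c in required if c not in members.columns]
        if missing:
            raise ValueError(f"pedigree table lacks columns: {missing}")
        members = members[required].astype(
            {"fid": str, "iid": str, "pat": str, "mat": str}
        )
        if members["iid"].duplicated().any():
            dup = members.loc[members["iid"].duplicated(), "iid"].iloc[0]
            raise ValueError(f"duplicate individual id: {dup!r}")
        self.members = members.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        by_fam = self.members.groupby("fid")
        parent_of = {}
        for _, row in self.members.iterrows():
            parent_of[row.iid] = (row.pat, row.mat)
        ids_by_fam = {fid: set(g["iid"]) for fid, g in by_fam}
        for _, row in self.members.iterrows():
            for p in (row.pat, row.mat):
                if p != FOUNDER and p not in ids_by_fam[row.fid]:
                    raise ValueError(
                        f"individual {row.iid}: parent {p} absent from family {row.fid}"
                    )
            n_known = (row.pat != FOUNDER) + (row.mat != FOUNDER)
            if n_known == 1:
                raise ValueError(
                    f"individual {row.iid} has exactly one known parent; "
                    "complete nuclear families are required"
                )
        # no individual may be its own ancestor
        for iid in parent_of:
            seen = set()
            stack = [iid]
            while stack:
                cur = stack.pop()
                for p in parent_of.get(cur, (FOUNDER, FOUNDER)):
                    if p == FOUNDER:
                        continue
                    if p == iid:
                        raise ValueError(f"individual {iid} is its own ancestor")
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)

    @property
    def ids(self) -> list[str]:
        return list(self.members["iid"])

    def is_founder(self) -> pd.Series:
        m = self.members
        return (m["pat"] == FOUNDER) & (m["mat"] == FOUNDER)

    @property
    def founder_ids(self) -> list[str]:
        return list(self.members.loc[self.is_founder().values, "iid"])

    def nuclear_families(self) -> list[NuclearFamily]:
        """Decompose into father-mother-offspring units.

        Every parent-offspring triple appears in exactly one unit; an
        individual may appear as offspring in one unit and as parent in
        another (three-generation chains).
        """
        units: list[NuclearFamily] = []
        nonf = self.members[~self.is_founder().values]
        for (fid, pat, mat), grp in nonf.groupby(["fid", "pat", "mat"], sort=True):
            units.append(
                NuclearFamily(
                    family_id=fid,
                    father=pat,
                    mother=mat,
                    offspring=tuple(grp["iid"]),
                )
            )
        return units

    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self.members.equals(other.members)


# ---------------------------------------------------------------------------
# Genotypes

@dataclass
class SnpMeta:
    snp: str
    chrom: int
    pos: int
    minor: str
    major: str


class GenotypeMatrix:
    """Additive minor-allele-count genotypes, individuals x SNPs.

    ``values`` is a float DataFrame indexed by individual id with SNP-id
    columns; entries are 0/1/2 or NaN for missing.  Allele labels per SNP are
    kept so PED round-trips are lossless up to allele ordering.
    """

    def __init__(self, values: pd.DataFrame, meta: list[SnpMeta]):
        if list(values.columns) != [m.snp for m in meta]:
            raise ValueError("genotype columns do not match SNP metadata order")
        bad = ~(values.isin([0.0, 1.0, 2.0]) | values.isna())
        if bad.any().any():
            raise ValueError("genotype values must be 0/1/2 or missing")
        self.values = values.astype(float)
        self.meta = meta

    @property
    def snps(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    def maf(self, founder_ids=None) -> pd.Series:
        sub = self.values if founder_ids is None else self.values.loc[founder_ids]
        return sub.mean(axis=0, skipna=True) / 2.0

    def swap_coding(self, snp: str) -> "GenotypeMatrix":
        """Return a copy with minor/major labels (and counts) flipped at one SNP."""
        vals = self.values.copy()
        vals[snp] = 2.0 - vals[snp]
        meta = [
            SnpMeta(m.snp, m.chrom, m.pos, m.major, m.minor) if m.snp == snp else m
            for m in self.meta
        ]
        return GenotypeMatrix(vals, meta)


def _transmissible(g: float) -> set[int]:
    return {0.0: {0}, 1.0: {0, 1}, 2.0: {1}}[g]


def mendelian_errors(ped: Pedigree, geno: GenotypeMatrix) -> list[tuple[str, str]]:
    """(individual, snp) pairs where the child genotype is impossible given
    both typed parents."""
    errors = []
    vals = geno.values
    for fam in ped.nuclear_families():
        if fam.father not in vals.index or fam.mother not in vals.index:
            continue
        gf = vals.loc[fam.father]
        gm = vals.loc[fam.mother]
        for child in fam.offspring:
            if child not in vals.index:
                continue
            gc = vals.loc[child]
            for snp in geno.snps:
                f, m, c = gf[snp], gm[snp], gc[snp]
                if np.isnan(f) or np.isnan(m) or np.isnan(c):
                    continue
                possible = {a + b for a in _transmissible(f) for b in _transmissible(m)}
                if c not in possible:
                    errors.append((child, snp))
    return errors


# ---------------------------------------------------------------------------
# PED/MAP

def write_pedmap(
    ped: Pedigree,
    geno: GenotypeMatrix,
    ped_path,
    map_path,
    phenotype: pd.Series | None = None,
) -> None:
    """Write PLINK text PED/MAP.

    PED columns: FID IID PAT MAT SEX PHENO then two allele columns per SNP
    (missing = ``0 0``).  MAP columns: chrom, snp id, genetic distance 0,
    1-based bp position.
    """
    with open(map_path, "w") as fh:
        for m in geno.meta:
            fh.write(f"{m.chrom}\t{m.snp}\t0\t{m.pos}\n")
    vals = geno.values
    with open(ped_path, "w") as fh:
        for _, row in ped.members.iterrows():
            pheno = "-9"
            if phenotype is not None and row.iid in phenotype.index:
                pheno = f"{phenotype[row.iid]:g}"
            fields = [row.fid, row.iid, row.pat, row.mat, str(row.sex), pheno]
            if row.iid in vals.index:
                g = vals.loc[row.iid]
            else:
                g = pd.Series(np.nan, index=vals.columns)
            for m in geno.meta:
                x = g[m.snp]
                if np.isnan(x):
                    fields += [MISSING_ALLELE, MISSING_ALLELE]
                else:
                    n_minor = int(x)
                    fields += [m.minor] * n_minor + [m.major] * (2 - n_minor)
            fh.write("\t".join(fields) + "\n")


def read_pedmap(ped_path, map_path) -> tuple[Pedigree, GenotypeMatrix, list[SnpMeta]]:
    """Read PLINK text PED/MAP, recode to minor-allele counts and screen for
    Mendelian errors.

    The minor allele is the one with the lower allele frequency among
    founders (ties broken lexicographically).  Child genotypes impossible
    given both typed parents are set missing; each is logged and counted.
    """
    snps: list[tuple[int, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{map_path}: malformed line {lineno}")
            snps.append((int(parts[0]), parts[1], int(parts[3])))

    n_cols = 6 + 2 * len(snps)
    rows = []
    alleles = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != n_cols:
                raise ValueError(
                    f"{ped_path}: malformed line {lineno}: expected {n_cols} "
                    f"fields, got {len(parts)}"
                )
            rows.append(parts[:6])
            alleles.append(parts[6:])

    members = pd.DataFrame(rows, columns=["fid", "iid", "pat", "mat", "sex", "pheno"])
    members["sex"] = members["sex"].astype(int)
    pedigree = Pedigree(members[["fid", "iid", "pat", "mat", "sex"]])

    allele_arr = np.array(alleles, dtype=object).reshape(len(rows), len(snps), 2)
    founder_mask = pedigree.is_founder().values

    meta: list[SnpMeta] = []
    codes = np.full((len(rows), len(snps)), np.nan)
    for j, (chrom, snp, pos) in enumerate(snps):
        col = allele_arr[:, j, :]
        observed = col[col != MISSING_ALLELE]
        labels = sorted(set(observed))
        if len(labels) > 2:
            raise ValueError(f"SNP {snp}: more than two alleles: {labels}")
        if len(labels) == 0:
            labels = ["A", "B"]
        if len(labels) == 1:
            labels = labels + [labels[0] + "'"]
        f_col = col[founder_mask]
        f_obs = f_col[f_col != MISSING_ALLELE]
        freq0 = np.mean(f_obs == labels[0]) if len(f_obs) else 0.5
        # lower founder frequency -> minor; exact tie -> lexicographic
        if freq0 < 0.5 or (freq0 == 0.5 and labels[0] < labels[1]):
            minor, major = labels[0], labels[1]
        else:
            minor, major = labels[1], labels[0]
        meta.append(SnpMeta(snp, chrom, pos, minor, major))
        known = (col != MISSING_ALLELE).all(axis=1)
        codes[known, j] = (col[known] == minor).sum(axis=1)

    values = pd.DataFrame(codes, index=members["iid"].values, columns=[s[1] for s in snps])
    geno = GenotypeMatrix(values, meta)

    errors = mendelian_errors(pedigree, geno)
    for iid, snp in errors:
        logger.warning("Mendelian error: individual %s at %s set to missing", iid, snp)
        geno.values.loc[iid, snp] = np.nan
    if errors:
        logger.warning("%d Mendelian error(s) set to missing", len(errors))
    geno.n_mendelian_errors = len(errors)
    return pedigree, geno, meta


# ---------------------------------------------------------------------------
# Phenotypes and manifest

def derive_indices(pheno: pd.DataFrame) -> pd.DataFrame:
    """Add BMI (weight kg / height m^2) and WHR (waist/hip) columns derived
    from the raw anthropometric fields."""
    out = pheno.copy()
    out["BMI"] = out["weight"] / out["height"] ** 2
    out["WHR"] = out["waist"] / out["hip"]
    return out


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"iid": str})
    return df.set_index("iid")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=True, index_label="iid")


def read_manifest(path) -> pd.DataFrame:
    """Gene manifest: two-column TSV (snp id, gene label)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["snp", "gene"], comment="#")
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise ValueError(f"SNP {dup} assigned to more than one gene")
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[["snp", "gene"]].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class ExclusionLog:
    n_initial: int
    n_final: int
    counts: dict = field(default_factory=dict)

    def render(self) -> str:
        lines = [f"initial rows: {self.n_initial}"]
        for reason, n in self.counts.items():
            lines.append(f"excluded ({reason}): {n}")
        lines.append(f"final rows: {self.n_final}")
        return "\n".join(lines)


def apply_exclusions(
    pheno: pd.DataFrame, required_fields: list[str]
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop rows missing smoking status or any required covariate.

    Smoking-status missingness is counted separately from other covariates,
    mirroring how the study reported its sample accounting.  Returns the
    retained table and a log with counts per reason.
    """
    missing_cols = [c for c in required_fields if c not in pheno.columns]
    if missing_cols:
        raise ValueError(f"required fields absent from phenotype table: {missing_cols}")
    log = ExclusionLog(n_initial=len(pheno), n_final=len(pheno))
    kept = pheno
    if "smoking" in required_fields:
        miss_smoke = kept["smoking"].isna()
        log.counts["missing smoking status"] = int(miss_smoke.sum())
        kept = kept[~miss_smoke]
    others = [c for c in required_fields if c != "smoking"]
    if others:
        miss_cov = kept[others].isna().any(axis=1)
        log.counts["missing covariate"] = int(miss_cov.sum())
        kept = kept[~miss_cov]
    log.n_final = len(kept)
    if log.n_final == 0:
        logger.warning("exclusion filter removed every row")
    return kept, log
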