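"""Published reference inputs for the nAChR gene-family analysis.

The study genotyped 61 tagSNPs in seven nicotinic acetylcholine receptor
(nAChR) subunit genes in a family-based cohort and reported per-SNP
family-based association p-values for four obesity traits (BMI, waist
circumference, waist-to-hip ratio, percent body fat), plus gene-level
p-values obtained by the weighted truncated product method.  Individual-level
data are restricted, but the printed SNP manifest and p-value tables are
public and serve here as inputs: the manifest anchors the synthetic-data
fixture and the gene-level p-values exercise the combination stage directly.

Chromosome assignments follow the genes' genomic locations: CHRNB2 on 1,
CHRNA6/CHRNB3 adjacent on 8, the CHRNA5-CHRNA3-CHRNB4 cluster on 15, and
CHRNA4 on 20.
"""

from __future__ import annotations

import pandas as pd

TRAITS = ("BMI", "WC", "WHR", "PBF")

GENE_CHROMOSOMES = {
    "CHRNB2": 1,
    "CHRNA6": 8,
    "CHRNB3": 8,
    "CHRNA3": 15,
    "CHRNA5": 15,
    "CHRNB4": 15,
    "CHRNA4": 20,
}

# (snp, gene, p_BMI, p_WC, p_WHR, p_PBF) — single-SNP family-based
# association p-values, covariate-adjusted, as published.
SNP_PVALUE_ROWS = [
    ("rs1051730", "CHRNA3", 0.1877, 0.0412, 0.0365, 0.8535),
    ("rs11637630", "CHRNA3", 0.2825, 0.2414, 0.3157, 0.5119),
    ("rs12910984", "CHRNA3", 0.2631, 0.1942, 0.2390, 0.5500),
    ("rs12914385", "CHRNA3", 0.0980, 0.0218, 0.0178, 0.1244),
    ("rs1317286", "CHRNA3", 0.0915, 0.0167, 0.0117, 0.5951),
    ("rs1878399", "CHRNA3", 0.4281, 0.8369, 0.6572, 0.3977),
    ("rs3743074", "CHRNA3", 0.3945, 0.3921, 0.2356, 0.1417),
    ("rs3743078", "CHRNA3", 0.3160, 0.2671, 0.3977, 0.6535),
    ("rs578776", "CHRNA3", 0.3284, 0.2962, 0.5690, 0.1495),
    ("rs6495308", "CHRNA3", 0.3171, 0.2105, 0.1912, 0.5500),
    ("rs660652", "CHRNA3", 0.6294, 0.6067, 0.3738, 0.2455),
    ("rs7177514", "CHRNA3", 0.2710, 0.1923, 0.2423, 0.5869),
    ("rs2236196", "CHRNA4", 0.2525, 0.1869, 0.1944, 0.6613),
    ("rs2273504", "CHRNA4", 0.1865, 0.2433, 0.5767, 0.1302),
    ("rs3787116", "CHRNA4", 0.1821, 0.2634, 0.2975, 0.1245),
    ("rs3787137", "CHRNA4", 0.4825, 0.4961, 0.1098, 0.1499),
    ("rs6122429", "CHRNA4", 0.1202, 0.2037, 0.8469, 0.2186),
    ("rs11633585", "CHRNA5", 0.3977, 0.4575, 0.5277, 0.9635),
    ("rs11637635", "CHRNA5", 0.6294, 0.5317, 0.3256, 0.2455),
    ("rs16969968", "CHRNA5", 0.1503, 0.0381, 0.0344, 0.7120),
    ("rs17483686", "CHRNA5", 0.0221, 0.0257, 0.2607, 0.2522),
    ("rs17486278", "CHRNA5", 0.1903, 0.0605, 0.0660, 0.7120),
    ("rs2036527", "CHRNA5", 0.1006, 0.0228, 0.0161, 0.6179),
    ("rs514743", "CHRNA5", 0.6566, 0.5117, 0.3174, 0.2507),
    ("rs569207", "CHRNA5", 0.3125, 0.2745, 0.3082, 0.7889),
    ("rs588765", "CHRNA5", 0.7221, 0.8917, 0.5775, 0.3476),
    ("rs615470", "CHRNA5", 0.4599, 0.6513, 0.5450, 0.1476),
    ("rs637137", "CHRNA5", 0.3166, 0.2928, 0.3302, 0.8278),
    ("rs680244", "CHRNA5", 0.6953, 0.6374, 0.4410, 0.5823),
    ("rs684513", "CHRNA5", 0.9469, 0.7493, 0.6940, 0.7512),
    ("rs8034191", "CHRNA5", 0.1258, 0.0199, 0.0187, 0.3158),
    ("rs905739", "CHRNA5", 0.3011, 0.1160, 0.3512, 0.4066),
    ("rs951266", "CHRNA5", 0.3051, 0.0853, 0.1057, 0.5417),
    ("rs2304297", "CHRNA6", 0.6362, 0.4043, 0.3585, 0.3681),
    ("rs2072658", "CHRNB2", 0.1954, 0.1876, 0.3787, 0.6123),
    ("rs2072659", "CHRNB2", 0.3214, 0.1891, 0.0823, 0.2303),
    ("rs2072660", "CHRNB2", 0.8459, 0.5275, 0.0926, 0.2502),
    ("rs2072661", "CHRNB2", 0.7452, 0.4177, 0.0584, 0.2765),
    ("rs3811450", "CHRNB2", 0.1970, 0.1414, 0.0260, 0.1095),
    ("rs10958726", "CHRNB3", 0.0594, 0.0225, 0.1464, 0.0168),
    ("rs13277254", "CHRNB3", 0.1179, 0.0535, 0.2173, 0.0491),
    ("rs13280604", "CHRNB3", 0.1150, 0.0479, 0.2607, 0.0513),
    ("rs4950", "CHRNB3", 0.1437, 0.0542, 0.2759, 0.0635),
    ("rs4952", "CHRNB3", 0.0470, 0.1484, 0.5240, 0.1034),
    ("rs4953", "CHRNB3", 0.0470, 0.1484, 0.5240, 0.1034),
    ("rs4954", "CHRNB3", 0.6603, 0.5589, 0.9305, 0.3235),
    ("rs6474413", "CHRNB3", 0.0741, 0.0284, 0.1514, 0.0257),
    ("rs11633223", "CHRNB4", 0.1690, 0.2089, 0.2744, 0.5478),
    ("rs11636605", "CHRNB4", 0.1269, 0.1615, 0.1820, 0.2898),
    ("rs12440014", "CHRNB4", 0.9045, 0.7610, 0.3659, 0.6559),
    ("rs12914008", "CHRNB4", 0.7220, 0.5278, 0.1373, 0.6542),
    ("rs1316971", "CHRNB4", 0.1115, 0.1543, 0.1947, 0.2898),
    ("rs16970006", "CHRNB4", 0.3634, 0.2398, 0.2761, 0.2166),
    ("rs17487223", "CHRNB4", 0.3746, 0.3187, 0.1100, 0.0967),
    ("rs1948", "CHRNB4", 0.3430, 0.7518, 0.4674, 0.5464),
    ("rs1996371", "CHRNB4", 0.0797, 0.0216, 0.0118, 0.3807),
    ("rs3813567", "CHRNB4", 0.1407, 0.0573, 0.0996, 0.5025),
    ("rs3971872", "CHRNB4", 0.1438, 0.3257, 0.2571, 0.7550),
    ("rs7178270", "CHRNB4", 0.4334, 0.3123, 0.1807, 0.5865),
    ("rs8023462", "CHRNB4", 0.4391, 0.8614, 0.2181, 0.4958),
    ("rs950776", "CHRNB4", 0.6998, 0.4449, 0.0702, 0.8830),
]

# Gene-level p-values (weighted truncated product method, 50,000 Monte Carlo
# draws) and the gene-family row, per trait, as published.
GENE_PVALUES = {
    "CHRNA3": {"BMI": 0.1730, "WC": 0.0360, "WHR": 0.0320, "PBF": 0.4870},
    "CHRNA4": {"BMI": 0.2380, "WC": 0.2220, "WHR": 0.2150, "PBF": 0.1460},
    "CHRNA5": {"BMI": 0.3050, "WC": 0.0001, "WHR": 0.0160, "PBF": 0.5870},
    "CHRNA6": {"BMI": 0.6352, "WC": 0.4033, "WHR": 0.3575, "PBF": 0.3671},
    "CHRNB2": {"BMI": 0.3840, "WC": 0.3010, "WHR": 0.0190, "PBF": 0.2110},
    "CHRNB3": {"BMI": 0.0470, "WC": 0.0370, "WHR": 0.1980, "PBF": 0.0300},
    "CHRNB4": {"BMI": 0.1890, "WC": 0.0560, "WHR": 0.0950, "PBF": 0.3310},
}

GENE_FAMILY_PVALUES = {"BMI": 0.1970, "WC": 0.0001, "WHR": 0.0001, "PBF": 0.2910}

# Reported sample accounting: 3,665 enrolled, 15 missing smoking status,
# 10 missing other covariates, 3,640 analyzed.
N_ENROLLED = 3665
N_MISSING_SMOKING = 15
N_MISSING_COVARIATES = 10
N_ANALYZED = 3640


def snp_pvalue_table() -> pd.DataFrame:
    """Per-SNP published p-values as a DataFrame (snp, gene, BMI, WC, WHR, PBF)."""
    return pd.DataFrame(
        SNP_PVALUE_ROWS, columns=["snp", "gene"] + list(TRAITS)
    )


def gene_pvalue_table() -> pd.DataFrame:
    """Gene-level published p-values, one row per gene, one column per trait."""
    df = pd.DataFrame(GENE_PVALUES).T
    df.index.name = "gene"
    return df


def default_manifest() -> pd.DataFrame:
    """The 61-SNP / 7-gene manifest (columns: snp, gene) in published order."""
    return pd.DataFrame(
        [(snp, gene) for snp, gene, *_ in SNP_PVALUE_ROWS], columns=["snp", "gene"]
    )
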