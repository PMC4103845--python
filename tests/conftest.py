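import numpy as np
import pandas as pd
import pytest

import famassoc as fa
from famassoc import fbat, simulate
from famassoc.simulate import LdBlock, SimConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Compact two-gene design used by most unit tests."""
    return SimConfig(
        n_families=30,
        units_per_family=(1, 1),
        offspring_per_family=(2, 4),
        ld_blocks=[
            LdBlock("GENE1", ["s1", "s2", "s3"], r=0.6),
            LdBlock("GENE2", ["s4", "s5"], r=0.6),
        ],
        snp_freqs=np.array([0.2, 0.22, 0.18, 0.3, 0.32]),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return fa.simulate_study(small_cfg)


@pytest.fixture(scope="session")
def small_manifest(small_cfg) -> pd.DataFrame:
    return pd.DataFrame(
        [(s, b.gene) for b in small_cfg.ld_blocks for s in b.snps],
        columns=["snp", "gene"],
    )


@pytest.fixture(scope="session")
def default_study():
    """One replicate of the full 94-family / 61-SNP design (all-null)."""
    return fa.simulate_study(SimConfig(seed=7))


def trio_setup(father_g: float, mother_g: float, child_gs, residuals):
    """Build a one-family Pedigree/GenotypeMatrix/TraitResiduals by hand."""
    rows = [
        ("F1", "dad", "0", "0", 1),
        ("F1", "mom", "0", "0", 2),
    ]
    geno_rows = {"dad": father_g, "mom": mother_g}
    resid = {}
    for k, (g, t) in enumerate(zip(child_gs, residuals), 1):
        cid = f"kid{k}"
        rows.append(("F1", cid, "dad", "mom", 1))
        geno_rows[cid] = g
        resid[cid] = t
    ped = fa.Pedigree(pd.DataFrame(rows, columns=["fid", "iid", "pat", "mat", "sex"]))
    values = pd.DataFrame({"s1": geno_rows}).astype(float)
    geno = fa.GenotypeMatrix(values, [fa.genio.SnpMeta("s1", 1, 100, "A", "G")])
    tr = fbat.TraitResiduals("T", pd.Series(resid, dtype=float), 0.0, False)
    return ped, geno, tr
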