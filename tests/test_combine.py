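"""Truncated product method: statistic arithmetic, closed-form null,
Monte Carlo ensemble, gene and gene-family stages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import famassoc as fa
from famassoc import combine, fixtures
from famassoc.combine import (
    CombineConfig,
    estimate_ld_correlation,
    gene_based_test,
    gene_family_test,
    leave_one_snp_out,
    mc_null_ensemble,
    nearest_psd,
    tpm_log_statistic,
    tpm_pvalue_closedform,
    tpm_statistic,
)


class TestStatistic:
    def test_published_wc_gene_pvalues_product(self):
        """Uniform-weight TPM of the seven published waist-circumference
        gene-level p-values keeps exactly the three at or below 0.05."""
        pvals = fixtures.gene_pvalue_table()["WC"].values
        W = tpm_statistic(pvals, None, tau=0.05)
        assert W == pytest.approx(0.0360 * 0.0001 * 0.0370, rel=1e-9)
        assert W == pytest.approx(1.332e-7, rel=1e-3)

    def test_empty_product_is_one(self):
        assert tpm_statistic([0.2, 0.9], None, tau=0.05) == 1.0

    def test_weighted_product(self):
        W = tpm_statistic([0.01, 0.04], np.array([2.0, 1.0]), tau=0.05)
        assert W == pytest.approx(0.01**2 * 0.04, rel=1e-9)

    def test_zero_pvalue_needs_floor(self):
        with pytest.raises(ValueError, match="floor"):
            tpm_log_statistic([0.0, 0.2], None, 0.05)
        lw = tpm_log_statistic([0.0, 0.2], None, 0.05, floor=1e-5)
        assert lw == pytest.approx(np.log(1e-5))

    def test_log_domain_no_underflow(self):
        lw = tpm_log_statistic(np.full(61, 1e-300), None, tau=0.05)
        assert np.isfinite(lw)
        assert lw == pytest.approx(61 * np.log(1e-300))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        pvals=st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=10),
        drop=st.integers(0, 9),
    )
    def test_monotone_in_subtau_pvalues(self, pvals, drop):
        """Decreasing a sub-tau p-value cannot increase W; adding a p > tau
        leaves W unchanged."""
        tau = 0.05
        base = tpm_log_statistic(pvals, None, tau)
        smaller = list(pvals)
        i = drop % len(pvals)
        if smaller[i] <= tau:
            smaller[i] = smaller[i] / 2
            assert tpm_log_statistic(smaller, None, tau) <= base
        assert tpm_log_statistic(pvals + [0.5], None, tau) == pytest.approx(base)


class TestClosedForm:
    def test_single_untruncated_p_is_itself(self):
        for W in (0.3, 0.01, 1e-6):
            assert tpm_pvalue_closedform(W, L=1, tau=1.0) == pytest.approx(W, rel=1e-12)

    def test_w_of_one_gives_one(self):
        assert tpm_pvalue_closedform(1.0, L=7, tau=0.05) == 1.0

    def test_invalid_w_rejected(self):
        with pytest.raises(ValueError):
            tpm_pvalue_closedform(0.0, L=3, tau=0.05)
        with pytest.raises(ValueError):
            tpm_pvalue_closedform(1.5, L=3, tau=0.05)

    @pytest.mark.parametrize("L,W", [(2, 1e-4), (7, 1.332e-7), (7, 1e-3), (61, 1e-4)])
    def test_agrees_with_uniform_simulation(self, L, W):
        """Brute-force draw of uniform p-values reproduces the analytic
        distribution within Monte Carlo error."""
        tau = 0.05
        B = 400_000
        rng = np.random.default_rng(L * 1000 + 17)
        P = rng.random((B, L))
        with np.errstate(divide="ignore"):
            logw = np.where(P <= tau, np.log(P), 0.0).sum(axis=1)
        mc = np.mean(logw <= np.log(W))
        cf = tpm_pvalue_closedform(W, L, tau)
        se = np.sqrt(max(cf * (1 - cf), 1e-12) / B)
        assert abs(mc - cf) <= 3 * se + 1e-9


class TestLdEstimation:
    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.binomial(2, 0.3, size=(500, 4)).astype(float),
            index=[f"i{k}" for k in range(500)],
            columns=list("abcd"),
        )
        geno = fa.GenotypeMatrix(
            vals, [fa.genio.SnpMeta(s, 1, i, "A", "G") for i, s in enumerate("abcd")]
        )
        ld = estimate_ld_correlation(geno)
        off = ld.R[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_duplicated_column_correlation_one(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.3, 100).astype(float)
        vals = pd.DataFrame({"a": x, "b": x}, index=[f"i{k}" for k in range(100)])
        geno = fa.GenotypeMatrix(
            vals, [fa.genio.SnpMeta(s, 1, i, "A", "G") for i, s in enumerate("ab")]
        )
        ld = estimate_ld_correlation(geno)
        assert ld.R[0, 1] == pytest.approx(1.0)

    def test_simulator_round_trip_recovers_block_r(self):
        cfg = fa.SimConfig(
            n_families=300,
            units_per_family=(1, 1),
            offspring_per_family=(2, 2),
            ld_blocks=[fa.simulate.LdBlock("G", ["a", "b", "c"], r=0.8)],
            snp_freqs=np.array([0.3, 0.3, 0.3]),
            seed=2,
        )
        ped, geno, _ = fa.simulate_study(cfg)
        ld = estimate_ld_correlation(geno, founder_ids=ped.founder_ids)
        assert ld.R[0, 1] == pytest.approx(0.8, abs=0.1)
        assert ld.R[1, 2] == pytest.approx(0.8, abs=0.1)

    def test_monomorphic_snp_identity_row(self, caplog):
        vals = pd.DataFrame(
            {"a": np.zeros(50), "b": np.tile([0.0, 1.0], 25)},
            index=[f"i{k}" for k in range(50)],
        )
        geno = fa.GenotypeMatrix(
            vals, [fa.genio.SnpMeta(s, 1, i, "A", "G") for i, s in enumerate("ab")]
        )
        with caplog.at_level("WARNING", logger="famassoc"):
            ld = estimate_ld_correlation(geno)
        assert ld.R[0, 1] == 0.0
        assert "monomorphic" in caplog.text

    def test_nearest_psd_repair(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        out, repaired = nearest_psd(R)
        assert repaired
        assert np.linalg.eigvalsh(out).min() >= -1e-10
        assert np.allclose(np.diag(out), 1.0)


class TestNullEnsemble:
    def test_identity_columns_uniform(self):
        cfg = CombineConfig(B=50_000, seed=3, null_mode="independent")
        ens = mc_null_ensemble(None, cfg, snps=["a", "b"])
        for j in range(2):
            stat, p = stats.kstest(ens.pvals[:, j], "uniform")
            assert p > 0.01

    def test_perfect_correlation_degenerate(self):
        cfg = CombineConfig(B=100, seed=4, null_mode="ld_mvn")
        R = np.ones((3, 3))
        ens = mc_null_ensemble(R, cfg, snps=list("abc"))
        # up to the tiny jitter added for Cholesky stability
        assert np.allclose(ens.pvals[:, 0], ens.pvals[:, 1], atol=1e-3)

    def test_fixed_seed_identical(self):
        cfg = CombineConfig(B=500, seed=5, null_mode="independent")
        a = mc_null_ensemble(None, cfg, snps=["a"])
        b = mc_null_ensemble(None, cfg, snps=["a"])
        assert np.array_equal(a.pvals, b.pvals)


def _tidy(snps, ps, bs=None, vs=None):
    return pd.DataFrame(
        {
            "snp": snps,
            "trait": "WC",
            "p": ps,
            "b": bs if bs is not None else np.ones(len(snps)),
            "V": vs if vs is not None else np.ones(len(snps)),
        }
    )


class TestGeneTest:
    def test_extreme_statistic_floor(self):
        manifest = pd.DataFrame({"snp": ["a"], "gene": ["G"]})
        cfg = CombineConfig(B=1000, seed=6, null_mode="independent", weight_mode="uniform")
        ens = mc_null_ensemble(None, cfg, snps=["a"])
        res = gene_based_test(_tidy(["a"], [1e-300]), "G", manifest, ens, cfg)
        assert res.p == pytest.approx(1 / 1001)

    def test_single_snp_gene_reduces_to_snp_p(self):
        manifest = pd.DataFrame({"snp": ["a"], "gene": ["G"]})
        cfg = CombineConfig(B=200_000, seed=7, tau=1.0, null_mode="independent",
                            weight_mode="uniform")
        ens = mc_null_ensemble(None, cfg, snps=["a"])
        for p_obs in (0.03, 0.4, 0.9):
            res = gene_based_test(_tidy(["a"], [p_obs]), "G", manifest, ens, cfg)
            se = np.sqrt(p_obs * (1 - p_obs) / cfg.B)
            assert abs(res.p - p_obs) < 4 * se

    def test_mc_matches_closed_form_grid(self):
        """Independent null, uniform weights: the Monte Carlo estimate of the
        gene p converges to the analytic distribution."""
        L, tau, B = 5, 0.05, 100_000
        snps = [f"s{k}" for k in range(L)]
        manifest = pd.DataFrame({"snp": snps, "gene": "G"})
        cfg = CombineConfig(B=B, seed=8, tau=tau, null_mode="independent",
                            weight_mode="uniform")
        ens = mc_null_ensemble(None, cfg, snps=snps)
        for ps in ([0.01, 0.5, 0.5, 0.5, 0.5], [0.01, 0.02, 0.04, 0.5, 0.9]):
            res = gene_based_test(_tidy(snps, ps), "G", manifest, ens, cfg)
            W = tpm_statistic(ps, None, tau)
            cf = tpm_pvalue_closedform(W, L, tau)
            se = np.sqrt(cf * (1 - cf) / B)
            assert abs(res.p - cf) <= 3 * se + 2 / B

    def test_all_p_above_tau_gives_one(self):
        manifest = pd.DataFrame({"snp": ["a", "b"], "gene": "G"})
        cfg = CombineConfig(B=500, seed=9, null_mode="independent", weight_mode="uniform")
        ens = mc_null_ensemble(None, cfg, snps=["a", "b"])
        res = gene_based_test(_tidy(["a", "b"], [0.3, 0.8]), "G", manifest, ens, cfg)
        assert res.p == 1.0


class TestGeneFamily:
    def _setup(self, ps_by_gene, B=20_000, seed=10, weight_mode="uniform"):
        snps, genes, ps = [], [], []
        for g, gene_ps in ps_by_gene.items():
            for i, p in enumerate(gene_ps):
                snps.append(f"{g}_s{i}")
                genes.append(g)
                ps.append(p)
        manifest = pd.DataFrame({"snp": snps, "gene": genes})
        cfg = CombineConfig(B=B, seed=seed, null_mode="independent",
                            weight_mode=weight_mode)
        ens = mc_null_ensemble(None, cfg, snps=snps)
        tidy = _tidy(snps, ps)
        gene_results = [
            gene_based_test(tidy, g, manifest, ens, cfg) for g in ps_by_gene
        ]
        return gene_results, ens, manifest, cfg

    def test_all_null_genes_give_family_p_one(self):
        gene_results, ens, manifest, cfg = self._setup(
            {"G1": [0.5, 0.6], "G2": [0.7], "G3": [0.9, 0.3]}
        )
        assert all(g.p == 1.0 for g in gene_results)
        fam = gene_family_test(gene_results, ens, manifest, cfg)
        assert fam.p == 1.0

    def test_single_extreme_gene_drives_family(self):
        """One extreme gene among nulls: truncation keeps the null genes out
        of the product, so the family p tracks the analytic distribution of
        a single sub-tau member."""
        gene_results, ens, manifest, cfg = self._setup(
            {"G1": [1e-6, 1e-6], "G2": [0.7, 0.6], "G3": [0.9, 0.3]}
        )
        fam = gene_family_test(gene_results, ens, manifest, cfg)
        top = min(g.p for g in gene_results)
        cf = tpm_pvalue_closedform(top, L=3, tau=cfg.tau)
        se = np.sqrt(cf * (1 - cf) / cfg.B)
        assert fam.p <= cf + 4 * se + 3 / cfg.B
        assert fam.p < 0.01

    def test_needs_two_genes(self):
        gene_results, ens, manifest, cfg = self._setup({"G1": [0.01]})
        with pytest.raises(ValueError, match=">= 2"):
            gene_family_test(gene_results, ens, manifest, cfg)

    def test_stage_two_matches_closed_form(self):
        """With independent single-SNP genes, the family-stage null is the
        TPM of independent uniforms and must agree with the analytic form."""
        ps_by_gene = {f"G{k}": [p] for k, p in enumerate([0.01, 0.3, 0.6, 0.02, 0.9])}
        gene_results, ens, manifest, cfg = self._setup(ps_by_gene, B=100_000)
        fam = gene_family_test(gene_results, ens, manifest, cfg)
        W = tpm_statistic([g.p for g in gene_results], None, cfg.tau)
        cf = tpm_pvalue_closedform(W, L=5, tau=cfg.tau)
        se = np.sqrt(cf * (1 - cf) / cfg.B)
        assert abs(fam.p - cf) <= 4 * se + 2 / cfg.B


class TestLeaveOneOut:
    def _base(self):
        snps = ["a", "b", "c", "d"]
        manifest = pd.DataFrame({"snp": snps, "gene": ["G1", "G1", "G2", "G2"]})
        cfg = CombineConfig(B=5000, seed=11, null_mode="independent",
                            weight_mode="uniform")
        ens = mc_null_ensemble(None, cfg, snps=snps)
        tidy = _tidy(snps, [0.01, 0.5, 0.3, 0.6])
        return tidy, manifest, ens, cfg

    def test_dropping_suprathreshold_snp_keeps_gene_w(self):
        tidy, manifest, ens, cfg = self._base()
        base = gene_based_test(tidy, "G1", manifest, ens, cfg)
        gres, _ = leave_one_snp_out(tidy, manifest, ens, cfg, "b")
        g1 = [g for g in gres if g.gene == "G1"][0]
        assert g1.log_w == pytest.approx(base.log_w)

    def test_dropping_only_significant_snp_gives_w_one(self):
        tidy, manifest, ens, cfg = self._base()
        gres, _ = leave_one_snp_out(tidy, manifest, ens, cfg, "a")
        g1 = [g for g in gres if g.gene == "G1"][0]
        assert g1.log_w == 0.0
        assert g1.p == 1.0

    def test_unknown_snp_rejected(self):
        tidy, manifest, ens, cfg = self._base()
        with pytest.raises(ValueError, match="not in manifest"):
            leave_one_snp_out(tidy, manifest, ens, cfg, "zzz")
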