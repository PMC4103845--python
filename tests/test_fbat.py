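"""Family-based score test: Mendelian conditioning, enumeration oracle,
covariate adjustment, coding invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import famassoc as fa
from famassoc import fbat
from famassoc.fbat import (
    adjust_covariates,
    family_contribution,
    fbat_test,
    offspring_genotype_distribution,
)

from conftest import trio_setup


def enumerate_family_moments(father, mother, residuals):
    """Independent oracle: exhaustive enumeration of U over all offspring
    genotype configurations given the parents.

    Returns (E[U], Var[U]) where U = sum_j T_j (X_j - E[X_j|parents]),
    computed by summing over the full product distribution.
    """
    dist = offspring_genotype_distribution(father, mother)
    e_x = float(np.dot([0, 1, 2], dist))
    eu = 0.0
    eu2 = 0.0
    k = len(residuals)
    for config in itertools.product((0, 1, 2), repeat=k):
        prob = float(np.prod([dist[g] for g in config]))
        if prob == 0.0:
            continue
        u = sum(t * (g - e_x) for t, g in zip(residuals, config))
        eu += prob * u
        eu2 += prob * u * u
    return eu, eu2 - eu**2


class TestOffspringDistribution:
    @pytest.mark.parametrize(
        "father,mother,expected",
        [
            (2, 2, (0, 0, 1)),
            (1, 1, (0.25, 0.5, 0.25)),
            (1, 0, (0.5, 0.5, 0)),
            (0, 0, (1, 0, 0)),
            (2, 0, (0, 1, 0)),
            (2, 1, (0, 0.5, 0.5)),
        ],
    )
    def test_mendelian_probabilities(self, father, mother, expected):
        assert offspring_genotype_distribution(father, mother) == pytest.approx(expected)

    def test_missing_parent_flagged(self):
        with pytest.raises(ValueError, match="parental"):
            offspring_genotype_distribution(np.nan, 1)


class TestFamilyContribution:
    def test_homozygous_parents_uninformative(self):
        ped, geno, tr = trio_setup(2, 2, [2, 2], [1.0, -0.5])
        fam = ped.nuclear_families()[0]
        assert family_contribution(fam, geno, tr, "s1") == (0.0, 0.0)

    def test_double_het_trio(self):
        ped, geno, tr = trio_setup(1, 1, [2], [1.0])
        fam = ped.nuclear_families()[0]
        U, V = family_contribution(fam, geno, tr, "s1")
        assert U == pytest.approx(1.0)
        assert V == pytest.approx(0.5)

    def test_two_sibs_opposite_residuals(self):
        ped, geno, tr = trio_setup(1, 1, [0, 2], [1.0, -1.0])
        fam = ped.nuclear_families()[0]
        U, V = family_contribution(fam, geno, tr, "s1")
        assert U == pytest.approx(-2.0)
        assert V == pytest.approx(1.0)

    def test_missing_parent_raises(self):
        ped, geno, tr = trio_setup(np.nan, 1, [1], [1.0])
        fam = ped.nuclear_families()[0]
        with pytest.raises(ValueError, match="not genotyped"):
            family_contribution(fam, geno, tr, "s1")

    @pytest.mark.parametrize("father,mother", list(itertools.product((0, 1, 2), repeat=2)))
    @pytest.mark.parametrize("n_off", [1, 2, 3, 4])
    def test_variance_matches_enumeration_oracle(self, father, mother, n_off):
        """Analytic V equals the enumeration variance, and E[U] = 0 exactly,
        for every parental pair and family size up to 4."""
        rng = np.random.default_rng(father * 16 + mother * 4 + n_off)
        residuals = rng.normal(size=n_off).round(3)
        eu, var_u = enumerate_family_moments(father, mother, residuals)
        assert abs(eu) < 1e-12
        dist = offspring_genotype_distribution(father, mother)
        # draw one realized config to exercise the implementation's V
        child_gs = rng.choice([0, 1, 2], size=n_off, p=dist)
        ped, geno, tr = trio_setup(father, mother, child_gs, residuals)
        fam = ped.nuclear_families()[0]
        _, V = family_contribution(fam, geno, tr, "s1")
        assert V == pytest.approx(var_u, abs=1e-12)


class TestFbatTest:
    def test_z_and_p_arithmetic(self):
        ped, geno, tr = trio_setup(1, 1, [2], [1.0])
        res = fbat_test(ped.nuclear_families(), geno, tr, "s1", min_informative=1)
        assert res.Z == pytest.approx(1.4142, abs=1e-4)
        assert res.p == pytest.approx(0.1573, abs=1e-4)
        assert res.b == pytest.approx(2.0)
        assert res.n_informative == 1

    def test_all_uninformative_flagged(self):
        ped, geno, tr = trio_setup(0, 0, [0, 0], [1.0, 2.0])
        res = fbat_test(ped.nuclear_families(), geno, tr, "s1", min_informative=1)
        assert np.isnan(res.p)
        assert res.reason == "uninformative"

    def test_min_informative_threshold(self):
        ped, geno, tr = trio_setup(1, 1, [2], [1.0])
        res = fbat_test(ped.nuclear_families(), geno, tr, "s1", min_informative=10)
        assert np.isnan(res.p)
        assert "too few" in res.reason

    def test_coding_swap_flips_z(self, small_study):
        ped, geno, pheno = small_study
        tr = adjust_covariates(pheno, "BMI", ["age", "sex"], log_transform=True)
        fams = ped.nuclear_families()
        res = fbat_test(fams, geno, tr, "s1", min_informative=1)
        res_sw = fbat_test(fams, geno.swap_coding("s1"), tr, "s1", min_informative=1)
        assert res_sw.Z == pytest.approx(-res.Z)
        assert res_sw.p == pytest.approx(res.p)

    def test_noncontributing_residual_shift_invariance(self, small_study):
        """Adding a constant to residuals of individuals outside informative
        families leaves Z unchanged."""
        ped, geno, pheno = small_study
        tr = adjust_covariates(pheno, "BMI", ["age"], log_transform=True)
        fams = ped.nuclear_families()
        base = fbat_test(fams, geno, tr, "s1", min_informative=1)
        contributing = set()
        for fam in fams:
            gf = geno.values.loc[fam.father, "s1"]
            gm = geno.values.loc[fam.mother, "s1"]
            if gf in (1.0,) or gm in (1.0,):
                contributing.update(fam.offspring)
        shifted = tr.residuals.copy()
        outside = [i for i in shifted.index if i not in contributing]
        shifted.loc[outside] += 5.0
        tr2 = fbat.TraitResiduals("BMI", shifted, tr.offset, True)
        res2 = fbat_test(fams, geno, tr2, "s1", min_informative=1)
        assert res2.Z == pytest.approx(base.Z)

    def test_vectorized_engine_matches_per_family_path(self, small_study):
        ped, geno, pheno = small_study
        tr = adjust_covariates(pheno, "WC", ["age", "sex", "smoking"], log_transform=True)
        fams = ped.nuclear_families()
        tidy = fbat.run_snp_tests(ped, geno, {"WC": tr}, min_informative=1)
        for snp in geno.snps:
            slow = fbat_test(fams, geno, tr, snp, min_informative=1)
            row = tidy[(tidy.snp == snp)].iloc[0]
            assert row["U"] == pytest.approx(slow.U, abs=1e-10)
            assert row["V"] == pytest.approx(slow.V, abs=1e-10)


class TestCovariateAdjustment:
    def test_no_covariates_centers_trait(self):
        pheno = pd.DataFrame({"T": [1.0, 2.0, 3.0, 6.0]}, index=list("abcd"))
        tr = adjust_covariates(pheno, "T", [], log_transform=False)
        assert np.allclose(tr.residuals, pheno["T"] - 3.0)
        assert tr.offset == pytest.approx(3.0)

    def test_residuals_orthogonal_to_covariate(self):
        rng = np.random.default_rng(0)
        n = 3000
        age = rng.uniform(20, 80, n)
        trait = np.exp(0.1 * age / 10 + rng.normal(0, 0.3, n))
        pheno = pd.DataFrame({"T": trait, "age": age})
        tr = adjust_covariates(pheno, "T", ["age"], log_transform=True)
        r = np.corrcoef(tr.residuals.values, age)[0, 1]
        assert abs(r) < 0.02
        assert tr.residuals.sum() == pytest.approx(0.0, abs=1e-8)

    def test_nonpositive_trait_cannot_log(self):
        pheno = pd.DataFrame({"T": [1.0, -1.0], "age": [30, 40]})
        with pytest.raises(ValueError, match="positive"):
            adjust_covariates(pheno, "T", ["age"], log_transform=True)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(20, 80, 100)
        pheno = pd.DataFrame({"T": rng.uniform(1, 2, 100), "age": age, "age2": age})
        with pytest.raises(ValueError, match="rank-deficient"):
            adjust_covariates(pheno, "T", ["age", "age2"], log_transform=False)

    def test_adding_bmi_covariate_changes_residuals_only(self, default_study):
        _, _, pheno = default_study
        base = adjust_covariates(pheno, "WC", ["age", "sex"], log_transform=True)
        adj = adjust_covariates(pheno, "WC", ["age", "sex", "BMI"], log_transform=True)
        assert not np.allclose(base.residuals, adj.residuals)
        assert base.residuals.index.equals(adj.residuals.index)
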