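import numpy as np
import pandas as pd
import pytest

from ecosweep import (
    blup_trait,
    define_regions,
    genomic_inflation,
    gwas_mlm,
    haplotype_means,
    significance_threshold,
)
from ecosweep.genotype_io import ValidationError
from ecosweep.population_structure import KinshipMatrix, kinship_vanraden
from ecosweep.synthetic_data import ChromSpec, SimConfig, simulate_panel

from conftest import make_matrix


def balanced_pheno(n=60, years=(2012, 2013), sigma_g=2.0, sigma_e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    gvals = rng.normal(0, sigma_g, n)
    year_eff = {y: e for y, e in zip(years, (0.0, 3.0, -2.0, 5.0))}
    rows = [(f"s{j:03d}", y, 150 + year_eff[y] + gvals[j] + rng.normal(0, sigma_e))
            for y in years for j in range(n)]
    return pd.DataFrame(rows, columns=["sample_id", "year", "value"])


class TestBlup:
    def test_near_zero_residual_recovers_adjusted_means(self):
        pheno = balanced_pheno(n=40, sigma_g=3.0, sigma_e=1e-4, seed=1)
        blups = blup_trait(pheno)
        adj = pheno.copy()
        adj["v"] = adj["value"] - adj.groupby("year")["value"].transform("mean") \
            + adj["value"].mean()
        means = adj.groupby("sample_id")["v"].mean()
        np.testing.assert_allclose(blups.to_numpy(), means.loc[blups.index].to_numpy(),
                                   atol=0.01)

    def test_constant_phenotype_all_equal(self):
        pheno = pd.DataFrame({"sample_id": ["a", "b", "a", "b"],
                              "year": [2012, 2012, 2013, 2013],
                              "value": [150.0] * 4})
        blups = blup_trait(pheno)
        assert (blups == 150.0).all()

    def test_shrinkage_toward_grand_mean(self):
        pheno = balanced_pheno(n=100, sigma_g=2.0, sigma_e=2.0, seed=2)
        blups = blup_trait(pheno)
        mu = blups.mean()
        adj = pheno.copy()
        adj["v"] = adj["value"] - adj.groupby("year")["value"].transform("mean") \
            + adj["value"].mean()
        means = adj.groupby("sample_id")["v"].mean().loc[blups.index]
        assert (np.abs(blups - mu) <= np.abs(means - means.mean()) + 1e-6).all()

    def test_balanced_design_shrinkage_factor(self):
        # sigma_g^2 = 4, sigma_e^2 = 1, r = 2 years -> shrink = 4 / (4 + 1/2)
        pheno = balanced_pheno(n=200, sigma_g=2.0, sigma_e=1.0, seed=3)
        blups = blup_trait(pheno)
        adj = pheno.copy()
        adj["v"] = adj["value"] - adj.groupby("year")["value"].transform("mean") \
            + adj["value"].mean()
        means = adj.groupby("sample_id")["v"].mean().loc[blups.index]
        slope = np.polyfit(means - means.mean(), blups - blups.mean(), 1)[0]
        assert slope == pytest.approx(4 / 4.5, abs=0.1)

    def test_single_year_rejected(self):
        pheno = pd.DataFrame({"sample_id": ["a", "b"], "year": [2012, 2012],
                              "value": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            blup_trait(pheno)


@pytest.fixture(scope="module")
def panel():
    cfg = SimConfig(seed=13, groups=(("winter", 120),),
                    chroms=(ChromSpec("A01", 4_000_000, 800, founders=0),),
                    fst={"winter": 0.05}, sweeps=(), phenotype=None)
    return simulate_panel(cfg).genotypes


class TestGwasMlm:
    def test_identity_kinship_no_pcs_equals_ols(self, panel):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(0, 1, panel.n_samples), index=panel.samples)
        K = KinshipMatrix(list(panel.samples), np.eye(panel.n_samples))
        res = gwas_mlm(y, panel, K, n_pcs=0)
        for j in [3, 50, 400]:
            x = panel.dosage[:, j].astype(float)
            if np.var(x) == 0:
                continue
            ols = sm.OLS(y.to_numpy(), sm.add_constant(x)).fit()
            assert res["p_value"].iloc[j] == pytest.approx(ols.pvalues[1], abs=1e-8)
            assert res["beta"].iloc[j] == pytest.approx(ols.params[1], abs=1e-8)

    def test_phenotype_equal_to_dosage_is_top_hit(self, panel):
        j = 37
        y = pd.Series(panel.dosage[:, j].astype(float) + 100.0, index=panel.samples)
        K = kinship_vanraden(panel)
        res = gwas_mlm(y, panel, K, n_pcs=0)
        assert res["p_value"].idxmin() == j

    def test_monomorphic_snp_skipped(self):
        d = np.column_stack([
            np.zeros(30, dtype=np.int8),
            np.random.default_rng(0).integers(0, 3, 30).astype(np.int8),
            np.random.default_rng(1).integers(0, 3, 30).astype(np.int8),
        ])
        g = make_matrix(d)
        y = pd.Series(np.random.default_rng(2).normal(size=30), index=g.samples)
        K = KinshipMatrix(list(g.samples), np.eye(30))
        res = gwas_mlm(y, g, K, n_pcs=0)
        assert np.isnan(res["p_value"].iloc[0])
        assert res["p_value"].iloc[1:].notna().all()

    def test_pve_bounded(self, panel):
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(0, 1, panel.n_samples), index=panel.samples)
        res = gwas_mlm(y, panel, kinship_vanraden(panel), n_pcs=2)
        pve = res["pve"].dropna()
        assert ((pve >= 0) & (pve <= 1)).all()


class TestThresholdRule:
    def test_paper_scale_value(self):
        assert significance_threshold(20_576) == pytest.approx(4.86e-5, rel=1e-3)

    def test_degenerate_and_other_sizes(self):
        assert significance_threshold(1) == 1.0
        assert significance_threshold(33_186) == pytest.approx(3.01e-5, rel=1e-2)

    def test_invalid_rejected(self):
        with pytest.raises(ValidationError):
            significance_threshold(0)


class TestDefineRegions:
    def test_isolated_peak_is_point_region(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (50, 5)).astype(np.int8)
        g = make_matrix(d, positions=[10_000, 300_000, 600_000, 900_000, 1_200_000])
        res = g.snps[["snp_id", "chrom", "pos"]].copy()
        res["p_value"] = [0.5, 1e-8, 0.5, 0.5, 0.5]
        out = define_regions(res, g, p_cutoff=1e-4)
        assert len(out) == 1
        assert (out.start.iloc[0], out.end.iloc[0]) == (299_999, 300_000)

    def test_block_peaks_merge(self):
        # two significant SNPs 50 kb apart inside a 2-founder LD block
        cfg = SimConfig(seed=21, groups=(("winter", 150),),
                        chroms=(ChromSpec("A01", 1_000_000, 200, block_len=1_000_000,
                                          founders=2),),
                        fst={"winter": 0.1}, sweeps=(), phenotype=None)
        from ecosweep import filter_snps

        g, _ = filter_snps(simulate_panel(cfg).genotypes, maf_min=0.05)
        res = g.snps[["snp_id", "chrom", "pos"]].copy()
        res["p_value"] = 0.5
        pos = g.snps["pos"].to_numpy()
        i = int(np.argmin(np.abs(pos - 400_000)))
        j = int(np.argmin(np.abs(pos - 450_000)))
        res.loc[i, "p_value"] = 1e-9
        res.loc[j, "p_value"] = 1e-7
        out = define_regions(res, g, p_cutoff=1e-4)
        assert len(out) == 1
        assert out.n_hits.iloc[0] == 2


class TestHaplotypeMeans:
    def test_single_class_no_test(self):
        d = np.tile([1, 1], (20, 1)).astype(np.int8)
        g = make_matrix(d)
        vals = pd.Series(np.arange(20.0), index=g.samples)
        block = haplotype_means(list(g.snps["snp_id"]), g, vals)
        assert block.p_value is None
        assert "skipped" in block.note

    def test_means_match_brute_force_groupby(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, (40, 2)).astype(np.int8)
        g = make_matrix(d)
        vals = pd.Series(rng.normal(150, 10, 40), index=g.samples)
        block = haplotype_means(list(g.snps["snp_id"]), g, vals, min_class_n=2)
        for row in block.classes.itertuples(index=False):
            key = tuple(int(x) for x in row.haplotype.split("/"))
            mask = (d[:, 0] == key[0]) & (d[:, 1] == key[1])
            assert row.mean_trait == pytest.approx(vals[mask].mean(), abs=1e-12)
            assert row.n == mask.sum()

    def test_separated_classes_detected(self):
        rng = np.random.default_rng(9)
        detected = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            d = np.repeat([[0, 0], [2, 2]], 50, axis=0).astype(np.int8)
            g = make_matrix(d)
            shift = np.where(d[:, 0] == 0, 0.0, 10.0)
            vals = pd.Series(150 + shift + r.normal(0, 5, 100), index=g.samples)
            block = haplotype_means(list(g.snps["snp_id"]), g, vals)
            detected += block.p_value < 1e-3
        assert detected >= 9

    def test_missing_genotypes_excluded(self):
        d = np.array([[0, 0], [2, 2], [-1, 0], [2, 2]], dtype=np.int8)
        g = make_matrix(d)
        vals = pd.Series([1.0, 2.0, 3.0, 4.0], index=g.samples)
        block = haplotype_means(list(g.snps["snp_id"]), g, vals, min_class_n=1)
        assert block.classes["n"].sum() == 3


def test_genomic_inflation_on_uniform_p():
    rng = np.random.default_rng(10)
    lam = genomic_inflation(rng.uniform(size=20_000))
    assert lam == pytest.approx(1.0, abs=0.05)
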