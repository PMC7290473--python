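import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mwas.synthetic_data import (
    ConfigError,
    ScenarioConfig,
    causal_indices,
    gen_gwas_cohorts,
    gen_mqtl_summary,
    gen_reference_panel,
    simulate_study,
)


def _cfg(**kw):
    base = dict(
        scenario="pleiotropy", n_ref=500, n_mqtl=1000, cohort_sizes=((500, 500),),
        m_snps=10, ld_rho=0.8, beta_zx=0.5, b_xy=0.4, seed=0,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"scenario": "bogus"},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"ld_rho": 1.0},
            {"n_ref": 1},
            {"cohort_sizes": ((1, 500),)},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            _cfg(**kw)

    def test_linkage_truth_has_two_causal_snps(self):
        cfg = _cfg(scenario="linkage", m_snps=15)
        panel = gen_reference_panel(cfg)
        _, truth = gen_mqtl_summary(panel, cfg)
        assert len(set(truth.causal_snps)) == 2

    def test_non_linkage_truth_single_causal(self):
        cfg = _cfg()
        panel = gen_reference_panel(cfg)
        _, truth = gen_mqtl_summary(panel, cfg)
        assert len(truth.causal_snps) == 1


class TestPanel:
    def test_seed_determinism(self):
        a = gen_reference_panel(_cfg())
        b = gen_reference_panel(_cfg())
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_different_seed_differs(self):
        a = gen_reference_panel(_cfg())
        b = gen_reference_panel(_cfg(seed=1))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_unlinked_panel_uncorrelated(self):
        """ld_rho=0: mean adjacent |r| stays near zero."""
        cfg = _cfg(ld_rho=0.0, n_ref=2000, m_snps=30)
        d = gen_reference_panel(cfg).dosages.astype(float)
        rs = [abs(np.corrcoef(d[:, j], d[:, j + 1])[0, 1]) for j in range(d.shape[1] - 1)]
        assert np.mean(rs) < 0.05

    def test_high_rho_adjacent_correlation_band(self):
        """ld_rho=0.9 with maf 0.2-0.5: thresholding attenuates the latent
        correlation; the Monte-Carlo-derived band for mean adjacent r is
        [0.55, 0.78]."""
        rs = []
        for seed in range(3):
            cfg = _cfg(ld_rho=0.9, n_ref=2000, m_snps=30, maf_range=(0.2, 0.5), seed=seed)
            d = gen_reference_panel(cfg).dosages.astype(float)
            rs += [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(d.shape[1] - 1)]
        assert 0.55 <= np.mean(rs) <= 0.78

    def test_polymorphic_and_sorted(self):
        panel = gen_reference_panel(_cfg(n_ref=100))
        assert (panel.dosages.min(axis=0) != panel.dosages.max(axis=0)).all()
        assert (np.diff(panel.meta["Bp"]) > 0).all()


class TestMqtl:
    def test_seed_determinism(self):
        cfg = _cfg()
        panel = gen_reference_panel(cfg)
        a, _ = gen_mqtl_summary(panel, cfg)
        b, _ = gen_mqtl_summary(panel, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_null_pvalues_uniform(self):
        """beta_zx=0 over 200 SNPs: KS test against Uniform(0,1)."""
        cfg = _cfg(beta_zx=0.0, ld_rho=0.0, m_snps=200, n_mqtl=800)
        panel = gen_reference_panel(cfg)
        mqtl, _ = gen_mqtl_summary(panel, cfg)
        assert stats.kstest(mqtl["p"], "uniform").pvalue > 0.01

    def test_causal_snp_usually_top(self):
        """beta_zx=0.5 at n=2000: the causal SNP attains the minimum p
        among cis SNPs in >= 90% of replicates."""
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            cfg = _cfg(beta_zx=0.5, n_mqtl=2000, m_snps=10, seed=s)
            panel = gen_reference_panel(cfg)
            mqtl, truth = gen_mqtl_summary(panel, cfg)
            top_snp = mqtl.loc[mqtl["p"].idxmin(), "SNP"]
            hits += top_snp == panel.meta.iloc[truth.causal_snps[0]]["SNP"]
        assert hits / n_rep >= 0.9

    def test_freq_within_reported_bounds(self):
        cfg = _cfg(n_mqtl=2000)
        panel = gen_reference_panel(cfg)
        mqtl, _ = gen_mqtl_summary(panel, cfg)
        assert mqtl["Freq"].between(0.01, 0.99).all()


class TestGwas:
    def test_seed_determinism(self):
        cfg = _cfg(cohort_sizes=((400, 400), (300, 300)))
        panel = gen_reference_panel(cfg)
        _, truth = gen_mqtl_summary(panel, cfg)
        a = gen_gwas_cohorts(panel, cfg, truth)
        b = gen_gwas_cohorts(panel, cfg, truth)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    def test_null_pvalues_uniform(self):
        cfg = _cfg(scenario="null", b_xy=0.0, ld_rho=0.0, m_snps=200,
                   cohort_sizes=((800, 800),))
        panel = gen_reference_panel(cfg)
        _, truth = gen_mqtl_summary(panel, cfg)
        gwas = gen_gwas_cohorts(panel, cfg, truth)[0]
        assert stats.kstest(gwas["p"], "uniform").pvalue > 0.01

    def test_causal_z_exceeds_distant_z(self):
        """Pleiotropy: median |z| at the causal SNP beats the most distant
        cis SNP across replicates."""
        z_causal, z_far = [], []
        for s in range(50):
            cfg = _cfg(scenario="pleiotropy", b_xy=0.4, beta_zx=0.8,
                       cohort_sizes=((1000, 1000),), m_snps=11, seed=s)
            panel = gen_reference_panel(cfg)
            _, truth = gen_mqtl_summary(panel, cfg)
            gwas = gen_gwas_cohorts(panel, cfg, truth)[0].set_index("SNP")
            c = truth.causal_snps[0]
            csnp = panel.meta.iloc[c]["SNP"]
            far_idx = 0 if c >= len(panel.meta) // 2 else len(panel.meta) - 1
            fsnp = panel.meta.iloc[far_idx]["SNP"]
            if csnp in gwas.index and fsnp in gwas.index:
                z_causal.append(abs(gwas.loc[csnp, "b"] / gwas.loc[csnp, "se"]))
                z_far.append(abs(gwas.loc[fsnp, "b"] / gwas.loc[fsnp, "se"]))
        assert np.median(z_causal) > np.median(z_far)

    def test_group_ratio_zero_removes_group_b_effect(self):
        cfg = _cfg(scenario="group_heterogeneity", group_ratio=0.0)
        panel = gen_reference_panel(cfg)
        _, truth = gen_mqtl_summary(panel, cfg)
        assert truth.b_xy_group_a == pytest.approx(0.4)
        assert truth.b_xy_group_b == 0.0


class TestStudy:
    def test_alleles_consistent_across_tables(self):
        cfg = _cfg(n_probes=2)
        study = simulate_study(cfg)
        panel_alleles = study["panel"].meta.set_index("SNP")[["A1", "A2"]]
        mqtl_alleles = study["mqtl"].set_index("SNP")[["A1", "A2"]]
        for snp in mqtl_alleles.index:
            assert tuple(mqtl_alleles.loc[snp]) == tuple(panel_alleles.loc[snp])
        for tab in study["gwas"]:
            for _, r in tab.iterrows():
                assert (r["A1"], r["A2"]) == tuple(panel_alleles.loc[r["SNP"]])

    def test_null_type_one_error_band(self):
        """Fraction of null GWAS SNPs at p<0.05 within 3 binomial SDs."""
        cfg = _cfg(scenario="null", b_xy=0.0, ld_rho=0.0, m_snps=250,
                   cohort_sizes=((600, 600),), n_probes=4)
        study = simulate_study(cfg)
        p = pd.concat(study["gwas"])["p"]
        n = len(p)
        assert n >= 900
        rate = (p < 0.05).mean()
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n)

    def test_scenarios_override(self):
        cfg = _cfg(n_probes=3)
        study = simulate_study(cfg, scenarios=["null", "pleiotropy", "linkage"])
        assert [t.scenario for t in study["truth"]] == ["null", "pleiotropy", "linkage"]

    def test_block_separation_beyond_cis_window(self):
        cfg = _cfg(n_probes=2)
        study = simulate_study(cfg)
        bp = study["mqtl"].groupby("ProbeID")["ProbeBp"].first().to_numpy()
        assert abs(bp[1] - bp[0]) > 4_000_000
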