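import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mwas.smr_heidi import (
    pick_top_mqtl,
    run_mwas,
    select_eligible_probes,
    smr_test,
)


class TestSmrTest:
    def test_hand_worked_example(self):
        b, se, p = smr_test(0.1, 0.02, 0.5, 0.05)
        assert b == pytest.approx(0.2)
        assert se == pytest.approx(0.2 / np.sqrt(20), rel=1e-6)
        assert p == pytest.approx(stats.chi2.sf(20, 1), rel=1e-6)

    def test_null_gwas_gives_unit_p(self):
        b, se, p = smr_test(0.0, 0.02, 0.5, 0.05)
        assert b == 0.0
        assert p == 1.0
        assert np.isinf(se)

    def test_zero_mqtl_beta_rejected(self):
        with pytest.raises(ValueError):
            smr_test(0.1, 0.02, 0.0, 0.05)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            smr_test(0.1, -0.02, 0.5, 0.05)

    @given(
        b1=st.floats(-1, 1), se1=st.floats(0.01, 0.5),
        b2=st.floats(0.05, 2), se2=st.floats(0.01, 0.5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_identity_and_bounds(self, b1, se1, b2, se2):
        """(b/se)^2 = T exactly; T <= min(z1^2, z2^2); p_smr >= both p's."""
        b, se, p = smr_test(b1, se1, b2, se2)
        z1sq, z2sq = (b1 / se1) ** 2, (b2 / se2) ** 2
        t = z1sq * z2sq / (z1sq + z2sq) if z1sq + z2sq else 0.0
        if np.isfinite(se):
            assert (b / se) ** 2 == pytest.approx(t, rel=1e-9)
        assert t <= min(z1sq, z2sq) + 1e-12
        assert p >= stats.chi2.sf(z1sq, 1) - 1e-12
        assert p >= stats.chi2.sf(z2sq, 1) - 1e-12


def _probe_table(pvals, snps_in_gwas):
    """One probe per p-value; each probe has a single cis SNP."""
    mqtl = pd.DataFrame(
        {
            "ProbeID": [f"cg{i}" for i in range(len(pvals))],
            "ProbeChr": "1", "ProbeBp": 1000, "Gene": "NA", "Orientation": "+",
            "SNP": [f"rs{i}" for i in range(len(pvals))],
            "SnpChr": "1", "SnpBp": 900,
            "A1": "A", "A2": "G", "Freq": 0.3,
            "b": 0.5, "se": 0.05, "p": pvals, "n": 1000,
        }
    )
    probes = mqtl[["ProbeID", "ProbeChr", "ProbeBp", "Gene", "Orientation"]].drop_duplicates()
    gwas = pd.DataFrame(
        {
            "SNP": snps_in_gwas, "A1": "A", "A2": "G", "freq": 0.3,
            "b": 0.1, "se": 0.05, "p": 0.045, "n": 5000,
        }
    )
    return probes, mqtl, gwas


def test_eligibility_hand_count():
    """{1e-9 ok, 1e-7 no, 4e-8 ok, 1e-20 but SNP absent, 5e-8 boundary no} -> 2."""
    pvals = [1e-9, 1e-7, 4e-8, 1e-20, 5e-8]
    probes, mqtl, gwas = _probe_table(pvals, ["rs0", "rs1", "rs2", "rs4"])
    eligible = select_eligible_probes(probes, mqtl, gwas)
    assert eligible == ["cg0", "cg2"]


class TestPickTop:
    def _mqtl(self, ps, zs, pos):
        return pd.DataFrame(
            {
                "ProbeID": "cg1", "ProbeChr": "1", "ProbeBp": 1000,
                "Gene": "NA", "Orientation": "+",
                "SNP": [f"rs{i}" for i in range(len(ps))],
                "SnpChr": "1", "SnpBp": pos,
                "A1": "A", "A2": "G", "Freq": 0.3,
                "b": [z * 0.01 for z in zs], "se": 0.01, "p": ps, "n": 1000,
            }
        )

    def _gwas(self, n):
        return pd.DataFrame(
            {"SNP": [f"rs{i}" for i in range(n)], "A1": "A", "A2": "G",
             "freq": 0.3, "b": 0.1, "se": 0.05, "p": 0.04, "n": 100}
        )

    def test_unique_minimum(self):
        top = pick_top_mqtl("cg1", self._mqtl([1e-8, 1e-5], [10, 5], [100, 200]),
                            self._gwas(2))
        assert top["SNP"] == "rs0"

    def test_tie_broken_by_larger_z(self):
        top = pick_top_mqtl("cg1", self._mqtl([1e-8, 1e-8], [9, 10], [100, 200]),
                            self._gwas(2))
        assert top["SNP"] == "rs1"

    def test_tie_broken_by_position(self):
        top = pick_top_mqtl("cg1", self._mqtl([1e-8, 1e-8], [10, 10], [200, 100]),
                            self._gwas(2))
        assert top["SNP"] == "rs1"  # rs1 at position 100

    def test_no_shared_snp_raises(self):
        with pytest.raises(ValueError, match="cg1"):
            pick_top_mqtl("cg1", self._mqtl([1e-8], [10], [100]),
                          self._gwas(0))


def test_run_mwas_flags_and_threshold(mixed_study):
    study, scenarios = mixed_study
    results, counts = run_mwas(
        "all", study["gwas"][0], study["probes"], study["mqtl"], study["panel"],
        bonferroni_denominator=91000,
    )
    assert counts["smr_threshold"] == pytest.approx(0.05 / 91000)
    # flags are consistent with the reported p-values
    for _, r in results.iterrows():
        assert r["passes_SMR"] == (r["P_SMR"] < 0.05 / 91000)
        if r["passes_SMR"] and not np.isnan(r["P_HEIDI"]):
            assert r["passes_HEIDI"] == (r["P_HEIDI"] >= 0.05)
        assert r["N_HEIDI"] <= 20


def test_run_mwas_smr_significant_but_heidi_failed_excluded():
    """A probe may clear the SMR threshold yet fail HEIDI; it is kept in
    the table with passes_HEIDI False so the final list excludes it."""
    results = pd.DataFrame(
        {
            "ProbeID": ["a", "b"],
            "passes_SMR": [True, True],
            "passes_HEIDI": [True, False],
        }
    )
    final = results.loc[results["passes_SMR"] & results["passes_HEIDI"], "ProbeID"]
    assert list(final) == ["a"]


def test_run_mwas_empty_eligible_warns(toy_gwas_df, caplog):
    probes = pd.DataFrame(
        {"ProbeID": ["cgX"], "ProbeChr": ["1"], "ProbeBp": [1000],
         "Gene": ["NA"], "Orientation": ["+"]}
    )
    mqtl = pd.DataFrame(
        {
            "ProbeID": "cgX", "ProbeChr": "1", "ProbeBp": 1000, "Gene": "NA",
            "Orientation": "+", "SNP": "rs1", "SnpChr": "1", "SnpBp": 900,
            "A1": "A", "A2": "G", "Freq": 0.3, "b": 0.1, "se": 0.05,
            "p": [1e-4], "n": 1000,  # not mQTL-significant
        }
    )
    from mwas.synthetic_data import LdPanel
    panel = LdPanel(
        meta=pd.DataFrame({"SNP": ["rs1"], "Chr": ["1"], "Bp": [900],
                           "A1": ["A"], "A2": ["G"]}),
        dosages=np.array([[0], [1], [2], [1]], dtype=np.int8),
    )
    with caplog.at_level("WARNING"):
        results, counts = run_mwas("all", toy_gwas_df, probes, mqtl, panel)
    assert counts["n_eligible"] == 0
    assert len(results) == 0
    assert "no eligible probes" in caplog.text
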