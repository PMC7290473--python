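import numpy as np
import pandas as pd
import pytest

from mwas.synthetic_data import ScenarioConfig, simulate_study


@pytest.fixture
def toy_gwas_df():
    return pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "A1": ["A", "T", "C"],
            "A2": ["G", "C", "G"],
            "freq": [0.3, 0.2, 0.45],
            "b": [0.12, -0.05, 0.3],
            "se": [0.04, 0.05, 0.1],
            "p": [2.7e-3, 0.317, 2.7e-3],
            "n": [5000, 5000, 4800],
        }
    )


@pytest.fixture
def toy_mqtl_df():
    rows = []
    for pid, pbp in (("cgA", 1_000_000), ("cgB", 3_000_000)):
        for j, (snp, sbp, p) in enumerate(
            [("rs%s1" % pid[-1], 999_000, 1e-12),
             ("rs%s2" % pid[-1], 1_001_000, 1e-6),
             ("rs%s3" % pid[-1], 1_050_000, 0.05)]
        ):
            rows.append(
                dict(ProbeID=pid, ProbeChr="1", ProbeBp=pbp, Gene="GENE" + pid[-1],
                     Orientation="+", SNP=snp, SnpChr="1",
                     SnpBp=sbp + (2_000_000 if pid == "cgB" else 0),
                     A1="A", A2="G", Freq=0.25, b=0.5 - 0.1 * j, se=0.05,
                     p=p, n=1980)
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def mixed_study():
    """Five-probe toy study: 2 strong pleiotropy, 1 linkage, 2 null."""
    config = ScenarioConfig(
        scenario="pleiotropy", n_ref=1500, n_mqtl=4000,
        cohort_sizes=((1500, 1500), (1500, 1500)),
        m_snps=15, ld_rho=0.85, beta_zx=0.8, b_xy=0.6,
        n_probes=5, seed=42,
    )
    scenarios = ["pleiotropy", "pleiotropy", "linkage", "null", "null"]
    return simulate_study(config, scenarios=scenarios), scenarios
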