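"""Simulation-based calibration checks for the whole pipeline.

Each function runs the generators and the inference end to end at a
fixed, documented problem size and returns the measured operating
characteristic: type-I error of the SMR test under a null disease model,
bias and interval coverage of the SMR ratio estimate under pleiotropy,
HEIDI rejection rates under pleiotropy vs linkage, agreement of the
weighted-chi-square tail with direct Monte Carlo, the null distribution
of the stratified Wald contrast, and exact truth recovery on a small
mixed-scenario study.  Problem sizes are desk-scale choices that keep
each check to seconds while leaving the binomial error bands tight
enough to be informative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._chi2comb import chi2comb_sf
from .heterogeneity import wald_chisq_diff
from .smr_heidi import heidi_test, pick_top_mqtl, run_mwas, smr_test
from .synthetic_data import (
    ScenarioConfig,
    gen_gwas_cohorts,
    gen_mqtl_summary,
    gen_reference_panel,
    simulate_study,
)

__all__ = [
    "smr_null_type1",
    "smr_bias_coverage",
    "heidi_rejection_rates",
    "heidi_oracle_agreement",
    "wald_equal_effects_ks",
    "toy_study_recovery",
]


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2**31 - 1)


def _smr_at_top(cfg: ScenarioConfig):
    """One full replicate: panel -> mQTL -> GWAS -> SMR at the top mQTL."""
    panel = gen_reference_panel(cfg)
    mqtl, truth = gen_mqtl_summary(panel, cfg)
    gwas = gen_gwas_cohorts(panel, cfg, truth)[0]
    top = pick_top_mqtl(truth.probe_id, mqtl, gwas)
    gw = gwas.set_index("SNP")
    b, se, p = smr_test(gw.loc[top["SNP"], "b"], gw.loc[top["SNP"], "se"],
                        top["b"], top["se"])
    return b, se, p, (panel, mqtl, gwas, top, truth)


def smr_null_type1(n_probes: int = 500, seed: int = 1, level: float = 0.05) -> float:
    """Fraction of null-disease probes with P_SMR below ``level``.

    Probes carry a strong mQTL (so the instrument is valid) but no
    methylation-disease effect; P_SMR should then be uniform.
    """
    hits = 0
    for i in range(n_probes):
        cfg = ScenarioConfig(
            scenario="null", n_ref=400, n_mqtl=1500, cohort_sizes=((800, 800),),
            m_snps=8, ld_rho=0.8, beta_zx=0.5, b_xy=0.0, seed=_sub_seed(seed, i),
        )
        _, _, p, _ = _smr_at_top(cfg)
        hits += p < level
    return hits / n_probes


def smr_bias_coverage(n_reps: int = 200, seed: int = 1) -> tuple[float, float]:
    """Relative bias of b_SMR and 95% interval coverage under pleiotropy.

    Study conditions: methylation n = 5000, one 2500/2500 case-control
    cohort, beta_zx = 0.5, b_xy = 0.4.
    """
    b_xy = 0.4
    est, covered = [], 0
    for i in range(n_reps):
        cfg = ScenarioConfig(
            scenario="pleiotropy", n_ref=500, n_mqtl=5000,
            cohort_sizes=((2500, 2500),), m_snps=10, ld_rho=0.8,
            beta_zx=0.5, b_xy=b_xy, seed=_sub_seed(seed, 100_000 + i),
        )
        b, se, _, _ = _smr_at_top(cfg)
        est.append(b)
        covered += (b - 1.96 * se) <= b_xy <= (b + 1.96 * se)
    rel_bias = (float(np.mean(est)) - b_xy) / b_xy
    return rel_bias, covered / n_reps


def heidi_rejection_rates(n_reps: int = 500, seed: int = 1) -> dict:
    """HEIDI rejection rate at 0.05 under pleiotropy and under linkage.

    Linkage places the disease variant at realized panel r ~ 0.5 from
    the methylation variant; a well-behaved filter rejects those far
    more often than single-variant architectures.
    """
    out = {}
    for offset, scen in ((200_000, "pleiotropy"), (300_000, "linkage")):
        rej = evaluable = 0
        for i in range(n_reps):
            cfg = ScenarioConfig(
                scenario=scen, n_ref=1000, n_mqtl=2000, cohort_sizes=((1500, 1500),),
                m_snps=15, ld_rho=0.85, beta_zx=0.8, b_xy=0.5,
                seed=_sub_seed(seed, offset + i),
            )
            _, _, _, (panel, mqtl, gwas, top, truth) = _smr_at_top(cfg)
            p, _ = heidi_test(truth.probe_id, mqtl, gwas, panel, top)
            if not np.isnan(p):
                evaluable += 1
                rej += p < 0.05
        out[scen] = rej / max(evaluable, 1)
        out[f"{scen}_evaluable"] = evaluable
    return out


def heidi_oracle_agreement(
    n_instances: int = 20, n_draws: int = 200_000, seed: int = 1
) -> pd.DataFrame:
    """Eigen-weighted chi-square tail vs direct Monte Carlo.

    For random correlation structures, compares the numerically
    evaluated tail with the empirical tail of 200,000 simulated draws of
    the weighted sum; columns: analytic, mc, mc_se.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_instances):
        k = int(rng.integers(3, 16))
        A = rng.standard_normal((k, k))
        lam = np.clip(np.linalg.eigvalsh(np.corrcoef(A @ A.T)), 0, None)
        q = float(rng.uniform(0.5, 2.5) * k)
        draws = rng.standard_normal((n_draws, k)) ** 2 @ lam
        mc = float((draws > q).mean())
        mc_se = float(np.sqrt(max(mc * (1 - mc), 1e-12) / n_draws))
        rows.append({"analytic": chi2comb_sf(q, lam), "mc": mc, "mc_se": mc_se})
    return pd.DataFrame(rows)


def wald_equal_effects_ks(n_reps: int = 1000, seed: int = 1) -> float:
    """KS p-value of the stratified Wald statistic against chi-square(1).

    Two independent strata with identical true effects are simulated end
    to end (independent mQTL studies and cohorts); the contrast of their
    SMR estimates should then follow a 1-df chi-square.
    """
    chi2s = []
    for i in range(n_reps):
        pair = []
        for g in range(2):
            cfg = ScenarioConfig(
                scenario="pleiotropy", n_ref=300, n_mqtl=800,
                cohort_sizes=((500, 500),), m_snps=5, ld_rho=0.8,
                beta_zx=0.8, b_xy=0.4, seed=_sub_seed(seed, 400_000 + 2 * i + g),
            )
            b, se, _, _ = _smr_at_top(cfg)
            pair.append((b, se))
        (b1, se1), (b2, se2) = pair
        chi2s.append(wald_chisq_diff(b1, se1, b2, se2)[0])
    return float(stats.kstest(chi2s, stats.chi2(df=1).cdf).pvalue)


def toy_study_recovery(seed: int = 42) -> dict:
    """Mixed five-probe study; returns detected vs true pleiotropy probes.

    Two strong pleiotropy probes, one linkage probe, two null probes;
    the scan uses the study-wide 0.05/91000 threshold, so exactly the
    pleiotropy probes should pass both filters.
    """
    config = ScenarioConfig(
        scenario="pleiotropy", n_ref=1500, n_mqtl=4000,
        cohort_sizes=((1500, 1500), (1500, 1500)),
        m_snps=15, ld_rho=0.85, beta_zx=0.8, b_xy=0.6,
        n_probes=5, seed=seed,
    )
    scenarios = ["pleiotropy", "pleiotropy", "linkage", "null", "null"]
    study = simulate_study(config, scenarios=scenarios)
    from .meta_analysis import meta_analyze

    gwas = meta_analyze(study["gwas"])
    results, counts = run_mwas(
        "all", gwas, study["probes"], study["mqtl"], study["panel"],
        bonferroni_denominator=91000,
    )
    detected = set(results.loc[results["passes_SMR"] & results["passes_HEIDI"], "ProbeID"])
    truth = {t.probe_id for t in study["truth"] if t.scenario == "pleiotropy"}
    return {"detected": detected, "truth": truth, "counts": counts, "results": results}
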