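"""Per-probe SMR pleiotropy test and HEIDI linkage filter.

The SMR (summary-data-based Mendelian randomization) test asks whether a
disease association at a methylation probe's top cis-mQTL is consistent
with mediation through methylation.  With z_1 = b_GWAS/se_GWAS and
z_2 = b_mQTL/se_mQTL:

    b_SMR  = b_GWAS / b_mQTL
    T_SMR  = z_1^2 z_2^2 / (z_1^2 + z_2^2)      ~ chi-square(1 df)
    SE_SMR = |b_SMR| / sqrt(T_SMR)

so that (b_SMR/SE_SMR)^2 = T_SMR by construction, and
T_SMR <= min(z_1^2, z_2^2) always — the SMR p-value can never be smaller
than the larger of the two component p-values.

A significant SMR signal can arise either from a single causal variant
affecting both methylation and disease (pleiotropy) or from two distinct
variants in LD (linkage).  The HEIDI test discriminates: across cis SNPs
in moderate LD with the top instrument, the ratio estimate
b_i = b_GWAS(i)/b_mQTL(i) is constant under pleiotropy, so the deviations
d_i = b_i - b_top should be jointly zero.  Their covariance follows from
first-order error propagation, with SNP-pair correlations taken from a
reference genotype panel; the test statistic Q = sum z_d,i^2 is referred
to a weighted sum of 1-df chi-squares (weights = eigenvalues of the
correlation matrix of z_d).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._chi2comb import chi2comb_sf
from .meta_analysis import harmonize_to_reference
from .summary_io import RESULT_COLUMNS
from .synthetic_data import LdPanel

logger = logging.getLogger("mwas.smr")

__all__ = [
    "HeidiConfig",
    "smr_test",
    "select_eligible_probes",
    "pick_top_mqtl",
    "heidi_test",
    "run_mwas",
]

P_MQTL_THRESHOLD = 5e-8
HEIDI_RETAIN_LEVEL = 0.05


@dataclass(frozen=True)
class HeidiConfig:
    """Candidate-SNP selection thresholds for the HEIDI test.

    Defaults follow the cited method's standard settings: cis SNPs with
    mQTL p below ``p_mqtl_max`` (chi-square(1) > 10), r^2 with the top
    instrument inside ``r2_window``, pairwise pruning above the window's
    upper bound, and at most ``max_snps`` SNPs in total (top included).
    At least ``min_snps`` candidates besides the top are required to
    evaluate the test.
    """

    p_mqtl_max: float = 1.6e-3
    r2_window: tuple[float, float] = (0.05, 0.9)
    max_snps: int = 20
    min_snps: int = 3


def smr_test(b_gwas, se_gwas, b_mqtl, se_mqtl):
    """SMR ratio estimate, delta-method SE and 1-df chi-square p.

    Accepts scalars or arrays.  ``b_mqtl`` must be nonzero;
    ``b_gwas = 0`` gives (0, inf, 1).
    """
    b_gwas = np.asarray(b_gwas, dtype=float)
    se_gwas = np.asarray(se_gwas, dtype=float)
    b_mqtl = np.asarray(b_mqtl, dtype=float)
    se_mqtl = np.asarray(se_mqtl, dtype=float)
    if np.any(b_mqtl == 0):
        raise ValueError("b_mqtl must be nonzero (undefined ratio)")
    if np.any(se_gwas <= 0) or np.any(se_mqtl <= 0):
        raise ValueError("standard errors must be positive")
    z1sq = (b_gwas / se_gwas) ** 2
    z2sq = (b_mqtl / se_mqtl) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(z1sq + z2sq > 0, z1sq * z2sq / (z1sq + z2sq), 0.0)
    b_smr = b_gwas / b_mqtl
    se_smr = np.where(t > 0, np.abs(b_smr) / np.sqrt(np.where(t > 0, t, 1.0)), np.inf)
    p_smr = stats.chi2.sf(t, df=1)
    if b_smr.ndim == 0:
        return float(b_smr), float(se_smr), float(p_smr)
    return b_smr, se_smr, p_smr


def select_eligible_probes(
    probes: pd.DataFrame,
    mqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    p_mqtl_threshold: float = P_MQTL_THRESHOLD,
) -> list[str]:
    """Probes with >= 1 cis-mQTL at p < threshold whose SNP the GWAS covers."""
    in_gwas = mqtl["SNP"].isin(set(gwas["SNP"]))
    hit = mqtl.loc[in_gwas & (mqtl["p"] < p_mqtl_threshold), "ProbeID"]
    eligible = set(hit)
    return [p for p in probes["ProbeID"] if p in eligible]


def pick_top_mqtl(probe_id: str, mqtl: pd.DataFrame, gwas: pd.DataFrame) -> pd.Series:
    """Top instrument: minimum mQTL p among SNPs shared with the GWAS.

    Ties break by larger |z_mQTL|, then smaller position.
    """
    recs = mqtl.loc[(mqtl["ProbeID"] == probe_id) & mqtl["SNP"].isin(set(gwas["SNP"]))]
    if recs.empty:
        raise ValueError(f"{probe_id}: no cis SNP shared with the GWAS table")
    recs = recs.assign(_absz=(recs["b"] / recs["se"]).abs())
    recs = recs.sort_values(
        ["p", "_absz", "SnpBp"], ascending=[True, False, True], kind="mergesort"
    )
    return recs.iloc[0].drop("_absz")


def _aligned_dosages(panel: LdPanel, table: pd.DataFrame, snps: list[str]) -> np.ndarray:
    """Panel dosages for ``snps``, counted on each table row's effect allele."""
    meta = panel.meta.set_index("SNP")
    cols = []
    a1 = table.set_index("SNP")["A1"]
    snp_pos = {s: j for j, s in enumerate(panel.meta["SNP"])}
    for s in snps:
        g = panel.dosages[:, snp_pos[s]].astype(float)
        if str(meta.loc[s, "A1"]).upper() != str(a1.loc[s]).upper():
            g = 2.0 - g
        cols.append(g)
    return np.column_stack(cols)


def heidi_test(
    probe_id: str,
    mqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    panel: LdPanel,
    top: pd.Series,
    config: HeidiConfig = HeidiConfig(),
) -> tuple[float, int]:
    """HEIDI heterogeneity p-value and the number of SNPs used.

    Returns ``(nan, n)`` when fewer than ``config.min_snps`` candidates
    survive selection (the probe is then flagged, not silently passed).
    """
    recs = mqtl.loc[(mqtl["ProbeID"] == probe_id) & mqtl["SNP"].isin(set(gwas["SNP"]))]
    recs = recs.loc[recs["SNP"].isin(set(panel.meta["SNP"]))]
    cand = recs.loc[(recs["SNP"] != top["SNP"]) & (recs["p"] < config.p_mqtl_max)].copy()
    if cand.empty:
        return float("nan"), 1
    snps = [top["SNP"], *cand["SNP"].tolist()]
    G = _aligned_dosages(panel, pd.concat([top.to_frame().T, cand]), snps)
    R = np.corrcoef(G, rowvar=False)
    r_top = R[0, 1:]
    lo, hi = config.r2_window
    keep = (r_top**2 >= lo) & (r_top**2 <= hi)
    cand = cand.iloc[np.flatnonzero(keep)]
    if cand.empty:
        return float("nan"), 1
    # prune: no candidate pair above the upper r^2 bound, strongest |z| first
    order = np.argsort(-np.abs(cand["b"] / cand["se"]).to_numpy(), kind="mergesort")
    idx_kept: list[int] = []
    sub = np.flatnonzero(keep) + 1  # indices into R
    for o in order:
        if all(R[sub[o], sub[k]] ** 2 <= hi for k in idx_kept):
            idx_kept.append(o)
        if len(idx_kept) >= config.max_snps - 1:
            break
    cand = cand.iloc[idx_kept]
    n_heidi = len(cand) + 1
    if len(cand) < config.min_snps:
        return float("nan"), n_heidi
    snps = [top["SNP"], *cand["SNP"].tolist()]
    rows = pd.concat([top.to_frame().T, cand])
    G = _aligned_dosages(panel, rows, snps)
    R = np.corrcoef(G, rowvar=False)
    gw = gwas.set_index("SNP")
    bzx = rows["b"].to_numpy(dtype=float)
    sezx = rows["se"].to_numpy(dtype=float)
    bzy = gw.loc[snps, "b"].to_numpy(dtype=float)
    sezy = gw.loc[snps, "se"].to_numpy(dtype=float)
    bxy = bzy / bzx
    d = bxy[1:] - bxy[0]
    # cov(b_xy_i, b_xy_j) by first-order propagation; GWAS and mQTL
    # estimators are independent across studies, correlated r_ij within.
    cov_xy = (
        R * np.outer(sezy, sezy) / np.outer(bzx, bzx)
        + R * np.outer(sezx, sezx) * np.outer(bzy, bzy) / np.outer(bzx**2, bzx**2)
    )
    V = cov_xy[1:, 1:] - cov_xy[1:, [0]] - cov_xy[[0], 1:] + cov_xy[0, 0]
    sd = np.sqrt(np.diag(V))
    z_d = d / sd
    corr = V / np.outer(sd, sd)
    q = float(np.sum(z_d**2))
    lam = np.linalg.eigvalsh(corr)
    return chi2comb_sf(q, lam), n_heidi


def run_mwas(
    plan: str,
    gwas: pd.DataFrame,
    probes: pd.DataFrame,
    mqtl: pd.DataFrame,
    panel: LdPanel,
    alpha: float = 0.05,
    bonferroni_denominator: int | None = None,
    p_mqtl_threshold: float = P_MQTL_THRESHOLD,
    heidi: HeidiConfig = HeidiConfig(),
    keep_unevaluable: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full per-plan scan: eligibility, top instrument, SMR, HEIDI.

    ``bonferroni_denominator=None`` uses the realized eligible-probe
    count; pass a fixed integer (e.g. 91000) to reproduce a study-wide
    convention.  Returns the results table (standard published-results
    column contract, see :mod:`mwas.summary_io`) and a dict of filter
    counts.
    """
    gwas = harmonize_to_reference(mqtl[["SNP", "A1", "A2"]].drop_duplicates("SNP"), gwas)
    eligible = select_eligible_probes(probes, mqtl, gwas, p_mqtl_threshold)
    denom = bonferroni_denominator or max(len(eligible), 1)
    threshold = alpha / denom
    gw = gwas.set_index("SNP")
    rows = []
    for pid in eligible:
        top = pick_top_mqtl(pid, mqtl, gwas)
        b_smr, se_smr, p_smr = smr_test(
            gw.loc[top["SNP"], "b"], gw.loc[top["SNP"], "se"], top["b"], top["se"]
        )
        passes_smr = bool(p_smr < threshold)
        p_heidi, n_heidi = float("nan"), 0
        if passes_smr:
            p_heidi, n_heidi = heidi_test(pid, mqtl, gwas, panel, top, heidi)
        if np.isnan(p_heidi):
            passes_heidi = bool(keep_unevaluable) if passes_smr else False
        else:
            passes_heidi = p_heidi >= HEIDI_RETAIN_LEVEL
        rows.append(
            {
                "ProbeID": pid,
                "Chr": top["ProbeChr"],
                "ProbePos": int(top["ProbeBp"]),
                "Gene": top["Gene"],
                "SNP": top["SNP"],
                "Pos": int(top["SnpBp"]),
                "A1": top["A1"],
                "Freq": float(top["Freq"]),
                "P_GWAS": float(gw.loc[top["SNP"], "p"]),
                "P_mQTL": float(top["p"]),
                "b_SMR": b_smr,
                "SE_SMR": se_smr,
                "P_SMR": p_smr,
                "P_HEIDI": p_heidi,
                "N_HEIDI": n_heidi,
                "passes_SMR": passes_smr,
                "passes_HEIDI": passes_heidi,
            }
        )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    counts = {
        "plan": plan,
        "n_probes": int(len(probes)),
        "n_eligible": int(len(eligible)),
        "bonferroni_denominator": int(denom),
        "smr_threshold": threshold,
        "n_smr_significant": int(results["passes_SMR"].sum()) if len(results) else 0,
        "n_heidi_retained": int((results["passes_SMR"] & results["passes_HEIDI"]).sum())
        if len(results)
        else 0,
    }
    if not eligible:
        logger.warning("plan %s: no eligible probes", plan)
    return results, counts
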