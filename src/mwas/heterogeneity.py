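"""Wald chi-square contrasts of SMR effects between strata or tissues.

The statistic for two independent estimates (b1, se1) and (b2, se2) is

    chi2 = (b1 - b2)^2 / (se1^2 + se2^2),   p = chi-square(1 df) tail,

used both for group-specific scans (males vs females, hypertensive vs
non-hypertensive) and for blood-vs-brain concordance checks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mwas.heterogeneity")

__all__ = ["wald_chisq_diff", "group_specific_scan", "cross_tissue_concordance"]


def wald_chisq_diff(b1, se1, b2, se2):
    """Wald chi-square for a difference of two independent effects."""
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    se1 = np.asarray(se1, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValueError("standard errors must be positive")
    chi2 = (b1 - b2) ** 2 / (se1**2 + se2**2)
    p = stats.chi2.sf(chi2, df=1)
    if chi2.ndim == 0:
        return float(chi2), float(p)
    return chi2, p


def _passing(results: pd.DataFrame) -> set[str]:
    return set(results.loc[results["passes_SMR"] & results["passes_HEIDI"], "ProbeID"])


def group_specific_scan(
    results_a: pd.DataFrame, results_b: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Flag probes whose SMR effects differ between two strata.

    Candidates are probes passing both SMR and HEIDI filters in exactly
    one group.  Each is compared against its (possibly non-significant)
    estimate in the other group; probes absent from the other group's
    tested set are skipped with a log entry.  The family size m is the
    candidate count and the flag threshold is ``alpha/m``.
    """
    sig_a, sig_b = _passing(results_a), _passing(results_b)
    candidates = sig_a ^ sig_b
    a_idx = results_a.set_index("ProbeID")
    b_idx = results_b.set_index("ProbeID")
    rows, skipped = [], 0
    for pid in sorted(candidates):
        if pid not in a_idx.index or pid not in b_idx.index:
            skipped += 1
            logger.warning("contrast: %s absent from one group's tested set; skipped", pid)
            continue
        ra, rb = a_idx.loc[pid], b_idx.loc[pid]
        rows.append(
            {
                "ProbeID": pid,
                "b1": float(ra["b_SMR"]), "se1": float(ra["SE_SMR"]),
                "b2": float(rb["b_SMR"]), "se2": float(rb["SE_SMR"]),
                "significant_in": "A" if pid in sig_a else "B",
            }
        )
    m = len(rows)
    threshold = alpha / m if m else float("nan")
    table = pd.DataFrame(
        rows, columns=["ProbeID", "b1", "se1", "b2", "se2", "significant_in"]
    )
    if m:
        chi2, p = wald_chisq_diff(table["b1"], table["se1"], table["b2"], table["se2"])
        table["chi2"] = chi2
        table["p"] = p
        table["group_specific"] = p < threshold
    else:
        table["chi2"] = table["p"] = np.nan
        table["group_specific"] = pd.Series(dtype=bool)
    summary = {
        "m": m,
        "threshold": threshold,
        "n_group_specific": int(table["group_specific"].sum()) if m else 0,
        "n_skipped": skipped,
    }
    return table, summary


def cross_tissue_concordance(
    blood: pd.DataFrame, brain: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Sign concordance and effect-difference rate across tissues.

    Probes are matched by id over the two analyses' tested sets; the
    comparison family size m is the shared-probe count and the
    difference threshold ``alpha/m``.
    """
    shared = blood.merge(brain, on="ProbeID", suffixes=("_blood", "_brain"))
    m = len(shared)
    if m == 0:
        return shared, {"m": 0, "sign_concordance": float("nan"),
                        "frac_different": float("nan"), "threshold": float("nan")}
    threshold = alpha / m
    chi2, p = wald_chisq_diff(
        shared["b_SMR_blood"], shared["SE_SMR_blood"],
        shared["b_SMR_brain"], shared["SE_SMR_brain"],
    )
    same_sign = np.sign(shared["b_SMR_blood"]) == np.sign(shared["b_SMR_brain"])
    table = shared[["ProbeID"]].copy()
    table["b_blood"] = shared["b_SMR_blood"]
    table["b_brain"] = shared["b_SMR_brain"]
    table["same_sign"] = same_sign
    table["chi2"] = chi2
    table["p"] = p
    table["different"] = p < threshold
    summary = {
        "m": m,
        "threshold": threshold,
        "sign_concordance": float(same_sign.mean()),
        "frac_different": float((p < threshold).mean()),
    }
    return table, summary
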