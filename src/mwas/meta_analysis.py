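"""Allele harmonization and fixed-effects inverse-variance meta-analysis.

Per-cohort GWAS effects are pooled with weights w_i = 1/se_i^2:
pooled beta = sum(w b)/sum(w), pooled se = sum(w)^(-1/2).  A SNP absent
from a cohort is pooled over the cohorts that report it; the count of
contributing cohorts is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import GWAS_COLUMNS, SnpAssoc

__all__ = [
    "HarmonizationError",
    "MetaResult",
    "harmonize_alleles",
    "harmonize_to_reference",
    "meta_fixed",
    "meta_analyze",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_FREQ_WINDOW = (0.4, 0.6)


class HarmonizationError(ValueError):
    """Allele sets of the same SNP cannot be reconciled."""


@dataclass(frozen=True)
class MetaResult:
    snp_id: str
    beta: float
    se: float
    z: float
    p: float
    n_cohorts: int


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_alleles(reference: SnpAssoc, other: SnpAssoc) -> SnpAssoc | None:
    """Align ``other`` to the reference record's effect allele.

    Returns the aligned record, or ``None`` when the SNP is a strand-
    ambiguous palindrome (A/T or C/G) with allele frequency in
    [0.4, 0.6] — such records are dropped.  Raises
    :class:`HarmonizationError` when the allele sets differ.
    """
    if reference.snp_id != other.snp_id:
        raise HarmonizationError(
            f"snp ids differ: {reference.snp_id} vs {other.snp_id}"
        )
    ra1, ra2 = reference.a1.upper(), reference.a2.upper()
    oa1, oa2 = other.a1.upper(), other.a2.upper()
    lo, hi = PALINDROMIC_FREQ_WINDOW
    if _is_palindromic(oa1, oa2) and lo <= other.freq_a1 <= hi:
        return None
    if (oa1, oa2) == (ra1, ra2):
        return other
    if (oa1, oa2) == (ra2, ra1):
        return SnpAssoc(
            snp_id=other.snp_id, a1=ra1, a2=ra2,
            freq_a1=1.0 - other.freq_a1, beta=-other.beta,
            se=other.se, p=other.p, n=other.n,
            chrom=other.chrom, pos=other.pos,
        )
    raise HarmonizationError(
        f"{other.snp_id}: incompatible allele pairs "
        f"({ra1},{ra2}) vs ({oa1},{oa2})"
    )


def harmonize_to_reference(reference: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Vectorized harmonization of a GWAS-dialect table to a reference table.

    SNPs absent from the reference pass through unchanged; incompatible
    allele pairs and ambiguous palindromes are dropped.
    """
    ref = reference.set_index("SNP")[["A1", "A2"]]
    df = other.copy()
    a1 = df["A1"].str.upper()
    a2 = df["A2"].str.upper()
    in_ref = df["SNP"].isin(ref.index)
    ra1 = df["SNP"].map(ref["A1"]).astype("string").str.upper()
    ra2 = df["SNP"].map(ref["A2"]).astype("string").str.upper()
    palindromic = a1.map(_COMPLEMENT).fillna("") == a2
    lo, hi = PALINDROMIC_FREQ_WINDOW
    ambiguous = palindromic & df["freq"].between(lo, hi)
    same = in_ref & (a1 == ra1) & (a2 == ra2)
    flipped = in_ref & (a1 == ra2) & (a2 == ra1)
    incompatible = in_ref & ~(same | flipped)
    df.loc[flipped, "b"] = -df.loc[flipped, "b"]
    df.loc[flipped, "freq"] = 1.0 - df.loc[flipped, "freq"]
    df.loc[flipped, "A1"] = ra2[flipped]
    df.loc[flipped, "A2"] = ra1[flipped]
    keep = ~(ambiguous | incompatible)
    return df.loc[keep].reset_index(drop=True)


def meta_fixed(effects: Sequence[tuple[float, float]], snp_id: str = "") -> MetaResult:
    """Fixed-effects inverse-variance pooling of (beta, se) pairs."""
    if len(effects) == 0:
        raise ValueError("meta_fixed requires at least one effect")
    betas = np.array([b for b, _ in effects], dtype=float)
    ses = np.array([s for _, s in effects], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(snp_id, beta, se, z, p, len(effects))


def meta_analyze(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-cohort GWAS-dialect tables into one meta-analysis table.

    Alleles are harmonized to the first table carrying each SNP.  The
    output keeps the GWAS dialect (so it can feed the SMR stage
    directly) plus a ``n_cohorts`` column.
    """
    if not tables:
        raise ValueError("no cohort tables supplied")
    harmonized = [tables[0]]
    for t in tables[1:]:
        harmonized.append(harmonize_to_reference(tables[0], t))
    stacked = pd.concat(harmonized, keys=range(len(harmonized)), names=["cohort"])
    rows = []
    for snp, grp in stacked.groupby("SNP", sort=False):
        res = meta_fixed(list(zip(grp["b"], grp["se"])), snp_id=snp)
        first = grp.iloc[0]
        rows.append(
            {
                "SNP": snp, "A1": first["A1"], "A2": first["A2"],
                "freq": float(np.mean(grp["freq"])),
                "b": res.beta, "se": res.se, "p": res.p,
                "n": float(grp["n"].sum()), "n_cohorts": res.n_cohorts,
            }
        )
    return pd.DataFrame(rows, columns=GWAS_COLUMNS + ["n_cohorts"])
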