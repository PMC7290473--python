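"""Competitive gene-set enrichment of per-gene association scores.

Each gene receives the best (maximum) -log10 SMR p-value over its
probes.  A pathway's z-score compares the mean score of its genes with
the population mean, scaled by the population SD over sqrt(count):

    z = (mean_set - mean_all) / (sd_all / sqrt(count)),

with a one-sided upper-tail normal p.  Benjamini-Hochberg q-values
follow, and the reporting FDR level is chosen so that the expected
number of false positives, q * (#pathways at q), stays below one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "gene_score",
    "pathway_z",
    "enrich",
    "bh_fdr",
    "select_fdr_level",
]

FDR_GRID = (0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    source: str
    size: int
    count: int
    z: float
    p: float


def gene_score(results: pd.DataFrame) -> pd.Series:
    """Per-gene score: max -log10 P_SMR over the gene's probes."""
    df = results.loc[results["Gene"].notna() & (results["Gene"] != "")]
    scores = -np.log10(df["P_SMR"].astype(float).clip(lower=1e-300))
    return scores.groupby(df["Gene"].map(lambda g: str(g).strip().upper())).max()


def pathway_z(scores: pd.Series, gene_set, name: str = "", source: str = "") -> EnrichmentResult:
    """Competitive z-score of one gene set against the scored population."""
    if len(scores) < 2:
        raise ValueError("need at least 2 scored genes")
    members = {str(g).strip().upper() for g in gene_set}
    in_set = scores.index.isin(members)
    count = int(in_set.sum())
    if count < 1:
        raise ValueError(f"gene set {name!r} has no scored genes")
    sd = float(scores.std(ddof=0))  # population SD
    if sd == 0:
        return EnrichmentResult(name, source, len(members), count, 0.0, 0.5)
    z = (float(scores[in_set].mean()) - float(scores.mean())) / (sd / np.sqrt(count))
    return EnrichmentResult(name, source, len(members), count, z, float(stats.norm.sf(z)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(scores: pd.Series, gene_sets) -> pd.DataFrame:
    """Score every gene set; skip sets with no scored genes.

    ``gene_sets`` is a sequence of (name, source, genes) triples as
    returned by :func:`mwas.summary_io.read_gene_sets`.
    """
    rows = []
    for name, source, genes in gene_sets:
        try:
            res = pathway_z(scores, genes, name=name, source=source)
        except ValueError:
            continue
        rows.append(res.__dict__)
    df = pd.DataFrame(rows, columns=["pathway", "source", "size", "count", "z", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def select_fdr_level(q_values, grid=FDR_GRID) -> tuple[float | None, list[float]]:
    """Choose the reporting FDR level from a grid.

    A level q is admissible when q * counts(q) < 1, where counts(q) is
    the number of pathways with q-value <= q (so the expected number of
    false positives stays below one).  Returns (chosen, admissible):
    the chosen level is the largest admissible one, or None when no
    level is admissible.
    """
    q = np.asarray(q_values, dtype=float)
    admissible = [level for level in grid if level * int((q <= level).sum()) < 1.0]
    chosen = max(admissible) if admissible else None
    return chosen, admissible
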