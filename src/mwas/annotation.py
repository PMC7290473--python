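"""Probe-to-gene assignment, catalog locus classification, list overlap.

Probes inside a gene body or within 1.5 kb of a transcription start site
are annotated to that gene; intergenic probes go to the nearest gene by
TSS distance.  Loci are classified against an association catalog within
a window: G (genome-wide, p < 5e-8), S (suggestive, 5e-8 <= p < 5e-6) or
N (none) — strict inequalities, so p exactly 5e-8 is S and exactly 5e-6
is N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneAssignment",
    "LocusClassification",
    "assign_probe_gene",
    "classify_locus",
    "overlap_genes",
]

TSS_WINDOW = 1_500
GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 5e-6
CATALOG_WINDOW = 1_000_000


@dataclass(frozen=True)
class GeneAssignment:
    probe_id: str
    gene: str
    assignment_class: str  # gene_body | tss1500 | igr_nearest | unassigned


@dataclass(frozen=True)
class LocusClassification:
    probe_id: str
    window: int
    locus_class: str  # N | G | S
    n_supporting: int


def assign_probe_gene(
    probe, gene_models: pd.DataFrame, metric: str = "tss"
) -> GeneAssignment:
    """Assign a probe to a gene.

    ``probe`` carries ProbeID/ProbeChr/ProbeBp (mapping or Series).
    ``metric`` selects the intergenic distance: "tss" (default) or
    "boundary" (distance to the nearest gene edge).
    """
    pid, chrom, pos = probe["ProbeID"], probe["ProbeChr"], int(probe["ProbeBp"])
    genes = gene_models.loc[gene_models["chrom"].astype(str) == str(chrom)]
    if genes.empty:
        return GeneAssignment(pid, "", "unassigned")
    tss_dist = (genes["tss"] - pos).abs()
    in_body = (genes["start"] <= pos) & (pos <= genes["end"])
    near_tss = tss_dist <= TSS_WINDOW
    hits = genes.loc[in_body | near_tss]
    if not hits.empty:
        best = tss_dist.loc[hits.index].idxmin()  # closest TSS wins ties
        cls = "gene_body" if in_body.loc[best] else "tss1500"
        return GeneAssignment(pid, genes.loc[best, "gene"], cls)
    if metric == "boundary":
        dist = np.maximum(genes["start"] - pos, 0) + np.maximum(pos - genes["end"], 0)
    else:
        dist = tss_dist
    best = dist.idxmin()
    return GeneAssignment(pid, genes.loc[best, "gene"], "igr_nearest")


def classify_locus(
    probe, catalog: pd.DataFrame, window: int = CATALOG_WINDOW
) -> LocusClassification:
    """Classify a probe's locus by nearby catalog associations."""
    pid, chrom, pos = probe["ProbeID"], probe["ProbeChr"], int(probe["ProbeBp"])
    if catalog.empty:
        return LocusClassification(pid, window, "N", 0)
    near = catalog.loc[
        (catalog["Chr"].astype(str) == str(chrom))
        & ((catalog["Bp"] - pos).abs() <= window)
    ]
    genome_wide = near.loc[near["p"] < GENOME_WIDE_P]
    if not genome_wide.empty:
        return LocusClassification(pid, window, "G", len(genome_wide))
    suggestive = near.loc[(near["p"] >= GENOME_WIDE_P) & (near["p"] < SUGGESTIVE_P)]
    if not suggestive.empty:
        return LocusClassification(pid, window, "S", len(suggestive))
    return LocusClassification(pid, window, "N", 0)


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


def overlap_genes(mwa_genes, twa_genes) -> pd.DataFrame:
    """Genes significant in both analyses, after symbol normalization.

    Inputs are iterables of gene symbols or of (symbol, provenance)
    pairs; provenance strings are carried through when given.
    """

    def to_map(genes):
        out: dict[str, list[str]] = {}
        for g in genes:
            if isinstance(g, (tuple, list)):
                sym, prov = _norm(g[0]), str(g[1])
            else:
                sym, prov = _norm(g), ""
            out.setdefault(sym, [])
            if prov:
                out[sym].append(prov)
        return out

    a, b = to_map(mwa_genes), to_map(twa_genes)
    shared = sorted(set(a) & set(b))
    return pd.DataFrame(
        {
            "gene": shared,
            "mwa_provenance": [";".join(a[g]) for g in shared],
            "twa_provenance": [";".join(b[g]) for g in shared],
        }
    )
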