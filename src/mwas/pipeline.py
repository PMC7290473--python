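"""End-to-end orchestration of the five analysis plans.

A :class:`PlanSpec` names the per-cohort GWAS tables, the mQTL study,
the LD panel and thresholds for one plan (all / males / females /
hypertensive / non-hypertensive).  :func:`run_plan` chains
meta-analysis -> eligibility -> SMR -> HEIDI -> annotation ->
enrichment and writes every stage's table plus a filter-count log and
an input-checksum manifest, so a bundle is a pure function of
(inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation as ann
from . import enrichment as enr
from . import summary_io as sio
from .heterogeneity import group_specific_scan
from .meta_analysis import meta_analyze
from .smr_heidi import HeidiConfig, run_mwas
from .synthetic_data import LdPanel

logger = logging.getLogger("mwas.pipeline")

__all__ = ["PlanSpec", "run_plan", "run_contrast"]

PLAN_IDS = ("all", "males", "females", "htn", "no_htn")
CONTRAST_PAIRS = {"males": "females", "females": "males", "htn": "no_htn", "no_htn": "htn"}


@dataclass
class PlanSpec:
    plan: str
    cohort_files: list[str]
    mqtl_file: str
    panel_file: str
    out_dir: str
    tissue: str = "blood"
    alpha: float = 0.05
    p_mqtl_threshold: float = 5e-8
    heidi_retain_level: float = 0.05
    bonferroni_denominator: int | None = None  # None -> realized eligible count
    gene_models_file: str | None = None
    catalog_file: str | None = None
    gene_sets_file: str | None = None

    def __post_init__(self):
        if self.plan not in PLAN_IDS:
            raise ValueError(f"unknown plan {self.plan!r}; expected one of {PLAN_IDS}")
        if self.tissue not in ("blood", "brain"):
            raise ValueError("tissue must be 'blood' or 'brain'")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_plan(spec: PlanSpec) -> dict:
    """Run one analysis plan end to end; returns the result bundle."""
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = [*spec.cohort_files, spec.mqtl_file, spec.panel_file]
    for opt in (spec.gene_models_file, spec.catalog_file, spec.gene_sets_file):
        if opt:
            inputs.append(opt)
    manifest = {str(p): _sha256(p) for p in inputs}

    cohorts = [sio.read_gwas_table(p) for p in spec.cohort_files]
    gwas = meta_analyze(cohorts)
    probes, mqtl = sio.read_mqtl_table(spec.mqtl_file)
    panel_meta, panel_dos = sio.read_panel(spec.panel_file)
    panel = LdPanel(meta=panel_meta, dosages=panel_dos)

    results, counts = run_mwas(
        spec.plan, gwas, probes, mqtl, panel,
        alpha=spec.alpha,
        bonferroni_denominator=spec.bonferroni_denominator,
        p_mqtl_threshold=spec.p_mqtl_threshold,
        heidi=HeidiConfig(),
    )

    if spec.gene_models_file:
        models = sio.read_gene_models(spec.gene_models_file)
        assignments = [
            ann.assign_probe_gene(
                {"ProbeID": r["ProbeID"], "ProbeChr": r["Chr"], "ProbeBp": r["ProbePos"]},
                models,
            )
            for _, r in results.iterrows()
        ]
        results["Gene"] = [a.gene for a in assignments]
        results["GeneClass"] = [a.assignment_class for a in assignments]
    annotation_table = None
    if spec.catalog_file:
        catalog = sio.read_catalog(spec.catalog_file)
        classes = [
            ann.classify_locus(
                {"ProbeID": r["ProbeID"], "ProbeChr": r["Chr"], "ProbeBp": r["ProbePos"]},
                catalog,
            )
            for _, r in results.iterrows()
        ]
        annotation_table = pd.DataFrame(
            {
                "ProbeID": [c.probe_id for c in classes],
                "Current": [c.locus_class for c in classes],
                "n_supporting": [c.n_supporting for c in classes],
            }
        )
        annotation_table.to_csv(out / "annotation.tsv", sep="\t", index=False)

    enrichment_table = None
    if spec.gene_sets_file and len(results):
        scores = enr.gene_score(results)
        if len(scores) >= 2:
            sets = sio.read_gene_sets(spec.gene_sets_file)
            enrichment_table = enr.enrich(scores, sets)
            enrichment_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    sio.write_results(results, out / "results.tsv")
    gwas.to_csv(out / "gwas_meta.tsv", sep="\t", index=False)
    with open(out / "counts.json", "w") as fh:
        json.dump(counts, fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "results": results,
        "counts": counts,
        "annotation": annotation_table,
        "enrichment": enrichment_table,
        "manifest": manifest,
    }


def run_contrast(results_a: pd.DataFrame, results_b: pd.DataFrame,
                 tissue_a: str = "blood", tissue_b: str = "blood",
                 out_path=None, alpha: float = 0.05) -> dict:
    """Group contrast of two completed plans on the same tissue."""
    if tissue_a != tissue_b:
        raise ValueError(f"tissue mismatch: {tissue_a} vs {tissue_b}")
    table, summary = group_specific_scan(results_a, results_b, alpha=alpha)
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write(f"# m={summary['m']} threshold={summary['threshold']:.6g}\n")
            table.to_csv(fh, sep="\t", index=False)
    return {"table": table, "summary": summary}
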