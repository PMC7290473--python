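"""Readers and writers for every tabular dialect the pipeline touches.

All coordinates inside the pipeline are 1-based inclusive; the BED
converters below are the only place a 0-based half-open convention
appears.  Readers validate row by row: invalid rows are dropped and
logged with their line number, unless ``strict=True`` in which case the
first violation raises :class:`FormatError`.

Dialects
--------
GWAS summary ("ma"-style):   SNP A1 A2 freq b se p n
mQTL flat table:             ProbeID ProbeChr ProbeBp Gene Orientation
                             SNP SnpChr SnpBp A1 A2 Freq b se p n
LD panel:                    SNP Chr Bp A1 A2 then one dosage column per
                             individual (values in {0,1,2})
catalog:                     SNP Chr Bp p source
gene models:                 BED6 (chrom start end name score strand)
gene sets:                   GMT (name, source, tab-separated genes)
results:                     ProbeID Chr ProbePos Gene SNP Pos A1 Freq
                             P_GWAS P_mQTL b_SMR SE_SMR P_SMR P_HEIDI
                             N_HEIDI passes_SMR passes_HEIDI
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mwas.io")

GWAS_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "n"]
MQTL_COLUMNS = [
    "ProbeID", "ProbeChr", "ProbeBp", "Gene", "Orientation",
    "SNP", "SnpChr", "SnpBp", "A1", "A2", "Freq", "b", "se", "p", "n",
]
CATALOG_COLUMNS = ["SNP", "Chr", "Bp", "p", "source"]
RESULT_COLUMNS = [
    "ProbeID", "Chr", "ProbePos", "Gene", "SNP", "Pos", "A1", "Freq",
    "P_GWAS", "P_mQTL", "b_SMR", "SE_SMR", "P_SMR", "P_HEIDI", "N_HEIDI",
    "passes_SMR", "passes_HEIDI",
]

DEFAULT_CIS_WINDOW = 2_000_000


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass(frozen=True)
class SnpAssoc:
    """One SNP association record (GWAS or mQTL role)."""

    snp_id: str
    a1: str
    a2: str
    freq_a1: float
    beta: float
    se: float
    p: float
    n: float
    chrom: str | None = None
    pos: int | None = None


@dataclass(frozen=True)
class ProbeInfo:
    probe_id: str
    chrom: str
    pos: int
    gene: str = ""
    orientation: str = "+"


@dataclass(frozen=True)
class CatalogEntry:
    snp_id: str
    chrom: str
    pos: int
    p: float
    source: str = ""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _assoc_row_error(row) -> str | None:
    """Return a rejection reason for an association row, or None if valid."""
    if str(row["A1"]).upper() == str(row["A2"]).upper():
        return "a1 == a2"
    freq = row.get("freq", row.get("Freq"))
    if not (0.0 < freq < 1.0):
        return "freq outside (0,1)"
    if not (row["se"] > 0):
        return "non-positive se"
    if not (0.0 < row["p"] <= 1.0):
        return "p outside (0,1]"
    if not (row["n"] >= 1):
        return "n < 1"
    return None


def _warn_p_inconsistency(df: pd.DataFrame, path) -> None:
    with np.errstate(divide="ignore", invalid="ignore"):
        p_chk = stats.chi2.sf((df["b"] / df["se"]) ** 2, df=1)
    bad = (df["p"] > 2 * np.maximum(p_chk, 1e-300)) | (df["p"] < p_chk / 2)
    # chi-square p of 0 underflows for huge z; skip those
    bad &= p_chk > 0
    if bad.any():
        logger.warning(
            "%s: %d row(s) with p inconsistent with (b/se)^2 beyond a factor of 2",
            path, int(bad.sum()),
        )


def _drop_invalid(df: pd.DataFrame, path, strict: bool) -> pd.DataFrame:
    keep = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        reason = _assoc_row_error(row)
        if reason is not None:
            if strict:
                raise FormatError(f"{path}: line {i + 2}: {reason}")
            logger.warning("%s: line %d rejected (%s)", path, i + 2, reason)
            keep[i] = False
    return df.loc[keep].reset_index(drop=True)


def _read_table(path, columns, numeric, path_label=None) -> pd.DataFrame:
    label = path_label or path
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{label}: unreadable ({exc})") from exc
    _require_columns(df, columns, label)
    df = df[list(columns)].copy()
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            for line in (np.flatnonzero(bad.to_numpy()) + 2)[:20]:
                logger.warning("%s: line %d non-numeric %s", label, line, col)
        df[col] = converted
    df = df.dropna(subset=list(numeric)).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# GWAS summary tables

def read_gwas_table(path, strict: bool = False) -> pd.DataFrame:
    """Read an "ma"-style GWAS summary table; validate each row."""
    df = _read_table(path, GWAS_COLUMNS, ["freq", "b", "se", "p", "n"])
    df = _drop_invalid(df, path, strict)
    _warn_p_inconsistency(df, path)
    return df


def write_gwas_table(df: pd.DataFrame, path) -> None:
    df[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mQTL flat tables

def read_mqtl_table(
    path, cis_window: int = DEFAULT_CIS_WINDOW, strict: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the flat mQTL dialect.

    Returns
    -------
    probes : DataFrame with columns ProbeID ProbeChr ProbeBp Gene Orientation
    records : DataFrame with one row per probe-SNP pair (all mQTL columns)
    """
    df = _read_table(
        path, MQTL_COLUMNS,
        ["ProbeBp", "SnpBp", "Freq", "b", "se", "p", "n"],
    )
    df = df.rename(columns={"Freq": "freq"})
    df = _drop_invalid(df, path, strict)
    df = df.rename(columns={"freq": "Freq"})
    # cis constraint: same chromosome, within the window
    non_cis = (df["ProbeChr"] != df["SnpChr"]) | (
        (df["SnpBp"] - df["ProbeBp"]).abs() > cis_window
    )
    if non_cis.any():
        if strict:
            raise FormatError(f"{path}: {int(non_cis.sum())} non-cis record(s)")
        for line in (np.flatnonzero(non_cis.to_numpy()) + 2)[:20]:
            logger.warning("%s: line %d rejected (non-cis)", path, line)
        df = df.loc[~non_cis].reset_index(drop=True)
    df["ProbeBp"] = df["ProbeBp"].astype(int)
    df["SnpBp"] = df["SnpBp"].astype(int)
    probes = (
        df[["ProbeID", "ProbeChr", "ProbeBp", "Gene", "Orientation"]]
        .drop_duplicates("ProbeID")
        .reset_index(drop=True)
    )
    return probes, df


def write_mqtl_table(records: pd.DataFrame, path) -> None:
    records[MQTL_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD reference panel

def read_panel(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a panel TSV.  Returns (snp metadata, dosage matrix n x m)."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "Chr": str, "A1": str, "A2": str})
    _require_columns(df, ["SNP", "Chr", "Bp", "A1", "A2"], path)
    meta = df[["SNP", "Chr", "Bp", "A1", "A2"]].copy()
    if meta["SNP"].duplicated().any():
        raise FormatError(f"{path}: duplicate SNP ids in panel")
    dosage_cols = [c for c in df.columns if c not in meta.columns]
    dosages = df[dosage_cols].to_numpy(dtype=np.int8).T  # individuals x SNPs
    if not np.isin(dosages, (0, 1, 2)).all():
        raise FormatError(f"{path}: dosages must be 0/1/2")
    return meta, dosages


def write_panel(meta: pd.DataFrame, dosages: np.ndarray, path) -> None:
    dos = pd.DataFrame(
        dosages.T, columns=[f"ind{i + 1}" for i in range(dosages.shape[0])]
    )
    out = pd.concat([meta[["SNP", "Chr", "Bp", "A1", "A2"]].reset_index(drop=True), dos], axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (BED), gene sets (GMT), association catalog

def read_gene_models(path, strict: bool = False) -> pd.DataFrame:
    """Read a BED6 gene-model file into 1-based inclusive coordinates.

    The TSS is the ``start`` for '+' strand genes and ``end`` for '-'.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                msg = f"{path}: line {lineno}: expected 6 BED columns"
                if strict:
                    raise FormatError(msg)
                logger.warning(msg)
                continue
            chrom, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if end <= start:
                msg = f"{path}: line {lineno}: end <= start"
                if strict:
                    raise FormatError(msg)
                logger.warning(msg)
                continue
            rows.append((name, chrom, start + 1, end, strand, score))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand", "score"])
    df["tss"] = np.where(df["strand"] == "-", df["end"], df["start"])
    return df


def write_gene_models(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r['gene']}\t"
                f"{r.get('score', 0)}\t{r['strand']}\n"
            )


def read_gene_sets(path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT file: (set name, source/description, gene list) per line."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: truncated GMT line")
            name, source, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                logger.warning("%s: line %d: empty gene set %r kept", path, lineno, name)
            sets.append((name, source, genes))
    return sets


def write_gene_sets(sets, path) -> None:
    with open(path, "w") as fh:
        for name, source, genes in sets:
            fh.write("\t".join([name, source, *genes]) + "\n")


def read_catalog(path, strict: bool = False) -> pd.DataFrame:
    df = _read_table(path, CATALOG_COLUMNS, ["Bp", "p"])
    bad = ~((df["p"] > 0) & (df["p"] <= 1))
    if bad.any():
        if strict:
            raise FormatError(f"{path}: {int(bad.sum())} row(s) with p outside (0,1]")
        for line in (np.flatnonzero(bad.to_numpy()) + 2)[:20]:
            logger.warning("%s: line %d rejected (p outside (0,1])", path, line)
        df = df.loc[~bad].reset_index(drop=True)
    df["Bp"] = df["Bp"].astype(int)
    return df


def write_catalog(df: pd.DataFrame, path) -> None:
    df[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results tables

def write_results(df: pd.DataFrame, path) -> None:
    df[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    _require_columns(df, RESULT_COLUMNS, path)
    return df
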