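"""Synthetic LD panels, cis-mQTL summaries and case-control GWAS summaries.

Every downstream stage of the pipeline consumes only summary statistics,
so the generator emulates the *summary-level* consequences of four causal
structures around a methylation probe:

``null``
    cis SNPs drive methylation (when ``beta_zx`` > 0) but neither
    methylation nor any cis SNP affects disease.
``pleiotropy``
    one causal SNP drives methylation, and disease risk depends on the
    genetically driven methylation component (log-odds ``b_xy`` per
    methylation unit) — the single-locus structure the SMR test is
    designed to detect and the HEIDI filter should retain.
``linkage``
    one SNP drives methylation while a *different* SNP in LD carries a
    direct disease effect — the structure the HEIDI filter should reject.
``group_heterogeneity``
    pleiotropy whose disease effect is multiplied by ``group_ratio`` in
    group B cohorts, for testing stratified contrasts.

Genotypes follow a latent-Gaussian AR(1) model: each haplotype is a
first-order autoregressive Gaussian vector with adjacent correlation
``ld_rho``, thresholded at the allele-frequency quantile; summing two
independent haplotypes yields Hardy-Weinberg dosages in {0,1,2}.
Thresholding attenuates the latent correlation, so the realized
genotype r is below ``ld_rho`` (the Monte-Carlo tests quantify this).

All randomness flows from ``ScenarioConfig.seed`` through a documented
splitting scheme: stage streams are ``default_rng((seed, STAGE, index))``
with STAGE offsets 0 (panel), 1 (mQTL), 2 (GWAS cohorts), so each stage
is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import GWAS_COLUMNS, MQTL_COLUMNS

logger = logging.getLogger("mwas.synthetic")

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "LdPanel",
    "gen_reference_panel",
    "gen_mqtl_summary",
    "gen_gwas_cohorts",
    "simulate_study",
    "write_truth_table",
]

SCENARIOS = ("null", "pleiotropy", "linkage", "group_heterogeneity")

_STAGE_PANEL = 0
_STAGE_MQTL = 1
_STAGE_GWAS = 2

# non-palindromic allele pairs assigned to simulated SNPs
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))

_BLOCK_SPACING = 10_000_000  # bp between probe LD blocks (>> cis window)
_SNP_SPACING = 2_000  # bp between adjacent cis SNPs


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the source study's summary-level layout at desk
    scale: a blood mQTL study of 1980 subjects, four case-control
    cohorts totalling roughly 2700 cases and 14700 controls, and a
    reference panel of 2000 individuals for LD estimation.  Causal
    effect sizes are calibration choices (the study reports none).
    """

    scenario: str = "pleiotropy"
    n_ref: int = 2000
    n_mqtl: int = 1980
    cohort_sizes: tuple[tuple[int, int], ...] = (
        (685, 3685), (685, 3685), (685, 3685), (686, 3684),
    )
    m_snps: int = 20
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    beta_zx: float = 0.5
    b_xy: float = 0.4
    group_ratio: float = 0.0
    n_probes: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho <= 0.99):
            raise ConfigError("ld_rho must be in [0, 0.99]")
        if self.n_ref < 2 or self.n_mqtl < 2:
            raise ConfigError("sample sizes must be >= 2")
        if any(nc < 2 or nk < 2 for nc, nk in self.cohort_sizes):
            raise ConfigError("cohort sizes must be >= 2")
        if self.m_snps < 1 or self.n_probes < 1:
            raise ConfigError("m_snps and n_probes must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Known ground truth for one simulated probe."""

    probe_id: str
    causal_snps: tuple[int, ...]  # column indices within the probe's block
    beta_zx: float
    b_xy_group_a: float
    b_xy_group_b: float
    scenario: str


@dataclass
class LdPanel:
    """Reference genotypes: SNP metadata plus an individuals x SNPs matrix."""

    meta: pd.DataFrame  # SNP Chr Bp A1 A2 (+ maf used for generation)
    dosages: np.ndarray

    def __post_init__(self):
        if self.meta["SNP"].duplicated().any():
            raise ConfigError("duplicate SNP ids in panel")
        bp = self.meta["Bp"].to_numpy()
        if np.any(np.diff(bp) <= 0):
            raise ConfigError("panel positions must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def ld_r(self, top_index: int) -> np.ndarray:
        """Pearson dosage correlation of every panel SNP with one SNP."""
        g = self.dosages.astype(float)
        g = g - g.mean(axis=0)
        denom = np.sqrt((g**2).sum(axis=0) * (g[:, top_index] ** 2).sum())
        return g.T @ g[:, top_index] / denom


def _rng(config: ScenarioConfig, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng((config.seed, stage, index))


def _ar1_haplotypes(rng, n_hap: int, m: int, rho: float) -> np.ndarray:
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return z


def _genotypes(rng, n: int, mafs: np.ndarray, rho: float) -> np.ndarray:
    """Dosage matrix n x m under the latent-Gaussian AR(1) HWE model."""
    m = len(mafs)
    thresh = stats.norm.ppf(mafs)
    h1 = _ar1_haplotypes(rng, n, m, rho) < thresh
    h2 = _ar1_haplotypes(rng, n, m, rho) < thresh
    return (h1.astype(np.int8) + h2.astype(np.int8))


def _block_snp_meta(rng, config: ScenarioConfig, probe_index: int) -> pd.DataFrame:
    base = _BLOCK_SPACING * (probe_index + 1)
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), config.m_snps)]
    return pd.DataFrame(
        {
            "SNP": [f"rs{probe_index:03d}{j:04d}" for j in range(config.m_snps)],
            "Chr": "1",
            "Bp": base + _SNP_SPACING * np.arange(config.m_snps),
            "A1": [p[0] for p in pairs],
            "A2": [p[1] for p in pairs],
        }
    )


def probe_id(probe_index: int) -> str:
    return f"cg{probe_index:06d}"


def probe_position(probe_index: int, config: ScenarioConfig) -> int:
    """Probe sits at the centre of its block."""
    base = _BLOCK_SPACING * (probe_index + 1)
    return base + _SNP_SPACING * (config.m_snps // 2) + 137


LINKAGE_TARGET_R = 0.5


def causal_indices(config: ScenarioConfig, panel: LdPanel | None = None) -> tuple[int, ...]:
    """Deterministic causal SNP index/indices for a block.

    The methylation-causal SNP is the central one.  Under linkage the
    disease-causal SNP is the distinct SNP whose *realized* panel
    dosage correlation with the first is closest to 0.5 (thresholding
    attenuates the latent AR(1) correlation, so the latent rho is a
    poor guide); without a panel, the latent decay is used.
    """
    if config.scenario != "linkage":
        if panel is not None:
            return (panel.dosages.shape[1] // 2,)
        return (config.m_snps // 2,)
    if config.m_snps < 2:
        raise ConfigError("linkage scenario needs at least 2 cis SNPs")
    if panel is not None:
        m = panel.dosages.shape[1]
        c1 = m // 2
        r = panel.ld_r(c1)
        r[c1] = np.inf  # exclude self
        c2 = int(np.argmin(np.abs(np.abs(r) - LINKAGE_TARGET_R)))
        return (c1, c2)
    c1 = config.m_snps // 2
    if config.ld_rho <= 0:
        offset = 1
    else:
        offset = max(1, round(np.log(LINKAGE_TARGET_R) / np.log(config.ld_rho)))
    c2 = min(config.m_snps - 1, c1 + offset)
    if c2 == c1:
        c2 = c1 - 1
    return (c1, c2)


def gen_reference_panel(config: ScenarioConfig, probe_index: int = 0) -> LdPanel:
    """Generate the LD reference panel for one probe's cis block.

    Monomorphic SNPs are redrawn up to 10 times, then excluded.
    """
    rng = _rng(config, _STAGE_PANEL, probe_index)
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, config.m_snps)
    dos = _genotypes(rng, config.n_ref, mafs, config.ld_rho)
    for _ in range(10):
        mono = (dos.min(axis=0) == dos.max(axis=0))
        if not mono.any():
            break
        dos[:, mono] = _genotypes(rng, config.n_ref, mafs[mono], 0.0)
    mono = (dos.min(axis=0) == dos.max(axis=0))
    meta = _block_snp_meta(rng, config, probe_index)
    meta["maf"] = mafs
    if mono.any():
        logger.warning("panel: excluding %d monomorphic SNP(s)", int(mono.sum()))
        meta = meta.loc[~mono].reset_index(drop=True)
        dos = dos[:, ~mono]
    return LdPanel(meta=meta, dosages=dos)


def _marginal_ols(G: np.ndarray, y: np.ndarray):
    """Per-SNP simple-regression beta, se and two-sided p (vectorized)."""
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    beta = gc.T @ yc / sxx
    resid_ss = (yc**2).sum() - beta**2 * sxx
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df=n - 2)
    return beta, se, np.clip(p, 1e-300, 1.0)


def gen_mqtl_summary(
    panel: LdPanel, config: ScenarioConfig, probe_index: int = 0
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate the probe's methylation trait and per-SNP marginal effects.

    Methylation y = beta_zx * g_causal + N(0,1) for ``n_mqtl`` fresh
    individuals from the same LD model.  Returns the mQTL flat table
    (one row per cis SNP) and the probe's :class:`TruthRecord`.
    """
    rng = _rng(config, _STAGE_MQTL, probe_index)
    mafs = panel.meta["maf"].to_numpy() if "maf" in panel.meta else 2 * panel.maf()
    G = _genotypes(rng, config.n_mqtl, mafs, config.ld_rho)
    causal = causal_indices(config, panel)
    y = config.beta_zx * G[:, causal[0]] + rng.standard_normal(config.n_mqtl)
    poly = G.min(axis=0) != G.max(axis=0)
    if not poly.all():
        logger.warning(
            "mqtl: dropping %d monomorphic SNP(s) in simulated sample",
            int((~poly).sum()),
        )
    beta, se, p = _marginal_ols(G[:, poly].astype(float), y.astype(float))
    meta = panel.meta.loc[poly].reset_index(drop=True)
    pid = probe_id(probe_index)
    records = pd.DataFrame(
        {
            "ProbeID": pid,
            "ProbeChr": meta["Chr"],
            "ProbeBp": probe_position(probe_index, config),
            "Gene": "NA",
            "Orientation": "+",
            "SNP": meta["SNP"],
            "SnpChr": meta["Chr"],
            "SnpBp": meta["Bp"],
            "A1": meta["A1"],
            "A2": meta["A2"],
            "Freq": G[:, poly].mean(axis=0) / 2.0,
            "b": beta,
            "se": se,
            "p": p,
            "n": config.n_mqtl,
        }
    )[MQTL_COLUMNS]
    b_a = config.b_xy if config.scenario in ("pleiotropy", "linkage", "group_heterogeneity") else 0.0
    b_b = b_a * config.group_ratio if config.scenario == "group_heterogeneity" else b_a
    if config.scenario == "null":
        b_a = b_b = 0.0
    truth = TruthRecord(
        probe_id=pid,
        causal_snps=causal,
        beta_zx=config.beta_zx,
        b_xy_group_a=b_a,
        b_xy_group_b=b_b,
        scenario=config.scenario,
    )
    return records, truth


def _logistic_wald(G: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-10):
    """Per-SNP logistic regression (intercept + dosage) by IRLS, vectorized.

    Returns (beta, se, p, ok) where ``ok`` flags converged, separation-free
    fits.
    """
    n, m = G.shape
    a = np.zeros(m)
    ybar = y.mean()
    a[:] = np.log(ybar / (1.0 - ybar))
    b = np.zeros(m)
    ok = np.ones(m, dtype=bool)
    yv = y[:, None]
    for _ in range(max_iter):
        eta = a[None, :] + b[None, :] * G
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        r = yv - mu
        g0 = r.sum(axis=0)
        g1 = (r * G).sum(axis=0)
        s0 = w.sum(axis=0)
        s1 = (w * G).sum(axis=0)
        s2 = (w * G * G).sum(axis=0)
        det = s0 * s2 - s1 * s1
        bad = det <= 1e-12
        ok &= ~bad
        det = np.where(bad, 1.0, det)
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        a += np.where(ok, da, 0.0)
        b += np.where(ok, db, 0.0)
        if np.max(np.abs(np.concatenate([da[ok], db[ok]])) if ok.any() else [0.0]) < tol:
            break
    ok &= np.abs(b) < 10.0  # separation / divergence guard
    eta = a[None, :] + b[None, :] * G
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    s0 = w.sum(axis=0)
    s1 = (w * G).sum(axis=0)
    s2 = (w * G * G).sum(axis=0)
    det = np.maximum(s0 * s2 - s1 * s1, 1e-300)
    se = np.sqrt(s0 / det)
    z = np.divide(b, se, out=np.zeros_like(b), where=se > 0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return b, se, p, ok


def gen_gwas_cohorts(
    panel: LdPanel,
    config: ScenarioConfig,
    truth: TruthRecord,
    group: str = "A",
    probe_index: int = 0,
) -> list[pd.DataFrame]:
    """Simulate per-cohort case-control GWAS summary tables.

    Disease status follows a logistic model whose linear predictor is
    ``b_xy * (beta_zx * g_causal)`` under pleiotropy (the genetically
    driven methylation component), a direct per-allele effect ``b_xy``
    of the second causal SNP under linkage, or zero under null.  Cases
    and controls are then ascertained to the configured counts and
    per-SNP logistic Wald statistics computed by IRLS.
    """
    mafs = panel.meta["maf"].to_numpy() if "maf" in panel.meta else 2 * panel.maf()
    b_eff = truth.b_xy_group_b if group.upper() == "B" else truth.b_xy_group_a
    causal = truth.causal_snps
    base_prev = 0.3
    alpha0 = np.log(base_prev / (1 - base_prev))
    tables = []
    for ci, (n_cases, n_controls) in enumerate(config.cohort_sizes):
        rng = _rng(config, _STAGE_GWAS, probe_index * 1000 + ci + (0 if group.upper() == "A" else 500))
        Gs, ys = [], []
        got_cases = got_controls = 0
        need = n_cases + n_controls
        for _ in range(20):
            n_draw = int(1.6 * max(n_cases / base_prev, n_controls / (1 - base_prev)))
            G = _genotypes(rng, n_draw, mafs, config.ld_rho)
            if config.scenario == "linkage":
                eta = alpha0 + b_eff * G[:, causal[1]]
            elif config.scenario == "null":
                eta = np.full(n_draw, alpha0)
            else:
                eta = alpha0 + b_eff * config.beta_zx * G[:, causal[0]]
            status = (rng.random(n_draw) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
            Gs.append(G)
            ys.append(status)
            got_cases += int(status.sum())
            got_controls += int((1 - status).sum())
            if got_cases >= n_cases and got_controls >= n_controls:
                break
        G = np.concatenate(Gs)
        y = np.concatenate(ys)
        case_idx = np.flatnonzero(y == 1)[:n_cases]
        control_idx = np.flatnonzero(y == 0)[:n_controls]
        sel = np.concatenate([case_idx, control_idx])
        Gsel = G[sel].astype(float)
        ysel = y[sel].astype(float)
        poly = Gsel.min(axis=0) != Gsel.max(axis=0)
        beta, se, p, ok = _logistic_wald(Gsel[:, poly], ysel)
        keep = np.flatnonzero(poly)[ok]
        if (~poly).any() or (~ok).any():
            logger.warning(
                "gwas cohort %d: dropped %d monomorphic and %d separated SNP(s)",
                ci, int((~poly).sum()), int((~ok).sum()),
            )
        meta = panel.meta.iloc[keep].reset_index(drop=True)
        tables.append(
            pd.DataFrame(
                {
                    "SNP": meta["SNP"],
                    "A1": meta["A1"],
                    "A2": meta["A2"],
                    "freq": Gsel[:, poly][:, ok].mean(axis=0) / 2.0,
                    "b": beta[ok],
                    "se": se[ok],
                    "p": p[ok],
                    "n": len(sel),
                }
            )[GWAS_COLUMNS]
        )
    return tables


def simulate_study(
    config: ScenarioConfig,
    scenarios: Sequence[str] | None = None,
    group: str = "A",
) -> dict:
    """Simulate a complete multi-probe study with known truth.

    ``scenarios`` optionally overrides ``config.scenario`` per probe
    (length ``n_probes``), so mixed fixtures (e.g. pleiotropy + linkage
    + null probes) come from one call.  Each probe occupies its own
    independent LD block 10 Mb from its neighbours.

    Returns a dict with keys ``panel`` (:class:`LdPanel` over all
    blocks), ``probes``, ``mqtl`` (flat-table DataFrames), ``gwas``
    (list of per-cohort GWAS DataFrames), ``truth`` (list of
    :class:`TruthRecord`).
    """
    if scenarios is None:
        scenarios = [config.scenario] * config.n_probes
    if len(scenarios) != config.n_probes:
        raise ConfigError("scenarios must have length n_probes")
    panels, mqtls, truths = [], [], []
    gwas_parts: list[list[pd.DataFrame]] = [[] for _ in config.cohort_sizes]
    for pi, scen in enumerate(scenarios):
        cfg = replace(config, scenario=scen)
        panel = gen_reference_panel(cfg, probe_index=pi)
        mqtl, truth = gen_mqtl_summary(panel, cfg, probe_index=pi)
        for ci, tab in enumerate(gen_gwas_cohorts(panel, cfg, truth, group=group, probe_index=pi)):
            gwas_parts[ci].append(tab)
        panels.append(panel)
        mqtls.append(mqtl)
        truths.append(truth)
    panel_meta = pd.concat([p.meta for p in panels], ignore_index=True)
    panel_dos = np.concatenate([p.dosages for p in panels], axis=1)
    mqtl = pd.concat(mqtls, ignore_index=True)
    probes = (
        mqtl[["ProbeID", "ProbeChr", "ProbeBp", "Gene", "Orientation"]]
        .drop_duplicates("ProbeID")
        .reset_index(drop=True)
    )
    gwas = [pd.concat(parts, ignore_index=True) for parts in gwas_parts]
    return {
        "panel": LdPanel(meta=panel_meta, dosages=panel_dos),
        "probes": probes,
        "mqtl": mqtl,
        "gwas": gwas,
        "truth": truths,
    }


def write_truth_table(truths: Sequence[TruthRecord], path) -> None:
    df = pd.DataFrame(
        {
            "probe": [t.probe_id for t in truths],
            "scenario": [t.scenario for t in truths],
            "causal_snps": [",".join(map(str, t.causal_snps)) for t in truths],
            "beta_zx": [t.beta_zx for t in truths],
            "b_xy_groupA": [t.b_xy_group_a for t in truths],
            "b_xy_groupB": [t.b_xy_group_b for t in truths],
        }
    )
    df.to_csv(path, sep="\t", index=False)
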