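"""Synthetic GWAS cohorts with a known causal chain, summarized per SNP.

The generator emulates the structure of the study this package targets: a
quantitative exposure GWAS (an immune-cell phenotype, n about 3,800), a
quantitative mediator GWAS (a plasma metabolite, n about 8,300), and a rare
binary outcome GWAS (case fraction about 0.3%), all drawn from three
*independent* cohorts so the two-sample assumption holds by construction.

Data-generating model (one draw of the population per cohort):

    G_j ~ Binomial(2, maf_j)                       independent loci; optional
                                                   LD blocks by allele copying
    X   = sum_j gamma_j G_j + e_x                  unit population variance
    M   = sum_j gammaM_j G_j + theta_xm X + e_m    unit population variance
    Y   ~ Bernoulli(expit(a0 + theta_xy X + theta_my M + sum_j alpha_j G_j))

The exposure and the mediator have disjoint causal SNP sets, so each MR leg
has instruments satisfying the exclusion restriction: real metabolites carry
their own QTLs, and without them the mediator-to-outcome leg would be
confounded by design.  alpha_j are direct (pleiotropic) SNP effects on the
outcome carried by a configurable fraction of the exposure instruments.  The
intercept a0 is solved numerically so the expected case fraction hits the
requested prevalence.

Per-SNP summary statistics use simple linear regression for quantitative
traits and per-SNP logistic regression (vectorized Newton-Raphson) for the
binary outcome, so outcome betas are log-odds and exponentiate to ORs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .gwas_io import CANONICAL_COLUMNS, LDTable
from .harmonize import HarmonizedSet

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_individuals",
    "summarize_cohort",
    "empirical_ld_table",
    "simulate_study",
    "simulate_summary_effects",
    "simulate_trait_pair",
]

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("T", "G"), ("G", "T")]
_N_CHROM = 22
_LOCUS_SPACING = 12_000_000  # bp between independent loci: beyond the clump window
_BLOCK_SPACING = 50_000  # bp between members of one LD block


@dataclass(frozen=True)
class SimulationConfig:
    """True parameters of one synthetic study.

    Cohort sizes default to the emulated GWAS scales (exposure 3,757, mediator
    8,299) with a 20,000-strong outcome cohort standing in for the much larger
    case-control meta-analysis; ``outcome_prevalence`` defaults to the rare
    0.003 case fraction.  Effects are on the standardized-trait scale
    (``theta_xy``/``theta_my`` on log-odds).  ``ld_blocks`` is a sequence of
    (start_index, size, copy_prob) triples: SNPs start..start+size-1 share a
    chromosome within ``_BLOCK_SPACING`` of each other and copy the anchor's
    alleles with the given probability.
    """

    n_exposure: int = 3757
    n_mediator: int = 8299
    n_outcome: int = 20_000
    m_snps: int = 200
    n_causal: int = 25
    n_causal_mediator: int = 25
    h2_exposure: float = 0.15
    h2_mediator: float = 0.15
    maf_range: tuple[float, float] = (0.05, 0.5)
    theta_xm: float = 0.0
    theta_xy: float = 0.0
    theta_my: float = 0.0
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outcome_prevalence: float = 0.003
    ld_blocks: tuple = ()
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5 or (0.0 < lo <= hi == 0.5)):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if not 0.0 < self.outcome_prevalence < 1.0:
            raise ValueError("outcome_prevalence must be in (0, 1)")
        if self.n_causal + self.n_causal_mediator > self.m_snps:
            raise ValueError("n_causal + n_causal_mediator must not exceed m_snps")
        if self.h2_exposure >= 1.0 or self.h2_mediator + self.theta_xm**2 >= 1.0:
            raise ValueError("heritabilities (plus theta_xm^2) must leave residual variance")
        for start, size, prob in self.ld_blocks:
            if start < 0 or start + size > self.m_snps or size < 2 or not 0 <= prob <= 1:
                raise ValueError(f"invalid ld_block {(start, size, prob)}")


@dataclass
class SimulatedStudy:
    exposure_stats: pd.DataFrame
    mediator_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    ld_table: LDTable
    truth: dict
    snp_meta: pd.DataFrame
    config: SimulationConfig = None


def _snp_metadata(config: SimulationConfig) -> pd.DataFrame:
    m = config.m_snps
    per_chrom = ceil(m / _N_CHROM)
    chrom = np.array([str(1 + j // per_chrom) for j in range(m)])
    pos = np.array(
        [1_000_000 + (j % per_chrom) * _LOCUS_SPACING for j in range(m)], dtype=np.int64
    )
    ea = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][0] for j in range(m)]
    oa = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][1] for j in range(m)]
    # LD-block members sit on the anchor's chromosome, tightly spaced
    for start, size, _ in config.ld_blocks:
        for k in range(1, size):
            chrom[start + k] = chrom[start]
            pos[start + k] = pos[start] + k * _BLOCK_SPACING
    return pd.DataFrame(
        {
            "SNP": [f"rs{j + 1}" for j in range(m)],
            "CHR": chrom,
            "POS": pos,
            "EA": ea,
            "OA": oa,
        }
    )


def _design(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Draw the study-level truth: MAFs, per-SNP effects, pleiotropy."""
    m = config.m_snps
    maf = rng.uniform(*config.maf_range, size=m)
    sd_g = np.sqrt(2.0 * maf * (1.0 - maf))

    gamma = np.zeros(m)
    idx_x = np.arange(config.n_causal)
    if config.n_causal:
        per_snp = np.sqrt(config.h2_exposure / config.n_causal)
        gamma[idx_x] = rng.choice([-1.0, 1.0], size=config.n_causal) * per_snp / sd_g[idx_x]

    gamma_m = np.zeros(m)
    idx_m = np.arange(config.n_causal, config.n_causal + config.n_causal_mediator)
    if config.n_causal_mediator:
        per_snp = np.sqrt(config.h2_mediator / config.n_causal_mediator)
        gamma_m[idx_m] = (
            rng.choice([-1.0, 1.0], size=config.n_causal_mediator) * per_snp / sd_g[idx_m]
        )

    alpha = np.zeros(m)
    n_pleio = int(round(config.pleiotropy_frac * config.n_causal))
    pleio_idx = rng.choice(idx_x, size=n_pleio, replace=False) if n_pleio else np.array([], int)
    if n_pleio:
        alpha[pleio_idx] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, n_pleio)

    return {
        "maf": maf,
        "gamma": gamma,
        "gamma_mediator": gamma_m,
        "alpha_pleiotropy": alpha,
        "causal_exposure": idx_x,
        "causal_mediator": idx_m,
        "pleiotropic": np.sort(pleio_idx),
        "theta_xm": config.theta_xm,
        "theta_xy": config.theta_xy,
        "theta_my": config.theta_my,
        "beta_total": config.theta_xy + config.theta_xm * config.theta_my,
        "prevalence": config.outcome_prevalence,
    }


def _genotypes(
    n: int, maf: np.ndarray, ld_blocks, rng: np.random.Generator
) -> np.ndarray:
    """Allele-count matrix (n, m); LD induced by copying anchor alleles."""
    m = maf.size
    hap = rng.random((n, m, 2)) < maf[None, :, None]  # two haplotypes per person
    for start, size, prob in ld_blocks:
        for k in range(1, size):
            copy = rng.random((n, 2)) < prob
            fresh = rng.random((n, 2)) < maf[start + k]
            hap[:, start + k, :] = np.where(copy, hap[:, start, :], fresh)
    return hap.sum(axis=2).astype(np.float64)


def _phenotypes(
    G: np.ndarray, design: dict, config: SimulationConfig, rng: np.random.Generator
) -> dict:
    n = G.shape[0]
    h2x = config.h2_exposure
    x = G @ design["gamma"] + rng.normal(0.0, np.sqrt(1.0 - h2x), n)
    var_m_resid = 1.0 - config.h2_mediator - config.theta_xm**2
    mtrait = (
        G @ design["gamma_mediator"]
        + config.theta_xm * x
        + rng.normal(0.0, np.sqrt(var_m_resid), n)
    )
    eta = config.theta_xy * x + config.theta_my * mtrait + G @ design["alpha_pleiotropy"]

    def gap(a0):
        return float(np.mean(expit(a0 + eta))) - config.outcome_prevalence

    a0 = brentq(gap, -40.0, 20.0)
    y = (rng.random(n) < expit(a0 + eta)).astype(np.float64)
    return {"G": G, "X": x, "M": mtrait, "Y": y, "intercept": a0}


def simulate_individuals(config: SimulationConfig, seed: Optional[int] = None) -> dict:
    """Three independent cohorts of genotypes and phenotypes plus the truth.

    Returns ``{"exposure": {...}, "mediator": {...}, "outcome": {...},
    "truth": {...}}``; each cohort dict carries G, X, M, Y and the solved
    outcome intercept.  Identical config and seed give bit-identical output.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    design_ss, *cohort_ss = root.spawn(4)
    design = _design(config, np.random.default_rng(design_ss))
    out = {"truth": design}
    for name, ss in zip(("exposure", "mediator", "outcome"), cohort_ss):
        rng = np.random.default_rng(ss)
        G = _genotypes({"exposure": config.n_exposure,
                        "mediator": config.n_mediator,
                        "outcome": config.n_outcome}[name],
                       design["maf"], config.ld_blocks, rng)
        out[name] = _phenotypes(G, design, config, rng)
    return out


def _quantitative_summary(G: np.ndarray, y: np.ndarray):
    n = G.shape[0]
    gm = G.mean(axis=0)
    gc = G - gm
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        s2 = np.maximum(syy - beta * sxy, 0.0) / (n - 2)
        se = np.sqrt(np.where(sxx > 0, s2 / np.where(sxx > 0, sxx, 1.0), np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    return beta, se, p


def _logistic_summary(G: np.ndarray, y: np.ndarray, chunk: int = 64, max_iter: int = 60):
    """Per-SNP logistic fits (intercept + allele count), Newton-Raphson
    vectorized across SNPs."""
    n, m = G.shape
    ybar = float(y.mean())
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    for lo in range(0, m, chunk):
        g = G[:, lo : lo + chunk]
        k = g.shape[1]
        a = np.full(k, logit(ybar))
        b = np.zeros(k)
        ok = g.std(axis=0) > 0
        for _ in range(max_iter):
            eta = np.clip(a[None, :] + b[None, :] * g, -30.0, 30.0)
            p = expit(eta)
            w = p * (1.0 - p)
            r = y[:, None] - p
            ga = r.sum(axis=0)
            gb = np.einsum("ij,ij->j", g, r)
            haa = w.sum(axis=0)
            hab = np.einsum("ij,ij->j", w, g)
            hbb = np.einsum("ij,ij,ij->j", w, g, g)
            det = haa * hbb - hab**2
            ok = ok & (det > 1e-12)
            safe_det = np.where(ok, det, 1.0)
            da = np.where(ok, (hbb * ga - hab * gb) / safe_det, 0.0)
            db = np.where(ok, (haa * gb - hab * ga) / safe_det, 0.0)
            a += da
            b += db
            if np.max(np.abs(np.concatenate([da, db]))) < 1e-10:
                break
        ok = ok & np.isfinite(b) & (det > 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_b = np.where(ok, haa / np.where(ok, det, 1.0), np.nan)
        beta[lo : lo + k] = np.where(ok, b, np.nan)
        se[lo : lo + k] = np.sqrt(var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, p


def summarize_cohort(
    G: np.ndarray,
    phenotype: np.ndarray,
    trait_type: str,
    snp_meta: pd.DataFrame,
    method: Optional[str] = None,
) -> pd.DataFrame:
    """Per-SNP association scan -> canonical summary-statistics frame.

    ``trait_type`` is ``"quantitative"`` (simple linear regression; betas in SD
    units when the phenotype has unit variance) or ``"binary"`` (per-SNP
    logistic regression; betas are log-odds).  ``method="linear"`` forces the
    faster linear-probability fit for a binary trait.  Monomorphic SNPs come
    back with missing beta/se/p and are excluded downstream by the p-value
    filter.
    """
    if trait_type == "quantitative":
        beta, se, p = _quantitative_summary(G, phenotype)
    elif trait_type == "binary":
        if method == "linear":
            beta, se, p = _quantitative_summary(G, phenotype)
        else:
            beta, se, p = _logistic_summary(G, phenotype)
    else:
        raise ValueError(f"unknown trait_type: {trait_type!r}")
    out = snp_meta.copy()
    out["EAF"] = G.mean(axis=0) / 2.0
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = np.clip(p, np.nextafter(0, 1), 1.0)
    out["N"] = G.shape[0]
    return out[CANONICAL_COLUMNS]


def empirical_ld_table(
    G: np.ndarray, snp_meta: pd.DataFrame, window_kb: float = 10_000.0
) -> LDTable:
    """r-squared (squared genotype correlation) for all same-chromosome pairs
    within the window, computed from a reference cohort's genotypes."""
    ld = LDTable()
    window_bp = window_kb * 1000.0
    chrom = snp_meta["CHR"].to_numpy()
    pos = snp_meta["POS"].to_numpy()
    ids = snp_meta["SNP"].to_numpy()
    sd = G.std(axis=0)
    Gc = G - G.mean(axis=0)
    n = G.shape[0]
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for ii, i in enumerate(idx):
            for j in idx[ii + 1 :]:
                if abs(pos[i] - pos[j]) > window_bp:
                    continue
                if sd[i] == 0 or sd[j] == 0:
                    r2 = 0.0
                else:
                    r = float(Gc[:, i] @ Gc[:, j]) / (n * sd[i] * sd[j])
                    r2 = min(r * r, 1.0)
                ld.add(ids[i], ids[j], r2)
    return ld


def simulate_study(config: SimulationConfig, seed: Optional[int] = None) -> SimulatedStudy:
    """Simulate the three cohorts and summarize each into GWAS tables.

    The exposure cohort is scanned against X, the mediator cohort against M,
    and the outcome cohort against Y (logistic); the LD table is computed
    empirically from the exposure cohort's genotypes.
    """
    meta = _snp_metadata(config)
    cohorts = simulate_individuals(config, seed=seed)
    exposure_stats = summarize_cohort(
        cohorts["exposure"]["G"], cohorts["exposure"]["X"], "quantitative", meta
    )
    mediator_stats = summarize_cohort(
        cohorts["mediator"]["G"], cohorts["mediator"]["M"], "quantitative", meta
    )
    outcome_stats = summarize_cohort(
        cohorts["outcome"]["G"], cohorts["outcome"]["Y"], "binary", meta
    )
    ld = empirical_ld_table(cohorts["exposure"]["G"], meta)
    return SimulatedStudy(
        exposure_stats=exposure_stats,
        mediator_stats=mediator_stats,
        outcome_stats=outcome_stats,
        ld_table=ld,
        truth=cohorts["truth"],
        snp_meta=meta,
        config=config,
    )


def simulate_summary_effects(
    n_snp: int = 50,
    beta_causal: float = 0.0,
    gamma_range: tuple[float, float] = (0.05, 0.15),
    se_exposure: float = 0.01,
    se_outcome: float = 0.05,
    pleiotropy_frac: float = 0.0,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    heterogeneity_sd: float = 0.0,
    seed: int = 0,
) -> HarmonizedSet:
    """Directly simulate harmonized two-sample summary effects.

    The fast path for calibration and power studies: per SNP,
    bx ~ N(gamma_j, se_x) and by ~ N(theta_j gamma_j + alpha_j, se_y) with
    independent errors (the two-sample property), theta_j ~
    N(beta_causal, heterogeneity_sd), and pleiotropic offsets alpha_j on a
    random fraction of SNPs.
    """
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(*gamma_range, size=n_snp)
    alpha = np.zeros(n_snp)
    k = int(round(pleiotropy_frac * n_snp))
    if k:
        idx = rng.choice(n_snp, size=k, replace=False)
        alpha[idx] = rng.normal(pleiotropy_mean, pleiotropy_sd, k)
    theta = rng.normal(beta_causal, heterogeneity_sd, n_snp)
    bx = rng.normal(gamma, se_exposure)
    by = rng.normal(theta * gamma + alpha, se_outcome)
    return HarmonizedSet.from_arrays(
        bx, np.full(n_snp, se_exposure), by, np.full(n_snp, se_outcome)
    )


def simulate_trait_pair(
    n_snp: int = 20,
    beta_causal: float = 0.0,
    gamma_range: tuple[float, float] = (0.08, 0.15),
    se_exposure: float = 0.01,
    se_outcome: float = 0.05,
    n_exposure: int = 4000,
    n_outcome: int = 20_000,
    snp_prefix: str = "rs",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary-level exposure/outcome record pair with full metadata.

    Convenience for pipeline sweeps: returns two canonical frames sharing SNP
    ids, alleles and positions, with strongly associated exposure SNPs and
    outcome effects beta_causal * bx plus noise.  Loci are spaced beyond the
    clump window, so the pair exercises the screen rather than the clump.
    """
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(m_snps=n_snp, n_causal=min(n_snp, 1), n_causal_mediator=0)
    meta = _snp_metadata(cfg).copy()
    meta["SNP"] = [f"{snp_prefix}{j + 1}" for j in range(n_snp)]
    gamma = rng.uniform(*gamma_range, size=n_snp) * rng.choice([-1.0, 1.0], n_snp)
    bx = rng.normal(gamma, se_exposure)
    by = rng.normal(beta_causal * bx, se_outcome)
    eaf = rng.uniform(0.1, 0.9, n_snp)

    def frame(beta, se, n):
        z = np.abs(beta / se)
        return pd.DataFrame(
            {
                "SNP": meta["SNP"],
                "CHR": meta["CHR"],
                "POS": meta["POS"],
                "EA": meta["EA"],
                "OA": meta["OA"],
                "EAF": eaf,
                "BETA": beta,
                "SE": se,
                "P": np.clip(2.0 * stats.norm.sf(z), np.nextafter(0, 1), 1.0),
                "N": n,
            }
        )

    exposure = frame(bx, np.full(n_snp, se_exposure), n_exposure)
    outcome = frame(by, np.full(n_snp, se_outcome), n_outcome)
    return exposure, outcome
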