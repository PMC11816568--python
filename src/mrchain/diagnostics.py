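"""Heterogeneity, pleiotropy, influence and outlier diagnostics for MR fits.

* Cochran's Q under the fixed-effect IVW fit (df = n-1) and Rucker's Q under
  the Egger fit (df = n-2); p above 0.05 is read as no heterogeneity.
* The Egger intercept test for directional horizontal pleiotropy.
* Leave-one-out IVW refits to expose single-SNP influence.
* An MR-PRESSO-style residual-sum-of-squares simulation test: a global
  heterogeneity p, per-SNP outlier flags, and a distortion p for the change in
  the IVW estimate after removing flagged outliers.  All empirical p-values use
  the add-one rule and are therefore bounded below by 1/(n_sim+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import InsufficientInstruments, egger, ivw
from .harmonize import HarmonizedSet

__all__ = [
    "DiagnosticsReport",
    "PressoResult",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "mr_presso",
    "funnel_data",
    "diagnose",
]


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outliers: list[str]
    distortion_p: Optional[float]
    outlier_p: pd.Series  # per-SNP empirical p for the squared residual
    n_sim: int


@dataclass
class DiagnosticsReport:
    """All diagnostics for one exposure-outcome pair.

    Fields that need more SNPs than were available are None (Egger terms need
    3, the outlier test needs 4).
    """

    n_snp: int
    q_ivw: float
    q_ivw_df: int
    q_ivw_p: float
    q_egger: Optional[float] = None
    q_egger_df: Optional[int] = None
    q_egger_p: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    loo: Optional[pd.DataFrame] = None
    presso_global_p: Optional[float] = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_p: Optional[float] = None
    funnel: Optional[pd.DataFrame] = None


def cochran_q(hset: HarmonizedSet, model: str = "ivw") -> tuple[float, int, float]:
    """(Q, df, p): weighted residual sum of squares of the fixed-effect fit.

    ``model="ivw"`` uses the zero-intercept fit (df = n-1); ``model="egger"``
    the free-intercept fit (df = n-2).  p from chi-square with the stated df.
    """
    if model == "ivw":
        est = ivw(hset, mode="fixed")
        q, df = est.extra["q"], est.n_snp - 1
        if est.n_snp < 2:
            raise InsufficientInstruments("cochran_q(ivw) needs >= 2 SNPs")
    elif model == "egger":
        est = egger(hset)
        q, df = est.extra["q"], est.n_snp - 2
    else:
        raise ValueError(f"unknown model: {model!r}")
    return float(q), int(df), float(stats.chi2.sf(q, df))


def egger_intercept_test(hset: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, se, p): the pleiotropy block of the Egger fit."""
    e = egger(hset)
    return e.extra["intercept"], e.extra["intercept_se"], e.extra["intercept_p"]


def leave_one_out(
    hset: HarmonizedSet, mode: str = "multiplicative_random"
) -> pd.DataFrame:
    """One IVW refit per omitted SNP; columns SNP, beta, se, pval."""
    retained = hset.retained
    if len(retained) < 2:
        raise InsufficientInstruments("leave_one_out needs >= 2 SNPs")
    rows = []
    for i in range(len(retained)):
        sub = HarmonizedSet(
            hset.exposure_name,
            hset.outcome_name,
            retained.drop(index=i).reset_index(drop=True),
        )
        est = ivw(sub, mode=mode)
        rows.append((retained.at[i, "SNP"], est.beta, est.se, est.pval))
    return pd.DataFrame(rows, columns=["SNP", "beta", "se", "pval"])


def _loo_expected(bx, by, w):
    """Per-SNP prediction from the IVW fit that leaves that SNP out."""
    a = np.sum(w * bx * by, axis=-1, keepdims=True)
    b = np.sum(w * bx**2, axis=-1, keepdims=True)
    beta_loo = (a - w * bx * by) / (b - w * bx**2)
    return beta_loo * bx


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual-sum-of-squares outlier test.

    Global test: the observed weighted RSS of outcome effects about their
    leave-one-out IVW expectations is compared with ``n_sim`` parametric
    simulations under the no-pleiotropy model (bx* ~ N(bx, se_x),
    by* ~ N(beta_loo*bx, se_y)); empirical p with the add-one rule.
    Outlier test: per-SNP observed vs simulated squared residuals, flagged when
    the empirical p falls below ``outlier_alpha / n`` (Bonferroni-style).
    Distortion test: the shift in the IVW estimate after removing outliers is
    compared with shifts from removing equally many random SNPs.
    """
    bx, sx, by, sy = hset.arrays()
    n = bx.size
    if n < 4:
        raise InsufficientInstruments("mr_presso needs >= 4 SNPs")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    pred = _loo_expected(bx, by, w)
    resid2 = (by - pred) ** 2
    rss_obs = float(np.sum(w * resid2))

    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    by_sim = rng.normal(pred, sy, size=(n_sim, n))
    pred_sim = _loo_expected(bx_sim, by_sim, w)
    resid2_sim = (by_sim - pred_sim) ** 2
    rss_sim = np.sum(w * resid2_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    outlier_p = (1 + np.sum(resid2_sim >= resid2[None, :], axis=0)) / (n_sim + 1)
    snp_ids = hset.retained["SNP"]
    flagged = outlier_p < outlier_alpha / n
    outliers = snp_ids[flagged].tolist()

    distortion_p = None
    if outliers and not flagged.all():
        keep = ~flagged
        beta_all = np.sum(w * bx * by) / np.sum(w * bx**2)
        beta_corr = np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(
            w[keep] * bx[keep] ** 2
        )
        d_obs = abs(beta_all - beta_corr)
        k = int(flagged.sum())
        d_sim = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(n, size=k, replace=False)
            m = np.ones(n, dtype=bool)
            m[drop] = False
            beta_sub = np.sum(w[m] * bx[m] * by[m]) / np.sum(w[m] * bx[m] ** 2)
            d_sim[s] = abs(beta_all - beta_sub)
        distortion_p = float((1 + np.sum(d_sim >= d_obs)) / (n_sim + 1))

    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outliers=outliers,
        distortion_p=distortion_p,
        outlier_p=pd.Series(outlier_p, index=snp_ids.to_numpy(), name="outlier_p"),
        n_sim=n_sim,
    )


def funnel_data(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP (Wald ratio, precision) pairs for a funnel plot."""
    bx, _, by, sy = hset.arrays()
    return pd.DataFrame(
        {
            "SNP": hset.retained["SNP"],
            "ratio": by / bx,
            "precision": np.abs(bx) / sy,
        }
    )


def diagnose(
    hset: HarmonizedSet,
    ivw_mode: str = "multiplicative_random",
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> DiagnosticsReport:
    """Full diagnostics panel; skips what the SNP count cannot support."""
    n = hset.n_retained
    q, df, p = cochran_q(hset, "ivw")
    report = DiagnosticsReport(n_snp=n, q_ivw=q, q_ivw_df=df, q_ivw_p=p)
    report.loo = leave_one_out(hset, mode=ivw_mode)
    report.funnel = funnel_data(hset)
    if n >= 3:
        qe, dfe, pe = cochran_q(hset, "egger")
        report.q_egger, report.q_egger_df, report.q_egger_p = qe, dfe, pe
        (
            report.egger_intercept,
            report.egger_intercept_se,
            report.egger_intercept_p,
        ) = egger_intercept_test(hset)
    if n >= 4:
        presso = mr_presso(hset, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
        report.presso_global_p = presso.global_p
        report.presso_outliers = presso.outliers
        report.presso_distortion_p = presso.distortion_p
    return report
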