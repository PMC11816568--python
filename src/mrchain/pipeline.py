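"""Orchestrate the many-exposures screen with significance and consistency gates.

For each exposure trait: select instruments, harmonize against the outcome,
fit the five MR methods, run the diagnostics panel, then apply the gates:

* headline IVW p below ``ivw_alpha``;
* direction consistency — all five betas share a strict sign (a zero beta is
  inconsistent);
* no heterogeneity — both Cochran's Q p-values above 0.05;
* no directional pleiotropy — Egger intercept p above 0.05;
* outlier-test pass — global simulation p above 0.05.

Retained exposures are classified risk (IVW OR above 1) or protective (below
1).  A failing exposure never aborts the sweep; its verdict records the first
gate it failed.  No multiple-testing correction is applied by default (an
optional Benjamini-Hochberg adjustment of the IVW p-values can be switched
on), which mirrors common practice in large MR screens and is a documented
limitation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticsReport, diagnose
from .estimators import METHOD_ORDER, InsufficientInstruments, MREstimate, all_methods
from .gwas_io import LDTable
from .harmonize import harmonize
from .instruments import ClumpConfig, build_instrument_set

__all__ = ["ScreenCriteria", "ScreenResult", "run_screen", "export_report"]


@dataclass(frozen=True)
class ScreenCriteria:
    """Gate thresholds for the exposure screen."""

    ivw_alpha: float = 0.05
    require_direction_consistency: bool = True
    require_no_pleiotropy: bool = True
    require_no_heterogeneity: bool = True
    require_presso_pass: bool = True
    fdr: bool = False  # optional Benjamini-Hochberg on IVW p across exposures

    def __post_init__(self):
        if not 0 < self.ivw_alpha < 1:
            raise ValueError("ivw_alpha must be in (0, 1)")


@dataclass
class ScreenResult:
    exposure: str
    estimates: Optional[dict] = None  # method -> MREstimate
    diagnostics: Optional[DiagnosticsReport] = None
    verdict: str = "retained"  # "retained" | "rejected"
    reason: Optional[str] = None
    direction: Optional[str] = None  # "risk" | "protective"
    n_snp: int = 0


def _direction_consistent(estimates: Mapping[str, MREstimate]) -> bool:
    signs = {np.sign(estimates[m].beta) for m in METHOD_ORDER}
    return signs in ({1.0}, {-1.0})


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def run_screen(
    exposures: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    ld: LDTable,
    blacklist: Optional[pd.DataFrame] = None,
    criteria: ScreenCriteria = ScreenCriteria(),
    config: ClumpConfig = ClumpConfig(),
    palindrome_eaf_limit: float = 0.42,
    outcome_name: str = "outcome",
    seed: int = 0,
    n_boot: int = 1000,
    n_sim: int = 1000,
) -> list[ScreenResult]:
    """Screen many exposure traits against one outcome.

    ``exposures`` maps trait name to a canonical summary-stats frame.  Results
    come back in sorted-name order, one per exposure, with per-exposure seeds
    derived deterministically from ``seed``.
    """
    names = sorted(exposures)
    seeds = np.random.SeedSequence(seed).spawn(len(names))
    results = []
    for name, ss in zip(names, seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        res = _screen_one(
            name, exposures[name], outcome, ld, blacklist, criteria, config,
            palindrome_eaf_limit, outcome_name, sub_seed, n_boot, n_sim,
        )
        results.append(res)

    if criteria.fdr:
        testable = [r for r in results if r.estimates is not None]
        if testable:
            adj = _bh_adjust(np.array([r.estimates["ivw"].pval for r in testable]))
            for r, q in zip(testable, adj):
                r.estimates["ivw"].extra["ivw_p_fdr"] = float(q)
                if r.verdict == "retained" and q >= criteria.ivw_alpha:
                    r.verdict, r.reason, r.direction = "rejected", "ivw_not_significant_fdr", None
    return results


def _screen_one(
    name, stats_df, outcome, ld, blacklist, criteria, config,
    palindrome_eaf_limit, outcome_name, seed, n_boot, n_sim,
) -> ScreenResult:
    iset = build_instrument_set(stats_df, ld, blacklist, config, exposure_name=name)
    if iset.status != "ok":
        return ScreenResult(name, verdict="rejected", reason="insufficient_instruments")
    hset = harmonize(iset, outcome, palindrome_eaf_limit, outcome_name=outcome_name)
    if hset.n_retained < 3:
        return ScreenResult(
            name, verdict="rejected", reason="insufficient_instruments",
            n_snp=hset.n_retained,
        )
    try:
        estimates = all_methods(hset, n_boot=n_boot, seed=seed)
    except InsufficientInstruments:
        return ScreenResult(
            name, verdict="rejected", reason="insufficient_instruments",
            n_snp=hset.n_retained,
        )
    report = diagnose(hset, n_sim=n_sim, seed=seed)
    res = ScreenResult(
        name, estimates=estimates, diagnostics=report, n_snp=hset.n_retained
    )

    ivw_est = estimates["ivw"]
    if ivw_est.pval >= criteria.ivw_alpha:
        res.verdict, res.reason = "rejected", "ivw_not_significant"
    elif criteria.require_direction_consistency and not _direction_consistent(estimates):
        res.verdict, res.reason = "rejected", "direction_inconsistency"
    elif criteria.require_no_heterogeneity and (
        report.q_ivw_p <= 0.05
        or (report.q_egger_p is not None and report.q_egger_p <= 0.05)
    ):
        res.verdict, res.reason = "rejected", "heterogeneity"
    elif criteria.require_no_pleiotropy and (
        report.egger_intercept_p is not None and report.egger_intercept_p <= 0.05
    ):
        res.verdict, res.reason = "rejected", "pleiotropy"
    elif criteria.require_presso_pass and (
        report.presso_global_p is not None and report.presso_global_p <= 0.05
    ):
        res.verdict, res.reason = "rejected", "presso_global"
    else:
        res.direction = "risk" if ivw_est.or_value > 1.0 else "protective"
    return res


def export_report(
    results: list[ScreenResult],
    forest_path=None,
    summary_path=None,
) -> tuple[pd.DataFrame, dict]:
    """Forest-plot data (one row per exposure x method) and a JSON-able summary.

    Rows are sorted by exposure name then the fixed method order; re-export of
    the same results is byte-identical.
    """
    rows = []
    for res in sorted(results, key=lambda r: r.exposure):
        if res.estimates is None:
            continue
        for method in METHOD_ORDER:
            est = res.estimates[method]
            rows.append(
                {
                    "exposure": res.exposure,
                    "method": method,
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "or_value": est.or_value,
                    "or_low": est.or_low,
                    "or_high": est.or_high,
                    "pval": est.pval,
                }
            )
    forest = pd.DataFrame(
        rows,
        columns=[
            "exposure", "method", "n_snp", "beta", "se", "ci_low", "ci_high",
            "or_value", "or_low", "or_high", "pval",
        ],
    )
    summary = {
        "n_exposures": len(results),
        "n_retained": sum(r.verdict == "retained" for r in results),
        "exposures": [
            {
                "exposure": r.exposure,
                "verdict": r.verdict,
                "reason": r.reason,
                "direction": r.direction,
                "n_snp": r.n_snp,
                "ivw_beta": r.estimates["ivw"].beta if r.estimates else None,
                "ivw_or": r.estimates["ivw"].or_value if r.estimates else None,
                "ivw_p": r.estimates["ivw"].pval if r.estimates else None,
            }
            for r in sorted(results, key=lambda r: r.exposure)
        ],
    }
    if forest_path is not None:
        forest.to_csv(forest_path, sep="\t", index=False, lineterminator="\n")
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return forest, summary
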