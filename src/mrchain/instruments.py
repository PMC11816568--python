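"""Instrumental-variable selection from a trait's GWAS summary statistics.

Four filters, applied in a fixed order: a significance threshold (default
P < 1e-5, the usual relaxed cutoff when genome-wide significance leaves too few
variants), greedy LD clumping (retain approximately independent SNPs: no
retained pair on the same chromosome within the window may exceed the r-squared
ceiling), an instrument-strength filter on the per-SNP F-statistic, and an
offline confounder blacklist standing in for a PhenoScanner-style lookup.

The F filter runs after clumping; each excluded SNP carries the rule that
removed it in the provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas_io import CANONICAL_COLUMNS, LDTable

__all__ = [
    "ClumpConfig",
    "InstrumentSet",
    "select_by_pvalue",
    "ld_clump",
    "f_statistic",
    "f_statistic_variance_explained",
    "exclude_confounded",
    "build_instrument_set",
]


@dataclass(frozen=True)
class ClumpConfig:
    """Thresholds for instrument selection.

    p_threshold : significance cutoff on the exposure association.
    window_kb   : clumping window, center-to-center, in kilobases (inclusive).
    r2_max      : maximum pairwise r-squared among retained SNPs in the window.
    f_min       : minimum per-SNP F-statistic; F below this is a weak instrument
                  (F exactly at the bound is kept).
    """

    p_threshold: float = 1e-5
    window_kb: float = 10_000.0
    r2_max: float = 0.001
    f_min: float = 10.0

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must be in [0, 1]")
        if self.f_min < 0:
            raise ValueError("f_min must be non-negative")


@dataclass
class InstrumentSet:
    """Selected instruments plus a per-SNP audit of every filter decision."""

    exposure_name: str
    records: pd.DataFrame
    f_stats: pd.Series
    provenance: pd.DataFrame  # columns: SNP, status, rule, detail
    status: str = "ok"  # "ok" | "insufficient_instruments"

    @property
    def n_snp(self) -> int:
        return len(self.records)


def select_by_pvalue(records: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Rows with P strictly below the threshold, original order preserved."""
    return records.loc[records["P"] < p_threshold].reset_index(drop=True)


def _clump_order(records: pd.DataFrame) -> pd.DataFrame:
    # Greedy seed order: most significant first; deterministic tie-break.
    return records.sort_values(
        ["P", "CHR", "POS", "SNP"], kind="mergesort"
    ).reset_index(drop=True)


def ld_clump(
    records: pd.DataFrame,
    ld: LDTable,
    config: ClumpConfig = ClumpConfig(),
    return_log: bool = False,
):
    """Greedy LD clumping.

    SNPs are visited by ascending p-value; a SNP is accepted iff no
    already-accepted SNP on the same chromosome within ``window_kb`` has
    r-squared above ``r2_max`` with it.  Pairs absent from the LD table count
    as r2 = 0 outside the window or across chromosomes, but as *unknown* inside
    the window, in which case the less significant SNP is conservatively
    dropped.  Retained rows come back sorted by (CHR, POS, SNP).
    """
    window_bp = config.window_kb * 1000.0
    ordered = _clump_order(records)
    kept: list[int] = []
    log: dict[str, str] = {}
    for i in range(len(ordered)):
        snp, chrom, pos = ordered.at[i, "SNP"], ordered.at[i, "CHR"], ordered.at[i, "POS"]
        verdict = None
        for j in kept:
            if ordered.at[j, "CHR"] != chrom:
                continue
            if abs(ordered.at[j, "POS"] - pos) > window_bp:
                continue
            r2 = ld.r2(snp, ordered.at[j, "SNP"])
            if r2 is None:
                verdict = f"r2 unknown within window of {ordered.at[j, 'SNP']}"
                break
            if r2 > config.r2_max:
                verdict = f"r2={r2:g} with {ordered.at[j, 'SNP']} exceeds {config.r2_max:g}"
                break
        if verdict is None:
            kept.append(i)
        else:
            log[snp] = verdict
    out = (
        ordered.iloc[kept]
        .sort_values(["CHR", "POS", "SNP"], kind="mergesort")
        .reset_index(drop=True)
    )
    return (out, log) if return_log else out


def f_statistic(beta, se):
    """Per-SNP instrument-strength F, the summary-data approximation (beta/se)^2.

    Equals the squared Wald z-score; accepts scalars or arrays.
    """
    return (np.asarray(beta, dtype=float) / np.asarray(se, dtype=float)) ** 2


def f_statistic_variance_explained(beta, eaf, n):
    """Opt-in F from variance explained: (n-2) * R2 / (1 - R2).

    R2 = 2 * eaf * (1-eaf) * beta^2 for a unit-variance quantitative trait.
    Requires EAF and sample size; use when beta is on the SD scale.
    """
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
    return (n - 2.0) * r2 / (1.0 - r2)


def exclude_confounded(
    records: pd.DataFrame, blacklist: pd.DataFrame | None, return_log: bool = False
):
    """Drop SNPs listed in a confounder blacklist (columns SNP, TRAIT).

    A SNP listed under several confounder traits is removed once; all traits
    appear in the log.
    """
    if blacklist is None or len(blacklist) == 0:
        out = records.reset_index(drop=True)
        return (out, {}) if return_log else out
    traits = blacklist.groupby("SNP")["TRAIT"].apply(lambda s: sorted(set(s)))
    listed = records["SNP"].isin(traits.index)
    log = {
        snp: "confounder-associated: " + ", ".join(traits[snp])
        for snp in records.loc[listed, "SNP"]
    }
    out = records.loc[~listed].reset_index(drop=True)
    return (out, log) if return_log else out


def build_instrument_set(
    records: pd.DataFrame,
    ld: LDTable,
    blacklist: pd.DataFrame | None = None,
    config: ClumpConfig = ClumpConfig(),
    exposure_name: str = "exposure",
) -> InstrumentSet:
    """Compose the four filters: p-threshold -> LD clump -> F -> blacklist.

    Never raises on an empty result; an InstrumentSet with
    status="insufficient_instruments" is returned instead.  The provenance
    frame holds one row per input SNP with the rule that dropped it, or
    "selected".
    """
    drop_rule: dict[str, tuple[str, str]] = {}

    sig = select_by_pvalue(records, config.p_threshold)
    for snp, p in zip(records["SNP"], records["P"]):
        if snp not in set(sig["SNP"]):
            drop_rule[snp] = ("p_threshold", f"P={p:g} >= {config.p_threshold:g}")

    clumped, clump_log = ld_clump(sig, ld, config, return_log=True)
    for snp, why in clump_log.items():
        drop_rule[snp] = ("ld_clump", why)

    f = f_statistic(clumped["BETA"], clumped["SE"])
    weak = f < config.f_min
    for snp, fi in zip(clumped.loc[weak, "SNP"], f[weak]):
        drop_rule[snp] = ("f_statistic", f"F={fi:.3g} < {config.f_min:g}")
    strong = clumped.loc[~weak].reset_index(drop=True)

    final, bl_log = exclude_confounded(strong, blacklist, return_log=True)
    for snp, why in bl_log.items():
        drop_rule[snp] = ("blacklist", why)

    prov_rows = []
    for snp in records["SNP"]:
        if snp in drop_rule:
            rule, detail = drop_rule[snp]
            prov_rows.append((snp, "dropped", rule, detail))
        else:
            prov_rows.append((snp, "selected", "", ""))
    provenance = pd.DataFrame(prov_rows, columns=["SNP", "status", "rule", "detail"])

    f_final = pd.Series(
        f_statistic(final["BETA"], final["SE"]), index=final.index, name="F"
    )
    status = "ok" if len(final) >= 1 else "insufficient_instruments"
    return InstrumentSet(
        exposure_name=exposure_name,
        records=final[CANONICAL_COLUMNS].reset_index(drop=True),
        f_stats=f_final,
        provenance=provenance,
        status=status,
    )
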