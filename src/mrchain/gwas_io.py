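"""Read, validate and write GWAS summary statistics, LD tables and blacklists.

All three file kinds are UTF-8 tab-delimited text with a header row.  Summary
statistics use the canonical column names

    SNP  CHR  POS  EA  OA  EAF  BETA  SE  P  N

where ``EA`` is the effect allele, ``BETA`` the per-effect-allele effect (SD
units for quantitative traits, log-odds for binary traits), ``EAF`` the effect
allele frequency ('.' or empty when unknown) and ``N`` the sample size.  Real
summary-stat files vary wildly in their headers, so every reader accepts a
``dialect`` mapping from canonical names to the names actually present.

Positions are 1-based base pairs; only autosomal biallelic A/C/G/T variants are
supported.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "SummaryStatsError",
    "LDTable",
    "read_summary_stats",
    "write_summary_stats",
    "validate_summary_stats",
    "read_ld_table",
    "write_ld_table",
    "read_blacklist",
    "write_blacklist",
]

#: Canonical summary-statistics column order.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_REQUIRED = [c for c in CANONICAL_COLUMNS if c != "EAF"]
_NUMERIC = ["POS", "EAF", "BETA", "SE", "P", "N"]
_VALID_ALLELES = frozenset("ACGT")


class SummaryStatsError(ValueError):
    """Malformed or invariant-violating summary-statistics input."""


def _fmt_rows(rows: Iterable[int], limit: int = 10) -> str:
    rows = list(rows)
    head = ", ".join(str(r) for r in rows[:limit])
    if len(rows) > limit:
        head += f", ... ({len(rows)} rows total)"
    return head


def validate_summary_stats(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    """Validate a canonical-column summary-stats frame, raising on violations.

    Row numbers in error messages count data rows from 1 (the header is row 0).
    Returns the frame with normalized dtypes (alleles upper-cased, POS/N integer).
    """
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SummaryStatsError(f"{source}: missing required column(s): {', '.join(missing)}")
    df = df.copy()
    if "EAF" not in df.columns:
        df["EAF"] = np.nan

    for col in _NUMERIC:
        raw = df[col]
        if col == "EAF":
            raw = raw.replace({".": np.nan, "": np.nan})
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
            raise SummaryStatsError(
                f"{source}: unparseable numeric value(s) in column {col} on row(s) {_fmt_rows(rows)}"
            )
        if col != "EAF" and coerced.isna().any():
            rows = (np.flatnonzero(coerced.isna().to_numpy()) + 1).tolist()
            raise SummaryStatsError(
                f"{source}: missing value(s) in required column {col} on row(s) {_fmt_rows(rows)}"
            )
        df[col] = coerced

    for col in ("EA", "OA"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    df["SNP"] = df["SNP"].astype(str)
    df["CHR"] = df["CHR"].astype(str)

    checks = {
        "EA/OA must be one of A,C,G,T": ~(df["EA"].isin(_VALID_ALLELES) & df["OA"].isin(_VALID_ALLELES)),
        "effect allele equals other allele": df["EA"] == df["OA"],
        "POS must be >= 1": df["POS"] < 1,
        "SE must be > 0": df["SE"] <= 0,
        "P must be in (0, 1]": (df["P"] <= 0) | (df["P"] > 1),
        "N must be a positive integer": df["N"] < 1,
        "EAF must be in [0, 1]": df["EAF"].notna() & ((df["EAF"] < 0) | (df["EAF"] > 1)),
    }
    for rule, bad in checks.items():
        if bad.any():
            rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
            raise SummaryStatsError(f"{source}: {rule}; violated on row(s) {_fmt_rows(rows)}")

    df["POS"] = df["POS"].astype(np.int64)
    df["N"] = df["N"].astype(np.int64)
    return df[CANONICAL_COLUMNS].reset_index(drop=True)


def read_summary_stats(
    path, dialect: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file into a canonical frame.

    Parameters
    ----------
    path
        File to read.
    dialect
        Optional mapping ``{canonical name: column name in file}`` for files
        that do not use the canonical header.  Unmapped canonical names are
        looked up verbatim.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    raw = raw.replace({"": np.nan})
    if dialect:
        rename = {}
        for canonical, actual in dialect.items():
            if canonical not in CANONICAL_COLUMNS:
                raise SummaryStatsError(f"unknown canonical column in dialect: {canonical}")
            if actual not in raw.columns:
                raise SummaryStatsError(f"{path}: dialect maps {canonical} to missing column {actual}")
            rename[actual] = canonical
        raw = raw.rename(columns=rename)
    return validate_summary_stats(raw, source=str(path))


def write_summary_stats(df: pd.DataFrame, path) -> None:
    """Write a canonical summary-stats frame as deterministic tab-delimited text.

    Columns are emitted in canonical order, missing EAF as '.'.  Floats use
    Python's shortest round-trip representation, so read-back equality holds.
    """
    df = validate_summary_stats(df)
    out = df[CANONICAL_COLUMNS].copy()
    out["EAF"] = out["EAF"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    for col in ("BETA", "SE", "P"):
        out[col] = out[col].map(lambda v: repr(float(v)))
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


class LDTable:
    """Symmetric pairwise r-squared lookup.

    Pairs are stored order-insensitively; ``r2(a, a)`` is always 1.  Pairs not
    in the table return ``None`` ("unknown"): the clumping step decides whether
    an unknown pair means "far apart, r2 = 0" or "within the window, drop the
    weaker SNP conservatively".
    """

    def __init__(self, pairs: Optional[Iterable[tuple]] = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs is not None:
            for a, b, r2 in pairs:
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, snp_a: str, snp_b: str, r2: float) -> None:
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise SummaryStatsError(f"r2 must be in [0, 1], got {r2} for ({snp_a}, {snp_b})")
        if snp_a == snp_b and r2 != 1.0:
            raise SummaryStatsError(f"r2 of {snp_a} with itself must be 1, got {r2}")
        self._r2[self._key(str(snp_a), str(snp_b))] = r2

    def r2(self, snp_a: str, snp_b: str) -> Optional[float]:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get(self._key(snp_a, snp_b))

    def __len__(self) -> int:
        return len(self._r2)

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted((a, b, r2) for (a, b), r2 in self._r2.items())
        return pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])


def read_ld_table(path) -> LDTable:
    """Read a tab-delimited LD table with columns SNP_A, SNP_B, R2."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP_A": str, "SNP_B": str})
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise SummaryStatsError(f"{path}: missing required column(s): {col}")
    r2 = pd.to_numeric(df["R2"], errors="coerce")
    if r2.isna().any():
        rows = (np.flatnonzero(r2.isna().to_numpy()) + 1).tolist()
        raise SummaryStatsError(f"{path}: unparseable R2 on row(s) {_fmt_rows(rows)}")
    try:
        return LDTable(zip(df["SNP_A"], df["SNP_B"], r2))
    except SummaryStatsError as exc:
        raise SummaryStatsError(f"{path}: {exc}") from None


def write_ld_table(ld: LDTable, path) -> None:
    ld.to_dataframe().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_blacklist(path) -> pd.DataFrame:
    """Read a confounder-SNP blacklist with columns SNP, TRAIT."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("SNP", "TRAIT"):
        if col not in df.columns:
            raise SummaryStatsError(f"{path}: missing required column(s): {col}")
    if (df["SNP"].str.strip() == "").any():
        bad = df.index[df["SNP"].str.strip() == ""] + 1
        raise SummaryStatsError(f"{path}: empty SNP id on row(s) {_fmt_rows(bad.tolist())}")
    return df[["SNP", "TRAIT"]].reset_index(drop=True)


def write_blacklist(df: pd.DataFrame, path) -> None:
    df[["SNP", "TRAIT"]].to_csv(path, sep="\t", index=False, lineterminator="\n")
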