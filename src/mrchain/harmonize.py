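"""Align exposure and outcome associations to a shared effect allele per SNP.

Per SNP the outcome record is reconciled with the exposure's allele pair:

* same alleles, same orientation          -> ``aligned``
* effect/other swapped                    -> outcome beta negated, EAF
                                             complemented, ``swapped``
* opposite strand (A<->T, C<->G labels)   -> relabelled, ``strand_flipped``
  (composed with a swap when also reversed -> ``swapped_and_flipped``)
* palindromic (A/T or C/G) variants       -> strand is unidentifiable from the
  alleles; kept only when both allele frequencies are extreme on the same side
  (both below the limit or both above one minus the limit), otherwise
  ``dropped_palindromic``
* anything irreconcilable, or absent from the outcome -> ``dropped_incompatible``

Nothing raises: every problem becomes an action code, and estimation uses only
the retained rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HarmonizedSet", "harmonize", "RETAINED_ACTIONS", "DROPPED_ACTIONS"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

RETAINED_ACTIONS = frozenset(
    {"aligned", "swapped", "strand_flipped", "swapped_and_flipped"}
)
DROPPED_ACTIONS = frozenset({"dropped_palindromic", "dropped_incompatible"})

_SNP_COLUMNS = [
    "SNP",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf_exposure",
    "eaf_outcome",
    "action",
]


@dataclass
class HarmonizedSet:
    """Per-SNP exposure/outcome effect pairs on a shared effect allele.

    ``snps`` holds one row per exposure instrument, including dropped ones
    (identified by their action code); estimators consume ``retained``.
    """

    exposure_name: str
    outcome_name: str
    snps: pd.DataFrame

    @property
    def retained(self) -> pd.DataFrame:
        return self.snps.loc[self.snps["action"].isin(RETAINED_ACTIONS)].reset_index(
            drop=True
        )

    @property
    def n_retained(self) -> int:
        return int(self.snps["action"].isin(RETAINED_ACTIONS).sum())

    @classmethod
    def from_arrays(
        cls,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        snp_ids=None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedSet":
        """Build an already-aligned set directly from effect arrays."""
        bx = np.asarray(beta_exposure, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(bx.size)]
        snps = pd.DataFrame(
            {
                "SNP": list(snp_ids),
                "beta_exposure": bx,
                "se_exposure": np.asarray(se_exposure, dtype=float),
                "beta_outcome": np.asarray(beta_outcome, dtype=float),
                "se_outcome": np.asarray(se_outcome, dtype=float),
                "eaf_exposure": np.nan,
                "eaf_outcome": np.nan,
                "action": "aligned",
            }
        )
        return cls(exposure_name, outcome_name, snps)

    def arrays(self):
        """Retained (beta_exposure, se_exposure, beta_outcome, se_outcome)."""
        r = self.retained
        return (
            r["beta_exposure"].to_numpy(float),
            r["se_exposure"].to_numpy(float),
            r["beta_outcome"].to_numpy(float),
            r["se_outcome"].to_numpy(float),
        )


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def _resolve(ea_x, oa_x, ea_y, oa_y):
    """Map outcome alleles onto the exposure pair.

    Returns (flip_sign, action) or (None, 'dropped_incompatible').
    Palindromic exposure pairs are handled by the caller.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return False, "aligned"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return True, "swapped"
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return False, "strand_flipped"
    if (cea, coa) == (oa_x, ea_x):
        return True, "swapped_and_flipped"
    return None, "dropped_incompatible"


def harmonize(
    exposure,
    outcome: pd.DataFrame,
    palindrome_eaf_limit: float = 0.42,
    exposure_name: str | None = None,
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Harmonize exposure instruments with outcome summary statistics.

    Parameters
    ----------
    exposure
        An :class:`~mrchain.instruments.InstrumentSet` or a canonical
        summary-stats frame of the selected instruments.
    outcome
        Canonical summary-stats frame for the outcome trait; instruments are
        looked up by SNP id (no proxy search).
    palindrome_eaf_limit
        A palindromic SNP is kept only when both EAFs are known and both are
        below this limit or both above one minus it.  Palindromic SNPs with
        any missing EAF are always dropped, never guessed.
    """
    if hasattr(exposure, "records"):  # InstrumentSet
        exp = exposure.records
        exposure_name = exposure_name or exposure.exposure_name
    else:
        exp = exposure
        exposure_name = exposure_name or "exposure"

    out_by_snp = {row.SNP: row for row in outcome.itertuples(index=False)}
    rows = []
    for e in exp.itertuples(index=False):
        eaf_x = float(e.EAF) if pd.notna(e.EAF) else np.nan
        base = dict(
            SNP=e.SNP,
            beta_exposure=float(e.BETA),
            se_exposure=float(e.SE),
            beta_outcome=np.nan,
            se_outcome=np.nan,
            eaf_exposure=eaf_x,
            eaf_outcome=np.nan,
        )
        o = out_by_snp.get(e.SNP)
        if o is None:
            rows.append({**base, "action": "dropped_incompatible"})
            continue
        beta_y, se_y = float(o.BETA), float(o.SE)
        eaf_y = float(o.EAF) if pd.notna(o.EAF) else np.nan

        if _is_palindromic(e.EA, e.OA):
            if {o.EA, o.OA} != {e.EA, e.OA}:
                rows.append({**base, "action": "dropped_incompatible"})
                continue
            flip = o.EA != e.EA
            if flip:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if not np.isnan(eaf_y) else np.nan
            lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
            identifiable = (
                not np.isnan(eaf_x)
                and not np.isnan(eaf_y)
                and ((eaf_x < lo and eaf_y < lo) or (eaf_x > hi and eaf_y > hi))
            )
            if not identifiable:
                rows.append({**base, "action": "dropped_palindromic"})
                continue
            action = "swapped" if flip else "aligned"
            rows.append(
                {
                    **base,
                    "beta_outcome": beta_y,
                    "se_outcome": se_y,
                    "eaf_outcome": eaf_y,
                    "action": action,
                }
            )
            continue

        flip, action = _resolve(e.EA, e.OA, o.EA, o.OA)
        if flip is None:
            rows.append({**base, "action": action})
            continue
        if flip:
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y if not np.isnan(eaf_y) else np.nan
        rows.append(
            {
                **base,
                "beta_outcome": beta_y,
                "se_outcome": se_y,
                "eaf_outcome": eaf_y,
                "action": action,
            }
        )

    snps = pd.DataFrame(rows, columns=_SNP_COLUMNS)
    if snps["SNP"].duplicated().any():
        dup = snps.loc[snps["SNP"].duplicated(), "SNP"].tolist()
        raise ValueError(f"duplicate instrument SNP ids: {dup}")
    return HarmonizedSet(exposure_name, outcome_name, snps)
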