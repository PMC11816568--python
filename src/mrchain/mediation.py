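"""Two-step mediation MR: reverse-causality gate and product-of-coefficients.

The decomposition follows the product method on three IVW legs:

    beta1 : exposure -> mediator
    beta2 : mediator -> outcome
    beta  : exposure -> outcome (total effect)

    indirect = beta1 * beta2
    direct   = beta - beta1 * beta2
    R        = (beta1 * beta2) / beta      (proportion mediated)

The reverse screen re-runs the five MR methods with the outcome as exposure;
mediation is only trusted when every method's p exceeds 0.05 (strictly), i.e.
no evidence that the outcome drives the exposure.

``se_indirect`` uses the product delta method,
sqrt(beta1^2 se2^2 + beta2^2 se1^2); the proportion is reported as a signed
fraction and values outside [0, 1] (inconsistent mediation) are returned
verbatim with a flag, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .diagnostics import diagnose
from .estimators import METHOD_ORDER, MREstimate, all_methods, ivw
from .gwas_io import LDTable
from .harmonize import harmonize
from .instruments import ClumpConfig, build_instrument_set

__all__ = [
    "MediationResult",
    "MediationAudit",
    "LegFailure",
    "reverse_mr_screen",
    "mediation_decompose",
    "run_mediation",
]


class LegFailure(RuntimeError):
    """An MR leg could not be estimated; ``leg`` names which one."""

    def __init__(self, leg: str, reason: str):
        super().__init__(f"mediation leg '{leg}' failed: {reason}")
        self.leg = leg
        self.reason = reason


@dataclass
class MediationResult:
    beta_total: float
    beta1: float
    beta2: float
    indirect: float
    direct: float
    proportion: float
    se_indirect: Optional[float] = None
    exposure: str = "exposure"
    mediator: str = "mediator"
    outcome: str = "outcome"
    flags: list[str] = field(default_factory=list)


@dataclass
class MediationAudit:
    """Everything behind a MediationResult: per-leg estimates and diagnostics."""

    legs: dict  # leg name -> {"estimates": {method: MREstimate}, "diagnostics": ..., "n_snp": int}
    reverse_verdict: str  # "pass" | "fail" | "insufficient_instruments"
    reverse_estimates: Optional[dict] = None
    valid: bool = True


def reverse_mr_screen(mr_results: Mapping[str, MREstimate]) -> str:
    """'pass' iff every one of the five methods' p-values strictly exceeds 0.05.

    ``mr_results`` are estimates for the reversed pair (outcome as exposure).
    A missing method is an error, not a pass.
    """
    missing = [m for m in METHOD_ORDER if m not in mr_results]
    if missing:
        raise ValueError(f"reverse screen needs all five methods; missing: {missing}")
    return "pass" if all(mr_results[m].pval > 0.05 for m in METHOD_ORDER) else "fail"


def mediation_decompose(
    beta_total: float,
    beta1: float,
    beta2: float,
    se_total: Optional[float] = None,
    se1: Optional[float] = None,
    se2: Optional[float] = None,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Product-of-coefficients decomposition of a total effect.

    The identities direct + indirect = beta_total and
    proportion * beta_total = indirect hold exactly.  Standard errors are
    optional; when ``se1`` and ``se2`` are both given, ``se_indirect`` is the
    delta-method sqrt(beta1^2 se2^2 + beta2^2 se1^2).
    """
    indirect = beta1 * beta2
    if beta_total == 0.0:
        if indirect != 0.0:
            raise ZeroDivisionError(
                "proportion mediated undefined: total effect is zero with nonzero indirect effect"
            )
        proportion = 0.0
    else:
        proportion = indirect / beta_total
    direct = beta_total - indirect
    se_indirect = None
    if se1 is not None and se2 is not None:
        se_indirect = float(np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2))
    flags = []
    if not 0.0 <= proportion <= 1.0:
        flags.append("inconsistent_mediation: proportion outside [0, 1]")
    return MediationResult(
        beta_total=float(beta_total),
        beta1=float(beta1),
        beta2=float(beta2),
        indirect=float(indirect),
        direct=float(direct),
        proportion=float(proportion),
        se_indirect=se_indirect,
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        flags=flags,
    )


def _fit_leg(
    name: str,
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    ld: LDTable,
    blacklist,
    config: ClumpConfig,
    palindrome_eaf_limit: float,
    exposure_name: str,
    outcome_name: str,
    seed: int,
    n_boot: int,
    min_snps: int,
    full_methods: bool,
):
    iset = build_instrument_set(
        exposure_stats, ld, blacklist, config, exposure_name=exposure_name
    )
    if iset.status != "ok":
        raise LegFailure(name, "insufficient instruments after selection")
    hset = harmonize(
        iset, outcome_stats, palindrome_eaf_limit, outcome_name=outcome_name
    )
    if hset.n_retained < min_snps:
        raise LegFailure(
            name, f"only {hset.n_retained} SNPs retained after harmonization"
        )
    if full_methods and hset.n_retained >= 3:
        estimates = all_methods(hset, n_boot=n_boot, seed=seed)
    else:  # the five-method panel needs >= 3 SNPs; IVW alone degrades gracefully
        estimates = {"ivw": ivw(hset)}
    diag = diagnose(hset, seed=seed) if hset.n_retained >= 2 else None
    return hset, estimates, diag


def run_mediation(
    exposure_stats: pd.DataFrame,
    mediator_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    ld: LDTable,
    blacklist: Optional[pd.DataFrame] = None,
    config: ClumpConfig = ClumpConfig(),
    palindrome_eaf_limit: float = 0.42,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
    seed: int = 0,
    n_boot: int = 1000,
) -> tuple[MediationResult, MediationAudit]:
    """Full two-step mediation analysis from three summary-statistic tables.

    Three forward IVW legs (total, exposure->mediator, mediator->outcome) are
    fitted after their own instrument selection and harmonization, each with
    the five-method panel and the diagnostics suite; the reverse leg
    (outcome -> exposure) feeds the screen.  A failed reverse screen flags the
    result invalid; a reverse leg without instruments is recorded as such and
    does not invalidate (the screen simply could not run).
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    legs = {}
    spec = [
        ("total", exposure_stats, outcome_stats, exposure, outcome),
        ("exposure_to_mediator", exposure_stats, mediator_stats, exposure, mediator),
        ("mediator_to_outcome", mediator_stats, outcome_stats, mediator, outcome),
    ]
    for (name, exp_s, out_s, exp_n, out_n), leg_seed in zip(spec, seeds[:3]):
        hset, estimates, diag = _fit_leg(
            name, exp_s, out_s, ld, blacklist, config, palindrome_eaf_limit,
            exp_n, out_n, leg_seed, n_boot, min_snps=1, full_methods=True,
        )
        legs[name] = {
            "hset": hset,
            "estimates": estimates,
            "diagnostics": diag,
            "n_snp": hset.n_retained,
        }

    reverse_estimates = None
    try:
        _, reverse_estimates, _ = _fit_leg(
            "reverse", outcome_stats, exposure_stats, ld, blacklist, config,
            palindrome_eaf_limit, outcome, exposure, seeds[3], n_boot,
            min_snps=3, full_methods=True,
        )
        reverse_verdict = reverse_mr_screen(reverse_estimates)
    except LegFailure:
        reverse_verdict = "insufficient_instruments"

    e_total = legs["total"]["estimates"]["ivw"]
    e1 = legs["exposure_to_mediator"]["estimates"]["ivw"]
    e2 = legs["mediator_to_outcome"]["estimates"]["ivw"]
    result = mediation_decompose(
        e_total.beta, e1.beta, e2.beta,
        se_total=e_total.se, se1=e1.se, se2=e2.se,
        exposure=exposure, mediator=mediator, outcome=outcome,
    )
    if reverse_verdict == "fail":
        result.flags.append("reverse_causation: reverse MR screen failed")
    audit = MediationAudit(
        legs=legs,
        reverse_verdict=reverse_verdict,
        reverse_estimates=reverse_estimates,
        valid=reverse_verdict != "fail",
    )
    return result, audit
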