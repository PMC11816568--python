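"""The five two-sample MR estimators plus the per-SNP Wald ratio.

Every method consumes a :class:`~mrchain.harmonize.HarmonizedSet` — per-SNP
exposure effects ``beta_x`` with standard errors ``se_x`` and outcome effects
``beta_y`` with ``se_y``, aligned to a shared effect allele — and returns an
:class:`MREstimate`.  For a binary outcome the causal beta is a log-odds ratio
per SD of exposure and is also reported exponentiated with a 95% CI.

Methods
-------
ivw
    Weighted regression of ``beta_y`` on ``beta_x`` through the origin with
    weights 1/se_y^2; the primary reference method.  The default multiplicative
    random-effects variant inflates the standard error by
    sqrt(max(1, Q/(n-1))) so that between-SNP heterogeneity never shrinks it.
egger
    Same regression with a free intercept after orienting all exposure effects
    positive; a nonzero intercept indicates directional horizontal pleiotropy.
    Slope and intercept are tested against t with n-2 df.
weighted_median
    The per-SNP ratio at cumulative weight one half; consistent when at least
    half of the total instrument weight is valid.  SE by seeded parametric
    bootstrap.
mode_estimate (simple / weighted)
    Kernel-density mode of the per-SNP ratios with a modified-Silverman
    bandwidth; consistent when the largest homogeneous instrument subset is
    valid.  SE by seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet

__all__ = [
    "MREstimate",
    "InsufficientInstruments",
    "METHOD_ORDER",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "all_methods",
    "to_odds_ratio",
]

#: Fixed reporting order of the five headline methods.
METHOD_ORDER = ["ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"]

_Z95 = 1.96  # conventional 95% normal quantile used for all reported intervals


class InsufficientInstruments(ValueError):
    """Too few retained SNPs for the requested method."""


@dataclass
class MREstimate:
    """One method's causal estimate on the beta (log-odds / SD) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_value: float
    or_low: float
    or_high: float
    pval: float
    n_snp: int
    extra: dict = field(default_factory=dict)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: (OR, lower 95%, upper 95%)."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - _Z95 * se)),
        float(np.exp(beta + _Z95 * se)),
    )


def _estimate(method, beta, se, n_snp, pval=None, extra=None) -> MREstimate:
    beta, se = float(beta), float(se)
    if pval is None:
        pval = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    if se > 0:
        or_value, or_low, or_high = to_odds_ratio(beta, se)
        ci_low, ci_high = beta - _Z95 * se, beta + _Z95 * se
    else:
        or_value, or_low, or_high = float(np.exp(beta)), float(np.exp(beta)), float(np.exp(beta))
        ci_low = ci_high = beta
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        or_value=or_value,
        or_low=or_low,
        or_high=or_high,
        pval=float(pval),
        n_snp=int(n_snp),
        extra=extra or {},
    )


def _arrays(hset: HarmonizedSet, minimum: int, method: str):
    bx, sx, by, sy = hset.arrays()
    if bx.size < minimum:
        raise InsufficientInstruments(
            f"{method} needs >= {minimum} retained SNPs, got {bx.size}"
        )
    return bx, sx, by, sy


def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-SNP causal estimate beta_y / beta_x.

    The first-order standard error |se_y / beta_x| ignores uncertainty in the
    exposure effect; ``second_order=True`` adds the beta_y^2 se_x^2 / beta_x^4
    term of the delta expansion.
    """
    if beta_exposure == 0:
        raise ZeroDivisionError("Wald ratio undefined: beta_exposure is zero")
    beta = beta_outcome / beta_exposure
    var = se_outcome**2 / beta_exposure**2
    if second_order:
        var += beta_outcome**2 * se_exposure**2 / beta_exposure**4
    return _estimate("wald_ratio", beta, np.sqrt(var), 1)


def ivw(
    hset: HarmonizedSet,
    mode: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance weighted estimate (zero-intercept weighted regression).

    beta = sum(w * bx * by) / sum(w * bx^2) with w = 1/se_y^2.  With a single
    SNP this reduces exactly to the Wald ratio.  ``extra`` carries Cochran's Q
    of the fixed-effect fit and the applied scale inflation.
    """
    bx, _, by, sy = _arrays(hset, 1, "ivw")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = np.sqrt(1.0 / denom)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    n = bx.size
    inflation = 1.0
    if mode == "multiplicative_random" and n > 1:
        inflation = np.sqrt(max(1.0, q / (n - 1)))
    elif mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown ivw mode: {mode!r}")
    se *= inflation
    return _estimate(
        "ivw", beta, se, n, extra={"q": q, "mode": mode, "scale_inflation": float(inflation)}
    )


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit of by on bx with a free intercept.

    Exposure effects are oriented non-negative internally (sign pairs flipped),
    which leaves the slope and the weighted residual sum of squares invariant
    but fixes the sign convention of the intercept.  Residual scale uses
    multiplicative inflation max(1, Q_egger/(n-2)); slope and intercept p-values
    use t with n-2 df.  Intercept terms are returned in ``extra``
    (``intercept``, ``intercept_se``, ``intercept_p``, ``q``).
    """
    bx, _, by, sy = _arrays(hset, 3, "egger")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    # Closed-form weighted least squares with design [1, x].
    sw = w.sum()
    swx = float(np.sum(w * x))
    swxx = float(np.sum(w * x * x))
    det = sw * swxx - swx**2
    if det <= 0:
        raise InsufficientInstruments("egger: no variation in exposure effects")
    intercept = (swxx * float(np.sum(w * y)) - swx * float(np.sum(w * x * y))) / det
    slope = (sw * float(np.sum(w * x * y)) - swx * float(np.sum(w * y))) / det
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    n = x.size
    phi = max(1.0, q / (n - 2))
    var_intercept = phi * swxx / det
    var_slope = phi * sw / det
    se_slope = float(np.sqrt(var_slope))
    se_intercept = float(np.sqrt(var_intercept))
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df=n - 2)
    p_intercept = 2.0 * stats.t.sf(abs(intercept / se_intercept), df=n - 2)
    return _estimate(
        "egger",
        slope,
        se_slope,
        n,
        pval=p_slope,
        extra={
            "intercept": float(intercept),
            "intercept_se": se_intercept,
            "intercept_p": float(p_intercept),
            "q": q,
            "scale_inflation": float(np.sqrt(phi)),
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Ratio at cumulative weight 0.5 with linear interpolation."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    # midpoint cumulative weights: below the first midpoint or above the last
    # the estimate saturates at the extreme order statistic
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Per-SNP Wald ratios are ordered and weighted by bx^2/se_y^2 (the
    first-order inverse variance of the ratio); the estimate is the ratio at
    cumulative weight one half.  The bootstrap redraws (bx, by) from normal
    distributions centred at the observed effects.
    """
    bx, sx, by, sy = _arrays(hset, 3, "weighted_median")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        boots[b] = _weighted_median_point(byb / bxb, bxb**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", beta, se, bx.size, extra={"n_boot": n_boot})


def _silverman_scale(r: np.ndarray) -> float:
    n = r.size
    sd = float(np.std(r, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(r - np.median(r))))
    scales = [s for s in (sd, mad) if s > 0]
    if not scales:
        return 0.0
    return 0.9 * min(scales) * n ** (-1 / 5)


def _mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float, grid_size: int = 512
) -> float:
    h = bandwidth_factor * _silverman_scale(ratios)
    if h == 0.0:  # all ratios identical (or no spread the scale can see)
        return float(np.median(ratios))
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ (
        weights / weights.sum()
    )
    return float(grid[np.argmax(dens)])


def mode_estimate(
    hset: HarmonizedSet,
    variant: Literal["simple", "weighted"] = "simple",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: kernel-density mode of the per-SNP ratios.

    ``simple`` weighs every ratio equally; ``weighted`` uses the first-order
    inverse variance bx^2/se_y^2.  Normal kernel, bandwidth =
    ``bandwidth_factor`` x 0.9 min(sd, 1.4826 MAD) n^(-1/5), mode located on a
    512-point grid spanning the ratios plus/minus three bandwidths.  SE by
    seeded parametric bootstrap.
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    bx, sx, by, sy = _arrays(hset, 3, f"{variant}_mode")
    ratios = by / bx

    def wts(bxa):
        if variant == "simple":
            return np.ones_like(bxa)
        if variant == "weighted":
            return bxa**2 / sy**2
        raise ValueError(f"unknown mode variant: {variant!r}")

    beta = _mode_point(ratios, wts(bx), bandwidth_factor)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        boots[b] = _mode_point(byb / bxb, wts(bxb), bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    return _estimate(
        f"{variant}_mode", beta, se, bx.size, extra={"n_boot": n_boot, "bandwidth_factor": bandwidth_factor}
    )


def all_methods(
    hset: HarmonizedSet,
    ivw_mode: Literal["fixed", "multiplicative_random"] = "multiplicative_random",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """The five headline estimates keyed by method name, in METHOD_ORDER."""
    ss = np.random.SeedSequence(seed).spawn(3)
    return {
        "ivw": ivw(hset, mode=ivw_mode),
        "egger": egger(hset),
        "weighted_median": weighted_median(hset, n_boot=n_boot, seed=ss[0]),
        "simple_mode": mode_estimate(hset, "simple", n_boot=n_boot, seed=ss[1]),
        "weighted_mode": mode_estimate(hset, "weighted", n_boot=n_boot, seed=ss[2]),
    }
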