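"""Univariable two-sample MR estimators.

Five estimators over a harmonized instrument set: inverse-variance-weighted
(IVW, with a multiplicative random-effects fallback when Cochran's Q exceeds
its degrees of freedom), MR-Egger regression, the weighted median, and the
weighted and simple mode estimators.  All operate on per-SNP Wald ratios
ratio_j = Γ_j/γ_j with first-order SEs se_Γj/|γ_j|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instruments import HarmonizedInstrumentSet, InsufficientInstrumentsError

log = logging.getLogger(__name__)

Z95 = 1.96  # normal 95% half-width used for all printed CIs


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds (or SD-unit) scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_: float
    ci_low: float
    ci_high: float
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    model: str = "fixed"  # fixed | multiplicative-random

    @classmethod
    def from_beta_se(cls, method: str, beta: float, se: float, pval: float,
                     n_snp: int, **kw) -> "MREstimate":
        or_, lo, hi = beta_to_or(beta, se)
        return cls(method=method, beta=beta, se=se, pval=pval, n_snp=n_snp,
                   or_=or_, ci_low=lo, ci_high=hi, **kw)


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio exp(β) with 95% CI exp(β ± 1.96·SE)."""
    if se < 0:
        raise ValueError(f"se must be >= 0, got {se}")
    return math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)


def _require(h: HarmonizedInstrumentSet, minimum: int, method: str) -> None:
    if len(h) < minimum:
        raise InsufficientInstrumentsError(
            f"{method}: needs >= {minimum} instruments, got {len(h)}"
        )


def wald_ratios(h: HarmonizedInstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates Γ_j/γ_j with first-order SEs se_Γj/|γ_j|.

    Variants with γ_j = 0 are excluded with a warning (the ratio is undefined).
    """
    g = h.gamma
    G = h.capital_gamma
    seG = h.se_capital_gamma
    ok = g != 0.0
    if not ok.all():
        log.warning("wald_ratios: excluded %d variants with gamma = 0", int((~ok).sum()))
    return G[ok] / g[ok], seG[ok] / np.abs(g[ok])


def _ivw_arrays(g: np.ndarray, G: np.ndarray, seG: np.ndarray):
    """Pooled IVW slope, fixed-effect SE and Cochran's Q from raw arrays."""
    w = g**2 / seG**2
    ratio = G / g
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratio - beta) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedInstrumentSet) -> MREstimate:
    """Inverse-variance-weighted estimate: weighted regression of Γ on γ
    through the origin with weights 1/se_Γ², identical to the inverse-variance
    pooled mean of Wald ratios.  When Cochran's Q exceeds its degrees of
    freedom the SE is inflated by √(Q/df) (multiplicative random effects)."""
    _require(h, 2, "ivw")
    g, G, seG = h.gamma, h.capital_gamma, h.se_capital_gamma
    if np.any(g == 0.0):
        keep = g != 0.0
        g, G, seG = g[keep], G[keep], seG[keep]
        _require_n(len(g), 2, "ivw")
    beta, se, q = _ivw_arrays(g, G, seG)
    df = len(g) - 1
    model = "fixed"
    if df > 0 and q / df > 1.0:
        se *= math.sqrt(q / df)
        model = "multiplicative-random"
    pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    return MREstimate.from_beta_se("ivw", beta, se, float(pval), len(g), model=model)


def _require_n(n: int, minimum: int, method: str) -> None:
    if n < minimum:
        raise InsufficientInstrumentsError(f"{method}: needs >= {minimum} instruments, got {n}")


def egger(h: HarmonizedInstrumentSet) -> MREstimate:
    """MR-Egger: weighted regression of Γ on γ with a free intercept and
    weights 1/se_Γ².  Instruments are oriented so γ_j ≥ 0 (the standard
    convention; estimates are then invariant to per-SNP allele relabelling).
    The intercept estimates the average directional-pleiotropy effect; its
    p-value is the usual pleiotropy diagnostic.  SEs carry a multiplicative
    overdispersion factor floored at 1; p-values use t with J−2 df."""
    _require(h, 3, "egger")
    g, G, seG = h.gamma.copy(), h.capital_gamma.copy(), h.se_capital_gamma
    flip = g < 0
    g[flip] *= -1.0
    G = np.where(flip, -G, G)
    w = 1.0 / seG**2
    X = np.column_stack([np.ones_like(g), g])
    # weighted least squares via the normal equations (2 parameters)
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ G)
    resid = G - X @ coef
    df = len(g) - 2
    sigma2 = float(np.sum(w * resid**2) / df) if df > 0 else np.nan
    sigma2 = max(sigma2, 1.0)  # overdispersion floored at 1
    cov = sigma2 * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df) if se_slope > 0 else 0.0
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, df) if se_int > 0 else 0.0
    return MREstimate.from_beta_se(
        "egger", slope, se_slope, float(p_slope), len(g),
        egger_intercept=intercept, egger_intercept_p=float(p_int),
    )


def _weighted_median_arrays(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    w = weight[order] / weight.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    h: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator: the interpolated Wald ratio at cumulative
    inverse-variance weight 0.5; consistent when instruments carrying at
    least half the weight are valid.  SE by seeded parametric bootstrap
    (γ_j, Γ_j resampled from normals with their SEs)."""
    _require(h, 3, "weighted_median")
    ratio, se_ratio = wald_ratios(h)
    _require_n(len(ratio), 3, "weighted_median")
    weight = 1.0 / se_ratio**2
    beta = _weighted_median_arrays(ratio, weight)
    se = _bootstrap_se(h, lambda r, w: _weighted_median_arrays(r, w),
                       weighted=True, n_boot=n_boot, seed=seed)
    pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    return MREstimate.from_beta_se("weighted_median", beta, se, float(pval), len(ratio))


def _mode_arrays(ratio: np.ndarray, weight: np.ndarray, bandwidth_factor: float) -> float:
    """Kernel-smoothed weighted mode of the Wald ratios on a fixed grid.

    Bandwidth: 0.9·min(SD, MAD/0.6745)·J^(−1/5), scaled by bandwidth_factor
    (Silverman's rule on the robust scale estimate).
    """
    w = weight / weight.sum()
    mad = float(np.median(np.abs(ratio - np.median(ratio))))
    sd = float(np.std(ratio, ddof=1)) if len(ratio) > 1 else 0.0
    scale = min(sd, mad / 0.6745) if mad > 0 else sd
    if scale <= 0:
        # all ratios (nearly) identical: the mode is their common value
        return float(np.median(ratio))
    h_bw = bandwidth_factor * 0.9 * scale * len(ratio) ** (-0.2)
    lo = ratio.min() - 3 * h_bw
    hi = ratio.max() + 3 * h_bw
    grid = np.linspace(lo, hi, 2048)
    dens = np.sum(
        w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h_bw) ** 2), axis=0
    )
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    h: HarmonizedInstrumentSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimator: argmax of a Gaussian-kernel density over the Wald
    ratios, inverse-variance weighted (weighted mode) or uniform (simple
    mode); consistent when the largest group of instruments sharing one
    causal effect is valid.  SE by seeded parametric bootstrap."""
    _require(h, 3, "mode")
    ratio, se_ratio = wald_ratios(h)
    _require_n(len(ratio), 3, "mode")
    weight = 1.0 / se_ratio**2 if weighted else np.ones_like(ratio)
    beta = _mode_arrays(ratio, weight, bandwidth_factor)
    se = _bootstrap_se(h, lambda r, w: _mode_arrays(r, w, bandwidth_factor),
                       weighted=weighted, n_boot=n_boot, seed=seed)
    pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    name = "weighted_mode" if weighted else "simple_mode"
    return MREstimate.from_beta_se(name, beta, se, float(pval), len(ratio))


def _bootstrap_se(h, statistic, weighted: bool, n_boot: int, seed: int) -> float:
    """Parametric-bootstrap SE: resample (γ_j, Γ_j) from normals centred on
    the observed effects with their reported SEs, recompute the statistic."""
    if n_boot < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    g, seg = h.gamma, h.se_gamma
    G, seG = h.capital_gamma, h.se_capital_gamma
    keep = g != 0.0
    g, seg, G, seG = g[keep], seg[keep], G[keep], seG[keep]
    draws = np.empty(n_boot)
    for b in range(n_boot):
        gb = rng.normal(g, seg)
        Gb = rng.normal(G, seG)
        ok = gb != 0.0
        rb = Gb[ok] / gb[ok]
        sb = seG[ok] / np.abs(gb[ok])
        wb = 1.0 / sb**2 if weighted else np.ones_like(rb)
        draws[b] = statistic(rb, wb)
    return float(np.std(draws, ddof=1))


#: the five-method battery in the order reports print them
METHODS = ("ivw", "egger", "weighted_median", "weighted_mode", "simple_mode")


def run_all_methods(
    h: HarmonizedInstrumentSet,
    n_boot: int = 1000,
    bandwidth_factor: float = 1.0,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """All five estimators on one harmonized set; methods whose instrument
    minimum is not met are skipped with a log entry."""
    out: dict[str, MREstimate] = {}
    runners = {
        "ivw": lambda: ivw(h),
        "egger": lambda: egger(h),
        "weighted_median": lambda: weighted_median(h, n_boot=n_boot, seed=seed),
        "weighted_mode": lambda: mode_estimate(h, True, bandwidth_factor, n_boot, seed + 1),
        "simple_mode": lambda: mode_estimate(h, False, bandwidth_factor, n_boot, seed + 2),
    }
    for name, fn in runners.items():
        try:
            out[name] = fn()
        except InsufficientInstrumentsError as exc:
            log.info("%s/%s: %s", h.exposure, h.outcome, exc)
    return out
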