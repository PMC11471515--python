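"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q (IVW and Egger variants), the MR-PRESSO global / outlier /
distortion tests, and leave-one-out re-estimation.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _ivw_arrays, egger, ivw
from .instruments import HarmonizedInstrumentSet, InsufficientInstrumentsError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square upper-tail p-value."""

    q_stat: float
    df: int
    pval: float
    variant: str  # "ivw" | "egger"


@dataclass(frozen=True)
class LeaveOneOutResult:
    """IVW re-estimates, each row excluding one instrument."""

    df: pd.DataFrame  # columns: variant_id, beta, se, pval


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    rss_obs: float
    global_p: float
    n_sim: int
    outlier_indices: tuple[int, ...]
    outlier_variants: tuple[str, ...]
    outlier_pvals: tuple[float, ...]  # Bonferroni-adjusted, one per instrument
    distortion_p: float | None
    corrected_estimate: MREstimate | None
    seed: int


def cochran_q(h: HarmonizedInstrumentSet, variant: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q: Σ w_j (ratio_j − fit_j)² with w_j = γ_j²/se_Γj².

    For the IVW variant fit_j is the pooled IVW estimate (df = J−1); for the
    Egger variant fit_j is the Egger fitted ratio (intercept/γ_j + slope,
    df = J−2).  Identical to the overdispersion statistic driving IVW's
    random-effects fallback.
    """
    if variant not in ("ivw", "egger"):
        raise ValueError(f"unknown Q variant {variant!r}")
    g, G, seG = h.gamma, h.capital_gamma, h.se_capital_gamma
    keep = g != 0.0
    g, G, seG = g[keep], G[keep], seG[keep]
    n = len(g)
    df = n - 1 if variant == "ivw" else n - 2
    if df < 1:
        raise InsufficientInstrumentsError(f"cochran_q[{variant}]: df = {df} < 1")
    w = g**2 / seG**2
    ratio = G / g
    if variant == "ivw":
        _, _, q = _ivw_arrays(g, G, seG)
    else:
        est = egger(h)
        fit = (est.egger_intercept * np.sign(g) + est.beta * g) / g
        q = float(np.sum(w * (ratio - fit) ** 2))
    pval = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q_stat=float(q), df=df, pval=pval, variant=variant)


def leave_one_out(h: HarmonizedInstrumentSet) -> LeaveOneOutResult:
    """Re-run IVW J times, each run excluding one instrument."""
    if len(h) < 3:
        raise InsufficientInstrumentsError(f"leave_one_out: needs >= 3 instruments, got {len(h)}")
    rows = []
    ids = h.df["variant_id"].tolist()
    for i, vid in enumerate(ids):
        sub = h.take([j for j in range(len(ids)) if j != i])
        est = ivw(sub)
        rows.append({"variant_id": vid, "beta": est.beta, "se": est.se, "pval": est.pval})
    return LeaveOneOutResult(df=pd.DataFrame(rows))


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every j, from running sums."""
    swgG = np.sum(w * g * G)
    swgg = np.sum(w * g * g)
    return (swgG - w * g * G) / (swgg - w * g * g)


def mr_presso(
    h: HarmonizedInstrumentSet,
    n_sim: int = 1000,
    outlier_threshold: float = 0.05,
    seed: int = 0,
    n_distortion: int = 1000,
) -> PressoResult:
    """MR-PRESSO pleiotropy residual sum and outlier test.

    Global test: for each SNP j the leave-one-out IVW slope β̂₋j gives a
    residual r_j = Γ_j − β̂₋j·γ_j; the observed weighted RSS (weights
    1/se_Γ²) is compared against ``n_sim`` parametric replicates with
    Γ*_j ~ Normal(β̂₋j·γ_j, se_Γj²), p = (1 + #{RSS* ≥ RSS_obs})/(n_sim+1).

    Outlier test (run only when the global test is significant): each SNP's
    weighted squared residual against its own simulated null, Bonferroni-
    adjusted by the instrument count.  When outliers are found the corrected
    estimate is IVW on the remaining SNPs, and the distortion p compares the
    corrected-vs-full estimate shift against removals of random same-size
    instrument subsets.
    """
    n = len(h)
    if n < 4:
        raise InsufficientInstrumentsError(f"mr_presso: needs >= 4 instruments, got {n}")
    if n_sim < 100:
        log.warning("mr_presso: n_sim=%d gives coarse p-value resolution", n_sim)

    rng = np.random.default_rng(seed)
    # canonical internal order (by variant_id) so results do not depend on
    # the input row order; indices are mapped back at the end
    ids_in = h.df["variant_id"].tolist()
    perm = np.argsort(np.asarray(ids_in, dtype=object), kind="stable")
    g = h.gamma[perm]
    G = h.capital_gamma[perm]
    seG = h.se_capital_gamma[perm]
    w = 1.0 / seG**2

    b_loo = _loo_slopes(g, G, w)
    resid_obs = G - b_loo * g
    rss_j_obs = w * resid_obs**2
    rss_obs = float(np.sum(rss_j_obs))

    # parametric replicates: simulate Γ*, recompute LOO slopes per replicate
    G_sim = rng.normal(b_loo[None, :] * g[None, :], seG[None, :], size=(n_sim, n))
    swgg = np.sum(w * g * g)
    swgG_sim = G_sim @ (w * g)
    b_loo_sim = (swgG_sim[:, None] - (w * g)[None, :] * G_sim) / (swgg - w * g * g)[None, :]
    resid_sim = G_sim - b_loo_sim * g[None, :]
    rss_j_sim = w[None, :] * resid_sim**2
    rss_sim = rss_j_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outlier_idx: tuple[int, ...] = ()
    outlier_p = tuple(1.0 for _ in range(n))
    distortion_p = None
    corrected = None
    if global_p < outlier_threshold:
        p_raw = (1 + np.sum(rss_j_sim >= rss_j_obs[None, :], axis=0)) / (n_sim + 1)
        p_adj = np.minimum(p_raw * n, 1.0)
        # map per-SNP results back to the caller's row order
        p_adj_in = np.empty(n)
        p_adj_in[perm] = p_adj
        outlier_p = tuple(float(p) for p in p_adj_in)
        outlier_idx = tuple(sorted(int(perm[i]) for i in np.flatnonzero(p_adj < outlier_threshold)))
        if outlier_idx:
            keep = [i for i in range(n) if i not in outlier_idx]
            if len(keep) >= 2:
                corrected = ivw(h.take(keep))
                full = ivw(h)
                shift_obs = abs(corrected.beta - full.beta)
                # distortion: shifts from removing random subsets of the same size
                k = len(outlier_idx)
                shifts = np.empty(n_distortion)
                for b in range(n_distortion):
                    drop = rng.choice(n, size=k, replace=False)
                    keep_b = np.setdiff1d(np.arange(n), drop)
                    bb, _, _ = _ivw_arrays(g[keep_b], G[keep_b], seG[keep_b])
                    shifts[b] = abs(bb - full.beta)
                distortion_p = float((1 + np.sum(shifts >= shift_obs)) / (n_distortion + 1))
            else:
                log.warning("mr_presso: outlier removal leaves < 2 instruments; "
                            "no corrected estimate")

    ids = h.df["variant_id"].tolist()
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        n_sim=n_sim,
        outlier_indices=outlier_idx,
        outlier_variants=tuple(ids[i] for i in outlier_idx),
        outlier_pvals=outlier_p,
        distortion_p=distortion_p,
        corrected_estimate=corrected,
        seed=seed,
    )
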