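"""Benjamini-Hochberg FDR adjustment and significant/suggestive tiering.

Tiering convention: an association is *significant* when its BH-adjusted p
is below 0.05, *suggestive* when the raw p is below 0.05 but the adjusted p
is not, and *null* otherwise.  The adjustment family is one outcome across
all exposures of a panel (e.g. 41 cytokines, or 1,400 metabolite traits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass(frozen=True)
class TierDecision:
    raw_p: float
    fdr_p: float
    tier: str | None  # "significant" | "suggestive" | None


def bh_fdr(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    ``m`` optionally fixes the family size when the supplied vector is only
    the interesting subset of a larger family (the remaining members are
    assumed non-limiting, i.e. their step-up terms do not cap the minimum).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    adj = multipletests(p, method="fdr_bh")[1]
    if m is not None:
        if m < p.size:
            raise ValueError(f"family size m={m} smaller than vector length {p.size}")
        # rescale: multipletests used len(p) as family size; step-up with m
        # members is p_(i)·m/i cummin'd from the largest rank
        order = np.argsort(p, kind="stable")
        stepped = p[order] * m / (np.arange(p.size) + 1)
        adj_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        adj = np.empty_like(p)
        adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def bonferroni(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values (the stricter alternative family-wise bound)."""
    p = np.asarray(pvals, dtype=float)
    return np.minimum(p * (m if m is not None else p.size), 1.0)


def assign_tiers(
    raw: Sequence[float], adjusted: Sequence[float], alpha: float = ALPHA
) -> list[TierDecision]:
    """Pair raw and adjusted p-values into tier decisions."""
    raw = list(raw)
    adjusted = list(adjusted)
    if len(raw) != len(adjusted):
        raise ValueError(f"length mismatch: {len(raw)} raw vs {len(adjusted)} adjusted")
    out = []
    for p, q in zip(raw, adjusted):
        if q < alpha:
            tier = "significant"
        elif p < alpha:
            tier = "suggestive"
        else:
            tier = None
        out.append(TierDecision(raw_p=float(p), fdr_p=float(q), tier=tier))
    return out
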