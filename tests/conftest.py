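"""Shared fixtures: tiny hand-built instrument sets and simulated triplets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrmediate.instruments import HarmonizedInstrumentSet
from mrmediate.summstats import COLUMNS, TraitDataset

_ALLELES = [("A", "G"), ("T", "C"), ("C", "A"), ("G", "T")]


def make_dataset(
    name: str,
    betas,
    ses=None,
    pvals=None,
    eafs=None,
    chroms=None,
    positions=None,
    ns=None,
    trait_type: str = "continuous",
    alleles=None,
) -> TraitDataset:
    """Build a TraitDataset from parallel arrays with sensible filler values."""
    betas = np.asarray(betas, dtype=float)
    k = len(betas)
    ses = np.asarray(ses if ses is not None else np.full(k, 0.02), dtype=float)
    if pvals is None:
        from scipy import stats
        pvals = np.clip(2 * stats.norm.sf(np.abs(betas) / ses), 1e-300, 1.0)
    eafs = np.asarray(eafs if eafs is not None else np.full(k, 0.3), dtype=float)
    chroms = chroms if chroms is not None else [str(1 + i % 22) for i in range(k)]
    positions = positions if positions is not None else [1_000_000 * (i + 1) for i in range(k)]
    ns = ns if ns is not None else np.full(k, 10_000.0)
    alleles = alleles if alleles is not None else [_ALLELES[i % len(_ALLELES)] for i in range(k)]
    df = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(k)],
        "chrom": [str(c) for c in chroms],
        "pos": positions,
        "effect_allele": [a[0] for a in alleles],
        "other_allele": [a[1] for a in alleles],
        "eaf": eafs,
        "beta": betas,
        "se": ses,
        "pval": pvals,
        "n": ns,
    })
    return TraitDataset(name, trait_type, df[COLUMNS])


def make_harmonized(gamma, se_gamma, capital_gamma, se_capital_gamma,
                    delta=None, se_delta=None, variant_ids=None) -> HarmonizedInstrumentSet:
    """Build a HarmonizedInstrumentSet directly from effect arrays."""
    gamma = np.asarray(gamma, dtype=float)
    k = len(gamma)
    df = pd.DataFrame({
        "variant_id": variant_ids if variant_ids is not None
        else [f"rs{i + 1}" for i in range(k)],
        "gamma": gamma,
        "se_gamma": np.asarray(se_gamma, dtype=float),
        "capital_gamma": np.asarray(capital_gamma, dtype=float),
        "se_capital_gamma": np.asarray(se_capital_gamma, dtype=float),
        "alignment_flag": ["kept-as-is"] * k,
    })
    if delta is not None:
        df["delta"] = np.asarray(delta, dtype=float)
        df["se_delta"] = np.asarray(se_delta, dtype=float)
    return HarmonizedInstrumentSet(exposure="E", outcome="O", df=df,
                                   mediator="M" if delta is not None else None)


@pytest.fixture
def rng():
    return np.random.default_rng(20240930)


@pytest.fixture
def random_harmonized(rng):
    """A 12-instrument set with strong instruments and mild outcome noise."""
    k = 12
    gamma = rng.normal(0.0, 0.2, k)
    gamma += np.sign(gamma) * 0.08  # keep instruments away from zero
    se_gamma = np.full(k, 0.02)
    theta = 0.3
    se_G = np.full(k, 0.03)
    capital = theta * gamma + rng.normal(0.0, 0.02, k)
    return make_harmonized(gamma, se_gamma, capital, se_G)
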