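"""Seeded generator of multi-trait GWAS summary statistics.

Simulates the summary-level data of a two-sample MR mediation study under a
known structural model: instruments for a continuous exposure (standardized
scale, cohort of ~8,300), a continuous mediator with its own instruments
(~8,300), and a large case-control outcome on the log-odds scale.  Per SNP j:

* MAF_j ~ Uniform(maf_range), true exposure effect γ_j ~ Normal(0, effect_sd²);
* true mediator effect δ_j = τ·γ_j (plus the mediator's own instruments);
* true outcome effect Γ_j = θ_direct·γ_j + θ_mo·δ_j + α_j, where α_j is the
  horizontal-pleiotropy term (zero, balanced, or directional);
* per-trait SEs 1/√(2·MAF·(1−MAF)·N), with the effective case-control size
  N_eff = 4/(1/cases + 1/controls) for the binary outcome;
* observed effects are truth plus Normal(0, SE²) noise unless ``noiseless``.

Instrument *selection* is part of what the generator emulates: candidate
effects are drawn and a candidate becomes an instrument only if its observed
exposure association passes the selection threshold (default p < 1e-5), the
same screen a real analysis applies.  Selected instruments therefore carry
per-SNP F-statistics of roughly 19.5 upward by construction, matching the
strength profile of published metabolite/cytokine instrument sets.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .summstats import COLUMNS, TraitDataset

log = logging.getLogger(__name__)

# non-palindromic allele pairs (effect, other); strand-resolvable
_NON_PALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated exposure→mediator→outcome triplet.

    Defaults mirror the cohorts the generator emulates: a metabolite GWAS of
    8,299, a cytokine GWAS of 8,293, and a VTE-like FinnGen endpoint with
    21,021 cases / 391,160 controls; instrument counts sit inside the
    published 7-73 (exposure) and 4-17 (cytokine) ranges.
    """

    n_snps: int = 25                 # exposure instruments
    n_mediator_snps: int = 12        # mediator-only instruments
    n_outcome_snps: int = 0          # outcome-specific susceptibility loci
    n_exposure: int = 8_299
    n_mediator: int = 8_293
    n_outcome_cases: int = 21_021
    n_outcome_controls: int = 391_160
    theta_em: float = 0.0            # τ: exposure → mediator
    theta_mo: float = 0.0            # mediator → outcome
    theta_direct: float = 0.0        # exposure → outcome, not through mediator
    pleiotropy_mode: str = "none"    # none | balanced | directional
    pleiotropy_sd: float = 0.05
    pleiotropy_mean: float = 0.05    # α mean under directional pleiotropy
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd: float = 0.2           # SD of true instrument effects (SD units)
    select_p: float = 1e-5           # observed-association selection threshold
    palindrome_fraction: float = 0.0
    seed: int = 0
    noiseless: bool = False

    def __post_init__(self) -> None:
        if min(self.n_exposure, self.n_mediator,
               self.n_outcome_cases, self.n_outcome_controls) <= 0:
            raise ValueError("all sample sizes must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.effect_sd <= 0:
            raise ValueError("effect_sd must be > 0 (instruments must be relevant)")
        if self.n_snps < 2:
            raise ValueError("need at least 2 exposure instruments")

    @property
    def n_outcome_eff(self) -> float:
        """Effective sample size of the case-control outcome,
        4/(1/cases + 1/controls)."""
        return 4.0 / (1.0 / self.n_outcome_cases + 1.0 / self.n_outcome_controls)

    @property
    def total_effect(self) -> float:
        """θ_direct + τ·θ_mo, the structural total exposure→outcome effect."""
        return self.theta_direct + self.theta_em * self.theta_mo

    @property
    def mediated_proportion(self) -> float:
        """τ·θ_mo/(θ_direct + τ·θ_mo)."""
        return self.theta_em * self.theta_mo / self.total_effect


def _draw_selected_effects(rng, n_wanted, n_sample, effect_sd, maf_range, select_p,
                           noiseless):
    """Draw (maf, true effect, se, observed effect) quadruplets until
    ``n_wanted`` candidates pass the observed selection threshold."""
    z_min = stats.norm.isf(select_p / 2.0)
    mafs, trues, ses, obss = [], [], [], []
    guard = 0
    while len(mafs) < n_wanted:
        guard += 1
        if guard > 10_000:
            raise RuntimeError(
                "instrument selection not converging; effect_sd too small "
                "relative to the selection threshold"
            )
        batch = max(4 * (n_wanted - len(mafs)), 16)
        maf = rng.uniform(*maf_range, size=batch)
        true = rng.normal(0.0, effect_sd, size=batch)
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_sample)
        obs = true if noiseless else true + rng.normal(0.0, se)
        passed = np.abs(obs) / se > z_min
        for m, t, s, o in zip(maf[passed], true[passed], se[passed], obs[passed]):
            if len(mafs) < n_wanted:
                mafs.append(m); trues.append(t); ses.append(s); obss.append(o)
    return (np.array(mafs), np.array(trues), np.array(ses), np.array(obss))


def simulate_summary_stats(
    config: SimulationConfig,
) -> tuple[TraitDataset, TraitDataset, TraitDataset, SimulationConfig]:
    """Simulate (exposure, mediator, outcome) summary statistics plus the
    echoed truth.  Deterministic given the config (which carries the seed).

    Every returned dataset contains the same variants (exposure instruments
    followed by mediator-only instruments) so the three files behave like
    slices of genome-wide GWAS exports restricted to the loci of interest.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_e, n_m, n_o = cfg.n_snps, cfg.n_mediator_snps, cfg.n_outcome_snps
    n_tot = n_e + n_m + n_o

    # exposure instruments: selected on the observed exposure association
    maf_e, g_true_e, se_e_e, g_obs_e = _draw_selected_effects(
        rng, n_e, cfg.n_exposure, cfg.effect_sd, cfg.maf_range, cfg.select_p,
        cfg.noiseless)
    # mediator-only instruments: selected on the observed mediator association
    maf_m, d_true_m, se_m_m, d_obs_m = _draw_selected_effects(
        rng, n_m, cfg.n_mediator, cfg.effect_sd, cfg.maf_range, cfg.select_p,
        cfg.noiseless) if n_m > 0 else (np.empty(0),) * 4
    # outcome-specific susceptibility loci (no exposure/mediator effect)
    maf_o, G_true_o, se_o_o, G_obs_o = _draw_selected_effects(
        rng, n_o, cfg.n_outcome_eff, cfg.effect_sd, cfg.maf_range, cfg.select_p,
        cfg.noiseless) if n_o > 0 else (np.empty(0),) * 4

    maf = np.concatenate([maf_e, maf_m, maf_o])

    # structural truth per variant
    gamma_true = np.concatenate([g_true_e, np.zeros(n_m + n_o)])
    delta_true = np.concatenate([cfg.theta_em * g_true_e, d_true_m, np.zeros(n_o)])
    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(n_tot)
    elif cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, size=n_tot)
    else:
        # directional: mean mu > 0 relative to the exposure-increasing allele
        # (the frame in which the InSIDE assumption and the Egger intercept
        # are defined); SNPs without an exposure effect keep the raw draw
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_tot)
        orient = np.where(gamma_true != 0.0, np.sign(gamma_true), 1.0)
        alpha = alpha * orient
    capital_true = cfg.theta_direct * gamma_true + cfg.theta_mo * delta_true + alpha
    if n_o > 0:
        capital_true[n_e + n_m:] += G_true_o

    # per-trait standard errors
    het = 2.0 * maf * (1.0 - maf)
    se_exp = 1.0 / np.sqrt(het * cfg.n_exposure)
    se_med = 1.0 / np.sqrt(het * cfg.n_mediator)
    se_out = 1.0 / np.sqrt(het * cfg.n_outcome_eff)

    # observed effects: selection already fixed the instruments' own-trait
    # observations; the remaining trait/variant combinations get fresh noise
    def _observe(true, se):
        return true.copy() if cfg.noiseless else true + rng.normal(0.0, se)

    beta_exp = np.concatenate([g_obs_e, _observe(gamma_true[n_e:], se_exp[n_e:])])
    beta_med = np.concatenate([_observe(delta_true[:n_e], se_med[:n_e]), d_obs_m,
                               _observe(delta_true[n_e + n_m:], se_med[n_e + n_m:])])
    if n_o > 0:
        # outcome loci keep their selection-conditioned observations
        beta_out = np.concatenate([_observe(capital_true[:n_e + n_m],
                                            se_out[:n_e + n_m]), G_obs_o])
    else:
        beta_out = _observe(capital_true, se_out)

    # variant annotation: ids, scattered genomic positions, resolvable alleles
    chrom = rng.integers(1, 23, size=n_tot).astype(str)
    pos = rng.integers(1, 250_000_000, size=n_tot)
    pal = rng.random(n_tot) < cfg.palindrome_fraction
    pairs = [
        _PALINDROMIC[rng.integers(len(_PALINDROMIC))] if p
        else _NON_PALINDROMIC[rng.integers(len(_NON_PALINDROMIC))]
        for p in pal
    ]
    ea = np.array([p[0] for p in pairs])
    oa = np.array([p[1] for p in pairs])
    minor_is_effect = rng.random(n_tot) < 0.5
    eaf = np.where(minor_is_effect, maf, 1.0 - maf)
    # ids unique across seeds so panels simulated under different seeds can
    # be screened against one pooled outcome without accidental collisions
    vid = np.array([f"rs{cfg.seed * 10_000 + i}" for i in range(n_tot)])

    def _dataset(name, ttype, beta, se, n) -> TraitDataset:
        p = 2.0 * stats.norm.sf(np.abs(beta) / se)
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
        df = pd.DataFrame({
            "variant_id": vid, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "beta": beta, "se": se, "pval": p,
            "n": float(n) * np.ones(n_tot),
        })
        return TraitDataset(name, ttype, df[COLUMNS])

    exposure = _dataset("exposure", "continuous", beta_exp, se_exp, cfg.n_exposure)
    mediator = _dataset("mediator", "continuous", beta_med, se_med, cfg.n_mediator)
    outcome = _dataset("outcome", "binary", beta_out, se_out,
                       cfg.n_outcome_cases + cfg.n_outcome_controls)
    return exposure, mediator, outcome, cfg


def inject_outlier(
    dataset: TraitDataset, variant_id: str, shift_in_se: float
) -> TraitDataset:
    """Shift one variant's beta by ``shift_in_se`` × its SE (pleiotropic-
    outlier fixture); the p-value is updated to stay consistent."""
    df = dataset.df.copy()
    hit = df["variant_id"] == variant_id
    if not hit.any():
        raise KeyError(f"variant {variant_id!r} not in dataset {dataset.trait_name}")
    df.loc[hit, "beta"] = df.loc[hit, "beta"] + shift_in_se * df.loc[hit, "se"]
    z = np.abs(df.loc[hit, "beta"]) / df.loc[hit, "se"]
    df.loc[hit, "pval"] = np.clip(2.0 * stats.norm.sf(z), np.nextafter(0.0, 1.0), 1.0)
    return TraitDataset(dataset.trait_name, dataset.trait_type, df)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["maf_range"] = list(d["maf_range"])
    return d
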