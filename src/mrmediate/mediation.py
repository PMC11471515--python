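"""Multivariable MR and the two-step mediation calculus.

The mediation model follows the product-of-coefficients decomposition for an
exposure E, mediator M and outcome O:

* total effect β_EO (univariable IVW of E on O);
* first leg β_EM (univariable IVW of E on M);
* MVMR direct effects β'_EO and β'_MO (joint weighted regression of the
  SNP-outcome effects on SNP-exposure and SNP-mediator effects);
* mediated effect β_EMO = β_EM · β'_MO with delta-method SE
  √(β'_MO²·SE_EM² + β_EM²·SE'_MO²), 95% CI β_EMO ± 1.96·SE_EMO, and
  mediated proportion β_EMO/β_EO.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .estimators import Z95, MREstimate, ivw
from .instruments import HarmonizedInstrumentSet, InsufficientInstrumentsError
from .summstats import SummaryStatsError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MVMRResult:
    """Direct effects of exposure and mediator on the outcome, with SEs and
    per-exposure conditional instrument-strength diagnostics."""

    direct_exposure_effect: float   # β'_EO
    se_direct_exposure: float
    direct_mediator_effect: float   # β'_MO
    se_direct_mediator: float
    n_snp: int
    conditional_f_exposure: float
    conditional_f_mediator: float

    @property
    def ci_exposure(self) -> tuple[float, float]:
        return (self.direct_exposure_effect - Z95 * self.se_direct_exposure,
                self.direct_exposure_effect + Z95 * self.se_direct_exposure)

    @property
    def ci_mediator(self) -> tuple[float, float]:
        return (self.direct_mediator_effect - Z95 * self.se_direct_mediator,
                self.direct_mediator_effect + Z95 * self.se_direct_mediator)


@dataclass(frozen=True)
class TwoStepTriplet:
    """The three univariable IVW legs of a candidate mediation pathway."""

    beta_em: float
    se_em: float
    p_em: float
    beta_mo: float
    se_mo: float
    p_mo: float
    beta_eo: float
    se_eo: float
    p_eo: float
    flagged: bool                 # all three legs p < 0.05
    consistent_direction: bool    # sign(β_EM·β_MO) == sign(β_EO)


@dataclass(frozen=True)
class MediationResult:
    """Product-of-coefficients mediated effect with delta-method SE."""

    beta_em: float
    se_em: float
    beta_prime_mo: float
    se_prime_mo: float
    beta_eo: float
    beta_emo: float
    se_emo: float
    ci_low: float
    ci_high: float
    p_emo: float
    proportion: float       # β_EMO/β_EO; nan when β_EO = 0
    proportion_pct: float
    ci_includes_zero: bool


def se_from_ci(low: float, high: float, level: float = 0.95) -> float:
    """Standard error back-derived from a symmetric normal confidence interval:
    (high − low)/(2·z) with z the two-sided normal quantile."""
    if not (low < high):
        raise ValueError(f"need low < high, got ({low}, {high})")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0,1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (high - low) / (2.0 * z)


def mvmr_fit(h: HarmonizedInstrumentSet) -> MVMRResult:
    """Weighted multivariable regression of Γ on (γ_exposure, γ_mediator)
    with no intercept and weights 1/se_Γ².  SEs carry a multiplicative
    overdispersion factor floored at 1.  Conditional F per exposure is
    Q_x/(J−2), where Q_x is the weighted residual heterogeneity of that
    exposure's instrument effects regressed on the other's (a
    Sanderson-Windmeijer-style weak-instrument diagnostic)."""
    if h.delta is None:
        raise SummaryStatsError("mvmr_fit: harmonized set has no mediator effects")
    n = len(h)
    if n < 4:
        raise InsufficientInstrumentsError(f"mvmr_fit: needs >= 4 instruments, got {n}")
    g = h.gamma
    d = h.delta
    G = h.capital_gamma
    seG = h.se_capital_gamma
    if np.all(d == 0.0):
        # degenerate but well-defined: the model collapses to univariable IVW
        uni = ivw(h)
        return MVMRResult(
            direct_exposure_effect=uni.beta, se_direct_exposure=uni.se,
            direct_mediator_effect=0.0, se_direct_mediator=float("nan"),
            n_snp=n, conditional_f_exposure=float("nan"),
            conditional_f_mediator=float("nan"),
        )
    if float(np.std(g)) == 0.0 or float(np.std(d)) == 0.0:
        raise SummaryStatsError("mvmr_fit: an exposure column has no variation")
    X = np.column_stack([g, d])
    corr = np.corrcoef(g, d)[0, 1]
    if abs(corr) > 1.0 - 1e-10:
        raise SummaryStatsError(
            f"mvmr_fit: exposure and mediator instrument effects are collinear (r={corr:.6f})"
        )
    w = 1.0 / seG**2
    fit = sm.WLS(G, X, weights=w).fit()
    df = n - 2
    sigma2 = max(float(fit.mse_resid) if df > 0 else 1.0, 1.0)
    cov = sigma2 * np.asarray(fit.normalized_cov_params)
    se = np.sqrt(np.diag(cov))

    def _conditional_f(target, target_se, other) -> float:
        wt = 1.0 / np.asarray(target_se) ** 2
        sub = sm.WLS(target, other[:, None], weights=wt).fit()
        q = float(np.sum(wt * (target - sub.fittedvalues) ** 2))
        return q / (n - 2)

    se_g = h.se_gamma
    se_d = h.se_delta
    return MVMRResult(
        direct_exposure_effect=float(fit.params[0]),
        se_direct_exposure=float(se[0]),
        direct_mediator_effect=float(fit.params[1]),
        se_direct_mediator=float(se[1]),
        n_snp=n,
        conditional_f_exposure=_conditional_f(g, se_g, d),
        conditional_f_mediator=_conditional_f(d, se_d, g),
    )


def two_step_effects(
    em: MREstimate, mo: MREstimate, eo: MREstimate, alpha: float = 0.05
) -> TwoStepTriplet:
    """Package the three univariable IVW legs of a mediation pathway and
    flag the candidate for MVMR confirmation when all three are significant
    at ``alpha``.  A candidate whose β_EM·β_MO sign opposes β_EO is still
    flagged but labelled inconsistent-direction."""
    for leg, est in (("exposure→mediator", em), ("mediator→outcome", mo),
                     ("exposure→outcome", eo)):
        if est is None:
            raise SummaryStatsError(f"two_step_effects: missing {leg} estimate")
        if est.method != "ivw":
            raise SummaryStatsError(f"two_step_effects: {leg} estimate is {est.method}, not ivw")
    flagged = em.pval < alpha and mo.pval < alpha and eo.pval < alpha
    consistent = math.copysign(1.0, em.beta * mo.beta) == math.copysign(1.0, eo.beta)
    if flagged and not consistent:
        log.info("two_step_effects: candidate flagged but direction inconsistent "
                 "(sign(β_EM·β_MO) != sign(β_EO))")
    return TwoStepTriplet(
        beta_em=em.beta, se_em=em.se, p_em=em.pval,
        beta_mo=mo.beta, se_mo=mo.se, p_mo=mo.pval,
        beta_eo=eo.beta, se_eo=eo.se, p_eo=eo.pval,
        flagged=flagged, consistent_direction=consistent,
    )


def mediation_effect(
    beta_em: float,
    se_em: float,
    beta_prime_mo: float,
    se_prime_mo: float,
    beta_eo: float,
) -> MediationResult:
    """Product-of-coefficients mediated effect.

    β_EMO = β_EM·β'_MO; SE_EMO = √(β'_MO²·SE_EM² + β_EM²·SE'_MO²);
    95% CI = β_EMO ± 1.96·SE_EMO; p two-sided normal on β_EMO/SE_EMO;
    mediated proportion β_EMO/β_EO (undefined, returned as nan, when
    β_EO = 0).
    """
    if se_em < 0 or se_prime_mo < 0:
        raise ValueError("standard errors must be >= 0")
    beta_emo = beta_em * beta_prime_mo
    se_emo = math.sqrt(beta_prime_mo**2 * se_em**2 + beta_em**2 * se_prime_mo**2)
    ci_low = beta_emo - Z95 * se_emo
    ci_high = beta_emo + Z95 * se_emo
    if se_emo > 0:
        p = 2.0 * stats.norm.sf(abs(beta_emo) / se_emo)
    else:
        p = 0.0 if beta_emo != 0 else 1.0
    if beta_eo == 0.0:
        log.warning("mediation_effect: beta_eo = 0, mediated proportion undefined")
        prop = float("nan")
    else:
        prop = beta_emo / beta_eo
    return MediationResult(
        beta_em=beta_em, se_em=se_em,
        beta_prime_mo=beta_prime_mo, se_prime_mo=se_prime_mo,
        beta_eo=beta_eo,
        beta_emo=beta_emo, se_emo=se_emo,
        ci_low=ci_low, ci_high=ci_high, p_emo=float(p),
        proportion=prop, proportion_pct=prop * 100.0,
        ci_includes_zero=bool(ci_low <= 0.0 <= ci_high),
    )


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (table-printing convention), e.g.
    round_half_away(0.0865, 3) == 0.087 and round_half_away(-0.0865, 3) == -0.087."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def mediation_from_pipeline(
    em: MREstimate, mvmr: MVMRResult, eo: MREstimate
) -> MediationResult:
    """Convenience wiring: first-leg IVW + MVMR direct mediator effect +
    total-effect IVW into the mediation calculus."""
    return mediation_effect(
        beta_em=em.beta, se_em=em.se,
        beta_prime_mo=mvmr.direct_mediator_effect,
        se_prime_mo=mvmr.se_direct_mediator,
        beta_eo=eo.beta,
    )
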