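"""End-to-end orchestration of the MR screen, the mediation analysis, and
the reverse-direction screen.

Each stage is deterministic given (inputs, config, seed): per-pair seeds are
derived from the run seed and the pair's position, every dropped SNP or
skipped pair is logged with a reason code, and the resolved configuration is
written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import fdr as fdr_mod
from .estimators import MREstimate, ivw, run_all_methods
from .instruments import (
    HarmonizedInstrumentSet,
    InsufficientInstrumentsError,
    LDLookup,
    drop_palindromes,
    exclude_listed_snps,
    filter_weak_instruments,
    greedy_clump,
    harmonize,
    read_exclusion_list,
    select_by_pvalue,
)
from .mediation import (
    MediationResult,
    MVMRResult,
    TwoStepTriplet,
    mediation_from_pipeline,
    mvmr_fit,
    two_step_effects,
)
from .sensitivity import cochran_q, leave_one_out, mr_presso
from .summstats import (
    ReportRow,
    SummaryStatsError,
    TraitDataset,
    read_summary_stats,
    write_report,
)

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Resolved settings of one pipeline run.

    Defaults mirror the screen's standard thresholds: instrument selection at
    p < 1e-5 (metabolite-style panels; 5e-6 is the cytokine convention),
    clumping at r² = 0.001 within 10,000 kb, palindrome exclusion at
    eaf ∈ [0.42, 0.58], per-SNP F ≥ 10, and BH-FDR at 0.05.
    """

    exposure_files: list[str] = field(default_factory=list)
    panel_label: str = "exposures"
    mediator_file: str | None = None
    outcome_files: list[str] = field(default_factory=list)
    exposure_trait_type: str = "continuous"
    mediator_trait_type: str = "continuous"
    outcome_trait_type: str = "binary"
    p_iv: float = 1e-5
    p_iv_mediator: float = 5e-6
    p_iv_reverse: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    maf_band: tuple[float, float] = (0.42, 0.58)
    min_f: float = 10.0
    ld_file: str | None = None
    exclude_file: str | None = None
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    presso_sims: int = 1000
    presso_threshold: float = 0.05
    fdr_family: int | None = None   # None: family = number of exposures screened
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "maf_band" in raw:
            raw["maf_band"] = tuple(raw["maf_band"])
        return cls(**raw)

    def dump(self, path) -> None:
        d = dataclasses.asdict(self)
        d["maf_band"] = list(d["maf_band"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _pair_seed(base: int, index: int) -> int:
    return (base * 100_003 + 7919 * (index + 1)) % (2**31)


def prepare_instruments(
    exposure: TraitDataset,
    config: AnalysisConfig,
    ld: LDLookup | None = None,
    exclusion: set[str] | None = None,
    p_threshold: float | None = None,
) -> TraitDataset:
    """Instrument-building chain for one exposure: p-value screen, greedy
    clumping, palindrome exclusion, confounder-list exclusion, weak-
    instrument (F < min_f) removal.  When no LD table is supplied at all the
    instruments are treated as independent (clumping then only enforces the
    window rule trivially); a supplied-but-incomplete table treats missing
    in-window pairs as correlated."""
    p_thr = p_threshold if p_threshold is not None else config.p_iv
    ds = select_by_pvalue(exposure, p_thr)
    if len(ds) == 0:
        return ds
    missing_policy = "correlated" if ld is not None else "independent"
    ds = greedy_clump(ds, ld or LDLookup(), r2_max=config.clump_r2,
                      window_kb=config.clump_kb, missing_policy=missing_policy)
    ds = drop_palindromes(ds, config.maf_band)
    if exclusion:
        ds = exclude_listed_snps(ds, exclusion)
    if len(ds) == 0:
        return ds
    return filter_weak_instruments(ds, min_f=config.min_f)


@dataclass
class PairResult:
    """Everything one exposure-outcome pair produced."""

    exposure: str
    outcome: str
    harmonized: HarmonizedInstrumentSet | None
    estimates: dict[str, MREstimate]
    het_q_p: float | None
    presso_global_p: float | None
    presso_outliers: tuple[str, ...]
    corrected_estimate: MREstimate | None
    loo_max_shift: float | None
    excluded_after_correction: bool
    skip_reason: str | None = None


def analyze_pair(
    exposure: TraitDataset,
    outcome: TraitDataset,
    config: AnalysisConfig,
    seed: int,
    ld: LDLookup | None = None,
    exclusion: set[str] | None = None,
    p_threshold: float | None = None,
) -> PairResult:
    """Run the full univariable battery on one exposure-outcome pair."""
    name = f"{exposure.trait_name}/{outcome.trait_name}"
    iv = prepare_instruments(exposure, config, ld, exclusion, p_threshold)
    if len(iv) < 2:
        log.info("%s: skipped (insufficient-instruments: %d survive selection)",
                 name, len(iv))
        return PairResult(exposure.trait_name, outcome.trait_name, None, {}, None,
                          None, (), None, None, False,
                          skip_reason="insufficient-instruments")
    try:
        h = harmonize(iv, outcome)
    except SummaryStatsError as exc:
        log.info("%s: skipped (harmonization: %s)", name, exc)
        return PairResult(exposure.trait_name, outcome.trait_name, None, {}, None,
                          None, (), None, None, False, skip_reason="harmonization-failure")
    if len(h) < 2:
        return PairResult(exposure.trait_name, outcome.trait_name, h, {}, None,
                          None, (), None, None, False,
                          skip_reason="insufficient-instruments")

    estimates = run_all_methods(h, n_boot=config.n_boot,
                                bandwidth_factor=config.bandwidth_factor, seed=seed)
    het_p = None
    if len(h) >= 2:
        het_p = cochran_q(h, "ivw").pval

    presso_p = None
    outliers: tuple[str, ...] = ()
    corrected = None
    excluded = False
    if len(h) >= 4:
        pres = mr_presso(h, n_sim=config.presso_sims,
                         outlier_threshold=config.presso_threshold, seed=seed)
        presso_p = pres.global_p
        outliers = pres.outlier_variants
        corrected = pres.corrected_estimate
        if corrected is not None and corrected.pval > config.alpha:
            # association lost after outlier correction: drop from downstream
            excluded = True
            log.info("%s: excluded (post-outlier-correction p=%.3g > %.2f)",
                     name, corrected.pval, config.alpha)

    loo_shift = None
    if len(h) >= 3 and "ivw" in estimates:
        loo = leave_one_out(h)
        loo_shift = float((loo.df["beta"] - estimates["ivw"].beta).abs().max())

    return PairResult(exposure.trait_name, outcome.trait_name, h, estimates,
                      het_p, presso_p, outliers, corrected, loo_shift, excluded)


def _rows_from_pairs(pairs: list[PairResult], config: AnalysisConfig) -> list[ReportRow]:
    """ReportRows for every method of every retained pair, with per-outcome
    BH-FDR and tiering of the IVW rows."""
    rows: list[ReportRow] = []
    by_outcome: dict[str, list[PairResult]] = {}
    for pr in pairs:
        if pr.skip_reason or pr.excluded_after_correction or "ivw" not in pr.estimates:
            continue
        by_outcome.setdefault(pr.outcome, []).append(pr)

    for outcome, group in by_outcome.items():
        raw = [pr.estimates["ivw"].pval for pr in group]
        m = config.fdr_family if config.fdr_family is not None else len(raw)
        adj = fdr_mod.bh_fdr(raw, m=m)
        tiers = fdr_mod.assign_tiers(raw, adj, alpha=config.alpha)
        for pr, q, tier in zip(group, adj, tiers):
            for method, est in pr.estimates.items():
                is_ivw = method == "ivw"
                rows.append(ReportRow(
                    exposure=pr.exposure, outcome=outcome, method=method,
                    n_snp=est.n_snp, beta=est.beta, se=est.se, pval=est.pval,
                    or_=est.or_, ci_low=est.ci_low, ci_high=est.ci_high,
                    p_fdr=float(q) if is_ivw else None,
                    het_q_p=pr.het_q_p if is_ivw else None,
                    presso_p=pr.presso_global_p if is_ivw else None,
                    tier=tier.tier if is_ivw else None,
                ))
    return rows


def _load_many(paths, trait_type) -> list[TraitDataset]:
    return [read_summary_stats(p, trait_type=trait_type, trait_name=Path(p).stem)
            for p in paths]


def run_screen(
    config: AnalysisConfig,
    exposures: list[TraitDataset] | None = None,
    outcomes: list[TraitDataset] | None = None,
    write: bool = True,
    reverse: bool = False,
) -> list[ReportRow]:
    """The exposure screen: per exposure-outcome pair run IV selection,
    harmonization, the five estimators, Cochran's Q, MR-PRESSO and
    leave-one-out; drop exposures that lose their association after outlier
    correction; BH-FDR and tiering per outcome.  ``reverse=True`` swaps the
    roles (outcome-as-exposure at the binary-trait selection threshold)."""
    if exposures is None:
        exposures = _load_many(config.exposure_files, config.exposure_trait_type)
    if outcomes is None:
        outcomes = _load_many(config.outcome_files, config.outcome_trait_type)
    if not exposures or not outcomes:
        raise SummaryStatsError("run_screen: need at least one exposure and one outcome")
    if reverse:
        exposures, outcomes = outcomes, exposures

    ld = LDLookup.from_file(config.ld_file) if config.ld_file else None
    excl = read_exclusion_list(config.exclude_file) if config.exclude_file else None
    p_thr = config.p_iv_reverse if reverse else None

    pairs: list[PairResult] = []
    idx = 0
    for outcome in outcomes:
        for exposure in exposures:
            pairs.append(analyze_pair(exposure, outcome, config,
                                      seed=_pair_seed(config.seed, idx),
                                      ld=ld, exclusion=excl, p_threshold=p_thr))
            idx += 1

    rows = _rows_from_pairs(pairs, config)
    if write and rows:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prefix = "reverse" if reverse else "screen"
        for outcome in {r.outcome for r in rows}:
            write_report([r for r in rows if r.outcome == outcome],
                         out / f"{prefix}_{outcome}.tsv")
        config.dump(out / f"{prefix}_config.yaml")
    return rows


def run_reverse(
    config: AnalysisConfig,
    exposures: list[TraitDataset] | None = None,
    outcomes: list[TraitDataset] | None = None,
    write: bool = True,
) -> list[ReportRow]:
    """Reverse-direction MR: identical machinery with the roles swapped."""
    return run_screen(config, exposures, outcomes, write=write, reverse=True)


@dataclass
class MediationRow:
    """One candidate pathway's two-step triplet plus MVMR mediation result."""

    exposure: str
    mediator: str
    outcome: str
    triplet: TwoStepTriplet
    mvmr: MVMRResult | None
    mediation: MediationResult | None


def run_mediation(
    config: AnalysisConfig,
    exposures: list[TraitDataset] | None = None,
    mediator: TraitDataset | None = None,
    outcomes: list[TraitDataset] | None = None,
    write: bool = True,
) -> list[MediationRow]:
    """Two-step + MVMR mediation per (exposure, outcome) pair.

    Gate: all three univariable IVW legs (exposure→mediator,
    mediator→outcome, exposure→outcome) significant at ``alpha``; gated
    candidates go to MVMR on the union of the exposure's and mediator's
    instruments (re-harmonized to the outcome, jointly de-clumped), and the
    mediated effect is β_EM × β'_MO with the delta-method SE."""
    if exposures is None:
        exposures = _load_many(config.exposure_files, config.exposure_trait_type)
    if outcomes is None:
        outcomes = _load_many(config.outcome_files, config.outcome_trait_type)
    if mediator is None:
        if not config.mediator_file:
            raise SummaryStatsError("run_mediation: mediator file required")
        mediator = read_summary_stats(config.mediator_file,
                                      trait_type=config.mediator_trait_type,
                                      trait_name=Path(config.mediator_file).stem)

    ld = LDLookup.from_file(config.ld_file) if config.ld_file else None
    excl = read_exclusion_list(config.exclude_file) if config.exclude_file else None

    med_iv = prepare_instruments(mediator, config, ld, excl,
                                 p_threshold=config.p_iv_mediator)

    rows: list[MediationRow] = []
    idx = 0
    for outcome in outcomes:
        # mediator → outcome leg is shared across exposures of one outcome
        try:
            mo_est = ivw(harmonize(med_iv, outcome))
        except (SummaryStatsError, InsufficientInstrumentsError) as exc:
            log.warning("mediator/%s: no mediator→outcome estimate (%s); "
                        "outcome skipped", outcome.trait_name, exc)
            continue
        for exposure in exposures:
            idx += 1
            seed = _pair_seed(config.seed, idx)
            exp_iv = prepare_instruments(exposure, config, ld, excl)
            if len(exp_iv) < 2:
                log.info("%s: skipped in mediation (insufficient-instruments)",
                         exposure.trait_name)
                continue
            try:
                em_est = ivw(harmonize(exp_iv, mediator))
                eo_est = ivw(harmonize(exp_iv, outcome))
            except (SummaryStatsError, InsufficientInstrumentsError) as exc:
                log.info("%s/%s: skipped in mediation (%s)",
                         exposure.trait_name, outcome.trait_name, exc)
                continue
            triplet = two_step_effects(em_est, mo_est, eo_est, alpha=config.alpha)
            mvmr = None
            med_res = None
            if triplet.flagged:
                union_ids = sorted(set(exp_iv.df["variant_id"]) |
                                   set(med_iv.df["variant_id"]))
                union_exp = exposure.subset(exposure.df["variant_id"].isin(union_ids))
                union_exp = greedy_clump(
                    union_exp, ld or LDLookup(), r2_max=config.clump_r2,
                    window_kb=config.clump_kb,
                    missing_policy="correlated" if ld is not None else "independent")
                try:
                    h3 = harmonize(union_exp, outcome, mediator)
                    mvmr = mvmr_fit(h3)
                    med_res = mediation_from_pipeline(em_est, mvmr, eo_est)
                except (SummaryStatsError, InsufficientInstrumentsError) as exc:
                    log.warning("%s/%s: MVMR failed (%s); pair reported without "
                                "mediation estimate", exposure.trait_name,
                                outcome.trait_name, exc)
            rows.append(MediationRow(exposure.trait_name, mediator.trait_name,
                                     outcome.trait_name, triplet, mvmr, med_res))

    if not rows:
        log.info("run_mediation: no candidate passed the two-step gate")
    if write and rows:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_two_step_table(rows, out / "mediation_two_step.tsv")
        write_mvmr_table(rows, out / "mediation_mvmr.tsv")
        config.dump(out / "mediation_config.yaml")
    return rows


def _f(x) -> str:
    return "" if x is None else f"{x:.3f}"


def _p(x) -> str:
    return "" if x is None else f"{x:.2E}"


def write_two_step_table(rows: list[MediationRow], path) -> None:
    """Two-step (TSMR) table: the three univariable legs per candidate."""
    header = ["exposure", "mediator", "outcome",
              "beta_EM", "SE_EM", "P_EM", "beta_MO", "SE_MO", "P_MO",
              "beta_EO", "SE_EO", "P_EO", "flagged", "consistent_direction"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            t = r.triplet
            fh.write("\t".join([
                r.exposure, r.mediator, r.outcome,
                _f(t.beta_em), _f(t.se_em), _p(t.p_em),
                _f(t.beta_mo), _f(t.se_mo), _p(t.p_mo),
                _f(t.beta_eo), _f(t.se_eo), _p(t.p_eo),
                str(t.flagged).lower(), str(t.consistent_direction).lower(),
            ]) + "\n")


def write_mvmr_table(rows: list[MediationRow], path) -> None:
    """MVMR mediation table: direct effects, mediated effect, SE, CI,
    p, and mediated proportion per confirmed candidate."""
    header = ["exposure", "mediator", "outcome",
              "beta_EM", "beta_prime_MO", "beta_prime_EO", "beta_EO",
              "beta_EMO", "SE_EMO", "CI_low", "CI_high", "P_EMO",
              "proportion", "proportion_pct", "CI_includes_zero"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            if r.mediation is None or r.mvmr is None:
                continue
            m = r.mediation
            fh.write("\t".join([
                r.exposure, r.mediator, r.outcome,
                _f(m.beta_em), _f(m.beta_prime_mo),
                _f(r.mvmr.direct_exposure_effect), _f(m.beta_eo),
                _f(m.beta_emo), _f(m.se_emo), _f(m.ci_low), _f(m.ci_high),
                _p(m.p_emo), _f(m.proportion), _f(m.proportion_pct),
                str(m.ci_includes_zero).lower(),
            ]) + "\n")
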