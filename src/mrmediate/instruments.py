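"""Instrument selection and cross-dataset harmonization.

Implements the instrument-building steps of a two-sample MR analysis:
p-value screening, greedy LD clumping, exclusion of palindromic variants at
intermediate allele frequency, user-supplied confounder-SNP exclusion,
per-SNP explained variance (R²) and F-statistics, and allele harmonization
of exposure/mediator/outcome effects into one aligned table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .summstats import COLUMNS, SummaryStatsError, TraitDataset

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# alignment flags recorded per variant during harmonization
KEPT = "kept-as-is"
FLIPPED = "flipped"
DROPPED_PALINDROME = "dropped-palindrome"
DROPPED_MISSING = "dropped-missing"


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than an operation's minimum."""


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Per-SNP instrument-strength summary.

    r2 is the variance in the (standardized) exposure explained by the SNP,
    2·MAF·(1−MAF)·(β/SD)²; f_stat is the corresponding single-SNP F,
    (N−2)·R²/(1−R²).  ``set_f`` carries the k-instrument set-level F
    ((N−k−1)/k)·ΣR²/(1−ΣR²) and is identical across the rows of one set.
    """

    variant_id: str
    maf: float
    r2: float
    f_stat: float
    n: float
    k: int
    set_f: float
    weak: bool  # per-SNP F below the exclusion floor


@dataclass
class HarmonizedInstrumentSet:
    """Per-SNP aligned effects: gamma (SNP→exposure), capital_gamma (SNP→outcome),
    and optionally delta (SNP→mediator), all on the exposure's effect allele."""

    exposure: str
    outcome: str
    df: pd.DataFrame = field(repr=False)
    mediator: str | None = None
    dropped: pd.DataFrame | None = field(default=None, repr=False)

    REQUIRED = ["variant_id", "gamma", "se_gamma", "capital_gamma", "se_capital_gamma",
                "alignment_flag"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise SummaryStatsError(f"harmonized set missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gamma(self) -> np.ndarray:
        return self.df["gamma"].to_numpy(float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.df["se_gamma"].to_numpy(float)

    @property
    def capital_gamma(self) -> np.ndarray:
        return self.df["capital_gamma"].to_numpy(float)

    @property
    def se_capital_gamma(self) -> np.ndarray:
        return self.df["se_capital_gamma"].to_numpy(float)

    @property
    def delta(self) -> np.ndarray | None:
        return self.df["delta"].to_numpy(float) if "delta" in self.df.columns else None

    @property
    def se_delta(self) -> np.ndarray | None:
        return self.df["se_delta"].to_numpy(float) if "se_delta" in self.df.columns else None

    def drop_variants(self, variant_ids: Iterable[str]) -> "HarmonizedInstrumentSet":
        ids = set(variant_ids)
        keep = ~self.df["variant_id"].isin(ids)
        return HarmonizedInstrumentSet(
            self.exposure, self.outcome, self.df.loc[keep].copy(), mediator=self.mediator
        )

    def take(self, indices) -> "HarmonizedInstrumentSet":
        return HarmonizedInstrumentSet(
            self.exposure, self.outcome, self.df.iloc[np.asarray(indices)].copy(),
            mediator=self.mediator,
        )


# ---------------------------------------------------------------------------
# selection

def select_by_pvalue(dataset: TraitDataset, threshold: float) -> TraitDataset:
    """Keep variants with p strictly below the selection threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    kept = dataset.df["pval"] < threshold
    if not kept.any():
        log.warning("%s: no variant passes p < %g", dataset.trait_name, threshold)
    return dataset.subset(kept)


class LDLookup:
    """Pairwise r² lookup backed by a symmetric dict of variant-id pairs."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self._r2[(a, b)] = float(r2)
            self._r2[(b, a)] = float(r2)

    @classmethod
    def from_file(cls, path) -> "LDLookup":
        """Three-column tab-delimited pair list: variant_a, variant_b, r2."""
        df = pd.read_csv(path, sep="\t", header=None, names=["a", "b", "r2"], comment="#")
        return cls({(str(r.a), str(r.b)): float(r.r2) for r in df.itertuples()})

    def get(self, a: str, b: str) -> float | None:
        return self._r2.get((a, b))


def greedy_clump(
    dataset: TraitDataset,
    ld: LDLookup,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    missing_policy: str = "correlated",
) -> TraitDataset:
    """Greedy LD clumping: iterate variants by ascending p (ties broken by
    (chrom, pos)); keep the best remaining variant and discard any
    same-chromosome variant within ``window_kb`` whose r² with it exceeds
    ``r2_max``.  An in-window pair absent from the LD table is treated as
    correlated ("correlated", conservative) or independent ("independent").
    Output is independent of input row order."""
    if not (0.0 <= r2_max <= 1.0):
        raise ValueError(f"r2_max must be in [0,1], got {r2_max}")
    if missing_policy not in ("correlated", "independent"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    df = dataset.df.sort_values(["pval", "chrom", "pos"], kind="stable").reset_index(drop=True)
    window_bp = window_kb * 1000
    kept_rows: list[int] = []
    discarded = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    vid = df["variant_id"].to_numpy()

    for i in range(len(df)):
        if discarded[i]:
            continue
        kept_rows.append(i)
        for j in range(i + 1, len(df)):
            if discarded[j] or chrom[j] != chrom[i] or abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            r2 = ld.get(vid[i], vid[j])
            if r2 is None:
                log.debug("clump: no LD for in-window pair %s/%s (%s)", vid[i], vid[j],
                          missing_policy)
                if missing_policy == "correlated":
                    discarded[j] = True
                continue
            if r2 > r2_max:
                discarded[j] = True

    out = df.iloc[kept_rows]
    # restore a deterministic genomic order
    out = out.sort_values(["chrom", "pos"], kind="stable")
    return TraitDataset(dataset.trait_name, dataset.trait_type, out[COLUMNS].copy())


def drop_palindromes(
    dataset: TraitDataset, maf_band: tuple[float, float] = (0.42, 0.58)
) -> TraitDataset:
    """Remove A/T and C/G variants whose effect-allele frequency lies inside
    the intermediate band (inclusive); outside the band the frequency
    resolves the strand and the variant is retained."""
    low, high = maf_band
    if not (0.0 < low < high <= 1.0):
        raise ValueError(f"invalid maf_band {maf_band}")
    ea = dataset.df["effect_allele"]
    oa = dataset.df["other_allele"]
    palindromic = ea.map(COMPLEMENT.get) == oa
    intermediate = dataset.df["eaf"].between(low, high)
    drop = palindromic & intermediate
    if drop.any():
        log.info("%s: dropped %d palindromic variants at intermediate frequency",
                 dataset.trait_name, int(drop.sum()))
    return dataset.subset(~drop)


def exclude_listed_snps(dataset: TraitDataset, exclusion_list: Iterable[str]) -> TraitDataset:
    """Remove instruments on a user-supplied exclusion list (e.g. SNPs known
    to associate with confounders such as BMI or smoking)."""
    ids = set(exclusion_list)
    drop = dataset.df["variant_id"].isin(ids)
    n_drop = int(drop.sum())
    if n_drop:
        log.info("%s: excluded %d listed variants", dataset.trait_name, n_drop)
    out = dataset.subset(~drop)
    if len(out) == 0:
        log.warning("%s: exclusion list removed every variant", dataset.trait_name)
    return out


def read_exclusion_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


# ---------------------------------------------------------------------------
# instrument strength

def compute_instrument_strength(
    dataset: TraitDataset, phenotype_sd: float = 1.0, min_f: float = 10.0
) -> list[InstrumentDiagnostics]:
    """Per-SNP R² and F for a continuous exposure.

    R²_j = 2·MAF_j·(1−MAF_j)·(β_j/SD)², F_j = (N_j−2)·R²_j/(1−R²_j).
    The set-level F for the k retained instruments,
    ((N−k−1)/k)·ΣR²/(1−ΣR²), is reported alongside for diagnostics.
    Records with per-SNP F below ``min_f`` are flagged for exclusion.
    """
    if not (phenotype_sd > 0):
        raise ValueError(f"phenotype_sd must be > 0, got {phenotype_sd}")
    df = dataset.df
    maf = np.minimum(df["eaf"].to_numpy(float), 1.0 - df["eaf"].to_numpy(float))
    beta = df["beta"].to_numpy(float)
    n = df["n"].to_numpy(float)
    r2 = 2.0 * maf * (1.0 - maf) * (beta / phenotype_sd) ** 2
    if np.any(r2 >= 1.0):
        bad = df.loc[r2 >= 1.0, "variant_id"].tolist()
        raise SummaryStatsError(f"per-SNP R² >= 1 for {bad}: beta/SD implausible")
    f_snp = (n - 2.0) * r2 / (1.0 - r2)
    k = len(df)
    sum_r2 = float(r2.sum())
    n_bar = float(n.mean())
    set_f = ((n_bar - k - 1.0) / k) * sum_r2 / (1.0 - sum_r2) if sum_r2 < 1.0 else np.inf
    return [
        InstrumentDiagnostics(
            variant_id=v, maf=float(m), r2=float(r), f_stat=float(f), n=float(nn),
            k=k, set_f=set_f, weak=bool(f < min_f),
        )
        for v, m, r, f, nn in zip(df["variant_id"], maf, r2, f_snp, n)
    ]


def filter_weak_instruments(
    dataset: TraitDataset, phenotype_sd: float = 1.0, min_f: float = 10.0
) -> TraitDataset:
    """Drop instruments whose per-SNP F falls below ``min_f``."""
    diags = compute_instrument_strength(dataset, phenotype_sd, min_f)
    weak = {d.variant_id for d in diags if d.weak}
    if weak:
        log.info("%s: removed %d weak instruments (F < %g)", dataset.trait_name, len(weak), min_f)
    return dataset.subset(~dataset.df["variant_id"].isin(weak))


# ---------------------------------------------------------------------------
# harmonization

def _align_row(exp_row, other_row) -> tuple[float, float, str]:
    """Align one variant of a second dataset onto the exposure's effect allele.

    Returns (signed beta, eaf, flag).  Handles direct matches, allele swaps,
    and strand (complement) matches; anything else is an unresolvable mismatch.
    """
    ea, oa = exp_row["effect_allele"], exp_row["other_allele"]
    o_ea, o_oa = other_row["effect_allele"], other_row["other_allele"]
    beta, eaf = float(other_row["beta"]), float(other_row["eaf"])
    if (o_ea, o_oa) == (ea, oa):
        return beta, eaf, KEPT
    if (o_ea, o_oa) == (oa, ea):
        return -beta, 1.0 - eaf, FLIPPED
    # strand flip: compare on the complementary strand
    c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (ea, oa):
        return beta, eaf, KEPT
    if (c_ea, c_oa) == (oa, ea):
        return -beta, 1.0 - eaf, FLIPPED
    return np.nan, np.nan, DROPPED_MISSING


def harmonize(
    exposure: TraitDataset,
    outcome: TraitDataset,
    mediator: TraitDataset | None = None,
) -> HarmonizedInstrumentSet:
    """Intersect datasets on variant_id and align all effects to the
    exposure's effect allele.  Where the outcome's effect allele equals the
    exposure's other allele the outcome beta is sign-flipped and its
    frequency complemented; unresolvable allele mismatches are dropped and
    logged.  Harmonizing an already-harmonized set is a no-op."""
    for ds in (exposure, outcome) + ((mediator,) if mediator is not None else ()):
        if len(ds) == 0:
            raise SummaryStatsError(f"harmonize: dataset {ds.trait_name} is empty")

    out_ix = outcome.df.set_index("variant_id")
    med_ix = mediator.df.set_index("variant_id") if mediator is not None else None

    shared = [v for v in exposure.df["variant_id"] if v in out_ix.index
              and (med_ix is None or v in med_ix.index)]
    if not shared:
        top = exposure.df.nsmallest(5, "pval")["variant_id"].tolist()
        raise SummaryStatsError(
            f"harmonize: no shared variants between {exposure.trait_name} and "
            f"{outcome.trait_name}; top exposure variants missing from outcome: {top}"
        )

    rows = []
    dropped = []
    exp_ix = exposure.df.set_index("variant_id")
    for v in shared:
        e = exp_ix.loc[v]
        o = out_ix.loc[v]
        g_out, _, flag_o = _align_row(e, o)
        flag = flag_o
        d_med = se_med = None
        if med_ix is not None and flag != DROPPED_MISSING:
            m = med_ix.loc[v]
            d_med, _, flag_m = _align_row(e, m)
            se_med = float(m["se"])
            if flag_m == DROPPED_MISSING:
                flag = DROPPED_MISSING
            elif flag_m == FLIPPED or flag_o == FLIPPED:
                # record "flipped" if any leg needed re-orientation
                flag = FLIPPED
        if flag == DROPPED_MISSING:
            dropped.append({"variant_id": v, "alignment_flag": DROPPED_MISSING})
            continue
        row = {
            "variant_id": v,
            "chrom": e["chrom"], "pos": int(e["pos"]),
            "effect_allele": e["effect_allele"], "other_allele": e["other_allele"],
            "eaf": float(e["eaf"]),
            "gamma": float(e["beta"]), "se_gamma": float(e["se"]),
            "pval_gamma": float(e["pval"]), "n_exposure": float(e["n"]),
            "capital_gamma": g_out, "se_capital_gamma": float(o["se"]),
            "alignment_flag": flag,
        }
        if d_med is not None:
            row["delta"] = d_med
            row["se_delta"] = se_med
        rows.append(row)

    if dropped:
        log.info("harmonize %s/%s: dropped %d unresolvable variants",
                 exposure.trait_name, outcome.trait_name, len(dropped))
    if not rows:
        raise SummaryStatsError(
            f"harmonize: every shared variant of {exposure.trait_name}/"
            f"{outcome.trait_name} had unresolvable alleles"
        )
    return HarmonizedInstrumentSet(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        mediator=mediator.trait_name if mediator is not None else None,
        df=pd.DataFrame(rows),
        dropped=pd.DataFrame(dropped) if dropped else None,
    )
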