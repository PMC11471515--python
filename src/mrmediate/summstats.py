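"""GWAS summary-statistic data model and report-table I/O.

A :class:`TraitDataset` wraps a :class:`pandas.DataFrame` holding one row per
variant, with the per-variant association record (alleles, effect-allele
frequency, beta, SE, p, N) for a single trait.  Betas are per-allele effects:
SD units for continuous traits, log-odds for binary (case-control) traits.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: canonical column order of a TraitDataset frame
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: default header names in the common GWAS-SS layout
DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP", "chrom": "CHR", "pos": "POS",
    "effect_allele": "EA", "other_allele": "OA", "eaf": "EAF",
    "beta": "BETA", "se": "SE", "pval": "P", "n": "N",
}


class SummaryStatsError(ValueError):
    """Raised for unusable summary-statistic input (zero valid rows, bad fields)."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele not in NUCLEOTIDES or self.other_allele not in NUCLEOTIDES:
            raise SummaryStatsError(
                f"{self.variant_id}: alleles must be single nucleotides, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryStatsError(f"{self.variant_id}: effect and other allele identical")
        if not (self.se > 0):
            raise SummaryStatsError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not (0.0 <= self.eaf <= 1.0):
            raise SummaryStatsError(f"{self.variant_id}: eaf outside [0, 1]: {self.eaf}")
        if not (0.0 < self.pval <= 1.0):
            raise SummaryStatsError(f"{self.variant_id}: pval outside (0, 1]: {self.pval}")
        if not (self.n > 0):
            raise SummaryStatsError(f"{self.variant_id}: n must be > 0, got {self.n}")
        # soft consistency check: p should match the normal approximation to
        # within a factor of 10 (summary files mix genomic control, exact
        # tests and rounding, so warn only)
        p_expect = 2.0 * stats.norm.sf(abs(self.beta) / self.se)
        if p_expect > 0 and not (0.1 * p_expect <= self.pval <= min(10.0 * p_expect, 1.0)):
            log.warning(
                "%s: reported p=%.3g differs from normal-approximation p=%.3g "
                "by more than a factor of 10", self.variant_id, self.pval, p_expect,
            )

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G allele pairs cannot be strand-resolved from alleles alone."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class TraitDataset:
    """Summary statistics for one trait, one row per unique variant."""

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SummaryStatsError(f"trait_type must be continuous|binary, got {self.trait_type}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SummaryStatsError(f"dataset {self.trait_name} missing columns {missing}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"].tolist()
            raise SummaryStatsError(f"duplicate variant_ids in {self.trait_name}: {dups[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(
        cls, trait_name: str, trait_type: str, records: Iterable[SummaryStatRecord]
    ) -> "TraitDataset":
        rows = [vars(r) for r in records]
        if not rows:
            raise SummaryStatsError(f"no records for trait {trait_name}")
        return cls(trait_name, trait_type, pd.DataFrame(rows, columns=COLUMNS))

    def records(self) -> list[SummaryStatRecord]:
        return [SummaryStatRecord(**row) for row in self.df[COLUMNS].to_dict("records")]

    def subset(self, mask) -> "TraitDataset":
        """Same trait restricted to the boolean mask / index."""
        return TraitDataset(self.trait_name, self.trait_type, self.df.loc[mask, COLUMNS].copy())

    def write(self, path, column_map: Mapping[str, str] | None = None) -> None:
        """Tab-delimited export using the (inverse of the) given column map."""
        cmap = dict(column_map or DEFAULT_COLUMN_MAP)
        out = self.df[COLUMNS].rename(columns=cmap)
        out.to_csv(path, sep="\t", index=False)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
) -> TraitDataset:
    """Read a tab- or comma-delimited summary-statistics file.

    Rows with missing beta/SE/alleles, non-SNP alleles (indels, multi-allelic
    codes) or otherwise invalid fields are dropped and counted in the log.
    Duplicate variant ids keep the smallest p-value (ties keep the first
    occurrence).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})
    with _open_text(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=sep, dtype={cmap["chrom"]: str})

    missing_cols = [v for v in cmap.values() if v not in raw.columns]
    if missing_cols:
        raise SummaryStatsError(f"{path}: mapped columns absent from header: {missing_cols}")

    inv = {v: k for k, v in cmap.items()}
    raw = raw.rename(columns=inv)

    n_in = len(raw)
    records: list[SummaryStatRecord] = []
    n_dropped = 0
    for row in raw.to_dict("records"):
        try:
            vals = {c: row[c] for c in COLUMNS}
            if any(pd.isna(v) for v in vals.values()):
                raise SummaryStatsError("missing field")
            rec = SummaryStatRecord(
                variant_id=str(vals["variant_id"]),
                chrom=str(vals["chrom"]),
                pos=int(vals["pos"]),
                effect_allele=str(vals["effect_allele"]).upper(),
                other_allele=str(vals["other_allele"]).upper(),
                eaf=float(vals["eaf"]),
                beta=float(vals["beta"]),
                se=float(vals["se"]),
                pval=float(vals["pval"]),
                n=float(vals["n"]),
            )
        except (SummaryStatsError, TypeError, ValueError):
            n_dropped += 1
            continue
        records.append(rec)

    if not records:
        raise SummaryStatsError(f"{path}: zero valid rows ({n_in} read, {n_dropped} dropped)")

    df = pd.DataFrame([vars(r) for r in records], columns=COLUMNS)
    # dedup: smallest p wins; equal p keeps the first occurrence (stable sort)
    n_before = len(df)
    df = df.sort_values("pval", kind="stable").drop_duplicates("variant_id", keep="first")
    df = df.sort_index().reset_index(drop=True)
    n_dedup = n_before - len(df)
    if n_dropped or n_dedup:
        log.info(
            "%s: read %d rows, dropped %d invalid, removed %d duplicates -> %d records",
            path, n_in, n_dropped, n_dedup, len(df),
        )
    name = trait_name if trait_name is not None else str(path)
    return TraitDataset(name, trait_type, df)


def concat_datasets(trait_name: str, trait_type: str,
                    datasets: Sequence[TraitDataset]) -> TraitDataset:
    """Pool several datasets of one trait (e.g. per-locus slices of a
    genome-wide GWAS) into one; variant ids must not collide."""
    if not datasets:
        raise SummaryStatsError("concat_datasets: need at least one dataset")
    df = pd.concat([d.df[COLUMNS] for d in datasets], ignore_index=True)
    return TraitDataset(trait_name, trait_type, df)


# ---------------------------------------------------------------------------
# report tables

@dataclass
class ReportRow:
    """One line of an analysis report table (one method, one exposure-outcome pair)."""

    exposure: str
    outcome: str
    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    p_fdr: float | None = None
    het_q_p: float | None = None
    presso_p: float | None = None
    tier: str | None = None

    def __post_init__(self) -> None:
        if self.se > 0 and not (self.ci_low < self.or_ < self.ci_high):
            raise SummaryStatsError(
                f"{self.exposure}/{self.outcome}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket OR {self.or_}"
            )
        if not math.isclose(self.or_, math.exp(self.beta), rel_tol=1e-6):
            raise SummaryStatsError(
                f"{self.exposure}/{self.outcome}: OR {self.or_} != exp(beta) {math.exp(self.beta)}"
            )


REPORT_HEADER = [
    "exposure", "outcome", "method", "nSNP", "beta", "se", "pval",
    "OR", "CI_low", "CI_high", "P_FDR", "het_Q_p", "presso_p", "tier",
]


def _fmt_f(x: float | None) -> str:
    return "" if x is None else f"{x:.3f}"


def _fmt_p(x: float | None) -> str:
    return "" if x is None else f"{x:.2E}"


def write_report(rows: Sequence[ReportRow], path) -> None:
    """Write report rows tab-delimited: 3 decimals for effects/ORs/CIs,
    2-decimal scientific notation for p-values."""
    if not rows:
        raise SummaryStatsError("write_report: rows must be non-empty")
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_HEADER) + "\n")
        for r in rows:
            fields = [
                r.exposure, r.outcome, r.method, str(r.n_snp),
                _fmt_f(r.beta), _fmt_f(r.se), _fmt_p(r.pval),
                _fmt_f(r.or_), _fmt_f(r.ci_low), _fmt_f(r.ci_high),
                _fmt_p(r.p_fdr), _fmt_p(r.het_q_p), _fmt_p(r.presso_p),
                r.tier or "",
            ]
            fh.write("\t".join(fields) + "\n")
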