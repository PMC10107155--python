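"""Cohort-level aneuploidy statistics for viable-spore collections.

Covers per-chromosome disomy tallies and their chromosome-length
normalization (counts per Mbp), selection of the mid-frequency band of
chromosomes, Pearson correlation of counts with chromosome length,
dosage-sensitive-gene (DSG) impact scoring (the summed inverse copy-number
limit per chromosome) and its log-scale association with aneuploidy
counts, and the parental-origin balance of inherited homologs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ChromosomeTable, N_CHROMOSOMES
from .ploidy_caller import STATE_DISOMY, STATE_PARTIAL
from .synthetic_wgs import copy_numbers

__all__ = [
    "AneuploidyCounts",
    "LengthCorrelation",
    "count_aneuploidies",
    "counts_from_calls",
    "band_subset",
    "length_correlation",
    "dsg_impact",
    "log_association",
    "parental_bias",
    "make_synthetic_dsg_table",
]


@dataclass(frozen=True)
class AneuploidyCounts:
    """Per-chromosome disomy tallies over a spore cohort."""

    table: ChromosomeTable
    counts: np.ndarray
    per_spore_hist: np.ndarray
    n_spores: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.table.n,):
            raise ValueError("counts must align with the chromosome table")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def counts_per_mbp(self) -> np.ndarray:
        """count x 1e6 / length_bp, exact arithmetic on the integer counts."""
        return self.counts * 1e6 / self.table.lengths_bp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.table.names,
                "length_bp": self.table.lengths_bp,
                "count": self.counts,
                "counts_per_mbp": self.counts_per_mbp,
            }
        )


def count_aneuploidies(
    cohort: np.ndarray, table: ChromosomeTable
) -> AneuploidyCounts:
    """Tally disomies per chromosome over a cohort of spore karyotypes.

    ``cohort`` is an (n_spores, 16) array of state codes; any two-copy
    state (heterodisomy or a mitotic same-parent duplication) counts as one
    disomy.  Also returns the per-spore disomy-count histogram.
    """
    cohort = np.atleast_2d(np.asarray(cohort))
    if cohort.size == 0:
        raise ValueError("empty cohort")
    if cohort.shape[1] != table.n:
        raise ValueError("cohort width must match the chromosome table")
    total_copies = copy_numbers(cohort.ravel()).sum(axis=1).reshape(cohort.shape)
    is_disomy = total_copies == 2
    per_spore = is_disomy.sum(axis=1)
    return AneuploidyCounts(
        table=table,
        counts=is_disomy.sum(axis=0),
        per_spore_hist=np.bincount(per_spore, minlength=N_CHROMOSOMES + 1),
        n_spores=cohort.shape[0],
    )


def counts_from_calls(
    calls: pd.DataFrame, table: ChromosomeTable
) -> AneuploidyCounts:
    """Tally disomies from stacked caller output (columns sample, chrom,
    state); ``partial_reduction`` counts as a disomy at formation."""
    if calls.empty:
        raise ValueError("empty cohort")
    disomic = calls[calls["state"].isin([STATE_DISOMY, STATE_PARTIAL])]
    counts = (
        disomic.groupby("chrom").size().reindex(table.names, fill_value=0).to_numpy()
    )
    per_spore = (
        disomic.groupby("sample").size()
        .reindex(calls["sample"].unique(), fill_value=0)
        .to_numpy()
    )
    return AneuploidyCounts(
        table=table,
        counts=counts,
        per_spore_hist=np.bincount(per_spore, minlength=N_CHROMOSOMES + 1),
        n_spores=calls["sample"].nunique(),
    )


def band_subset(
    counts: AneuploidyCounts, low: float = 10.0, high: float = 25.0
) -> list[str]:
    """Chromosomes whose counts/Mbp fall in [low, high] --- the
    mid-frequency band used for the length regression."""
    if not low < high:
        raise ValueError("low must be smaller than high")
    cpm = counts.counts_per_mbp
    return [n for n, v in zip(counts.table.names, cpm) if low <= v <= high]


@dataclass(frozen=True)
class LengthCorrelation:
    """Pearson correlation of disomy counts with chromosome length."""

    r_subset: float
    slope: float
    intercept: float
    r_all: float
    subset: tuple[str, ...]


def length_correlation(
    counts: AneuploidyCounts, subset: list[str] | None = None
) -> LengthCorrelation:
    """Correlate raw disomy counts with chromosome length (bp), over a
    chromosome subset and over all chromosomes."""
    names = list(counts.table.names)
    if subset is None:
        subset = names
    if len(subset) < 3:
        raise ValueError("need at least 3 chromosomes for a correlation")
    idx = [names.index(s) for s in subset]
    x = counts.table.lengths_bp[idx].astype(float)
    y = counts.counts[idx].astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance in the selected subset")
    fit = stats.linregress(x, y)
    x_all = counts.table.lengths_bp.astype(float)
    y_all = counts.counts.astype(float)
    r_all = (
        float(stats.pearsonr(x_all, y_all).statistic)
        if np.ptp(y_all) > 0
        else float("nan")
    )
    return LengthCorrelation(
        r_subset=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_all=r_all,
        subset=tuple(subset),
    )


def dsg_impact(dsgs: pd.DataFrame, table: ChromosomeTable) -> pd.Series:
    """Total DSG impact per chromosome: sum of 1/copy_limit over its
    dosage-sensitive genes (0 for chromosomes without DSGs).

    ``dsgs`` has columns gene, chrom, copy_limit (the maximum tolerated
    extra copy number, >= 1)."""
    if (dsgs["copy_limit"] < 1).any():
        raise ValueError("copy limits must be >= 1")
    impact = (1.0 / dsgs["copy_limit"]).groupby(dsgs["chrom"]).sum()
    return impact.reindex(table.names, fill_value=0.0).rename("dsg_impact")


def log_association(
    counts: AneuploidyCounts,
    impact: pd.Series,
    log_counts: bool = False,
) -> tuple[float, int]:
    """Pearson correlation of disomy counts with ln(DSG impact).

    Chromosomes with zero impact are excluded with a warning (their log is
    undefined).  With ``log_counts=True`` the counts are log-transformed
    too (zero-count chromosomes then also drop out).  Returns (r, number of
    chromosomes used)."""
    impact = impact.reindex(counts.table.names)
    y = counts.counts.astype(float)
    usable = impact.to_numpy() > 0
    if (~usable).any():
        warnings.warn(
            f"excluding {int((~usable).sum())} chromosome(s) with zero DSG impact",
            stacklevel=2,
        )
    x = np.log(impact.to_numpy()[usable])
    y = y[usable]
    if log_counts:
        pos = y > 0
        x, y = x[pos], np.log(y[pos])
    if x.size < 3:
        raise ValueError("fewer than 3 usable chromosomes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic), int(x.size)


def parental_bias(
    cohort: np.ndarray, table: ChromosomeTable, conf: float = 0.95
) -> pd.DataFrame:
    """Fraction of parent-A homolog copies among all inherited copies, per
    chromosome and overall, with Clopper-Pearson confidence intervals.

    A monosomy contributes one copy of its parent, a heterodisomy one of
    each."""
    cohort = np.atleast_2d(np.asarray(cohort))
    if cohort.size == 0:
        raise ValueError("empty cohort")
    copies = copy_numbers(cohort.ravel()).reshape(cohort.shape + (2,))
    n_a = copies[:, :, 0].sum(axis=0)
    n_b = copies[:, :, 1].sum(axis=0)
    rows = list(zip(table.names, n_a, n_b)) + [("overall", n_a.sum(), n_b.sum())]
    records = []
    alpha = 1.0 - conf
    for name, a, b in rows:
        n = a + b
        frac = a / n if n else np.nan
        if n:
            lo = stats.beta.ppf(alpha / 2, a, n - a + 1) if a > 0 else 0.0
            hi = stats.beta.ppf(1 - alpha / 2, a + 1, n - a) if a < n else 1.0
        else:
            lo = hi = np.nan
        records.append((name, int(a), int(b), frac, lo, hi))
    return pd.DataFrame(
        records, columns=["chrom", "n_A", "n_B", "frac_A", "ci_low", "ci_high"]
    )


def make_synthetic_dsg_table(
    table: ChromosomeTable, genes_per_mbp: float = 5.0, seed: int = 0
) -> pd.DataFrame:
    """A synthetic dosage-sensitive-gene table for demonstrations and tests.

    Gene counts scale with chromosome length; copy-number limits are drawn
    log-uniformly from 1..100 (a limit of 1 marks a gene tolerating only a
    single extra copy, the strongest possible contribution, 1/limit = 1).
    This is a stand-in fixture, not the published DSG dataset; real data
    can be supplied as a TSV with columns gene, chrom, copy_limit.
    """
    rng = np.random.default_rng(seed)
    records = []
    for name, length in zip(table.names, table.lengths_bp):
        k = max(1, int(round(genes_per_mbp * int(length) / 1e6)))
        limits = np.round(np.exp(rng.uniform(0, np.log(100), size=k))).astype(int)
        limits = np.clip(limits, 1, 100)
        for j, lim in enumerate(limits):
            records.append((f"{name}_dsg{j + 1}", name, int(lim)))
    return pd.DataFrame(records, columns=["gene", "chrom", "copy_limit"])
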