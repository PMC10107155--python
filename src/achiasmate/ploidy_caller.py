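"""Karyotype, stability and recombination calling from spore sequencing.

Per-chromosome copy state is called in two passes, mirroring the joint use
of "SNP plots" and "coverage plots" for hybrid-diploid spores:

1. the coverage-weighted mean parent-A allele fraction ``f`` classifies a
   chromosome provisionally as parent-A monosomy (``f >= 1 - delta``),
   parent-B monosomy (``f <= delta``) or biparental (``|f - 0.5| <=
   delta``);
2. the monosome baseline --- the median mean depth over provisionally
   monosomic chromosomes --- converts each chromosome's mean depth into a
   normalized copy ratio ``r``; biparental chromosomes with ``r`` in the
   disomy band are heterodisomies, those with ``r`` strictly between the
   monosomy and disomy bands are partial (mosaic) reductions with
   estimated lost-cell fraction ``phi = 2 - r``.

Mitotic stability across a passage experiment is classified from the
monosome-normalized coverage ratio between the late (g-110) and early
(g-0) profile of the same clone, with loss below 0.5 and gain above 1.5.

A simplified genotype-changepoint detector counts crossovers and gene
conversions on monosomic (phased-by-construction) chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_wgs import ReadProfile

__all__ = [
    "CallerConfig",
    "RecombinationCalls",
    "call_karyotype",
    "smooth_coverage",
    "classify_stability",
    "detect_recombination",
    "genotypes_from_allele_depths",
]

STATE_NONE = "none"
STATE_MONO_A = "monoA"
STATE_MONO_B = "monoB"
STATE_DISOMY = "disomyAB"
STATE_PARTIAL = "partial_reduction"

#: state label for each 2-bit simulator code
CODE_TO_STATE = {0: STATE_NONE, 1: STATE_MONO_A, 2: STATE_MONO_B, 3: STATE_DISOMY}


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the two-pass karyotype caller.

    ``delta`` is the allele-fraction tolerance around 0/0.5/1; the coverage
    bands sit midway between integer copy expectations (monosomy around 1,
    disomy around 2) with the open interval between them reserved for
    partial reduction; ``none_max_ratio`` is the ratio below which a
    chromosome is called absent.
    """

    delta: float = 0.15
    mono_band: tuple[float, float] = (0.75, 1.25)
    disomy_band: tuple[float, float] = (1.75, 2.25)
    none_max_ratio: float = 0.3
    min_snps: int = 50


def call_karyotype(
    profile: ReadProfile,
    config: CallerConfig | None = None,
) -> pd.DataFrame:
    """Call per-chromosome copy state and parental origin for one sample.

    Returns a DataFrame (one row per chromosome) with columns state,
    mean_fA, ratio, copy_estimate, n_snps; ``attrs["baseline_fallback"]``
    records whether no provisional monosomy was available and the monosome
    baseline had to be approximated from the depth distribution.

    Raises ``ValueError`` when a chromosome has fewer than ``min_snps``
    SNPs in the profile.
    """
    cfg = config or CallerConfig()
    chroms = list(profile.coverage["chrom"].unique())

    ad = profile.allele_depths
    n_snps = ad.groupby("chrom", sort=False).size().reindex(chroms, fill_value=0)
    too_few = n_snps[n_snps < cfg.min_snps]
    if len(too_few):
        raise ValueError(
            f"chromosomes with fewer than {cfg.min_snps} SNPs: "
            f"{', '.join(too_few.index)}"
        )
    sums = ad.groupby("chrom", sort=False)[["countA", "countB"]].sum().reindex(chroms)
    total = (sums["countA"] + sums["countB"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_fa = np.where(total > 0, sums["countA"].to_numpy() / total, np.nan)

    depth = profile.mean_depth_per_chromosome().reindex(chroms).to_numpy()

    # Pass 1: provisional state from allele fractions alone.
    provisional = np.full(len(chroms), "ambiguous", dtype=object)
    provisional[mean_fa >= 1.0 - cfg.delta] = STATE_MONO_A
    provisional[mean_fa <= cfg.delta] = STATE_MONO_B
    provisional[np.abs(mean_fa - 0.5) <= cfg.delta] = "biparental"
    provisional[~np.isfinite(mean_fa)] = STATE_NONE

    # Pass 2: monosome coverage baseline, then copy ratios.
    mono_mask = (provisional == STATE_MONO_A) | (provisional == STATE_MONO_B)
    fallback = not mono_mask.any()
    if fallback:
        bip = provisional == "biparental"
        if bip.any():
            baseline = float(np.median(depth[bip])) / 2.0
        else:
            baseline = float(np.median(depth[np.isfinite(depth)]))
    else:
        baseline = float(np.median(depth[mono_mask]))
    if baseline <= 0:
        raise ValueError("cannot establish a positive monosome depth baseline")
    ratio = depth / baseline

    states = []
    for prov, f, r in zip(provisional, mean_fa, ratio):
        if r < cfg.none_max_ratio or prov == STATE_NONE:
            states.append(STATE_NONE)
        elif prov in (STATE_MONO_A, STATE_MONO_B):
            states.append(prov)
        elif prov == "biparental":
            if cfg.mono_band[1] < r < cfg.disomy_band[0]:
                states.append(STATE_PARTIAL)
            else:
                states.append(STATE_DISOMY)
        else:  # ambiguous allele fraction: mosaic with parent-skewed loss
            if cfg.mono_band[1] < r < cfg.disomy_band[0]:
                states.append(STATE_PARTIAL)
            elif r <= cfg.mono_band[1]:
                states.append(STATE_MONO_A if f > 0.5 else STATE_MONO_B)
            else:
                states.append(STATE_DISOMY)

    out = pd.DataFrame(
        {
            "chrom": chroms,
            "state": states,
            "mean_fA": mean_fa,
            "ratio": ratio,
            "copy_estimate": ratio,
            "n_snps": n_snps.to_numpy(),
        }
    )
    out.attrs["baseline_fallback"] = fallback
    out.attrs["monosome_baseline_depth"] = baseline
    return out


def smooth_depths(values: np.ndarray, window: int) -> np.ndarray:
    """Trailing simple moving average; leading bins average the available
    span, so output length equals input length."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, min_periods=1).mean().to_numpy()


def smooth_coverage(profile: ReadProfile, window: int) -> pd.DataFrame:
    """Per-chromosome trailing moving average of binned depths."""
    cov = profile.coverage.copy()
    cov["depth_smooth"] = (
        cov.groupby("chrom", sort=False)["depth"]
        .transform(lambda d: smooth_depths(d.to_numpy(), window))
    )
    return cov


def classify_stability(
    g0_profile: ReadProfile,
    g0_calls: pd.DataFrame,
    g110_profile: ReadProfile,
    min_ratio: float = 0.5,
    max_ratio: float = 1.5,
) -> pd.DataFrame:
    """Classify per-chromosome copy-number change over mitotic passaging.

    At each generation every chromosome's mean depth is normalized by that
    generation's monosome baseline (median mean depth over chromosomes
    called monosomic at g-0), cancelling run-to-run depth differences; the
    verdict compares the g-110/g-0 ratio of these normalized values to the
    loss (<= ``min_ratio``) and gain (> ``max_ratio``) thresholds.  The
    loss side is inclusive because an ideal complete disomy-to-monosomy
    loss sits exactly at 0.5; measured values scatter around it.
    Chromosomes absent at g-0 get verdict ``na``.
    """
    d0 = g0_profile.mean_depth_per_chromosome()
    d110 = g110_profile.mean_depth_per_chromosome()
    if set(d0.index) != set(d110.index):
        raise ValueError("g-0 and g-110 profiles cover different chromosomes")
    calls = g0_calls.set_index("chrom")["state"]
    missing = [c for c in d0.index if c not in calls.index]
    if missing:
        raise ValueError(f"missing g-0 calls for: {', '.join(missing)}")

    mono = calls[calls.isin([STATE_MONO_A, STATE_MONO_B])].index
    if len(mono) == 0:
        raise ValueError("no g-0 monosomy available for normalization")
    base0 = float(d0.loc[mono].median())
    base110 = float(d110.loc[mono].median())

    records = []
    for chrom in d0.index:
        if calls.loc[chrom] == STATE_NONE:
            records.append((chrom, np.nan, "na"))
            continue
        rel0 = d0.loc[chrom] / base0
        rel110 = d110.loc[chrom] / base110
        ratio = rel110 / rel0 if rel0 > 0 else np.nan
        if not np.isfinite(ratio):
            verdict = "na"
        elif ratio <= min_ratio:
            verdict = "loss"
        elif ratio > max_ratio:
            verdict = "gain"
        else:
            verdict = "stable"
        records.append((chrom, ratio, verdict))
    return pd.DataFrame(records, columns=["chrom", "ratio", "verdict"])


@dataclass(frozen=True)
class RecombinationCalls:
    """Crossover / gene-conversion calls on one chromosome."""

    crossovers: int
    gene_conversions: int
    co_positions: tuple[float, ...] = ()
    gc_tracts: tuple[tuple[int, int], ...] = ()


def genotypes_from_allele_depths(
    allele_depths: pd.DataFrame, min_depth: int = 1
) -> pd.DataFrame:
    """Majority-vote parental genotype per SNP (columns chrom, pos, parent
    in {"A","B"}); SNPs with depth below ``min_depth`` or a tie are
    dropped."""
    ad = allele_depths
    depth = ad["countA"] + ad["countB"]
    keep = (depth >= min_depth) & (ad["countA"] != ad["countB"])
    out = ad.loc[keep, ["chrom", "pos"]].copy()
    out["parent"] = np.where(ad.loc[keep, "countA"] > ad.loc[keep, "countB"], "A", "B")
    return out.reset_index(drop=True)


def detect_recombination(
    genotypes: np.ndarray,
    positions: np.ndarray,
    min_block: int = 20,
    max_gc_tract: int = 10_000,
) -> RecombinationCalls:
    """Count crossovers and gene conversions on one phased chromosome.

    ``genotypes`` is the per-SNP parental origin ("A"/"B" or 0/1) along the
    chromosome, ``positions`` the matching 1-based coordinates.  Runs of
    identical origin are simplified to a fixed point in priority order:
    isolated single-SNP flips are absorbed as noise; an internal tract of
    the opposite parent spanning at most ``max_gc_tract`` bp is one gene
    conversion; remaining runs shorter than ``min_block`` SNPs are
    ambiguous and absorbed.  Every boundary left between two blocks of at
    least ``min_block`` concordant SNPs is one crossover (positioned midway
    between the flanking SNPs).
    """
    g = np.asarray(genotypes)
    pos = np.asarray(positions, dtype=np.int64)
    if g.shape != pos.shape:
        raise ValueError("genotypes and positions must have equal length")
    if g.size == 0:
        return RecombinationCalls(0, 0)
    if g.dtype.kind in "USO":
        _, g = np.unique(g, return_inverse=True)  # runs only need equality
    # runs as [value, first_index, last_index]
    runs: list[list[int]] = []
    for i, v in enumerate(g):
        if runs and runs[-1][0] == v:
            runs[-1][2] = i
        else:
            runs.append([int(v), i, i])

    def merge(rs: list[list[int]]) -> list[list[int]]:
        out: list[list[int]] = []
        for r in rs:
            if out and out[-1][0] == r[0]:
                out[-1][2] = r[2]
            else:
                out.append(r)
        return out

    n_gc = 0
    gc_tracts: list[tuple[int, int]] = []
    while True:
        changed = False
        # 1) absorb isolated single-SNP flips as noise
        for i, r in enumerate(runs):
            if r[2] - r[1] + 1 == 1 and len(runs) > 1:
                neighbor = runs[i - 1] if i > 0 else runs[i + 1]
                r[0] = neighbor[0]
                runs = merge(runs)
                changed = True
                break
        if changed:
            continue
        # 2) internal short-span tracts are gene conversions
        for i in range(1, len(runs) - 1):
            r = runs[i]
            span = pos[r[2]] - pos[r[1]]
            if span <= max_gc_tract:
                n_gc += 1
                gc_tracts.append((int(pos[r[1]]), int(pos[r[2]])))
                r[0] = runs[i - 1][0]
                runs = merge(runs)
                changed = True
                break
        if changed:
            continue
        # 3) absorb remaining sub-threshold runs (ambiguous, no event)
        for i, r in enumerate(runs):
            if r[2] - r[1] + 1 < min_block and len(runs) > 1:
                neighbor = runs[i - 1] if i > 0 else runs[i + 1]
                r[0] = neighbor[0]
                runs = merge(runs)
                changed = True
                break
        if not changed:
            break

    co_positions = []
    for left, right in zip(runs[:-1], runs[1:]):
        if (left[2] - left[1] + 1) >= min_block and (
            right[2] - right[1] + 1
        ) >= min_block:
            co_positions.append(float(pos[left[2]] + pos[right[1]]) / 2.0)
    return RecombinationCalls(
        crossovers=len(co_positions),
        gene_conversions=n_gc,
        co_positions=tuple(co_positions),
        gc_tracts=tuple(gc_tracts),
    )


def recombination_per_chromosome(
    allele_depths: pd.DataFrame,
    calls: pd.DataFrame,
    min_block: int = 20,
    max_gc_tract: int = 10_000,
    min_depth: int = 1,
) -> pd.DataFrame:
    """Run the detector on every monosomic chromosome of one sample.

    Disomic (unphased) chromosomes are skipped with a warning; the wild-type
    haploid spore is the intended substrate.
    """
    genotypes = genotypes_from_allele_depths(allele_depths, min_depth=min_depth)
    records = []
    for chrom, state in zip(calls["chrom"], calls["state"]):
        if state in (STATE_DISOMY, STATE_PARTIAL):
            warnings.warn(
                f"skipping unphased disomic chromosome {chrom}", stacklevel=2
            )
            continue
        if state == STATE_NONE:
            continue
        grp = genotypes[genotypes["chrom"] == chrom]
        calls_c = detect_recombination(
            grp["parent"].to_numpy(),
            grp["pos"].to_numpy(),
            min_block=min_block,
            max_gc_tract=max_gc_tract,
        )
        records.append((chrom, calls_c.crossovers, calls_c.gene_conversions))
    return pd.DataFrame(records, columns=["chrom", "crossovers", "gene_conversions"])
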