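"""Synthetic hybrid-diploid spore sequencing data with known ground truth.

Emulates short-read resequencing of viable spores from an S288c x SK1-style
hybrid diploid in which the two parental genomes differ at ~0.7% of
positions.  For each spore the generator produces a :class:`ReadProfile`:
binned read depths per chromosome (Poisson noise around copies x per-copy
depth) and per-SNP counts of reads supporting each parental allele
(binomial sampling around the parental copy fraction, with a symmetric
substitution error).  Partial (mosaic) copy reduction of a disomy --- a
fraction ``phi`` of the cells having lost one copy --- scales the expected
depth to ``2 - phi``.  A passage step models chromosome copy-number change
during mitotic growth (disomy -> monosomy losses, monosomy duplications).

Chromosome states are the 2-bit parent codes of
:mod:`achiasmate.meiosis_model` (0=none, 1=monoA, 2=monoB, 3=heterodisomy)
extended with 4 (two parent-A copies) and 5 (two parent-B copies), which
only arise from mitotic duplication, never from the meiotic simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import ChromosomeTable, N_CHROMOSOMES

__all__ = [
    "GroundTruth",
    "ReadProfile",
    "generate_snp_table",
    "simulate_reads",
    "simulate_passage",
    "copy_numbers",
]

_BASES = np.array(list("ACGT"))

# state code -> (parent-A copies, parent-B copies)
_COPY_TABLE = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [2, 0], [0, 2]])


def copy_numbers(states: np.ndarray) -> np.ndarray:
    """(n, 2) parent-A / parent-B copy counts for a state-code vector."""
    states = np.asarray(states, dtype=np.int64)
    if (states < 0).any() or (states > 5).any():
        raise ValueError("state codes must lie in 0..5")
    return _COPY_TABLE[states]


@dataclass(frozen=True)
class GroundTruth:
    """Known karyotype (and mosaicism) of one simulated spore clone.

    ``mosaic`` maps chromosome name -> fraction of cells that lost one copy
    of a disomy; ``mosaic_lost_parent`` maps chromosome name -> which
    parental copy is lost ("A", "B", or "random" for an even mixture).
    """

    states: np.ndarray
    mosaic: dict[str, float] = field(default_factory=dict)
    mosaic_lost_parent: dict[str, str] = field(default_factory=dict)
    passage_events: tuple = ()

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.uint8)
        object.__setattr__(self, "states", states)
        if states.shape != (N_CHROMOSOMES,):
            raise ValueError(f"karyotype must cover {N_CHROMOSOMES} chromosomes")
        if (states > 5).any():
            raise ValueError("state codes must lie in 0..5")
        for chrom, phi in self.mosaic.items():
            if not 0.0 <= phi <= 1.0:
                raise ValueError(f"mosaic fraction for {chrom} outside [0, 1]")

    def validate_mosaic(self, table: ChromosomeTable) -> None:
        """Mosaicism is only defined for disomic chromosomes."""
        two_copy = {3, 4, 5}
        for chrom in self.mosaic:
            if int(self.states[table.index(chrom)]) not in two_copy:
                raise ValueError(f"mosaic fraction on non-disomic chromosome {chrom}")


@dataclass(frozen=True)
class ReadProfile:
    """Binned depths and per-SNP parental allele depths for one sample.

    ``coverage``: columns chrom, start, end, depth (0-based half-open bins
    tiling each chromosome).  ``allele_depths``: columns chrom, pos
    (1-based), countA, countB.
    """

    coverage: pd.DataFrame
    allele_depths: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.coverage["depth"] < 0).any():
            raise ValueError("bin depths must be non-negative")
        if (self.allele_depths[["countA", "countB"]] < 0).to_numpy().any():
            raise ValueError("allele depths must be non-negative")

    def mean_depth_per_chromosome(self) -> pd.Series:
        return self.coverage.groupby("chrom", sort=False)["depth"].mean()


def generate_snp_table(
    table: ChromosomeTable, density: float = 0.007, seed: int | None = None
) -> pd.DataFrame:
    """Sample a biallelic SNP map distinguishing the two parental genomes.

    Per chromosome, ``round(density * length)`` positions are drawn without
    replacement (1-based, strictly increasing); each SNP gets two distinct
    parental bases.  Returns columns chrom, pos, alleleA, alleleB.
    """
    if not 0.0 <= density < 1.0:
        raise ValueError("SNP density must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    frames = []
    for name, length in zip(table.names, table.lengths_bp):
        k = int(round(density * int(length)))
        if k == 0:
            continue
        pos = np.sort(rng.choice(int(length), size=k, replace=False)) + 1
        allele_a = rng.integers(0, 4, size=k)
        allele_b = (allele_a + rng.integers(1, 4, size=k)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": pos,
                    "alleleA": _BASES[allele_a],
                    "alleleB": _BASES[allele_b],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "alleleA", "alleleB"])
    return pd.concat(frames, ignore_index=True)


def _effective_copies(
    truth: GroundTruth, table: ChromosomeTable, background_copies: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-chromosome effective total copies and parent-A read fraction."""
    copies = copy_numbers(truth.states).astype(float)
    eff = copies.copy()
    for chrom, phi in truth.mosaic.items():
        i = table.index(chrom)
        lost = truth.mosaic_lost_parent.get(chrom, "random")
        if lost == "A":
            eff[i, 0] -= phi
        elif lost == "B":
            eff[i, 1] -= phi
        else:  # even mixture of cells losing either copy
            eff[i, 0] -= phi / 2.0
            eff[i, 1] -= phi / 2.0
    total = eff.sum(axis=1)
    frac_a = np.where(total > 0, eff[:, 0] / np.maximum(total, 1e-300), 0.5)
    total = np.where(total > 0, total, background_copies)
    return total, frac_a


def simulate_reads(
    truth: GroundTruth,
    snps: pd.DataFrame,
    table: ChromosomeTable,
    mean_depth_per_copy: float = 30.0,
    error_rate: float = 0.002,
    bin_size: int = 1000,
    seed: int | None = None,
    background_copies: float = 0.02,
) -> ReadProfile:
    """Simulate binned coverage and per-SNP allele depths for one spore.

    Bin depth ~ Poisson(effective_copies x mean_depth_per_copy), where a
    mosaic disomy contributes ``2 - phi`` effective copies and an absent
    chromosome only a small mismapping background.  At each SNP the total
    depth is Poisson and the parent-A read count binomial with success
    probability ``fA (1-e) + (1-fA) e``.
    """
    if mean_depth_per_copy <= 0:
        raise ValueError("mean_depth_per_copy must be positive")
    truth.validate_mosaic(table)
    rng = np.random.default_rng(seed)
    total, frac_a = _effective_copies(truth, table, background_copies)

    cov_frames = []
    for i, (name, length) in enumerate(zip(table.names, table.lengths_bp)):
        starts = np.arange(0, int(length), bin_size)
        ends = np.minimum(starts + bin_size, int(length))
        lam = total[i] * mean_depth_per_copy
        depth = rng.poisson(lam, size=starts.size)
        cov_frames.append(
            pd.DataFrame({"chrom": name, "start": starts, "end": ends, "depth": depth})
        )
    coverage = pd.concat(cov_frames, ignore_index=True)

    chrom_idx = np.array([table.index(c) for c in snps["chrom"]])
    depth = rng.poisson(total[chrom_idx] * mean_depth_per_copy)
    p_a = frac_a[chrom_idx] * (1.0 - error_rate) + (1.0 - frac_a[chrom_idx]) * error_rate
    count_a = rng.binomial(depth, p_a)
    allele_depths = pd.DataFrame(
        {
            "chrom": snps["chrom"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "countA": count_a,
            "countB": depth - count_a,
        }
    )
    return ReadProfile(coverage=coverage, allele_depths=allele_depths)


def simulate_passage(
    truth: GroundTruth,
    table: ChromosomeTable,
    loss_rate: float = 0.0,
    gain_rate: float = 0.0,
    seed: int | None = None,
) -> GroundTruth:
    """Karyotype after mitotic passaging.

    Each two-copy chromosome independently drops to one copy with
    ``loss_rate`` (for a heterodisomy the retained parent is chosen
    uniformly); each monosomy duplicates with ``gain_rate``.  Viability is
    preserved: no chromosome is ever lost to zero copies.  Mosaic fractions
    are reset (the passaged clone is taken as karyotypically fixed).
    """
    if not (0.0 <= loss_rate <= 1.0 and 0.0 <= gain_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    states = truth.states.copy()
    events = list(truth.passage_events)
    for i, s in enumerate(states):
        name = table.names[i]
        if s in (3, 4, 5) and rng.random() < loss_rate:
            if s == 3:
                states[i] = 1 if rng.random() < 0.5 else 2
            else:
                states[i] = 1 if s == 4 else 2
            events.append(("loss", name))
        elif s in (1, 2) and rng.random() < gain_rate:
            states[i] = 4 if s == 1 else 5
            events.append(("gain", name))
    return replace(
        truth,
        states=states,
        mosaic={},
        mosaic_lost_parent={},
        passage_events=tuple(events),
    )
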