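"""Stochastic tetrad simulator for achiasmate (Spo11-less) meiosis.

Model
-----
A hybrid diploid carries 16 homolog pairs, one homolog from parent A and
one from parent B.  Without crossovers there are no chiasmata, so meiosis I
(MI) segregates each homolog pair at random and independently of the other
chromosomes: with probability ``x_N`` the pair disjoins (one homolog to each
MI daughter) and otherwise both homologs move to the same pole, chosen with
equal probability.  ``x_N`` may rise affinely with chromosome length between
``x_min`` (shortest chromosome) and ``x_max`` (longest), modelling
length-dependent homolog interaction; ``mode`` records whether the affine
probability is interpreted as the opposite-pole (``disjunction``, default)
or same-pole (``co_segregation``) probability.

Meiosis II (MII) then segregates sister chromatids equationally: a daughter
with both homologs of a chromosome yields heterodisomic spores, a daughter
with one homolog yields monosomic spores.  Accidental chromosome loss at
MII is governed by two per-spore, per-chromosome probabilities: ``pa``, the
probability that a monosomic copy is lost (lethal, since a viable spore
needs at least one copy of every chromosome), and ``pb``, the probability
that each copy of a disomic pair is lost (independently per copy, so a
disomy becomes a monosomy with probability ``2*pb*(1-pb)``).  Losses act
once, on the MII-entry state.

A tetrad is classified by its viable spores: ``copies`` (two viable spores
with identical karyotypes including parental origin), ``altered_copies``
(two viable spores that differ), ``single``, ``mii_dead`` (no viable spore
although an MI daughter carried a full set), ``mi_dead`` (no MI daughter
carried a full set), and ``multi`` (three or more viable spores, possible
only when both MI daughters are full; excluded from the four-category
ratios).

Chromosome states are encoded as 2-bit integers: bit 0 = parent-A copy
present, bit 1 = parent-B copy present, i.e. 0=none, 1=monoA, 2=monoB,
3=heterodisomy.  The MI complement of a daughter state is ``3 - state``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import ChromosomeTable, N_CHROMOSOMES

__all__ = [
    "ChromState",
    "SegregationBias",
    "LossParams",
    "SporeKaryotype",
    "TetradOutcome",
    "SimulationSummary",
    "FitResult",
    "compute_bias",
    "segregate_mi",
    "segregate_mii",
    "classify_tetrad",
    "simulate",
    "fit_pb",
    "fit_pa",
    "disomy_distribution",
]

CATEGORIES = ("copies", "altered_copies", "single", "mii_dead", "mi_dead", "multi")

STATE_LABELS = {0: "0", 1: "A", 2: "B", 3: "AB"}


class ChromState(IntEnum):
    NONE = 0
    MONO_A = 1
    MONO_B = 2
    DISOMY_AB = 3


@dataclass(frozen=True)
class SegregationBias:
    """Per-chromosome MI segregation probabilities.

    ``x`` holds the affine-in-length probability per chromosome; its
    interpretation depends on ``mode``: the probability that the homolog
    pair moves to opposite poles (``disjunction``) or to the same pole
    (``co_segregation``).
    """

    x: np.ndarray
    mode: str = "disjunction"
    x_min: float = 0.5
    x_max: float = 0.5

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 1 or x.size < 1:
            raise ValueError("bias must be a non-empty probability vector")
        if ((x < 0) | (x > 1)).any():
            raise ValueError("segregation probabilities must lie in [0, 1]")
        if self.mode not in ("disjunction", "co_segregation"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_chromosomes(self) -> int:
        return int(self.x.size)

    @property
    def same_pole(self) -> np.ndarray:
        """Probability per chromosome that both homologs reach one pole."""
        return 1.0 - self.x if self.mode == "disjunction" else self.x.copy()


@dataclass(frozen=True)
class LossParams:
    """MII chromosome-loss probabilities.

    ``pa``: per-spore probability that a monosomic copy is lost.
    ``pb``: per-spore probability that each copy of a disomy is lost
    (independently per copy).
    """

    pa: float = 0.0
    pb: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pa <= 1.0 and 0.0 <= self.pb <= 1.0):
            raise ValueError("loss probabilities must lie in [0, 1]")


def compute_bias(
    table: ChromosomeTable,
    x_min: float = 0.5,
    x_max: float = 0.5,
    mode: str = "disjunction",
) -> SegregationBias:
    """Length-dependent MI segregation bias, affine between x_min and x_max.

    The shortest chromosome gets ``x_min``, the longest ``x_max``, and every
    other chromosome is interpolated linearly in its length:
    ``x_N = (L_N - L_min) / (L_max - L_min) * (x_max - x_min) + x_min``.
    """
    for name, value in (("x_min", x_min), ("x_max", x_max)):
        if not (0.5 <= value <= 1.0):
            raise ValueError(f"{name} must lie in [0.5, 1.0], got {value}")
    lengths = table.lengths_bp.astype(float)
    span = table.l_max - table.l_min
    if span == 0:
        x = np.full(table.n, x_min)
    else:
        x = (lengths - table.l_min) / span * (x_max - x_min) + x_min
    return SegregationBias(x=x, mode=mode, x_min=x_min, x_max=x_max)


@dataclass(frozen=True)
class SporeKaryotype:
    """Per-chromosome copy states of one spore (2-bit parent encoding)."""

    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.uint8)
        object.__setattr__(self, "states", states)
        if states.ndim != 1:
            raise ValueError("states must be a 1-D state vector")
        if (states > 3).any():
            raise ValueError("states must be 2-bit codes in {0,1,2,3}")

    @property
    def viable(self) -> bool:
        """A spore is viable iff it has >=1 copy of every chromosome."""
        return bool((self.states != 0).all())

    @property
    def copy_numbers(self) -> np.ndarray:
        return ((self.states & 1) + ((self.states >> 1) & 1)).astype(np.int64)

    @property
    def n_disomies(self) -> int:
        return int((self.states == ChromState.DISOMY_AB).sum())

    def labels(self) -> list[str]:
        return [STATE_LABELS[int(s)] for s in self.states]


@dataclass(frozen=True)
class TetradOutcome:
    """Four spores of one ascus plus the ascus category."""

    spores: tuple[SporeKaryotype, SporeKaryotype, SporeKaryotype, SporeKaryotype]
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def segregate_mi(
    bias: SegregationBias, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One MI division: both daughters' per-chromosome states.

    Returns two state vectors (2-bit codes); the second daughter is the
    complement of the first (``3 - state``): disjunction gives one homolog
    to each daughter, a same-pole event gives one daughter both homologs
    (state 3) and the other none (state 0).
    """
    c = bias.same_pole
    same = rng.random(c.size) < c
    coin = rng.random(c.size) < 0.5
    d1 = np.where(same, np.where(coin, 3, 0), np.where(coin, 1, 2)).astype(np.uint8)
    return d1, (3 - d1).astype(np.uint8)


def segregate_mii(
    daughter: np.ndarray, loss: LossParams, rng: np.random.Generator
) -> tuple[SporeKaryotype, SporeKaryotype]:
    """One MII division of a daughter cell, with accidental losses.

    Each spore first mirrors the daughter's composition (both homologs
    present -> heterodisomy; one homolog -> monosomy of that parent), then
    each present copy is lost independently: with probability ``pb`` per
    copy on disomies, ``pa`` on monosomies.  Losses are evaluated on the
    MII-entry state only.
    """
    daughter = np.asarray(daughter, dtype=np.uint8)
    p_loss = np.where(daughter == 3, loss.pb, loss.pa)
    spores = []
    for _ in range(2):
        keep_a = (daughter & 1).astype(bool) & (rng.random(daughter.shape) >= p_loss)
        keep_b = ((daughter >> 1) & 1).astype(bool) & (
            rng.random(daughter.shape) >= p_loss
        )
        spores.append(
            SporeKaryotype(keep_a.astype(np.uint8) | (keep_b.astype(np.uint8) << 1))
        )
    return spores[0], spores[1]


def classify_tetrad(
    spores: Sequence[SporeKaryotype],
    daughters: tuple[np.ndarray, np.ndarray] | None = None,
) -> str:
    """Ascus category from the four spores (and, if known, the MI daughters).

    ``daughters`` distinguishes ``mi_dead`` (no MI daughter carried a full
    chromosome set) from ``mii_dead`` (a full daughter existed but all its
    spores died of MII losses); without it a dead tetrad with no fully
    disomy-free spore evidence is conservatively reconstructed from the
    spores' union.
    """
    if len(spores) != 4:
        raise ValueError("a tetrad has exactly four spores")
    viable = [s.viable for s in spores]
    n_viable = sum(viable)
    if n_viable >= 3:
        return "multi"
    if n_viable == 2:
        a, b = (s for s, v in zip(spores, viable) if v)
        return "copies" if np.array_equal(a.states, b.states) else "altered_copies"
    if n_viable == 1:
        return "single"
    if daughters is not None:
        full = any((np.asarray(d) != 0).all() for d in daughters)
    else:
        # Reconstruct the MI daughters: spores 0,1 came from one daughter,
        # 2,3 from the other; the daughter state is the pre-loss union.
        full = False
        for i, j in ((0, 1), (2, 3)):
            union = spores[i].states | spores[j].states
            if (union != 0).all():
                full = True
    return "mii_dead" if full else "mi_dead"


@dataclass
class SimulationSummary:
    """Aggregated outcome of a tetrad simulation run."""

    n_tetrads: int
    seed: int | None
    conditional: bool
    p_full_daughter: float
    category_counts: dict[str, int]
    disomy_hist: np.ndarray
    per_chrom_disomy: np.ndarray
    n_viable_spores: int
    params: dict = field(default_factory=dict)

    def category_fractions(self) -> dict[str, float]:
        """Fractions of the four MII categories, excluding ``multi``."""
        four = ("copies", "altered_copies", "single", "mii_dead")
        total = sum(self.category_counts[c] for c in four)
        if total == 0:
            return {c: float("nan") for c in four}
        return {c: self.category_counts[c] / total for c in four}

    @property
    def identity_fraction(self) -> float:
        """copies / (copies + altered_copies): identical pairs among pairs."""
        pairs = (
            self.category_counts["copies"] + self.category_counts["altered_copies"]
        )
        return self.category_counts["copies"] / pairs if pairs else float("nan")

    @property
    def pair_fraction(self) -> float:
        """(copies+altered) / (copies+altered+single): two-viable-spore asci
        among all asci that yielded at least one viable spore."""
        pairs = (
            self.category_counts["copies"] + self.category_counts["altered_copies"]
        )
        alive = pairs + self.category_counts["single"]
        return pairs / alive if alive else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_tetrads": self.n_tetrads,
            "seed": self.seed,
            "conditional": self.conditional,
            "p_full_daughter": self.p_full_daughter,
            "category_counts": dict(self.category_counts),
            "disomy_hist": [int(v) for v in self.disomy_hist],
            "per_chrom_disomy": [int(v) for v in self.per_chrom_disomy],
            "n_viable_spores": self.n_viable_spores,
            "params": self.params,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _mii_spore_chunk(
    daughters: np.ndarray, loss: LossParams, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized MII for one spore over a (m, 16) block of daughter states.

    Uses a single uniform per cell with the exact categorical outcome
    distribution: a disomy keeps both copies w.p. (1-pb)^2, loses exactly
    one (the fired copy) w.p. pb(1-pb) per parent, both w.p. pb^2; a
    monosomy keeps its copy w.p. 1-pa.
    """
    pa, pb = loss.pa, loss.pb
    q2 = np.float32((1.0 - pb) ** 2)
    t_lose_a = np.float32((1.0 - pb) ** 2 + pb * (1.0 - pb))
    t_lose_b = np.float32((1.0 - pb) ** 2 + 2.0 * pb * (1.0 - pb))
    keep_mono = np.float32(1.0 - pa)
    u = rng.random(daughters.shape, dtype=np.float32)
    # Ordered thresholds q2 < t_lose_a < t_lose_b encode the state directly:
    # 3 (kept both), 2 (lost A), 1 (lost B), 0 (lost both).
    s_dis = (u < q2).astype(np.uint8) + (u < t_lose_a) + (u < t_lose_b)
    s_mono = np.where(u < keep_mono, daughters, np.uint8(0))
    return np.where(daughters == 3, s_dis, s_mono)


def simulate(
    n: int,
    bias: SegregationBias,
    loss: LossParams,
    seed: int | np.random.Generator | None = None,
    conditional: bool = False,
    chunk_size: int = 1 << 19,
    collect_disomy: bool = True,
) -> SimulationSummary:
    """Simulate ``n`` tetrads and aggregate categories and disomy counts.

    With ``conditional=True`` only tetrads whose first MI daughter carries a
    full chromosome set are simulated (importance conditioning; in the
    unbiased model ~99% of tetrads are otherwise ``mi_dead``).  The
    analytic conditioning probability ``p_full_daughter`` is recorded so
    unconditional rates can be reconstructed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    c = bias.same_pole
    p_full = float(np.prod(1.0 - c / 2.0))
    # Conditional per-chromosome disomy probability given a full daughter.
    with np.errstate(divide="ignore", invalid="ignore"):
        p_dis = (c / 2.0) / (1.0 - c / 2.0)

    n_chrom = bias.n_chromosomes
    cat_counts = dict.fromkeys(CATEGORIES, 0)
    disomy_hist = np.zeros(n_chrom + 1, dtype=np.int64)
    per_chrom = np.zeros(n_chrom, dtype=np.int64)
    n_viable_spores = 0

    p32 = p_dis.astype(np.float32)
    c32 = c.astype(np.float32)

    done = 0
    while done < n:
        m = min(chunk_size, n - done)
        done += m
        u = rng.random((m, n_chrom), dtype=np.float32)
        if conditional:
            mid = p32 + (1.0 - p32) / 2.0
            mono = np.uint8(1) + (u >= mid)
            d1 = np.where(u < p32, np.uint8(3), mono)
        else:
            mid = c32 + (1.0 - c32) / 2.0
            mono = np.uint8(1) + (u >= mid)
            d1 = np.where(
                u < c32 / 2.0, np.uint8(3), np.where(u < c32, np.uint8(0), mono)
            )

        # Daughter 2 is the complement 3 - d1; it has a full set iff d1
        # carries no disomy.  Spores of a non-full daughter can never be
        # viable (some chromosome is absent before MII), so MII is
        # simulated only on the full-daughter row subsets.
        full1 = (d1 != 0).all(axis=1)
        full2 = (d1 != 3).all(axis=1)

        idx: list[np.ndarray] = []
        sp: list[np.ndarray] = [np.empty(0)] * 4
        vsub: list[np.ndarray] = [np.empty(0)] * 4
        for k, full in enumerate((full1, full2)):
            rows = np.nonzero(full)[0]
            idx.append(rows)
            d = d1[rows] if k == 0 else (3 - d1[rows]).astype(np.uint8)
            for h in range(2):
                s = _mii_spore_chunk(d, loss, rng)
                sp[2 * k + h] = s
                vsub[2 * k + h] = (s != 0).all(axis=1)

        viable = np.zeros((4, m), dtype=bool)
        for k in range(2):
            for h in range(2):
                viable[2 * k + h, idx[k]] = vsub[2 * k + h]

        n_v = viable.sum(axis=0)
        any_full = full1 | full2
        cat_counts["mi_dead"] += int(((n_v == 0) & ~any_full).sum())
        cat_counts["mii_dead"] += int(((n_v == 0) & any_full).sum())
        cat_counts["single"] += int((n_v == 1).sum())
        cat_counts["multi"] += int((n_v >= 3).sum())

        two = n_v == 2
        if two.any():
            identical = np.zeros(m, dtype=bool)
            pairs = ((0, 1, 0, 0), (2, 3, 1, 1), (0, 2, 0, 1), (0, 3, 0, 1),
                     (1, 2, 0, 1), (1, 3, 0, 1))
            for i, j, ki, kj in pairs:
                rows = np.nonzero(two & viable[i] & viable[j])[0]
                if rows.size:
                    pi = np.searchsorted(idx[ki], rows)
                    pj = np.searchsorted(idx[kj], rows)
                    identical[rows] |= (sp[i][pi] == sp[j][pj]).all(axis=1)
            cat_counts["copies"] += int((two & identical).sum())
            cat_counts["altered_copies"] += int((two & ~identical).sum())

        # Per-spore statistics: under daughter-1 conditioning the rare
        # tetrads where daughter 2 is also full are over-represented, so
        # only the conditioned daughter's spores enter the histogram; in
        # unconditional mode all viable spores do.
        stat_spores = range(2) if conditional else range(4)
        if collect_disomy:
            for s_i in stat_spores:
                v = vsub[s_i]
                if v.size and v.any():
                    is_dis = sp[s_i][v] == 3
                    disomy_hist += np.bincount(
                        is_dis.sum(axis=1), minlength=n_chrom + 1
                    )
                    per_chrom += is_dis.sum(axis=0)
        n_viable_spores += sum(int(vsub[s_i].sum()) for s_i in stat_spores)

    return SimulationSummary(
        n_tetrads=n,
        seed=seed if isinstance(seed, int) else None,
        conditional=conditional,
        p_full_daughter=p_full,
        category_counts=cat_counts,
        disomy_hist=disomy_hist,
        per_chrom_disomy=per_chrom,
        n_viable_spores=n_viable_spores,
        params={
            "pa": loss.pa,
            "pb": loss.pb,
            "x_min": bias.x_min,
            "x_max": bias.x_max,
            "mode": bias.mode,
        },
    )


@dataclass(frozen=True)
class FitResult:
    """Grid-search fit of one loss parameter."""

    value: float
    grid: np.ndarray
    fractions: np.ndarray
    target: float
    n_per_point: int

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "target": self.target,
            "n_per_point": self.n_per_point,
            "grid": [float(g) for g in self.grid],
            "fractions": [float(f) for f in self.fractions],
        }


def fit_pb(
    target_identity_fraction: float,
    bias: SegregationBias,
    grid: Sequence[float],
    n_per_point: int = 1_000_000,
    seed: int | None = None,
) -> FitResult:
    """Fit the disome-copy loss probability Pb against the identical-pair
    fraction, at Pa = 0.

    For each grid value the conditional simulator estimates the proportion
    of ``copies`` among all two-viable-spore asci; the grid point closest to
    the target is returned (ties resolve to the smaller Pb).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty Pb grid")
    if (grid < 0).any() or (grid > 0.30).any():
        raise ValueError("Pb grid must lie within [0, 0.30]")
    rng = np.random.default_rng(seed)
    fracs = np.empty(grid.size)
    for i, pb in enumerate(grid):
        summary = simulate(
            n_per_point,
            bias,
            LossParams(pa=0.0, pb=float(pb)),
            seed=rng,
            conditional=True,
            collect_disomy=False,
        )
        fracs[i] = summary.identity_fraction
    best = int(np.argmin(np.abs(fracs - target_identity_fraction)))
    return FitResult(
        value=float(grid[best]),
        grid=grid,
        fractions=fracs,
        target=target_identity_fraction,
        n_per_point=n_per_point,
    )


def fit_pa(
    pb: float,
    target_pair_fraction: float,
    bias: SegregationBias,
    grid: Sequence[float],
    n_per_point: int = 1_000_000,
    seed: int | None = None,
) -> FitResult:
    """Fit the monosome loss probability Pa at fixed Pb against the fraction
    of two-viable-spore asci among all viable-set asci."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty Pa grid")
    if (grid < 0).any() or (grid > 0.04).any():
        raise ValueError("Pa grid must lie within [0, 0.04]")
    rng = np.random.default_rng(seed)
    fracs = np.empty(grid.size)
    for i, pa in enumerate(grid):
        summary = simulate(
            n_per_point,
            bias,
            LossParams(pa=float(pa), pb=pb),
            seed=rng,
            conditional=True,
            collect_disomy=False,
        )
        fracs[i] = summary.pair_fraction
    best = int(np.argmin(np.abs(fracs - target_pair_fraction)))
    return FitResult(
        value=float(grid[best]),
        grid=grid,
        fractions=fracs,
        target=target_pair_fraction,
        n_per_point=n_per_point,
    )


def sample_viable_spores(
    n_spores: int,
    bias: SegregationBias,
    loss: LossParams,
    seed: int | np.random.Generator | None = None,
    chunk_size: int = 1 << 16,
) -> np.ndarray:
    """Draw ``n_spores`` viable spore karyotypes (state codes, shape
    (n_spores, 16)) by conditional simulation of full MI daughters.

    Viable spores appear in cohort order of the tetrads that produced
    them; any disomy is heterodisomy by construction.
    """
    if n_spores < 1:
        raise ValueError("n_spores must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    c = bias.same_pole
    with np.errstate(divide="ignore", invalid="ignore"):
        p32 = ((c / 2.0) / (1.0 - c / 2.0)).astype(np.float32)
    collected: list[np.ndarray] = []
    total = 0
    while total < n_spores:
        u = rng.random((chunk_size, bias.n_chromosomes), dtype=np.float32)
        mono = np.uint8(1) + (u >= p32 + (1.0 - p32) / 2.0)
        d1 = np.where(u < p32, np.uint8(3), mono)
        for _ in range(2):
            s = _mii_spore_chunk(d1, loss, rng)
            viable = (s != 0).all(axis=1)
            if viable.any():
                collected.append(s[viable])
                total += int(viable.sum())
    return np.concatenate(collected)[:n_spores]


def disomy_distribution(
    bias: SegregationBias,
    loss: LossParams,
    n: int,
    seed: int | None = None,
    conditional: bool = True,
) -> np.ndarray:
    """Histogram (length 17) of disomy counts per viable spore."""
    summary = simulate(n, bias, loss, seed=seed, conditional=conditional)
    return summary.disomy_hist
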