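"""Exact product-form probabilities for the achiasmate tetrad model.

Conditional on an MI daughter that carries a full chromosome set,
chromosomes behave independently, so every ascus-category probability
factorises into a product of per-chromosome kernels.  Each kernel is
obtained by exact enumeration of the per-chromosome joint outcome of the
daughter's two spores:

* with conditional probability ``p_N = (c_N/2) / (1 - c_N/2)`` the daughter
  carries both homologs (heterodisomy branch; ``c_N`` is the same-pole MI
  probability), and each spore independently keeps/loses each of its two
  copies with per-copy probability ``pb``;
* otherwise the daughter is monosomic and each spore keeps/loses its single
  copy with probability ``pa``.

These closed forms serve as the independent verification surface for the
Monte-Carlo simulator and its fitting procedures.  They condition on a
designated full daughter and ignore the rare tetrads in which both MI
daughters are full (probability ``prod((1-c_N)/(2-c_N))`` of full-daughter
tetrads, ~(2/3)^16 = 1.5e-3 in the unbiased 16-chromosome model), matching
the simulator's exclusion of ``multi`` asci up to that error bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meiosis_model import LossParams, SegregationBias

__all__ = [
    "PerChromosomePairKernel",
    "p_daughter_full",
    "conditional_disomy_probs",
    "pair_kernel",
    "category_fractions",
    "pair_identity_fraction",
    "pair_fraction",
]


def _same_pole(bias: SegregationBias | np.ndarray) -> np.ndarray:
    if isinstance(bias, SegregationBias):
        return bias.same_pole
    c = np.asarray(bias, dtype=float)
    if ((c < 0) | (c > 1)).any():
        raise ValueError("same-pole probabilities must lie in [0, 1]")
    return c


def p_daughter_full(bias: SegregationBias | np.ndarray) -> float:
    """Probability that a designated MI daughter has >=1 copy of every
    chromosome: ``prod(1 - c_N / 2)``.

    Accepts a :class:`SegregationBias` or a raw vector of same-pole
    probabilities (any genome size, for reduced-genome checks).
    """
    c = _same_pole(bias)
    return float(np.prod(1.0 - c / 2.0))


def conditional_disomy_probs(bias: SegregationBias | np.ndarray) -> np.ndarray:
    """Per-chromosome P(daughter carries both homologs | daughter full)."""
    c = _same_pole(bias)
    return (c / 2.0) / (1.0 - c / 2.0)


@dataclass(frozen=True)
class PerChromosomePairKernel:
    """Per-chromosome joint spore-pair probabilities, conditional on a full
    MI daughter: P(both spores keep the chromosome with identical state),
    P(both keep it), P(a designated spore keeps it)."""

    identical: float
    both_viable: float
    marginal: float

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (
            -eps <= self.identical <= self.both_viable + eps
            and self.both_viable <= self.marginal + eps
            and self.marginal <= 1.0 + eps
        ):
            raise ValueError("kernel must satisfy identical <= both <= marginal <= 1")


def pair_kernel(p_dis: float, loss: LossParams) -> PerChromosomePairKernel:
    """Exact kernel for one chromosome with conditional disomy probability
    ``p_dis``, by enumeration of the per-spore loss outcomes.

    Disomy branch (per spore): keeps both copies w.p. ``(1-pb)^2``, exactly
    one w.p. ``2 pb (1-pb)`` (the fired copy is the one lost, so the
    surviving parent is equally likely A or B), none w.p. ``pb^2``.
    Monosomy branch: keeps its copy w.p. ``1-pa``.
    """
    pa, pb = loss.pa, loss.pb
    q = 1.0 - pb
    # Disomy branch, per spore: states AB / A / B / none.
    p_ab, p_one, p_none = q * q, 2.0 * pb * q, pb * pb
    dis_identical = p_ab**2 + 2.0 * (p_one / 2.0) ** 2  # both AB, both A, both B
    dis_both = (1.0 - p_none) ** 2
    dis_marginal = 1.0 - p_none
    mono_identical = mono_both = (1.0 - pa) ** 2
    mono_marginal = 1.0 - pa
    return PerChromosomePairKernel(
        identical=p_dis * dis_identical + (1.0 - p_dis) * mono_identical,
        both_viable=p_dis * dis_both + (1.0 - p_dis) * mono_both,
        marginal=p_dis * dis_marginal + (1.0 - p_dis) * mono_marginal,
    )


def _log_product(values: np.ndarray) -> float:
    """Product of probabilities, in log space for numerical robustness."""
    values = np.asarray(values, dtype=float)
    if (values == 0.0).any():
        return 0.0
    return float(np.exp(np.log(values).sum()))


def category_fractions(
    bias: SegregationBias | np.ndarray, loss: LossParams
) -> dict[str, float]:
    """Exact fractions of copies / altered_copies / single / mii_dead among
    full-daughter tetrads.

    With per-chromosome kernels ``(i_N, b_N, m_N)``:
    ``copies = prod i_N``; ``both = prod b_N``; ``single = 2 (prod m_N -
    prod b_N)``; ``mii_dead = 1 - 2 prod m_N + prod b_N`` (each spore dies
    independently given the other's fate factorises chromosome-wise).
    """
    p_dis = conditional_disomy_probs(bias)
    kernels = [pair_kernel(float(p), loss) for p in p_dis]
    copies = _log_product([k.identical for k in kernels])
    both = _log_product([k.both_viable for k in kernels])
    marginal = _log_product([k.marginal for k in kernels])
    single = 2.0 * (marginal - both)
    mii_dead = 1.0 - 2.0 * marginal + both
    return {
        "copies": copies,
        "altered_copies": both - copies,
        "single": single,
        "mii_dead": mii_dead,
    }


def pair_identity_fraction(
    bias: SegregationBias | np.ndarray, loss: LossParams
) -> float:
    """copies / (copies + altered_copies): identical pairs among all
    two-viable-spore asci."""
    f = category_fractions(bias, loss)
    both = f["copies"] + f["altered_copies"]
    return f["copies"] / both if both > 0 else float("nan")


def pair_fraction(bias: SegregationBias | np.ndarray, loss: LossParams) -> float:
    """(copies + altered) / (copies + altered + single): two-viable-spore
    asci among all asci with at least one viable spore."""
    f = category_fractions(bias, loss)
    both = f["copies"] + f["altered_copies"]
    alive = both + f["single"]
    return both / alive if alive > 0 else float("nan")
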