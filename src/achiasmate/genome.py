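"""Chromosome tables for the 16-chromosome budding-yeast genome.

The default table ships the standard S288C (sacCer3) chromosome lengths.
A ``mini`` variant scales every chromosome down (default 0.15x, ~35-230 kb)
while preserving the length ordering, so that read-level simulations stay
fast; the shortest chromosome is chromosome 1 and the longest chromosome 4,
as in the real karyotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

N_CHROMOSOMES = 16


@dataclass(frozen=True)
class ChromosomeTable:
    """Names and lengths of the 16 chromosomes.

    Parameters
    ----------
    names
        Chromosome identifiers, e.g. ``chr1`` .. ``chr16``.
    lengths_bp
        Positive lengths in base pairs, same order as ``names``.
    """

    names: tuple[str, ...]
    lengths_bp: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths_bp, dtype=np.int64)
        object.__setattr__(self, "lengths_bp", lengths)
        if len(self.names) != N_CHROMOSOMES or lengths.shape != (N_CHROMOSOMES,):
            raise ValueError(
                f"a chromosome table must have exactly {N_CHROMOSOMES} entries"
            )
        if (lengths <= 0).any():
            raise ValueError("all chromosome lengths must be positive")
        if len(set(self.names)) != N_CHROMOSOMES:
            raise ValueError("chromosome names must be unique")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def l_min(self) -> int:
        return int(self.lengths_bp.min())

    @property
    def l_max(self) -> int:
        return int(self.lengths_bp.max())

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.names, "length_bp": self.lengths_bp})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChromosomeTable":
        return cls(tuple(df["name"].astype(str)), df["length_bp"].to_numpy())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromosomeTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_table() -> ChromosomeTable:
    """The sacCer3 chromosome table (chr1 shortest, chr4 longest)."""
    with resources.files("achiasmate.data").joinpath(
        "sacCer3_chromosomes.tsv"
    ).open() as fh:
        return ChromosomeTable.from_frame(pd.read_csv(fh, sep="\t"))


def mini_table(scale: float = 0.15) -> ChromosomeTable:
    """A scaled-down genome for fast read-level simulation.

    Lengths are the sacCer3 lengths multiplied by ``scale`` (rounded to
    whole kilobases), preserving relative lengths and ordering.
    """
    full = default_table()
    lengths = np.maximum(1, np.round(full.lengths_bp * scale / 1000)).astype(
        np.int64
    ) * 1000
    return ChromosomeTable(full.names, lengths)
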