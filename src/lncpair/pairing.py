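"""Within-sample rank-pair indicators.

For every unordered couple of genes {A, B} and each sample s, the indicator
C is 1 when expr_s(A) strictly exceeds expr_s(B) and 0 otherwise (ties score
0). Because C depends only on the within-sample ordering of two genes, the
resulting binary matrix is invariant to any strictly increasing per-sample
transform of the expression values — no normalization across samples is
needed. Pairs whose indicator is nearly constant across samples carry no
discriminative information and are removed by an open-interval frequency
filter (default: retain 0.2 < mean(C) < 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["PairMatrix", "build_pair_matrix", "filter_valid_pairs", "PAIR_SEP"]

PAIR_SEP = "|"


@dataclass
class PairMatrix:
    """Binary pair x sample indicator matrix.

    ``indicators`` is indexed by pair id ``"A|B"`` (A lexicographically before
    B) with one 0/1 column per sample; ``frequencies`` is the per-pair mean
    indicator over samples.
    """

    indicators: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.indicators.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("pair indicators must be 0 or 1")
        self.indicators = self.indicators.astype(np.int8)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.indicators.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicators.columns)

    @property
    def n_pairs(self) -> int:
        return self.indicators.shape[0]

    @property
    def frequencies(self) -> pd.Series:
        return self.indicators.mean(axis=1)

    def subset_samples(self, sample_ids) -> "PairMatrix":
        ids = [s for s in sample_ids if s in self.indicators.columns]
        return PairMatrix(self.indicators[ids])

    def to_tsv(self, path: str | Path) -> None:
        df = self.indicators.copy()
        df.index.name = "pair_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def build_pair_matrix(expr: ExpressionMatrix) -> PairMatrix:
    """Build the 0-or-1 indicator matrix over all unordered gene couples.

    Each couple appears once in canonical orientation (lexicographically
    smaller id first); for g genes exactly g(g-1)/2 pairs are emitted.
    ``C = 1`` iff the first gene's value strictly exceeds the second's.
    """
    genes = sorted(expr.gene_ids)
    if len(genes) < 2:
        raise ValueError("pairing requires at least 2 genes")
    for g in genes:
        if PAIR_SEP in g:
            raise ValueError(f"gene id {g!r} contains the reserved separator {PAIR_SEP!r}")
    vals = expr.values.loc[genes].to_numpy(dtype=float)
    ai, bi = np.triu_indices(len(genes), k=1)
    ind = (vals[ai] > vals[bi]).astype(np.int8)
    pair_ids = [f"{genes[a]}{PAIR_SEP}{genes[b]}" for a, b in zip(ai, bi)]
    return PairMatrix(pd.DataFrame(ind, index=pair_ids, columns=expr.sample_ids))


def filter_valid_pairs(pm: PairMatrix, low: float = 0.2, high: float = 0.8) -> PairMatrix:
    """Retain pairs whose indicator frequency lies strictly inside (low, high)."""
    if not (0.0 < low < high < 1.0):
        raise ValueError("require 0 < low < high < 1")
    f = pm.frequencies
    keep = (f > low) & (f < high)
    return PairMatrix(pm.indicators[keep.to_numpy()])
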