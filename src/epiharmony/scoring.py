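"""Screening fitness functions: Bayesian-network K2 score and Gini impurity.

Both scores grade how well the joint genotype combination at a SNP pair
partitions the phenotype, directly from the 9x2 contingency table:

* K2 score — the Bayesian-network marginal likelihood of the genotype
  combination as the sole parent of phenotype,
  ``K2 = prod_i [(J-1)! / (n_i + J - 1)!] * prod_j n_ij!``.
  The raw product underflows for realistic sample sizes, so it is kept as
  ``-ln K2`` computed in log space via log-gamma and *minimized*.

* Gini score — the genotype-frequency-weighted impurity
  ``sum_i P_i (1 - sum_j p_ij^2)`` with ``P_i = n_i / L`` and
  ``p_ij = n_ij / n_i``; 0 for a perfectly separating partition, 0.5 at
  maximal impurity for two phenotype classes.  Also minimized.

Empty genotype rows (n_i = 0) contribute 0 to both scores by continuity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data import ContingencyTable

__all__ = [
    "LOWER_IS_BETTER",
    "ScoredModel",
    "k2_neglog_score",
    "gini_score",
    "k2_neglog_from_counts",
    "gini_from_counts",
    "is_better",
]

#: Orientation of both fitness functions.  -ln(K2) and the Gini impurity both
#: decrease as the genotype partition explains phenotype better, so "best
#: harmony" means smallest score throughout the search.
LOWER_IS_BETTER: bool = True


def is_better(a: float, b: float) -> bool:
    """True if score ``a`` beats score ``b`` under the package orientation."""
    return a < b if LOWER_IS_BETTER else a > b


@dataclass(frozen=True)
class ScoredModel:
    """A canonical SNP pair with its two fitness values (one 'harmony')."""

    pair: tuple[int, int]
    k2_neglog: float
    gini: float

    def __post_init__(self) -> None:
        a, b = self.pair
        if not a < b:
            raise ValueError(f"pair must be ascending and distinct, got {self.pair}")


def k2_neglog_from_counts(counts: np.ndarray) -> np.ndarray:
    """-ln(K2) for one or a stack of count tables with shape (..., I, J).

    Per genotype row the log factor is
    ``lnGamma(n_i + J) - lnGamma(J) - sum_j lnGamma(n_ij + 1)``;
    rows with n_i = 0 contribute exactly 0.  Finite for any counts.
    """
    counts = np.asarray(counts, dtype=float)
    J = counts.shape[-1]
    row_totals = counts.sum(axis=-1)
    per_row = (
        gammaln(row_totals + J) - gammaln(J) - gammaln(counts + 1.0).sum(axis=-1)
    )
    return per_row.sum(axis=-1)


def gini_from_counts(counts: np.ndarray) -> np.ndarray:
    """Gini impurity for one or a stack of count tables, shape (..., I, J)."""
    counts = np.asarray(counts, dtype=float)
    row_totals = counts.sum(axis=-1)
    total = row_totals.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("Gini score undefined for an empty table")
    safe_rows = np.where(row_totals > 0, row_totals, 1.0)
    p = counts / safe_rows[..., None]
    impurity = 1.0 - (p * p).sum(axis=-1)
    weights = row_totals / total[..., None]
    return (weights * np.where(row_totals > 0, impurity, 0.0)).sum(axis=-1)


def k2_neglog_score(table: ContingencyTable) -> float:
    """-ln of the K2 Bayesian score of a contingency table (lower = better)."""
    return float(k2_neglog_from_counts(table.counts))


def gini_score(table: ContingencyTable) -> float:
    """Weighted Gini impurity of the genotype->phenotype partition."""
    return float(gini_from_counts(table.counts))
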