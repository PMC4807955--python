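"""Stage-2 statistical testing: the modified G-test with Bonferroni control.

The G statistic is the likelihood-ratio goodness-of-fit statistic
``G = 2 sum_ij O_ij ln(O_ij / E_ij)`` over the genotype-combination x
phenotype table, with two small-sample modifications for sparse genotype
cells:

* zero-observed cells contribute 0 to the sum (their limit value), and
* the degrees of freedom, nominally (I-1)(J-1), are reduced by one for
  every genotype row whose total count falls below a small integer
  threshold epsilon; if the adjusted df reaches 0 the table is untestable
  and the p-value is reported as 1.

Multiple testing over all C(N, k) pairs is controlled by the Bonferroni
correction alpha = alpha0 / C(N, k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .data import ContingencyTable, GenotypeDataset, build_contingency, single_locus_table

__all__ = [
    "GTestResult",
    "SignificancePolicy",
    "expected_counts",
    "g_statistic",
    "bonferroni_alpha",
    "test_candidates",
    "prefilter_loci",
]

#: Default small-count threshold for the df reduction rule: the classic
#: rule-of-thumb minimum for count-based asymptotics.
DEFAULT_EPSILON = 5


@dataclass(frozen=True)
class GTestResult:
    """G statistic with its adjusted degrees of freedom and p-value."""

    g: float
    df: int
    p_value: float
    epsilon: int
    expected: np.ndarray

    def __repr__(self) -> str:  # expected matrix is noise in logs
        return (
            f"GTestResult(g={self.g:.4g}, df={self.df}, p={self.p_value:.4g}, "
            f"epsilon={self.epsilon})"
        )


@dataclass(frozen=True)
class SignificancePolicy:
    """Bonferroni-corrected significance threshold over all C(N, k) models."""

    alpha0: float
    n_snps: int
    k: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha0 <= 1.0:
            raise ValueError("alpha0 must lie in (0, 1]")
        if self.n_snps < self.k:
            raise ValueError("need at least k SNPs")

    @property
    def alpha(self) -> float:
        return bonferroni_alpha(self.alpha0, self.n_snps, self.k)


def bonferroni_alpha(alpha0: float, n_snps: int, k: int = 2) -> float:
    """Per-test level alpha0 / C(n_snps, k)."""
    if n_snps < k:
        raise ValueError(f"cannot choose {k} loci from {n_snps}")
    return alpha0 / math.comb(n_snps, k)


def expected_counts(table: ContingencyTable, mode: str = "independence") -> np.ndarray:
    """Expected cell counts under the null of no genotype-phenotype association.

    ``independence`` (default) uses the contingency margin products
    ``E_ij = n_i. * n_.j / L``.  ``hwe`` instead rebuilds the genotype margin
    from Hardy-Weinberg proportions at the allele frequencies estimated from
    the pooled sample (per locus for a two-locus 9-row table), crossed with
    the phenotype margin.  Both modes conserve the table total.
    """
    if table.total == 0:
        raise ValueError("expected counts undefined for an empty table")
    if mode == "independence":
        return np.outer(table.row_totals, table.col_totals) / table.total
    if mode == "hwe":
        return _hwe_expected(table)
    raise ValueError(f"unknown expected-count mode {mode!r}")


def _hwe_expected(table: ContingencyTable) -> np.ndarray:
    """HWE-based genotype margin x phenotype margin."""
    L = table.total
    row_totals = table.row_totals
    if table.I == 3:  # single locus
        geno_probs = _hwe_row_probs(row_totals, L)
    elif table.I == 9:
        ga_counts = row_totals.reshape(3, 3).sum(axis=1)
        gb_counts = row_totals.reshape(3, 3).sum(axis=0)
        geno_probs = np.outer(
            _hwe_row_probs(ga_counts, L), _hwe_row_probs(gb_counts, L)
        ).ravel()
    else:
        raise ValueError("HWE expecteds defined for 3- or 9-row tables only")
    return np.outer(geno_probs, table.col_totals / L) * L


def _hwe_row_probs(genotype_counts: np.ndarray, L: int) -> np.ndarray:
    q = (genotype_counts[1] + 2 * genotype_counts[2]) / (2 * L)
    p = 1.0 - q
    return np.array([p * p, 2 * p * q, q * q])


def g_statistic(
    table: ContingencyTable,
    epsilon: int = DEFAULT_EPSILON,
    expected_mode: str = "independence",
) -> GTestResult:
    """Modified G-test of a genotype-combination x phenotype table.

    Zero-observed cells are dropped from the sum; each genotype row with
    total count below ``epsilon`` costs one degree of freedom.  A table whose
    adjusted df reaches 0 is untestable: p = 1.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    expected = expected_counts(table, expected_mode)
    observed = table.counts.astype(float)
    mask = observed > 0
    g = 2.0 * float(
        np.sum(observed[mask] * np.log(observed[mask] / expected[mask]))
    )
    g = max(g, 0.0)  # clip -0.0 / rounding residue on exact-fit tables

    df = (table.I - 1) * (table.J - 1)
    df -= int(np.count_nonzero(table.row_totals < epsilon))
    df = max(df, 0)
    p_value = float(chi2.sf(g, df)) if df > 0 else 1.0
    return GTestResult(g=g, df=df, p_value=p_value, epsilon=epsilon, expected=expected)


def test_candidates(
    ds: GenotypeDataset,
    candidate_pairs,
    policy: SignificancePolicy,
    epsilon: int = DEFAULT_EPSILON,
    expected_mode: str = "independence",
) -> list[tuple[tuple[int, int], GTestResult]]:
    """G-test a deduplicated collection of screened pairs; keep the significant.

    ``candidate_pairs`` may be any iterable of 0-based pairs (typically the
    union of the two harmony memories, via
    :meth:`~epiharmony.search.ScreeningResult.candidate_pairs`).  Returns the
    pairs with p-value below the Bonferroni-corrected level, sorted ascending
    by p-value.
    """
    results = gtest_pairs(ds, candidate_pairs, epsilon, expected_mode)
    passing = [(pair, res) for pair, res in results if res.p_value < policy.alpha]
    passing.sort(key=lambda item: item[1].p_value)
    return passing


def gtest_pairs(
    ds: GenotypeDataset,
    pairs,
    epsilon: int = DEFAULT_EPSILON,
    expected_mode: str = "independence",
) -> list[tuple[tuple[int, int], GTestResult]]:
    """G-test every unique pair (no thresholding); first-seen order."""
    seen: dict[tuple[int, int], None] = {}
    for pair in pairs:
        a, b = pair
        seen.setdefault((min(a, b), max(a, b)), None)
    return [
        (pair, g_statistic(build_contingency(ds, pair), epsilon, expected_mode))
        for pair in seen
    ]


def prefilter_loci(
    ds: GenotypeDataset,
    p_threshold: float = 0.3,
    epsilon: int = DEFAULT_EPSILON,
    keep_small_p: bool = True,
) -> tuple[GenotypeDataset, np.ndarray]:
    """Single-locus G-test prefilter used to shrink dense real datasets.

    Each SNP is tested on its 3x2 genotype-by-phenotype table (base df 2,
    same epsilon rule).  With ``keep_small_p`` (default) loci with
    p < ``p_threshold`` are retained — the reading under which a mostly-null
    genome keeps roughly the threshold fraction of loci.  The literal
    remove-if-small alternative is available with ``keep_small_p=False``.

    Returns the column-subset dataset and the kept 0-based column indices.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    p_values = np.array(
        [
            g_statistic(single_locus_table(ds, i), epsilon).p_value
            for i in range(ds.n_snps)
        ]
    )
    small = p_values < p_threshold
    kept = np.flatnonzero(small if keep_small_p else ~small)
    return ds.subset_loci(kept), kept
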