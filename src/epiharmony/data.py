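"""Genotype/phenotype containers, contingency tables, and dataset I/O.

Case-control SNP data is held as a dense integer matrix of minor-allele
counts (0 = homozygous major, 1 = heterozygous, 2 = homozygous minor) plus
a binary phenotype vector (0 = control, 1 = case).  Files use the plain
whitespace/tab-separated dialect produced by common epistasis simulators:
one header row of SNP identifiers followed by a phenotype column (named
``Class`` by convention), then one integer row per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "ContingencyTable",
    "DatasetParseError",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "build_contingency",
]


class DatasetParseError(ValueError):
    """A dataset file is structurally malformed (ragged rows, non-integers)."""


class DatasetValidationError(ValueError):
    """Data are structurally well formed but violate a dataset invariant."""


@dataclass
class GenotypeDataset:
    """L individuals x N SNPs with a binary phenotype.

    Parameters
    ----------
    genotypes
        ``(L, N)`` integer matrix with entries in ``{0, 1, 2}``.
    phenotype
        Length-``L`` integer vector with entries in ``{0, 1}``.
    snp_ids
        ``N`` unique SNP identifier strings, in column order.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.ascontiguousarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DatasetValidationError("genotypes must be a 2-D matrix")
        if not self.snp_ids:
            self.snp_ids = [f"X{i + 1}" for i in range(self.genotypes.shape[1])]
        self.snp_ids = [str(s) for s in self.snp_ids]
        validate_dataset(self)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    # short aliases used throughout the search code
    L = n_individuals
    N = n_snps

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n_individuals - self.n_cases

    def subset_loci(self, columns: np.ndarray | list[int]) -> "GenotypeDataset":
        """Column-subset copy keeping individuals and phenotype unchanged."""
        columns = np.asarray(columns, dtype=int)
        return GenotypeDataset(
            genotypes=self.genotypes[:, columns].copy(),
            phenotype=self.phenotype.copy(),
            snp_ids=[self.snp_ids[c] for c in columns],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
        )


def validate_dataset(ds: GenotypeDataset) -> None:
    """Raise :class:`DatasetValidationError` on any invariant violation."""
    L, N = ds.genotypes.shape
    if ds.phenotype.shape != (L,):
        raise DatasetValidationError(
            f"phenotype length {ds.phenotype.shape} does not match {L} individuals"
        )
    if len(ds.snp_ids) != N:
        raise DatasetValidationError(
            f"{len(ds.snp_ids)} SNP ids for {N} genotype columns"
        )
    if len(set(ds.snp_ids)) != N:
        raise DatasetValidationError("SNP ids are not unique")
    if L:
        gmin = ds.genotypes.min(initial=0)
        gmax = ds.genotypes.max(initial=0)
        if gmin < 0 or gmax > 2:
            raise DatasetValidationError(
                f"genotype entries outside {{0,1,2}} (range {gmin}..{gmax})"
            )
        pmin, pmax = ds.phenotype.min(), ds.phenotype.max()
        if pmin < 0 or pmax > 1:
            raise DatasetValidationError(
                f"phenotype entries outside {{0,1}} (range {pmin}..{pmax})"
            )


@dataclass
class ContingencyTable:
    """Genotype-combination x phenotype count table.

    For a pair of loci the ``I = 3**2 = 9`` rows index joint genotype
    combinations (row ``3*g_first + g_second`` with *first* the lower-index
    SNP) and the ``J = 2`` columns index phenotype states (control, case).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.ascontiguousarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise DatasetValidationError("contingency counts must be 2-D")
        if (self.counts < 0).any():
            raise DatasetValidationError("contingency counts must be non-negative")

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return self.counts.shape[0]

    @property
    def J(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_contingency(ds: GenotypeDataset, pair: tuple[int, int]) -> ContingencyTable:
    """Count individuals per joint-genotype combination and phenotype.

    ``pair`` holds two distinct 0-based column indices; they are canonicalized
    so the lower index drives the leading genotype digit.  The resulting 9x2
    table conserves mass: its total equals the number of individuals.
    """
    a, b = pair
    if a == b:
        raise ValueError("a two-locus model needs two distinct loci")
    if not (0 <= a < ds.n_snps and 0 <= b < ds.n_snps):
        raise IndexError(f"pair {pair} out of range for {ds.n_snps} SNPs")
    if a > b:
        a, b = b, a
    combo = 3 * ds.genotypes[:, a].astype(np.int64) + ds.genotypes[:, b]
    flat = np.bincount(combo * 2 + ds.phenotype, minlength=18)
    return ContingencyTable(flat.reshape(9, 2))


def single_locus_table(ds: GenotypeDataset, locus: int) -> ContingencyTable:
    """3x2 genotype-by-phenotype table for one SNP (used by the prefilter)."""
    g = ds.genotypes[:, locus].astype(np.int64)
    flat = np.bincount(g * 2 + ds.phenotype, minlength=6)
    return ContingencyTable(flat.reshape(3, 2))


def read_dataset(path, phenotype_column: str = "Class") -> GenotypeDataset:
    """Read a whitespace/tab-separated case-control genotype file.

    The last column (named ``phenotype_column`` when present in the header)
    is the binary phenotype; all other columns are SNPs in {0,1,2} coding.
    """
    # pandas quietly repairs ragged rows (NaN-fill or index shift), so field
    # counts are checked up front to report the offending 1-based line.
    with open(path) as fh:
        header_fields = fh.readline().split()
        n_fields = len(header_fields)
        if n_fields < 2:
            raise DatasetParseError(
                f"{path}: need at least one SNP column and a phenotype"
            )
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.split()) != n_fields:
                raise DatasetParseError(
                    f"{path}: line {lineno}: expected {n_fields} fields, "
                    f"got {len(line.split())}"
                )
    try:
        frame = pd.read_csv(path, sep=r"\s+", header=0, dtype="Int64")
    except pd.errors.ParserError as exc:
        raise DatasetParseError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise DatasetParseError(f"{path}: non-integer value in body: {exc}") from exc

    if phenotype_column in frame.columns:
        pheno = frame.pop(phenotype_column)
    else:
        pheno = frame.pop(frame.columns[-1])
    genotypes = frame.to_numpy(dtype=np.int64)
    phenotype = pheno.to_numpy(dtype=np.int64)
    if ((genotypes < 0) | (genotypes > 2)).any():
        raise DatasetValidationError(f"{path}: genotype value outside {{0,1,2}}")
    if ((phenotype < 0) | (phenotype > 1)).any():
        raise DatasetValidationError(f"{path}: phenotype value outside {{0,1}}")
    return GenotypeDataset(genotypes, phenotype, list(frame.columns))


def write_dataset(ds: GenotypeDataset, path, phenotype_column: str = "Class") -> None:
    """Write ``ds`` in the tab-separated dialect read by :func:`read_dataset`."""
    validate_dataset(ds)
    frame = pd.DataFrame(ds.genotypes, columns=ds.snp_ids)
    frame[phenotype_column] = ds.phenotype
    frame.to_csv(path, sep="\t", index=False)
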