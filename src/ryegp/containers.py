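"""In-memory containers shared across the pipeline.

The pipeline moves between three genotype representations:

* :class:`ReadMatrix` — raw GBS evidence, per-individual x per-SNP allele read
  counts.  Depth 0 means missing; nothing is imputed at this level.
* :class:`DosageMatrix` — alternate-allele dosages (0/1/2 from naive calls,
  fractional after mean imputation).
* :class:`RelationshipMatrix` — a genomic relationship estimate built either
  from imputed dosages (VanRaden) or directly from reads (depth-adjusted KGD).

Phenotypes travel as a plain :class:`pandas.DataFrame` in "trial table" layout
(one row per plot: family, population, location, replicate, row, column, then
one column per trait); see :func:`validate_trial_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

TRIAL_DESIGN_COLUMNS = ["family", "population", "location", "replicate", "row", "column"]


@dataclass
class ReadMatrix:
    """Per-individual x per-SNP reference/alternate allele read counts.

    Attributes
    ----------
    individuals : list of str
        Unique sample identifiers (rows).
    snps : pandas.DataFrame
        One row per SNP with columns ``chrom, pos, ref, alt`` and index
        ``chrom:pos:ref:alt`` (columns of the count matrices).
    ref_counts, alt_counts : ndarray of int, shape (n_individuals, n_snps)
        Read counts supporting the reference / alternate allele.  A cell with
        total depth 0 is a missing genotype.
    """

    individuals: list[str]
    snps: pd.DataFrame
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts)
        self.alt_counts = np.asarray(self.alt_counts)
        n, m = self.ref_counts.shape
        if self.alt_counts.shape != (n, m):
            raise ValueError("ref_counts and alt_counts shapes differ")
        if len(self.individuals) != n:
            raise ValueError("individuals length does not match count matrix rows")
        if len(self.snps) != m:
            raise ValueError("snps table length does not match count matrix columns")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("read counts must be non-negative")
        if len(set(self.individuals)) != n:
            raise ValueError("individual identifiers must be unique")
        if self.snps.index.duplicated().any():
            raise ValueError("SNP identifiers must be unique")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def depth(self) -> np.ndarray:
        """Total read depth per cell (0 = missing)."""
        return self.ref_counts + self.alt_counts

    def naive_calls(self) -> np.ndarray:
        """Naive genotype calls: alternate dosage 0/1/2, NaN where depth 0.

        A cell is called heterozygous iff both alleles were observed; with a
        single read a heterozygote is always observed as a homozygote (and at
        depth d is miscalled homozygous with probability 2^(1-d)).
        """
        depth = self.depth
        calls = np.full(depth.shape, np.nan)
        has_ref = self.ref_counts > 0
        has_alt = self.alt_counts > 0
        calls[has_ref & ~has_alt] = 0.0
        calls[has_ref & has_alt] = 1.0
        calls[~has_ref & has_alt] = 2.0
        return calls

    def subset_snps(self, mask: np.ndarray) -> "ReadMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ReadMatrix(
            individuals=list(self.individuals),
            snps=self.snps.iloc[idx].copy(),
            ref_counts=self.ref_counts[:, idx].copy(),
            alt_counts=self.alt_counts[:, idx].copy(),
        )

    def subset_individuals(self, ids: Sequence[str]) -> "ReadMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        idx = np.array([pos[i] for i in ids])
        return ReadMatrix(
            individuals=list(ids),
            snps=self.snps.copy(),
            ref_counts=self.ref_counts[idx],
            alt_counts=self.alt_counts[idx],
        )


@dataclass
class DosageMatrix:
    """Individuals x SNPs alternate-allele dosages with allele frequencies.

    ``values`` hold 0/1/2 calls (NaN = missing) or fractional dosages after
    mean imputation.  ``p`` is the per-SNP alternate allele frequency estimated
    from the observed (non-missing) calls.
    """

    individuals: list[str]
    snp_ids: list[str]
    values: np.ndarray
    p: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.individuals), len(self.snp_ids)):
            raise ValueError("dosage matrix shape inconsistent with identifiers")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0) < 0 or np.nanmax(self.values, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if self.p is None:
            self.p = np.nanmean(self.values, axis=0) / 2.0
        self.p = np.asarray(self.p, dtype=float)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def copy(self) -> "DosageMatrix":
        return replace(
            self,
            individuals=list(self.individuals),
            snp_ids=list(self.snp_ids),
            values=self.values.copy(),
            p=self.p.copy(),
        )


@dataclass
class RelationshipMatrix:
    """Symmetric genomic relationship estimate.

    ``method`` tags the construction ("vanraden" or "kgd").  ``n_shared``
    records, per pair, how many SNPs entered the estimate (for KGD this is the
    jointly covered subset; pairs with zero shared SNPs are flagged in
    ``missing_pairs`` and carry NaN until :meth:`filled` is called).
    """

    individuals: list[str]
    values: np.ndarray
    method: str
    n_shared: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square over individuals")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-10,
        ):
            raise ValueError("relationship matrix must be symmetric to 1e-10")

    @property
    def missing_pairs(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def filled(self, value: float = 0.0) -> "RelationshipMatrix":
        """Replace flagged missing estimates (e.g. zero shared SNPs) by ``value``.

        Model fitting needs a complete matrix; substituting 0 asserts the pair
        is unrelated, which is logged by callers.
        """
        out = self.values.copy()
        out[~np.isfinite(out)] = value
        return RelationshipMatrix(list(self.individuals), out, self.method, self.n_shared)

    def align(self, ids: Sequence[str]) -> np.ndarray:
        """Return the submatrix over ``ids`` in that order."""
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"identifiers absent from relationship matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]


def validate_trial_table(table: pd.DataFrame, traits: Sequence[str] | None = None) -> list[str]:
    """Check trial-table layout and return the trait column names.

    Raises ``ValueError`` naming the first problem found: a missing design
    column, or duplicated (family, location, replicate) plot keys.
    """
    for col in TRIAL_DESIGN_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"trial table is missing design column '{col}'")
    if traits is None:
        traits = [c for c in table.columns if c not in TRIAL_DESIGN_COLUMNS]
    else:
        for t in traits:
            if t not in table.columns:
                raise ValueError(f"trial table is missing trait column '{t}'")
    dup = table.duplicated(subset=["family", "location", "replicate"])
    if dup.any():
        raise ValueError("duplicated (family, location, replicate) plot records")
    return list(traits)
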