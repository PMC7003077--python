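"""Per-SNP statistics, the GBS filter chain, and mean imputation.

Statistics are computed from *naive* genotype calls (0/1/2 from observed
reads, heterozygous iff both alleles were seen), which is the natural basis at
low coverage: the read data are treated as allele observations rather than
genotypes.  Because a heterozygote at depth d is observed homozygous with
probability 2^(1-d), naive calls show an apparent heterozygote deficit, which
is why the Hardy-Weinberg disequilibrium filter keeps mildly positive D-hat
sites and removes only strongly negative ones (artifactual heterozygote
excess, e.g. collapsed paralogs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DosageMatrix, ReadMatrix

logger = logging.getLogger(__name__)

__all__ = ["SNPStats", "FilterReport", "compute_snp_stats", "filter_snps", "mean_impute", "calls_to_dosages"]


@dataclass
class SNPStats:
    """Per-SNP summaries from naive calls.

    ``maf``: minor allele frequency in [0, 0.5] (0 for sites with no calls,
    flagged in ``no_calls``).  ``call_rate``: fraction of individuals with
    depth > 0.  ``mean_depth``: average depth over covered individuals only.
    ``hw_diseq``: observed hom-reference frequency minus (reference allele
    frequency)^2.
    """

    table: pd.DataFrame  # index = snp ids; columns maf, call_rate, mean_depth, hw_diseq, no_calls

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_per_criterion: dict[str, int]  # counts failing each criterion (non-exclusive)
    thresholds: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input), ("retained", self.n_retained)]
        rows += [(f"failed_{k}", v) for k, v in self.removed_per_criterion.items()]
        return pd.DataFrame(rows, columns=["criterion", "n"])


def compute_snp_stats(reads: ReadMatrix) -> SNPStats:
    """Per-SNP MAF, call rate, mean depth and HW disequilibrium D-hat."""
    if reads.n_individuals < 1:
        raise ValueError("read matrix has no individuals")
    depth = reads.depth
    calls = reads.naive_calls()
    covered = depth > 0
    n_cov = covered.sum(axis=0)
    call_rate = n_cov / reads.n_individuals
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_depth = np.where(n_cov > 0, depth.sum(axis=0) / np.maximum(n_cov, 1), 0.0)
        alt_freq = np.nanmean(np.where(covered, calls, np.nan), axis=0) / 2.0
    alt_freq = np.where(n_cov > 0, alt_freq, np.nan)
    maf = np.where(np.isnan(alt_freq), 0.0, np.minimum(alt_freq, 1.0 - alt_freq))
    # D-hat: observed hom-reference frequency minus (reference freq)^2
    p_ref = 1.0 - alt_freq
    hom_ref = ((calls == 0.0) & covered).sum(axis=0) / np.maximum(n_cov, 1)
    hw = np.where(n_cov > 0, hom_ref - p_ref**2, 0.0)
    table = pd.DataFrame(
        {
            "maf": maf,
            "call_rate": call_rate,
            "mean_depth": mean_depth,
            "hw_diseq": hw,
            "no_calls": n_cov == 0,
        },
        index=reads.snps.index,
    )
    return SNPStats(table)


def filter_snps(
    reads: ReadMatrix,
    stats: SNPStats | None = None,
    max_missing: float = 0.5,
    min_maf: float = 0.05,
    min_mean_depth: float = 1.0,
    min_hwdiseq: float = -0.05,
) -> tuple[ReadMatrix, FilterReport]:
    """Apply the GBS filter chain; returns survivors plus a per-criterion report.

    Retains exactly the SNPs with call rate >= 1 - max_missing AND
    MAF > min_maf AND mean site depth > min_mean_depth AND
    D-hat > min_hwdiseq, preserving input order.  MAF and depth thresholds are
    strict inequalities; ``min_mean_depth`` is compared against the per-site
    mean depth over covered individuals (a site-level summary, not a
    per-genotype mask).
    """
    if stats is None:
        stats = compute_snp_stats(reads)
    t = stats.table
    if len(t) != reads.n_snps:
        raise ValueError("stats are not aligned with the read matrix")
    ok_call = t["call_rate"].to_numpy() >= 1.0 - max_missing
    ok_maf = t["maf"].to_numpy() > min_maf
    ok_depth = t["mean_depth"].to_numpy() > min_mean_depth
    ok_hw = t["hw_diseq"].to_numpy() > min_hwdiseq
    keep = ok_call & ok_maf & ok_depth & ok_hw
    report = FilterReport(
        n_input=reads.n_snps,
        n_retained=int(keep.sum()),
        removed_per_criterion={
            "call_rate": int((~ok_call).sum()),
            "maf": int((~ok_maf).sum()),
            "mean_depth": int((~ok_depth).sum()),
            "hw_diseq": int((~ok_hw).sum()),
        },
        thresholds={
            "max_missing": max_missing,
            "min_maf": min_maf,
            "min_mean_depth": min_mean_depth,
            "min_hwdiseq": min_hwdiseq,
        },
    )
    if report.n_retained == 0:
        warnings.warn("no SNPs survive the filter chain", stacklevel=2)
    return reads.subset_snps(keep), report


def calls_to_dosages(reads: ReadMatrix) -> DosageMatrix:
    """Naive 0/1/2 calls as a DosageMatrix (NaN where depth is zero)."""
    return DosageMatrix(
        individuals=list(reads.individuals),
        snp_ids=list(reads.snps.index),
        values=reads.naive_calls(),
    )


def mean_impute(calls: DosageMatrix) -> DosageMatrix:
    """Replace missing dosages by the per-SNP observed mean.

    Observed cells are untouched and per-SNP column means are preserved.
    A SNP with no observed value at all is rejected (it should have been
    removed by the call-rate filter).
    """
    values = calls.values
    n_obs = np.isfinite(values).sum(axis=0)
    if (n_obs == 0).any():
        bad = [calls.snp_ids[i] for i in np.flatnonzero(n_obs == 0)[:5]]
        raise ValueError(f"cannot mean-impute SNPs with no observed calls: {bad}")
    col_mean = np.nanmean(values, axis=0)
    out = np.where(np.isfinite(values), values, col_mean)
    return DosageMatrix(
        individuals=list(calls.individuals),
        snp_ids=list(calls.snp_ids),
        values=out,
        p=col_mean / 2.0,
    )
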