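"""Genomic relationship matrices from dosages (VanRaden) and raw reads (KGD).

The VanRaden matrix is the classic centered cross-product of imputed dosages,
G = (X - 2p)(X - 2p)' / (2 sum p(1-p)).  It is a Gram matrix and therefore
positive semi-definite, but at low sequencing depth its diagonal is inflated:
a heterozygote read at depth d is observed homozygous with probability
2^(1-d), and a homozygous call contributes (g - 2p)^2 terms that are too
large on average.

The KGD (kinship using depth adjustment) estimator works directly on allele
reads.  Off-diagonals use, for each pair, only the SNPs covered in *both*
individuals — no imputation — and are unbiased because the expected naive
call equals the true dosage.  Diagonals subtract the analytically derived
excess of the naive self cross-product: at a true heterozygote of depth d the
excess is exactly 2^(1-d) regardless of allele frequency, and the observed
het indicator g(2-g) detects a true het with probability 1 - 2^(1-d), so
subtracting g(2-g) / (2^(d-1) - 1) per SNP removes the inflation in
expectation.  Depth-1 SNPs are excluded from the diagonal sum: one read can
never reveal a heterozygote, so the inflation there cannot be estimated from
the observed call.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import DosageMatrix, ReadMatrix, RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = ["vanraden_grm", "kgd_grm"]


def vanraden_grm(dosages: DosageMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from (imputed) dosages.

    Requires a complete matrix (mean-impute first).  Allele frequencies are
    taken from the dosage container (estimated from the observed data).
    """
    X = dosages.values
    if not np.isfinite(X).all():
        raise ValueError("dosage matrix contains missing values; mean-impute first")
    p = dosages.p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs are monomorphic; VanRaden denominator is zero")
    W = X - 2.0 * p
    G = (W @ W.T) / denom
    n_shared = np.full((len(dosages.individuals),) * 2, dosages.n_snps)
    return RelationshipMatrix(list(dosages.individuals), G, "vanraden", n_shared)


def kgd_grm(reads: ReadMatrix) -> RelationshipMatrix:
    """Depth-adjusted (KGD) relationship matrix from raw allele reads.

    Off-diagonal (i, j): centered cross-product of naive calls over the SNPs
    covered in both i and j, scaled by 2 sum p(1-p) over that same subset.
    Diagonal (i, i): computed over SNPs covered at depth >= 2 in i, with the
    per-SNP correction g(2-g) / (2^(d-1) - 1) subtracted so the expectation
    equals 1 + F under the binomial read-sampling model.

    Pairs with zero jointly covered SNPs get a NaN estimate (flagged, not a
    silent zero); use :meth:`RelationshipMatrix.filled` before model fitting.
    """
    depth = reads.depth
    calls = reads.naive_calls()
    covered = depth > 0
    n_cov = covered.sum(axis=0)
    if (covered.sum(axis=1) == 0).any():
        bad = [reads.individuals[i] for i in np.flatnonzero(covered.sum(axis=1) == 0)]
        raise ValueError(f"individuals with no covered SNPs: {bad[:5]}")

    with np.errstate(invalid="ignore"):
        p = np.nansum(np.where(covered, calls, 0.0), axis=0) / np.maximum(2.0 * n_cov, 1.0)
    pq2 = 2.0 * p * (1.0 - p)

    W = np.where(covered, calls - 2.0 * p, 0.0)
    num = W @ W.T
    cov_f = covered.astype(float)
    den = cov_f @ (pq2[:, None] * cov_f.T)
    n_shared = (cov_f @ cov_f.T).astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    zero_pairs = int((den <= 0).sum() - np.sum(np.diag(den) <= 0))
    if zero_pairs:
        logger.warning("%d pairs share no covered SNPs; estimates flagged NaN", zero_pairs // 2)

    # depth-adjusted diagonal over SNPs with depth >= 2
    deep = depth >= 2
    with np.errstate(over="ignore"):
        corr = np.where(deep, 1.0 / (np.exp2(np.maximum(depth, 2) - 1.0) - 1.0), 0.0)
    het = np.where(deep & np.isfinite(calls), calls * (2.0 - calls), 0.0)
    self_num = np.sum(np.where(deep, W**2, 0.0) - het * corr, axis=1)
    self_den = deep @ pq2
    diag = np.where(self_den > 0, self_num / np.where(self_den > 0, self_den, 1.0), np.nan)
    if np.isnan(diag).any():
        logger.warning(
            "%d individuals have no depth>=2 SNPs; their self-relatedness is flagged NaN",
            int(np.isnan(diag).sum()),
        )
    np.fill_diagonal(G, diag)
    return RelationshipMatrix(list(reads.individuals), G, "kgd", n_shared)
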