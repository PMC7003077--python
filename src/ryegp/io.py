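"""Readers and writers for the pipeline's interchange formats.

Genotypes travel as VCF with GT plus AD (and DP) FORMAT fields: AD carries
the allele-level read evidence the depth-adjusted kinship estimator needs.
Records with a GT but no AD get their DP split as "allele unknown" and are
excluded from allele-level analyses (a logged count).  Phenotypes are
tab-delimited trial tables (family, population, location, replicate, row,
column, then one column per trait); relationship matrices are tab-delimited
square matrices with identifiers in the first row and column.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ReadMatrix, RelationshipMatrix, validate_trial_table

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf_reads",
    "write_vcf_reads",
    "read_trial_table",
    "write_trial_table",
    "read_relationship_matrix",
    "write_relationship_matrix",
    "derive_traits",
    "TETANY_RISK_THRESHOLD",
]

#: Tetany-index value above which hypomagnesaemia risk is considered elevated.
TETANY_RISK_THRESHOLD = 2.2


def write_vcf_reads(reads: ReadMatrix, path: str | Path) -> None:
    """Write allele read counts as an uncompressed VCF (GT, AD, DP)."""
    path = Path(path)
    depth = reads.depth
    calls = reads.naive_calls()
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Naive genotype call">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        for chrom in pd.unique(reads.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(reads.individuals) + "\n")
        snps = reads.snps
        for j in range(reads.n_snps):
            row = snps.iloc[j]
            cells = []
            for i in range(reads.n_individuals):
                d = int(depth[i, j])
                if d == 0:
                    cells.append("./.:0,0:0")
                else:
                    gt = gt_map[calls[i, j]]
                    cells.append(f"{gt}:{int(reads.ref_counts[i, j])},{int(reads.alt_counts[i, j])}:{d}")
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{snps.index[j]}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT:AD:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf_reads(path: str | Path) -> ReadMatrix:
    """Read biallelic SNP allele depths from a VCF (via cyvcf2).

    AD is preferred; records carrying only GT/DP cannot be split into allele
    reads and are counted and skipped for the read matrix (they would bias
    the depth-adjusted kinship).  Non-biallelic records are skipped with a
    logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    n = len(individuals)
    ref_rows, alt_rows, meta = [], [], []
    n_multi = n_no_ad = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] in (None, "", "<NON_REF>"):
            n_multi += 1
            continue
        ad = var.format("AD")
        if ad is None:
            n_no_ad += 1
            continue
        ad = np.asarray(ad)
        if ad.shape != (n, 2):
            n_multi += 1
            continue
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
        ref_rows.append(ad[:, 0])
        alt_rows.append(ad[:, 1])
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_multi:
        logger.info("skipped %d non-biallelic records", n_multi)
    if n_no_ad:
        logger.info("skipped %d records without AD (allele reads unavailable)", n_no_ad)
    if not meta:
        raise ValueError(f"no usable biallelic SNPs with AD found in {path}")
    snps = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    snps.index = [f"{c}:{p}:{r}:{a}" for c, p, r, a in meta]
    return ReadMatrix(
        individuals=individuals,
        snps=snps,
        ref_counts=np.column_stack(ref_rows),
        alt_counts=np.column_stack(alt_rows),
    )


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(table)
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited trial table.

    ``column_map`` renames file columns to the canonical schema, e.g.
    ``{"Family": "family", "Site": "location"}`` — deposited phenotype files
    rarely share one header convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"phenotype file not found: {path}")
    table = pd.read_csv(path, sep="\t")
    if column_map:
        table = table.rename(columns=column_map)
    validate_trial_table(table)
    return table


def write_relationship_matrix(grm: RelationshipMatrix, path: str | Path) -> None:
    pd.DataFrame(grm.values, index=grm.individuals, columns=grm.individuals).to_csv(
        path, sep="\t", index_label=grm.method
    )


def read_relationship_matrix(path: str | Path, method: str = "supplied") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("relationship matrix rows and columns disagree")
    return RelationshipMatrix(list(df.index), df.to_numpy(dtype=float), method)


def derive_traits(
    table: pd.DataFrame,
    nitrogen: str = "N",
    potassium: str = "K",
    calcium: str = "Ca",
    magnesium: str = "Mg",
) -> pd.DataFrame:
    """Append derived nutritive traits where their inputs are present.

    Crude protein CP = 6.25 x N (the standard nitrogen-to-protein factor);
    tetany ratio = K / (Mg + Ca), a hypomagnesaemia risk index (values above
    2.2 flag elevated risk in the ``tetany_risk`` column).  Plots with
    Mg + Ca = 0 get a NaN ratio and a logged count.
    """
    out = table.copy()
    if nitrogen in out.columns:
        out["CP"] = 6.25 * out[nitrogen]
    if all(c in out.columns for c in (potassium, calcium, magnesium)):
        denom = out[magnesium] + out[calcium]
        bad = denom == 0
        if bad.any():
            logger.warning("%d plots have Mg + Ca = 0; tetany ratio undefined", int(bad.sum()))
        out["tetany_ratio"] = np.where(bad, np.nan, out[potassium] / denom.replace(0, np.nan))
        out["tetany_risk"] = out["tetany_ratio"] > TETANY_RISK_THRESHOLD
    return out
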