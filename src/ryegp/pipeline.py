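"""End-to-end two-stage genomic-selection workflow on synthetic or real data.

Stage one fits the across-location mixed model per trait and extracts family
BLUPs (adjusted means), repeatability and genomic heritability; stage two
runs genomic prediction with cross-validation on those BLUPs.  Every output
table carries the configuration hash and seed in a header comment so a run
can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .containers import RelationshipMatrix
from .correlations import phenotypic_correlation
from .cv import bayescpi_predictor, gblup_predictor, kfold_cv
from .grm import kgd_grm, vanraden_grm
from .lmm import extract_blups, genomic_heritability, model2_spec, reml_fit, repeatability
from .prediction import PredictionModelSpec
from .qc import calls_to_dosages, compute_snp_stats, filter_snps, mean_impute
from .simulate import SimulationConfig, simulate_gbs_reads, simulate_population_set, simulate_trial

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` is set (synthetic run) or ``vcf_path`` +
    ``phenotype_path`` point at real inputs.  ``grm_snp_sets`` selects which
    SNP set feeds each relationship matrix ("filtered" or "unfiltered") —
    the convention differs between the VanRaden and depth-adjusted matrices
    in published practice, so it is explicit configuration here.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    vcf_path: str | None = None
    phenotype_path: str | None = None
    phenotype_column_map: dict = field(default_factory=dict)
    traits: list[str] | None = None
    max_missing: float = 0.5
    min_maf: float = 0.05
    min_mean_depth: float = 1.0
    min_hwdiseq: float = -0.05
    grm_snp_sets: dict = field(default_factory=lambda: {"vanraden": "unfiltered", "kgd": "filtered"})
    methods: tuple[str, ...] = ("gblup", "kgd-gblup", "bayescpi")
    cv_folds: int = 10
    cv_randomizations: int = 5
    bayescpi: PredictionModelSpec | None = None
    derive: bool = True

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        fields = dataclasses.asdict(self)
        fields.pop("out_dir", None)  # the hash identifies the analysis, not its location
        payload = json.dumps(fields, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if raw.get("bayescpi"):
            raw["bayescpi"] = PredictionModelSpec(**raw["bayescpi"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: RunConfig
    filter_report: pd.DataFrame
    grms: dict[str, RelationshipMatrix]
    fits: dict
    heritability: pd.DataFrame
    blups: pd.DataFrame
    phenotypic_correlations: pd.DataFrame | None
    cv_reports: dict
    out_dir: Path


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int, **to_csv_kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", **to_csv_kw)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute simulate/load -> QC -> GRMs -> stage-1 LMM -> stage-2 CV."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.digest()
    stage = "input"
    try:
        if config.simulation is not None:
            founders = simulate_population_set(config.simulation)
            reads = simulate_gbs_reads(founders)
            pheno = simulate_trial(founders)
            rio.write_vcf_reads(reads, out / "genotypes.vcf")
            rio.write_trial_table(pheno, out / "phenotypes.tsv")
        else:
            if not config.vcf_path or not config.phenotype_path:
                raise FileNotFoundError(
                    "run needs either a simulation config or vcf_path + phenotype_path"
                )
            reads = rio.read_vcf_reads(config.vcf_path)
            pheno = rio.read_trial_table(config.phenotype_path, config.phenotype_column_map or None)
        if config.derive:
            pheno = rio.derive_traits(pheno)
        traits = config.traits or [
            c
            for c in pheno.columns
            if c not in ("family", "population", "location", "replicate", "row", "column", "tetany_risk")
        ]
        logger.info("[%s] %d families, %d SNPs, traits: %s", stage, pheno["family"].nunique(),
                    reads.n_snps, traits)

        stage = "snp_qc"
        stats = compute_snp_stats(reads)
        filtered, report = filter_snps(
            reads, stats, config.max_missing, config.min_maf, config.min_mean_depth, config.min_hwdiseq
        )
        _write(report.to_frame(), out / "filter_report.tsv", cfg_hash, config.seed, index=False)
        rio.write_vcf_reads(filtered, out / "genotypes_filtered.vcf")

        stage = "grm"
        snp_sets = {"filtered": filtered, "unfiltered": reads}
        grms: dict[str, RelationshipMatrix] = {}
        grms["vanraden"] = vanraden_grm(
            mean_impute(calls_to_dosages(snp_sets[config.grm_snp_sets.get("vanraden", "unfiltered")]))
        )
        grms["kgd"] = kgd_grm(snp_sets[config.grm_snp_sets.get("kgd", "filtered")])
        for name, g in grms.items():
            rio.write_relationship_matrix(g.filled(0.0) if name == "kgd" else g, out / f"grm_{name}.tsv")

        stage = "stage1_lmm"
        fits, herit_rows, blup_cols = {}, [], {}
        s = pheno["location"].nunique()
        b = pheno["replicate"].nunique()
        for trait in traits:
            fit = reml_fit(pheno, model2_spec(trait))
            fits[trait] = fit
            R = repeatability(fit, s, b)
            h2g, _ = genomic_heritability(pheno, grms["kgd"].filled(0.0), trait)
            herit_rows.append((trait, R.value, h2g.value,
                               float(fit.components["family"]),
                               float(fit.components.get("family_location", 0.0)),
                               float(fit.components["residual"])))
            blup_cols[trait] = extract_blups(fit)
        heritability = pd.DataFrame(
            herit_rows, columns=["trait", "repeatability", "h2_genomic", "sigma2_g", "sigma2_gl", "sigma2_e"]
        )
        blups = pd.DataFrame(blup_cols)
        _write(heritability, out / "heritability.tsv", cfg_hash, config.seed, index=False)
        _write(blups, out / "family_blups.tsv", cfg_hash, config.seed, index_label="family")

        stage = "correlations"
        pheno_corr = phenotypic_correlation(blups) if len(traits) > 1 else None
        if pheno_corr is not None:
            _write(pheno_corr, out / "phenotypic_correlations.tsv", cfg_hash, config.seed)

        stage = "stage2_cv"
        dosage_imputed = mean_impute(
            calls_to_dosages(snp_sets[config.grm_snp_sets.get("vanraden", "unfiltered")])
        )
        cv_reports: dict = {}
        rows = []
        for trait in traits:
            y = blups[trait]
            for method in config.methods:
                if method == "gblup":
                    pred = gblup_predictor(grms["vanraden"])
                elif method == "kgd-gblup":
                    pred = gblup_predictor(grms["kgd"].filled(0.0), method="kgd-gblup")
                elif method == "bayescpi":
                    pred = bayescpi_predictor(dosage_imputed, config.bayescpi)
                else:
                    raise ValueError(f"unknown prediction method '{method}'")
                rep = kfold_cv(y, pred, k=config.cv_folds,
                               n_randomizations=config.cv_randomizations, seed=config.seed)
                cv_reports[(trait, method)] = rep
                rows.append(rep.summary())
        cv_summary = pd.DataFrame(rows)
        _write(cv_summary, out / "cv_summary.tsv", cfg_hash, config.seed, index=False)

        logger.info("pipeline finished in %.1f s", time.time() - t0)
        return PipelineResult(config, report.to_frame(), grms, fits, heritability, blups,
                              pheno_corr, cv_reports, out)
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage '{stage}' (artifacts so far are in {out}): {err}"
        ) from err
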