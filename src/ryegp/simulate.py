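"""Synthetic half-sib breeding-trial generator.

Emulates the data-generating process behind a multi-population forage
genomic-selection trial:

1. Five advanced breeding populations of roughly 102-117 maternal parents each
   (517 families total by default).  Populations share ancestral allele
   frequencies perturbed by drift (Balding-Nichols model), so the panel shows
   reproducible multi-population structure.
2. Each maternal parent founds one half-sib family via a polycross.  The family
   genetic effect is half the maternal breeding value plus an independent
   deviation for the pollen pool and Mendelian sampling, so marker-based
   prediction from maternal genotypes is informative but imperfect.
3. Genotyping-by-sequencing read counts at low coverage: depth is
   zero-inflated (a missing-call probability plus a zero-truncated Poisson for
   covered cells), and reads are drawn binomially from the true allele ratio,
   so a heterozygote at depth d is observed homozygous with probability
   2^(1-d).
4. A balanced 2-location x 3-replicate row-column trial with family,
   family-by-location, replicate, row, column and residual variance
   components.

Everything is deterministic under ``SimulationConfig.seed``; each stage draws
from its own child stream of the seed so that, e.g., re-running the trial
stage does not consume genotype randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import ReadMatrix

__all__ = [
    "TraitModel",
    "SimulationConfig",
    "FounderSet",
    "simulate_population_set",
    "simulate_gbs_reads",
    "simulate_trial",
    "default_config",
]

#: Across-location variance components used as the default simulated trait.
#: They correspond to a strongly heritable mineral trait (family-mean
#: repeatability 0.75 at 2 locations x 3 replicates); units are squared trait
#: units (% of DM squared, scaled by 1e-3).
SODIUM_LIKE = dict(sigma2_g=2.32e-3, sigma2_gs=0.25e-3, sigma2_e=3.93e-3)


@dataclass
class TraitModel:
    """Variance components and mean for one simulated trait.

    ``sigma2_g`` is the *family* variance (the variance of half-sib family
    effects, not of individual breeding values), ``sigma2_gs`` the
    family-by-location interaction, ``sigma2_b``/``sigma2_r``/``sigma2_c`` the
    replicate, row and column variances and ``sigma2_e`` the plot residual.
    """

    sigma2_g: float
    sigma2_gs: float
    sigma2_e: float
    sigma2_b: float = 0.0
    sigma2_r: float = 0.0
    sigma2_c: float = 0.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_gs", "sigma2_e", "sigma2_b", "sigma2_r", "sigma2_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name} must be >= 0")


@dataclass
class SimulationConfig:
    n_populations: int = 5
    families_per_population: int | Sequence[int] = (102, 104, 117, 110, 84)
    n_snps: int = 3000
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.05
    ancestral_pool_size: int | None = 20
    n_locations: int = 2
    n_replicates: int = 3
    traits: Mapping[str, TraitModel] = field(default_factory=lambda: {"Na": TraitModel(**SODIUM_LIKE)})
    trait_correlation: np.ndarray | None = None
    n_qtl: int = 300
    effect_distribution: str = "normal"  # "normal" | "point_mass"
    pi_zero: float = 0.9  # proportion of zero-effect markers under "point_mass"
    mean_depth: float = 2.98
    missing_rate: float = 0.23
    n_rows: int | None = None
    n_cols: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if np.isscalar(self.families_per_population):
            self.families_per_population = (int(self.families_per_population),) * self.n_populations
        else:
            self.families_per_population = tuple(int(x) for x in self.families_per_population)
        if len(self.families_per_population) != self.n_populations:
            raise ValueError("families_per_population length must equal n_populations")
        if any(f < 1 for f in self.families_per_population):
            raise ValueError("families_per_population entries must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.ancestral_pool_size is not None and self.ancestral_pool_size < 2:
            raise ValueError("ancestral_pool_size must be >= 2 (or None for unrelated founders)")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1 (mean of the covered-cell depth)")
        if self.n_locations < 1 or self.n_replicates < 1:
            raise ValueError("n_locations and n_replicates must be >= 1")
        if self.effect_distribution not in ("normal", "point_mass"):
            raise ValueError("effect_distribution must be 'normal' or 'point_mass'")
        if not 0 <= self.pi_zero < 1:
            raise ValueError("pi_zero must lie in [0, 1)")
        self.n_qtl = min(int(self.n_qtl), self.n_snps)
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")
        if self.trait_correlation is not None:
            R = np.asarray(self.trait_correlation, float)
            t = len(self.traits)
            if R.shape != (t, t):
                raise ValueError("trait_correlation must be square over the traits")
            self.trait_correlation = R

    @property
    def n_families(self) -> int:
        return int(sum(self.families_per_population))

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)


@dataclass
class FounderSet:
    """Maternal parents of the half-sib families, with simulation truth."""

    individuals: list[str]
    populations: list[str]
    genotypes: np.ndarray  # (n_parents, n_snps) dosages in {0,1,2}
    snps: pd.DataFrame
    breeding_values: pd.DataFrame  # parent x trait, centered per population
    marker_effects: pd.DataFrame  # snp x trait causal effects (mostly zero rows)
    config: SimulationConfig

    @property
    def n_parents(self) -> int:
        return len(self.individuals)


def default_config(**overrides) -> SimulationConfig:
    """The study-scale default configuration, with keyword overrides."""
    return SimulationConfig(**overrides)


def _stream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _trait_chol(config: SimulationConfig) -> np.ndarray:
    t = len(config.traits)
    if config.trait_correlation is None:
        return np.eye(t)
    return np.linalg.cholesky(config.trait_correlation + 1e-12 * np.eye(t))


def simulate_population_set(config: SimulationConfig) -> FounderSet:
    """Draw founder populations and per-trait breeding values.

    Ancestral alternate-allele frequencies are uniform over ``maf_range``
    (randomly folded about 0.5), then perturbed per population with a
    Balding-Nichols Beta draw at drift level ``fst``.  Maternal breeding
    values are causal-marker scores scaled so their variance is 2 sigma2_g:
    the half passed to a family (1/2 x maternal BV) then has variance
    sigma2_g / 2, one half of the configured family variance.
    """
    rng_freq = _stream(config.seed, 0)
    rng_geno = _stream(config.seed, 1)
    rng_eff = _stream(config.seed, 2)

    m = config.n_snps
    maf = rng_freq.uniform(*config.maf_range, size=m)
    flip = rng_freq.random(m) < 0.5
    p_anc = np.where(flip, 1.0 - maf, maf)

    fst = config.fst
    pop_names = [f"Pop{i + 1}" for i in range(config.n_populations)]
    individuals: list[str] = []
    populations: list[str] = []
    geno_blocks = []
    for pop, n_fam in zip(pop_names, config.families_per_population):
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_pop = np.clip(rng_freq.beta(a, b), 1e-6, 1 - 1e-6)
        else:
            p_pop = p_anc
        if config.ancestral_pool_size is None:
            g = rng_geno.binomial(2, p_pop, size=(n_fam, m))
        else:
            # advanced breeding populations are closed and inter-related:
            # parents are crosses among a finite ancestral pool, which creates
            # the within-population relatedness genomic prediction feeds on
            pool = rng_geno.binomial(2, p_pop, size=(config.ancestral_pool_size, m))
            ma = rng_geno.integers(config.ancestral_pool_size, size=n_fam)
            pa = rng_geno.integers(config.ancestral_pool_size, size=n_fam)
            clash = ma == pa
            while clash.any():  # no selfing
                pa[clash] = rng_geno.integers(config.ancestral_pool_size, size=int(clash.sum()))
                clash = ma == pa
            g = rng_geno.binomial(1, pool[ma] / 2.0) + rng_geno.binomial(1, pool[pa] / 2.0)
        geno_blocks.append(g)
        individuals.extend(f"{pop}_F{j + 1:03d}" for j in range(n_fam))
        populations.extend([pop] * n_fam)
    genotypes = np.vstack(geno_blocks)

    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "C",
        }
    )
    snps.index = [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(snps.chrom, snps.pos, snps.ref, snps.alt)]

    traits = config.trait_names
    qtl_idx = np.sort(rng_eff.choice(m, size=config.n_qtl, replace=False))
    L = _trait_chol(config)
    raw = rng_eff.standard_normal((config.n_qtl, len(traits))) @ L.T
    if config.effect_distribution == "point_mass":
        zero = rng_eff.random(config.n_qtl) < config.pi_zero
        raw[zero] = 0.0

    effects = np.zeros((m, len(traits)))
    bv = np.zeros((len(individuals), len(traits)))
    pop_arr = np.asarray(populations)
    for t, trait in enumerate(traits):
        target = 2.0 * config.traits[trait].sigma2_g  # maternal BV variance
        alpha = np.zeros(m)
        alpha[qtl_idx] = raw[:, t]
        score = genotypes @ alpha
        # center per population, then rescale to the target variance
        centered = score.copy()
        for pop in pop_names:
            mask = pop_arr == pop
            centered[mask] -= centered[mask].mean()
        sd = centered.std()
        if target > 0 and sd > 0:
            scale = math.sqrt(target) / sd
        else:
            scale = 0.0
        effects[:, t] = alpha * scale
        bv[:, t] = centered * scale

    return FounderSet(
        individuals=individuals,
        populations=populations,
        genotypes=genotypes,
        snps=snps,
        breeding_values=pd.DataFrame(bv, index=individuals, columns=traits),
        marker_effects=pd.DataFrame(effects, index=snps.index, columns=traits),
        config=config,
    )


def _ztp_lambda(mean_depth: float) -> float:
    """Rate of the zero-truncated Poisson with the given mean (>= 1)."""
    if mean_depth <= 1.0 + 1e-9:
        return 0.0
    f = lambda lam: lam / (1.0 - math.exp(-lam)) - mean_depth
    return brentq(f, 1e-9, max(10.0, 3 * mean_depth))


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson by rejection (redraw zeros until none remain)."""
    if lam == 0.0:
        return np.ones(size, dtype=np.int16)
    out = rng.poisson(lam, size=size)
    zeros = np.flatnonzero(out == 0)
    while zeros.size:
        redraw = rng.poisson(lam, size=zeros.size)
        out[zeros] = redraw
        zeros = zeros[redraw == 0]
    return out.astype(np.int16)


def simulate_gbs_reads(
    founders: FounderSet,
    mean_depth: float | None = None,
    missing_rate: float | None = None,
    seed: int | None = None,
) -> ReadMatrix:
    """GBS-like allele read counts for the maternal parents.

    Depth is zero-inflated: with probability ``missing_rate`` a cell has zero
    reads; otherwise depth follows a zero-truncated Poisson whose mean is
    ``mean_depth`` (so the printed mean-depth and missingness statistics are
    matched simultaneously).  Alternate reads are Binomial(depth, dosage/2).
    """
    cfg = founders.config
    mean_depth = cfg.mean_depth if mean_depth is None else mean_depth
    missing_rate = cfg.missing_rate if missing_rate is None else missing_rate
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = _stream(cfg.seed if seed is None else seed, 3)

    n, m = founders.genotypes.shape
    lam = _ztp_lambda(mean_depth)
    covered = rng.random((n, m)) >= missing_rate
    depth = np.zeros((n, m), dtype=np.int16)
    k = int(covered.sum())
    depth[covered] = _sample_ztp(rng, lam, k)
    alt = rng.binomial(depth.astype(np.int64), founders.genotypes / 2.0).astype(np.int16)
    ref = (depth - alt).astype(np.int16)
    return ReadMatrix(
        individuals=list(founders.individuals),
        snps=founders.snps.copy(),
        ref_counts=ref,
        alt_counts=alt,
    )


def _grid(n_fam: int, n_rows: int | None, n_cols: int | None) -> tuple[int, int]:
    if n_rows is None and n_cols is None:
        n_rows = int(math.ceil(math.sqrt(n_fam)))
        n_cols = int(math.ceil(n_fam / n_rows))
    elif n_rows is None:
        n_rows = int(math.ceil(n_fam / n_cols))
    elif n_cols is None:
        n_cols = int(math.ceil(n_fam / n_rows))
    if n_rows * n_cols < n_fam:
        raise ValueError(
            f"replicate grid {n_rows}x{n_cols} cannot hold {n_fam} families per block"
        )
    return n_rows, n_cols


def simulate_trial(founders: FounderSet, config: SimulationConfig | None = None) -> pd.DataFrame:
    """Simulate the balanced multi-location row-column trial.

    Each plot value is grand mean + location effect + population effect +
    family effect + family-by-location effect + replicate + row + column +
    residual, with the family effect split as 1/2 x maternal breeding value
    plus an independent N(0, sigma2_g/2) pollen-pool/Mendelian deviation.
    Every family appears once per replicate per location.
    """
    cfg = founders.config if config is None else config
    rng = _stream(cfg.seed, 4)
    traits = cfg.trait_names
    L = _trait_chol(cfg)
    pop_names = sorted(set(founders.populations))
    locations = [f"Loc{i + 1}" for i in range(cfg.n_locations)]
    fam_ids = founders.individuals
    pop_of = dict(zip(fam_ids, founders.populations))

    # fixed effects: location and population offsets, scaled to half the
    # phenotypic SD of each trait (zero when all variances are zero)
    sd_p = np.array(
        [
            math.sqrt(
                cfg.traits[t].sigma2_g
                + cfg.traits[t].sigma2_gs
                + cfg.traits[t].sigma2_b
                + cfg.traits[t].sigma2_r
                + cfg.traits[t].sigma2_c
                + cfg.traits[t].sigma2_e
            )
            for t in traits
        ]
    )
    loc_eff = {
        loc: rng.standard_normal(len(traits)) * 0.5 * sd_p for loc in locations
    }
    pop_eff = {pop: rng.standard_normal(len(traits)) * 0.5 * sd_p for pop in pop_names}

    sg = np.array([cfg.traits[t].sigma2_g for t in traits])
    sgs = np.array([cfg.traits[t].sigma2_gs for t in traits])
    sb = np.array([cfg.traits[t].sigma2_b for t in traits])
    sr = np.array([cfg.traits[t].sigma2_r for t in traits])
    sc = np.array([cfg.traits[t].sigma2_c for t in traits])
    se = np.array([cfg.traits[t].sigma2_e for t in traits])
    means = np.array([cfg.traits[t].mean for t in traits])

    # family effect = 1/2 maternal BV + correlated deviation with var sigma2_g/2
    dev = (rng.standard_normal((len(fam_ids), len(traits))) @ L.T) * np.sqrt(sg / 2.0)
    fam_eff = pd.DataFrame(
        0.5 * founders.breeding_values.loc[fam_ids, traits].to_numpy() + dev,
        index=fam_ids,
        columns=traits,
    )
    gs_eff = {
        loc: pd.DataFrame(
            (rng.standard_normal((len(fam_ids), len(traits))) @ L.T) * np.sqrt(sgs),
            index=fam_ids,
            columns=traits,
        )
        for loc in locations
    }

    records = []
    values = []
    for loc in locations:
        for pop in pop_names:
            fams = [f for f in fam_ids if pop_of[f] == pop]
            n_rows, n_cols = _grid(len(fams), cfg.n_rows, cfg.n_cols)
            for rep in range(1, cfg.n_replicates + 1):
                rep_eff = rng.standard_normal(len(traits)) * np.sqrt(sb)
                row_eff = rng.standard_normal((n_rows, len(traits))) * np.sqrt(sr)
                col_eff = rng.standard_normal((n_cols, len(traits))) * np.sqrt(sc)
                order = rng.permutation(len(fams))
                for cell, fi in enumerate(order):
                    fam = fams[fi]
                    r, c = divmod(cell, n_cols)
                    resid = rng.standard_normal(len(traits)) * np.sqrt(se)
                    y = (
                        means
                        + loc_eff[loc]
                        + pop_eff[pop]
                        + fam_eff.loc[fam].to_numpy()
                        + gs_eff[loc].loc[fam].to_numpy()
                        + rep_eff
                        + row_eff[r]
                        + col_eff[c]
                        + resid
                    )
                    records.append((fam, pop, loc, rep, r + 1, c + 1))
                    values.append(y)

    table = pd.DataFrame(
        records, columns=["family", "population", "location", "replicate", "row", "column"]
    )
    table[traits] = np.asarray(values)
    return table
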