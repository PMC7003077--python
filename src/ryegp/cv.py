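"""Cross-validation schemes for predictive ability.

Predictive ability is the Pearson correlation between observed adjusted means
(family BLUPs) and GEBVs in held-out families.  Four schemes are provided:

* k-fold (default 10-fold, 5 randomizations; held-out predictions are pooled
  within a randomization so each randomization yields one correlation, and
  the mean over randomizations is the reported predictive ability);
* Monte-Carlo (default 80/20 random splits, 500 iterations);
* within-population (half of every population trains a joint model; ability
  is scored on the held-out half of each focal population);
* a marker-density ladder (random marker subsets, GRM rebuilt per subset,
  Monte-Carlo CV per rung).

A *predictor* here is any callable ``predictor(train_blups, predict_ids)``
returning a Series of GEBVs; see :func:`gblup_predictor` and
:func:`bayescpi_predictor`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .containers import DosageMatrix, ReadMatrix, RelationshipMatrix
from .grm import vanraden_grm
from .prediction import GEBVTable, PredictionModelSpec, bayes_c_pi_predict, gblup_predict, prediction_bias
from .qc import calls_to_dosages, mean_impute

__all__ = [
    "CVReport",
    "gblup_predictor",
    "bayescpi_predictor",
    "kfold_cv",
    "monte_carlo_cv",
    "within_population_cv",
    "marker_density_ladder",
    "marker_subset_size",
    "DEFAULT_LADDER_FRACTIONS",
]

Predictor = Callable[[pd.Series, list], pd.Series]


def marker_subset_size(fraction: float, n_snps: int) -> int:
    """Markers in a ladder rung: floor(fraction x total), e.g. 1% of
    1,093,464 SNPs is 10,934 markers."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    n = int(fraction * n_snps)
    if n < 1:
        raise ValueError(f"fraction {fraction} of {n_snps} markers yields zero markers")
    return n

#: Ten rungs from 100% down to 0.1% of markers, including the quoted interior
#: points 5%, 1%, 0.5% and 0.1%.
DEFAULT_LADDER_FRACTIONS = (1.0, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005, 0.002, 0.001)


@dataclass
class CVReport:
    scheme: str
    trait: str
    method: str
    iterations: pd.DataFrame  # columns: iteration, r, slope
    seed: int
    partitions: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.iterations["r"].mean())

    @property
    def sd(self) -> float:
        return float(self.iterations["r"].std(ddof=1)) if len(self.iterations) > 1 else 0.0

    def summary(self) -> pd.Series:
        return pd.Series(
            dict(scheme=self.scheme, trait=self.trait, method=self.method,
                 n_iterations=len(self.iterations), mean_r=self.mean, sd_r=self.sd,
                 mean_slope=float(self.iterations["slope"].mean()), seed=self.seed,
                 **self.extra)
        )


def gblup_predictor(grm: RelationshipMatrix, method: str | None = None) -> Predictor:
    """Predictor closure over a relationship matrix (GBLUP / KGD-GBLUP)."""

    def _predict(train_blups: pd.Series, predict_ids: list) -> pd.Series:
        return gblup_predict(train_blups, grm, list(predict_ids), method=method).gebv

    _predict.method = method or ("kgd-gblup" if grm.method == "kgd" else "gblup")  # type: ignore[attr-defined]
    return _predict


def bayescpi_predictor(dosages: DosageMatrix, spec: PredictionModelSpec | None = None) -> Predictor:
    """Predictor closure running the BayesC-pi sampler on marker dosages."""
    base = spec or PredictionModelSpec(method="bayescpi")

    def _predict(train_blups: pd.Series, predict_ids: list) -> pd.Series:
        return bayes_c_pi_predict(train_blups, dosages, list(predict_ids), base).gebv

    _predict.method = "bayescpi"  # type: ignore[attr-defined]
    return _predict


def _method_of(predictor: Predictor) -> str:
    return getattr(predictor, "method", "custom")


def _corr_and_slope(obs: pd.Series, pred: pd.Series) -> tuple[float, float]:
    """Predictive ability r and the calibration slope (observed on GEBV)."""
    x = obs.to_numpy(dtype=float)
    yv = pred.loc[obs.index].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(yv) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, yv)[0, 1])
    slope = float(np.cov(x, yv, ddof=1)[0, 1] / np.var(yv, ddof=1))
    return r, slope


def kfold_cv(
    blups: pd.Series,
    predictor: Predictor,
    k: int = 10,
    n_randomizations: int = 5,
    seed: int = 0,
) -> CVReport:
    """k-fold CV repeated over fresh randomizations of the family set.

    Held-out predictions are pooled across the k folds of one randomization
    before correlating, giving one predictive ability per randomization.
    """
    ids = np.array([str(i) for i in blups.index])
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of families ({n})")
    rows, partitions = [], []
    for rep in range(n_randomizations):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        pred = pd.Series(np.nan, index=ids)
        folds = []
        for train_idx, test_idx in kf.split(ids):
            tr, te = ids[train_idx], ids[test_idx]
            out = predictor(blups.loc[tr], list(te))
            pred.loc[te] = out.loc[te].to_numpy(dtype=float)
            folds.append(list(te))
        # each randomization must cover every family exactly once
        assert not pred.isna().any()
        r, slope = _corr_and_slope(blups.loc[ids], pred)
        rows.append((rep, r, slope))
        partitions.append(folds)
    report = pd.DataFrame(rows, columns=["iteration", "r", "slope"])
    return CVReport("kfold", str(blups.name or "trait"), _method_of(predictor),
                    report, seed, partitions, extra=dict(k=k))


def monte_carlo_cv(
    blups: pd.Series,
    predictor: Predictor,
    train_fraction: float = 0.8,
    n_iterations: int = 500,
    seed: int = 0,
) -> CVReport:
    """Repeated random train/test splits; one correlation per split."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    ids = np.array([str(i) for i in blups.index])
    n = len(ids)
    n_train = int(round(train_fraction * n))
    if n - n_train < 3:
        raise ValueError("test set would have fewer than 3 families")
    rng = np.random.default_rng(seed)
    rows, partitions = [], []
    for it in range(n_iterations):
        perm = rng.permutation(n)
        tr, te = ids[perm[:n_train]], ids[perm[n_train:]]
        out = predictor(blups.loc[tr], list(te))
        r, slope = _corr_and_slope(blups.loc[te], out)
        rows.append((it, r, slope))
        partitions.append(dict(train=list(tr), test=list(te)))
    report = pd.DataFrame(rows, columns=["iteration", "r", "slope"])
    return CVReport("montecarlo", str(blups.name or "trait"), _method_of(predictor),
                    report, seed, partitions, extra=dict(train_fraction=train_fraction))


def within_population_cv(
    blups: pd.Series,
    populations: Mapping[str, str] | pd.Series,
    predictor: Predictor,
    n_iterations: int = 500,
    seed: int = 0,
) -> dict[str, CVReport]:
    """Balanced multi-population training; scored per focal population.

    Each iteration draws floor(n_p / 2) training families from *every*
    population (so each is represented equally), trains one model on the
    union, and computes the correlation on the held-out half of each focal
    population in turn.
    """
    pops = pd.Series(populations).astype(str)
    pops.index = pops.index.astype(str)
    ids = np.array([str(i) for i in blups.index])
    missing = [i for i in ids if i not in pops.index]
    if missing:
        raise KeyError(f"population label missing for families: {missing[:5]}")
    by_pop = {p: ids[pops.loc[ids].to_numpy() == p] for p in pops.loc[ids].unique()}
    for p, members in by_pop.items():
        if len(members) < 2:
            raise ValueError(f"population '{p}' has fewer than 2 families")
    rng = np.random.default_rng(seed)
    rows: dict[str, list] = {p: [] for p in by_pop}
    for it in range(n_iterations):
        train, held = [], {}
        for p, members in by_pop.items():
            perm = rng.permutation(len(members))
            n_tr = len(members) // 2
            train.extend(members[perm[:n_tr]])
            held[p] = members[perm[n_tr:]]
        test_all = [i for h in held.values() for i in h]
        out = predictor(blups.loc[train], test_all)
        for p, te in held.items():
            r, slope = _corr_and_slope(blups.loc[te], out)
            rows[p].append((it, r, slope))
    return {
        p: CVReport("within_population", str(blups.name or "trait"), _method_of(predictor),
                    pd.DataFrame(rows[p], columns=["iteration", "r", "slope"]), seed,
                    extra=dict(population=p, n_train_total=sum(len(m) // 2 for m in by_pop.values())))
        for p in by_pop
    }


def marker_density_ladder(
    blups: pd.Series,
    markers: DosageMatrix | ReadMatrix,
    fractions: Sequence[float] = DEFAULT_LADDER_FRACTIONS,
    n_iterations: int = 500,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> dict[float, CVReport]:
    """Predictive ability versus marker density.

    For each fraction, markers are sampled uniformly without replacement, a
    VanRaden GRM is rebuilt from the subset (allele frequencies re-estimated
    on the subset) and Monte-Carlo CV is run.  Reads are converted to naive
    calls and mean-imputed first.
    """
    if isinstance(markers, ReadMatrix):
        markers = mean_impute(calls_to_dosages(markers))
    rng = np.random.default_rng(seed)
    m = markers.n_snps
    reports: dict[float, CVReport] = {}
    for step, frac in enumerate(fractions):
        n_mark = marker_subset_size(frac, m)
        idx = np.sort(rng.choice(m, size=n_mark, replace=False))
        sub = DosageMatrix(
            individuals=list(markers.individuals),
            snp_ids=[markers.snp_ids[i] for i in idx],
            values=markers.values[:, idx],
        )
        grm = vanraden_grm(sub)
        rep = monte_carlo_cv(blups, gblup_predictor(grm), train_fraction,
                             n_iterations, seed=seed + 1000 * (step + 1))
        rep.scheme = "marker_ladder"
        rep.extra.update(fraction=frac, n_markers=n_mark)
        reports[frac] = rep
    return reports
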