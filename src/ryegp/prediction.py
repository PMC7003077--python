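"""Stage-two genomic prediction from family adjusted means.

``gblup_predict`` solves the mixed model y = 1 mu + u + e with
u ~ N(0, sigma2_u G) on the training families and propagates predictions to
unphenotyped families through their rows of G; with a VanRaden G this is
exactly ridge regression on centered marker dosages.  The variance ratio is
re-estimated by REML inside every training set unless fixed explicitly.

``bayes_c_pi_predict`` is a Gibbs sampler for the point-mass mixture model:
each marker has probability (1 - pi) of a nonzero effect, nonzero effects
share one variance, and pi itself carries a uniform prior.  GEBVs are the
posterior mean of the marker score after burn-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DosageMatrix, RelationshipMatrix
from .lmm import ModelSpec, RandomTerm, reml_fit

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionModelSpec",
    "GEBVTable",
    "gblup_predict",
    "bayes_c_pi_predict",
    "prediction_bias",
]


@dataclass
class PredictionModelSpec:
    method: str = "gblup"  # gblup | kgd-gblup | bayescpi
    iterations: int = 10_000
    burn_in: int = 2_000
    thinning: int = 1
    seed: int = 0
    # scaled-inverse-chi2 hyperparameters (weakly informative defaults)
    nu_effect: float = 4.0
    nu_residual: float = 4.0
    # diagnostics/testing hooks: hold parameters fixed instead of sampling
    fix_pi: float | None = None
    fix_effect_variance: float | None = None
    fix_residual_variance: float | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class GEBVTable:
    """GEBVs per family for one trait/method, with posterior SD for MCMC."""

    table: pd.DataFrame  # index family; columns gebv, sd (sd NaN for REML methods)
    method: str
    trait: str
    seed: int | None = None
    marker_stats: pd.DataFrame | None = None  # MCMC: posterior inclusion prob and mean effect per marker

    @property
    def gebv(self) -> pd.Series:
        return self.table["gebv"]


def _variance_ratio_reml(y: pd.Series, G_train: np.ndarray) -> tuple[float, float]:
    """REML estimates of (sigma2_u, sigma2_e) for y = mu + u + e, u~N(0, s2u G)."""
    ids = list(y.index.astype(str))
    data = pd.DataFrame({"family": ids, "y": y.to_numpy(dtype=float)})
    grm = RelationshipMatrix(ids, G_train, "supplied")
    spec = ModelSpec("y", [], [RandomTerm("family", ("family",), grm)])
    fit = reml_fit(data, spec)
    return float(fit.components["family"]), float(fit.components["residual"])


def gblup_predict(
    train_blups: pd.Series,
    grm: RelationshipMatrix,
    predict_ids: list[str] | None = None,
    var_components: tuple[float, float] | None = None,
    method: str | None = None,
) -> GEBVTable:
    """GBLUP GEBVs for ``predict_ids`` from training adjusted means.

    ``train_blups`` is a Series keyed by family.  The variance components are
    estimated by REML on the training records unless supplied.  Predictions
    are on the centered scale (a family unrelated to every training family
    gets GEBV 0).
    """
    train_ids = [str(i) for i in train_blups.index]
    if predict_ids is None:
        predict_ids = list(grm.individuals)
    predict_ids = [str(i) for i in predict_ids]
    if grm.missing_pairs.any():
        logger.warning("relationship matrix has flagged missing pairs; zero-filling")
        grm = grm.filled(0.0)
    all_ids = train_ids + [i for i in predict_ids if i not in set(train_ids)]
    G = grm.align(all_ids)
    nt = len(train_ids)
    G_tt = G[:nt, :nt]

    y = train_blups.to_numpy(dtype=float)
    if var_components is None:
        s2u, s2e = _variance_ratio_reml(train_blups, G_tt)
    else:
        s2u, s2e = var_components
    if s2u <= 0:
        logger.warning("zero genetic variance in training set; all GEBVs are 0")
        gebv_all = np.zeros(len(all_ids))
    else:
        V = s2u * G_tt + s2e * np.eye(nt)
        ones = np.ones(nt)
        Vi = np.linalg.solve(V, np.column_stack([y, ones]))
        mu = float(ones @ Vi[:, 0]) / float(ones @ Vi[:, 1])
        alpha = np.linalg.solve(V, y - mu * ones)
        gebv_all = s2u * (G[:, :nt] @ alpha)

    out = pd.Series(gebv_all, index=all_ids).loc[predict_ids]
    table = pd.DataFrame({"gebv": out, "sd": np.nan})
    name = method or ("kgd-gblup" if grm.method == "kgd" else "gblup")
    return GEBVTable(table, name, trait=str(train_blups.name or "trait"))


def bayes_c_pi_predict(
    train_blups: pd.Series,
    dosages: DosageMatrix,
    predict_ids: list[str] | None = None,
    spec: PredictionModelSpec | None = None,
) -> GEBVTable:
    """BayesC-pi Gibbs sampler; GEBV = posterior mean marker score.

    Markers enter centered by their allele frequency.  The chain samples the
    per-marker inclusion indicators, a shared effect variance, the zero-effect
    proportion pi (uniform prior), the intercept and the residual variance.
    """
    spec = spec or PredictionModelSpec(method="bayescpi")
    rng = np.random.default_rng(spec.seed)
    train_ids = [str(i) for i in train_blups.index]
    if predict_ids is None:
        predict_ids = list(dosages.individuals)
    predict_ids = [str(i) for i in predict_ids]

    pos = {ind: i for i, ind in enumerate(dosages.individuals)}
    missing = [i for i in train_ids + predict_ids if i not in pos]
    if missing:
        raise KeyError(f"identifiers absent from dosage matrix: {missing[:5]}")
    if not np.isfinite(dosages.values).all():
        raise ValueError("dosage matrix contains missing values; mean-impute first")

    W_all = dosages.values - 2.0 * dosages.p
    W = W_all[[pos[i] for i in train_ids]]
    Wp = W_all[[pos[i] for i in predict_ids]]
    y = train_blups.to_numpy(dtype=float)
    n, m = W.shape
    csq = np.einsum("ij,ij->j", W, W)
    active = csq > 1e-12  # monomorphic-in-training markers never enter

    vy = float(np.var(y))
    if vy <= 0:
        vy = 1.0
    # weakly informative scales: half the phenotypic variance to markers
    mean2pq = max(float(np.mean(csq) / max(n, 1)), 1e-8)
    S_alpha = 0.5 * vy / (mean2pq * max(m, 1) * 0.5)
    S_e = 0.5 * vy

    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=bool)
    mu = float(np.mean(y))
    s2a = spec.fix_effect_variance if spec.fix_effect_variance is not None else S_alpha
    s2e = spec.fix_residual_variance if spec.fix_residual_variance is not None else max(vy, 1e-12)
    pi = spec.fix_pi if spec.fix_pi is not None else 0.5
    e = y - mu

    n_keep = 0
    gebv_sum = np.zeros(len(predict_ids))
    gebv_sq = np.zeros(len(predict_ids))
    incl_sum = np.zeros(m)
    alpha_sum = np.zeros(m)
    for it in range(spec.iterations):
        # intercept
        mu_new = rng.normal(mu + e.mean(), np.sqrt(s2e / n))
        e += mu - mu_new
        mu = mu_new
        # marker effects with inclusion indicators
        lam = s2e / s2a
        order = np.flatnonzero(active)
        for k in order:
            wk = W[:, k]
            if delta[k]:
                e += wk * alpha[k]
            u = float(wk @ e)
            v = csq[k] + lam
            log_bf = 0.5 * np.log(lam / v) + u * u / (2.0 * s2e * v)
            log_odds = np.log((1.0 - pi) / max(pi, 1e-300)) + log_bf
            p_in = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
            if rng.random() < p_in:
                a = rng.normal(u / v, np.sqrt(s2e / v))
                alpha[k] = a
                delta[k] = True
                e -= wk * a
            else:
                alpha[k] = 0.0
                delta[k] = False
        m_in = int(delta.sum())
        # shared effect variance (scaled-inverse-chi2)
        if spec.fix_effect_variance is None:
            df_a = spec.nu_effect + m_in
            scale_a = (float(alpha @ alpha) + spec.nu_effect * S_alpha) / df_a
            s2a = df_a * scale_a / rng.chisquare(df_a)
        # residual variance
        if spec.fix_residual_variance is None:
            df_e = spec.nu_residual + n
            scale_e = (float(e @ e) + spec.nu_residual * S_e) / df_e
            s2e = df_e * scale_e / rng.chisquare(df_e)
        # pi with uniform prior: Beta(m - m_in + 1, m_in + 1)
        if spec.fix_pi is None:
            pi = rng.beta(m - m_in + 1, m_in + 1)
        if not (np.isfinite(s2a) and np.isfinite(s2e) and np.isfinite(alpha).all()):
            raise RuntimeError(f"BayesC-pi chain diverged at iteration {it}")
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
            g = Wp @ alpha
            gebv_sum += g
            gebv_sq += g * g
            incl_sum += delta
            alpha_sum += alpha
            n_keep += 1

    gebv = gebv_sum / n_keep
    sd = np.sqrt(np.maximum(gebv_sq / n_keep - gebv**2, 0.0))
    table = pd.DataFrame({"gebv": gebv, "sd": sd}, index=predict_ids)
    marker_stats = pd.DataFrame(
        {"inclusion_prob": incl_sum / n_keep, "mean_effect": alpha_sum / n_keep},
        index=dosages.snp_ids,
    )
    return GEBVTable(table, "bayescpi", trait=str(train_blups.name or "trait"),
                     seed=spec.seed, marker_stats=marker_stats)


def prediction_bias(
    gebv: GEBVTable | pd.Series,
    observed: pd.Series,
    direction: str = "obs_on_gebv",
) -> float:
    """OLS bias slope between GEBVs and observed adjusted means.

    The default regresses observed adjusted means on GEBVs: for a
    well-calibrated predictor E[obs | GEBV] = GEBV, so the expected slope is
    1; slopes above 1 indicate over-shrunken (under-dispersed) GEBVs.  The
    reversed direction ("gebv_on_obs", GEBVs on observed) is also available;
    its slope equals cov/var(obs) and is the squared accuracy under
    calibration, so it is not expected to be 1 except for perfect
    predictions.
    """
    g = gebv.gebv if isinstance(gebv, GEBVTable) else gebv
    common = g.index.intersection(observed.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired values for the bias slope")
    obs = observed.loc[common].to_numpy(dtype=float)
    pred = g.loc[common].to_numpy(dtype=float)
    if direction == "obs_on_gebv":
        x, yv = pred, obs
    elif direction == "gebv_on_obs":
        x, yv = obs, pred
    else:
        raise ValueError("direction must be 'obs_on_gebv' or 'gebv_on_obs'")
    vx = np.var(x, ddof=1)
    if vx <= 0:
        raise ValueError("regressor has zero variance; slope undefined")
    return float(np.cov(yv, x, ddof=1)[0, 1] / vx)
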