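"""REML mixed models for multi-location half-sib trials.

The three standard analyses are:

* Model 1 (single location): family + replicate + row + column random,
  population fixed.
* Model 2 (across locations): family + family-by-location + replicate + row +
  column random, location and population fixed.
* Model 3 (single population, across locations): as Model 2 without the
  population fixed effect.

Variance components are estimated by average-information (AI) REML with an EM
fallback whenever the AI step would leave the parameter space or decrease the
restricted likelihood.  Convergence is declared when the largest relative
component change drops below ``tol`` (default 1e-8); negative updates are
truncated at 1e-10 x the phenotypic variance, i.e. effectively at the zero
boundary.  The family random term accepts a genomic relationship matrix as
its covariance, which turns the family-variance ratio into a genomic
heritability.

Family-mean heritability (repeatability R, narrow-sense h2_n, or genomic h2_g
depending on which family variance is plugged in) is

    h2 = sigma2_g / (sigma2_g + sigma2_gs / s + sigma2_e / (s b))

with s locations and b replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2, norm

from .containers import RelationshipMatrix, validate_trial_table

logger = logging.getLogger(__name__)

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "LMMFit",
    "HeritabilityEstimate",
    "model1_spec",
    "model2_spec",
    "model3_spec",
    "reml_fit",
    "variance_significance",
    "heritability_from_components",
    "genomic_heritability",
    "extract_blups",
]


@dataclass
class RandomTerm:
    """One random term: a grouping key (possibly an interaction of columns)
    plus an optional covariance among the levels of ``columns[0]``."""

    name: str
    columns: tuple[str, ...]
    covariance: RelationshipMatrix | None = None


@dataclass
class ModelSpec:
    response: str
    fixed: list[str] = field(default_factory=list)
    random: list[RandomTerm] = field(default_factory=list)

    def without(self, term_name: str) -> "ModelSpec":
        kept = [t for t in self.random if t.name != term_name]
        if len(kept) == len(self.random):
            raise KeyError(f"random term '{term_name}' not in model")
        return ModelSpec(self.response, list(self.fixed), kept)


def model1_spec(trait: str, family_covariance: RelationshipMatrix | None = None) -> ModelSpec:
    """Single-location model: family, replicate, row, column random; population fixed."""
    return ModelSpec(
        response=trait,
        fixed=["population"],
        random=[
            RandomTerm("family", ("family",), family_covariance),
            RandomTerm("replicate", ("population", "replicate")),
            RandomTerm("row", ("population", "replicate", "row")),
            RandomTerm("column", ("population", "replicate", "column")),
        ],
    )


def model2_spec(trait: str, family_covariance: RelationshipMatrix | None = None) -> ModelSpec:
    """Across-location model with family-by-location interaction."""
    return ModelSpec(
        response=trait,
        fixed=["location", "population"],
        random=[
            RandomTerm("family", ("family",), family_covariance),
            RandomTerm("family_location", ("family", "location")),
            RandomTerm("replicate", ("location", "population", "replicate")),
            RandomTerm("row", ("location", "population", "replicate", "row")),
            RandomTerm("column", ("location", "population", "replicate", "column")),
        ],
    )


def model3_spec(trait: str, family_covariance: RelationshipMatrix | None = None) -> ModelSpec:
    """Within-population, across-location model (no population fixed effect)."""
    spec = model2_spec(trait, family_covariance)
    spec.fixed = ["location"]
    spec.random = [
        RandomTerm("family", ("family",), family_covariance),
        RandomTerm("family_location", ("family", "location")),
        RandomTerm("replicate", ("location", "replicate")),
        RandomTerm("row", ("location", "replicate", "row")),
        RandomTerm("column", ("location", "replicate", "column")),
    ]
    return spec


@dataclass
class LMMFit:
    components: pd.Series  # term name -> variance estimate (includes "residual")
    se: pd.Series
    loglik: float
    blups: dict[str, pd.Series]  # term name -> BLUPs keyed by level label
    fixed_effects: pd.Series
    converged: bool
    n_iter: int
    spec: ModelSpec
    n_obs: int
    iteration_trace: list[dict] = field(default_factory=list)
    _data: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def intercept(self) -> float:
        return float(self.fixed_effects.get("intercept", 0.0))

    def wald_z(self) -> pd.Series:
        """Wald z statistics (estimate / SE) for comparison with +-SE tables."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.components / self.se


@dataclass
class HeritabilityEstimate:
    kind: str  # "repeatability" | "narrow_sense" | "genomic"
    value: float
    s: int
    b: int
    components: dict[str, float]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[dict]):
        super().__init__(message)
        self.trace = trace


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Build response, fixed design X and random designs (Z_i, K_i, labels)."""
    df = data.loc[data[spec.response].notna()].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"no non-missing observations for response '{spec.response}'")
    y = df[spec.response].to_numpy(dtype=float)
    n = len(df)

    cols = [np.ones(n)]
    names = ["intercept"]
    for f in spec.fixed:
        if f not in df.columns:
            raise ValueError(f"fixed factor '{f}' not in the trial table")
        levels = pd.unique(df[f])
        if len(levels) < 2:
            continue  # single-level factor carries no contrast
        for lev in levels[1:]:
            cols.append((df[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular fixed-effect design over columns {spec.fixed}")

    terms = []
    for term in spec.random:
        for c in term.columns:
            if c not in df.columns:
                raise ValueError(f"random term '{term.name}' references missing column '{c}'")
        if len(term.columns) == 1:
            key = df[term.columns[0]].astype(str)
        else:
            key = df[list(term.columns)].astype(str).agg(":".join, axis=1)
        codes, labels = pd.factorize(key, sort=True)
        q = len(labels)
        Z = np.zeros((n, q))
        Z[np.arange(n), codes] = 1.0
        K = None
        if term.covariance is not None:
            if len(term.columns) != 1:
                raise ValueError(
                    f"covariance on interaction term '{term.name}' is not supported"
                )
            K = term.covariance.align(list(labels))
            # estimated relationship matrices (e.g. depth-adjusted kinship) can
            # be indefinite; bend by clipping eigenvalues so V stays PD
            w, U = np.linalg.eigh(K)
            if w.min() < 1e-8:
                logger.info(
                    "bending covariance of term '%s': min eigenvalue %.2e clipped",
                    term.name, w.min(),
                )
                K = (U * np.maximum(w, 1e-8)) @ U.T
        terms.append((term.name, Z, K, list(labels)))
    return df, y, X, names, terms


def reml_fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    verbose: bool = False,
) -> LMMFit:
    """Average-information REML with EM fallback.

    Returns the converged variance components, their AI-based standard
    errors, the restricted log-likelihood, BLUPs of every random term and the
    fixed-effect estimates.  Raises :class:`ConvergenceError` (carrying the
    iteration trace) if ``max_iter`` is exhausted.
    """
    df, y, X, fixed_names, terms = _design(data, spec)
    n, p = X.shape
    k = len(terms)
    vp = float(np.var(y))
    bound = 1e-10 * max(vp, 1e-300)

    names = [t[0] for t in terms] + ["residual"]
    if vp <= 1e-300:
        # constant response: every component at the zero boundary
        zero = pd.Series(0.0, index=names)
        blups = {t[0]: pd.Series(0.0, index=t[3]) for t in terms}
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return LMMFit(zero, zero.copy(), 0.0, blups, pd.Series(beta, index=fixed_names),
                      True, 0, spec, n, [], df)

    # covariance-weighted cross products M_i = Z K Z'
    Ms = []
    for _, Z, K, _ in terms:
        Ms.append(Z @ Z.T if K is None else Z @ K @ Z.T)

    sigma = np.full(k + 1, vp / (k + 1))
    trace: list[dict] = []
    prev_ll = -np.inf

    def _evaluate(sig):
        V = sig[k] * np.eye(n)
        for i in range(k):
            V += sig[i] * Ms[i]
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        ViX = Vinv @ X
        XtViX = X.T @ ViX
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        B = np.linalg.inv(XtViX)
        Py = Vinv @ y - ViX @ (B @ (ViX.T @ y))
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return dict(Vinv=Vinv, ViX=ViX, B=B, Py=Py, ll=ll)

    state = _evaluate(sigma)
    if state is None:
        raise ConvergenceError("initial covariance matrix is not positive definite", trace)

    converged = False
    it = 0
    AI = None
    pinned = np.zeros(k + 1, dtype=bool)  # components held at the zero boundary
    for it in range(1, max_iter + 1):
        Vinv, ViX, B, Py = state["Vinv"], state["ViX"], state["B"], state["Py"]
        # gradients; traces go through the thin Z_i factors, never full n x n
        # products per term: tr(V^-1 Z K Z') = sum((Z' V^-1 Z) o K)
        grad = np.empty(k + 1)
        ws = []
        for i in range(k):
            _, Z, K, _ = terms[i]
            ZtPy = Z.T @ Py
            ZtViZ = Z.T @ (Vinv @ Z)
            ZtViX = Z.T @ ViX
            if K is None:
                tr_vm = float(np.trace(ZtViZ))
                tr_qm = float(np.sum((ZtViX @ B) * ZtViX))
                w = Z @ ZtPy
            else:
                tr_vm = float(np.sum(ZtViZ * K))
                tr_qm = float(np.sum((ZtViX @ B) * (K @ ZtViX)))
                w = Z @ (K @ ZtPy)
            ws.append(w)
            grad[i] = -0.5 * ((tr_vm - tr_qm) - float(Py @ w))
        tr_p = np.trace(Vinv) - float(np.sum((ViX @ B) * ViX))
        ws.append(Py)
        grad[k] = -0.5 * (tr_p - float(Py @ Py))

        # average information matrix
        Wm = np.column_stack(ws)
        PW = Vinv @ Wm - ViX @ (B @ (ViX.T @ Wm))
        AI = 0.5 * (Wm.T @ PW)

        # active set: a component sitting at the zero boundary whose gradient
        # points further down is pinned there (residual never pins)
        at_bound = sigma <= bound * 10.0
        pinned = at_bound & (grad < 0)
        pinned[k] = False
        free = ~pinned
        sigma = np.where(pinned, bound, sigma)

        step_kind = "ai"
        new_sigma = None
        new_state = None
        try:
            delta = np.linalg.solve(AI[np.ix_(free, free)], grad[free])
            cand = sigma.copy()
            cand[free] = sigma[free] + delta
            # step-halve an AI proposal that leaves the space or drops loglik
            for _ in range(8):
                trial = np.maximum(cand, bound)
                st = _evaluate(trial)
                if st is not None and st["ll"] >= state["ll"] - 1e-8 * (1 + abs(state["ll"])):
                    new_sigma, new_state = trial, st
                    break
                cand = sigma + (cand - sigma) / 2.0
        except np.linalg.LinAlgError:
            pass

        if new_sigma is None:
            step_kind = "em"
            qs = np.array([t[1].shape[1] for t in terms] + [n], dtype=float)
            em = sigma.copy()
            for i in np.flatnonzero(free):
                w = ws[i]
                tr_pm = grad[i] * (-2.0) + float(Py @ w)  # recover tr(P M_i)
                em[i] = sigma[i] + (sigma[i] ** 2 / qs[i]) * (float(Py @ w) - tr_pm)
            new_sigma = np.maximum(em, bound)
            st = _evaluate(new_sigma)
            if st is None:
                raise ConvergenceError("EM update produced a singular covariance", trace)
            new_state = st

        moved = free & (np.maximum(np.abs(sigma), np.abs(new_sigma)) > bound * 10.0)
        if moved.any():
            rel = np.max(
                np.abs(new_sigma[moved] - sigma[moved])
                / np.maximum(np.abs(sigma[moved]), vp * 1e-6)
            )
        else:
            rel = 0.0
        trace.append(dict(iteration=it, step=step_kind, loglik=new_state["ll"],
                          components=dict(zip(names, new_sigma))))
        if verbose:
            logger.info("iter %d (%s): ll=%.6f rel=%.2e", it, step_kind, new_state["ll"], rel)
        sigma, state = new_sigma, new_state
        if rel < tol and abs(state["ll"] - prev_ll) < 1e-8 * (1 + abs(state["ll"])):
            converged = True
            break
        prev_ll = state["ll"]

    if not converged:
        raise ConvergenceError(f"REML did not converge in {max_iter} iterations", trace)

    # standard errors from the inverse average information at the optimum
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k + 1, np.nan)

    Vinv, ViX, B, Py = state["Vinv"], state["ViX"], state["B"], state["Py"]
    beta = B @ (ViX.T @ y)
    blups: dict[str, pd.Series] = {}
    for i, (name, Z, K, labels) in enumerate(terms):
        u = Z.T @ Py
        u = sigma[i] * (u if K is None else K @ u)
        blups[name] = pd.Series(u, index=labels)

    comp = pd.Series(np.where(sigma <= bound * 1.001, 0.0, sigma), index=names)
    return LMMFit(
        components=comp,
        se=pd.Series(se, index=names),
        loglik=float(state["ll"]),
        blups=blups,
        fixed_effects=pd.Series(beta, index=fixed_names),
        converged=True,
        n_iter=it,
        spec=spec,
        n_obs=n,
        iteration_trace=trace,
        _data=df,
    )


def variance_significance(fit: LMMFit, term: str) -> dict:
    """Likelihood-ratio test of one variance component at the zero boundary.

    The null distribution is the 1/2 chi2_0 + 1/2 chi2_1 mixture, so
    p = 0.5 * P(chi2_1 >= LR) for LR > 0 and p = 0.5 at LR = 0.  A Wald z
    p-value from the AI standard error is reported alongside.
    """
    if fit._data is None:
        raise ValueError("fit does not carry its data; refit with reml_fit")
    reduced = reml_fit(fit._data, fit.spec.without(term))
    lr = max(0.0, 2.0 * (fit.loglik - reduced.loglik))
    p_mix = 0.5 * chi2.sf(lr, 1) if lr > 0 else 0.5
    est, se = fit.components[term], fit.se[term]
    p_wald = float(norm.sf(est / se)) if se > 0 else np.nan
    return dict(term=term, lr_statistic=lr, p_value=float(p_mix), p_wald=p_wald,
                loglik_full=fit.loglik, loglik_reduced=reduced.loglik)


def heritability_from_components(
    sigma2_g: float,
    sigma2_gs: float,
    sigma2_e: float,
    s: int,
    b: int,
    kind: str = "repeatability",
) -> HeritabilityEstimate:
    """Family-mean heritability h2 = s2g / (s2g + s2gs/s + s2e/(s*b))."""
    if s < 1 or b < 1:
        raise ValueError("s and b must be >= 1")
    if min(sigma2_g, sigma2_gs, sigma2_e) < 0:
        raise ValueError("variance components must be >= 0")
    denom = sigma2_g + sigma2_gs / s + sigma2_e / (s * b)
    if denom <= 0:
        raise ValueError("zero phenotypic variance of a family mean")
    return HeritabilityEstimate(
        kind=kind,
        value=sigma2_g / denom,
        s=s,
        b=b,
        components=dict(sigma2_g=sigma2_g, sigma2_gs=sigma2_gs, sigma2_e=sigma2_e),
    )


def repeatability(fit: LMMFit, s: int | None = None, b: int | None = None) -> HeritabilityEstimate:
    """Repeatability from an identity-covariance Model 2 fit."""
    if s is None:
        s = fit._data["location"].nunique() if fit._data is not None else 2
    if b is None:
        b = fit._data["replicate"].nunique() if fit._data is not None else 3
    gs = float(fit.components.get("family_location", 0.0))
    return heritability_from_components(
        float(fit.components["family"]), gs, float(fit.components["residual"]), s, b
    )


def genomic_heritability(
    data: pd.DataFrame,
    grm: RelationshipMatrix,
    trait: str,
    spec: ModelSpec | None = None,
) -> tuple[HeritabilityEstimate, LMMFit]:
    """Across-location genomic heritability: Model 2 with family ~ N(0, G s2g).

    The family-by-location covariance stays identity.  Returns the estimate
    and the underlying fit.
    """
    validate_trial_table(data, [trait])
    if spec is None:
        spec = model2_spec(trait, family_covariance=grm)
    else:
        spec = ModelSpec(spec.response, list(spec.fixed), [
            RandomTerm(t.name, t.columns, grm if t.name == "family" else t.covariance)
            for t in spec.random
        ])
    fams = set(data["family"].astype(str))
    missing = fams - set(grm.individuals)
    if missing:
        raise KeyError(f"families absent from the relationship matrix: {sorted(missing)[:5]}")
    fit = reml_fit(data, spec)
    s = data["location"].nunique()
    b = data["replicate"].nunique()
    gs = float(fit.components.get("family_location", 0.0))
    est = heritability_from_components(
        float(fit.components["family"]), gs, float(fit.components["residual"]), s, b,
        kind="genomic",
    )
    return est, fit


def extract_blups(fit: LMMFit, term: str = "family", add_intercept: bool = True) -> pd.Series:
    """Adjusted means: BLUPs of one random term, optionally plus the grand mean.

    These are the stage-one outputs of the two-stage genomic-selection
    workflow (one adjusted mean per family).
    """
    if term not in fit.blups:
        raise KeyError(f"random term '{term}' not in fit (has {list(fit.blups)})")
    u = fit.blups[term].copy()
    if add_intercept:
        u = u + fit.intercept
    u.name = fit.spec.response
    return u
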