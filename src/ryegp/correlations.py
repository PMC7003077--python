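"""Genotypic and phenotypic correlations between traits.

The genotypic correlation uses family-level (co)variance components from the
across-location mixed model.  Rather than a literal MANOVA
sums-of-cross-products decomposition, the genetic covariance is obtained from
the sum-trait identity

    Cov_g(x, y) = [ s2g(x + y) - s2g(x) - s2g(y) ] / 2,

fitting the same model to x, y and x + y.  On balanced designs this equals
the MANOVA cross-product estimate (the equivalence is covered by a test),
and it remains well-defined under mild imbalance.  The phenotypic
correlation is simply the Pearson correlation of family BLUPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import validate_trial_table
from .lmm import LMMFit, ModelSpec, model2_spec, reml_fit

__all__ = ["GeneticCorrelation", "genotypic_correlation", "phenotypic_correlation"]


@dataclass
class GeneticCorrelation:
    trait_x: str
    trait_y: str
    cov_g: float
    var_x: float
    var_y: float
    r_g: float  # NaN when either family variance is non-positive
    fits: dict[str, LMMFit] | None = None


def genotypic_correlation(
    data: pd.DataFrame,
    trait_x: str,
    trait_y: str,
    spec_builder=model2_spec,
) -> GeneticCorrelation:
    """Family-level genetic correlation between two traits.

    Both traits must be observed on the same plots.  ``spec_builder`` maps a
    trait name to a :class:`ModelSpec` (the across-location model by
    default).  |r_g| is clamped to 1 with a warning if the component
    estimates push it marginally outside.
    """
    validate_trial_table(data, [trait_x, trait_y])
    both = data[[trait_x, trait_y]].notna().all(axis=1)
    df = data.loc[both].copy()
    sum_col = f"__sum_{trait_x}_{trait_y}"
    df[sum_col] = df[trait_x] + df[trait_y]

    fits = {}
    s2 = {}
    for trait in (trait_x, trait_y, sum_col):
        fit = reml_fit(df, spec_builder(trait))
        fits[trait] = fit
        s2[trait] = float(fit.components["family"])
    cov_g = (s2[sum_col] - s2[trait_x] - s2[trait_y]) / 2.0

    if s2[trait_x] <= 0 or s2[trait_y] <= 0:
        warnings.warn(
            f"non-positive family variance for '{trait_x}' or '{trait_y}'; r_g undefined",
            stacklevel=2,
        )
        r_g = np.nan
    else:
        r_g = cov_g / np.sqrt(s2[trait_x] * s2[trait_y])
        if abs(r_g) > 1.0:
            if abs(r_g) > 1.0 + 1e-6:
                warnings.warn(f"r_g({trait_x},{trait_y}) = {r_g:.3f} clamped to +-1", stacklevel=2)
            r_g = float(np.clip(r_g, -1.0, 1.0))
    return GeneticCorrelation(trait_x, trait_y, cov_g, s2[trait_x], s2[trait_y], float(r_g), fits)


def phenotypic_correlation(blups: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of family BLUPs (one column per trait).

    Constant columns yield NaN entries with a warning rather than an error.
    """
    if len(blups) < 3:
        raise ValueError("need at least 3 families for a phenotypic correlation")
    constant = [c for c in blups.columns if np.nanstd(blups[c].to_numpy(dtype=float)) == 0]
    if constant:
        warnings.warn(f"constant BLUP columns give undefined correlations: {constant}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return blups.corr(method="pearson")
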