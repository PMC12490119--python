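"""Family-clustered generalized estimating equations.

All burden, adjusted-odds, and probability models in this package are
marginal regressions fit by GEE with the family as the cluster, an
exchangeable working correlation by default, and robust (sandwich)
standard errors. Siblings share environment and half their genome, so
observations within a family are positively correlated; GEE keeps the
marginal interpretation of the coefficients while making the inference
robust to that correlation and to working-correlation misspecification.

The estimating equations are solved by statsmodels; this module defines
the modelling contracts (formulas, families, contrasts, reporting) used
throughout the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotype_stats import ORResult

logger = logging.getLogger(__name__)

_FAMILIES = {
    "poisson_log": sm.families.Poisson,
    "binomial_logit": sm.families.Binomial,
}
_CORR = {
    "independence": sm.cov_struct.Independence,
    "exchangeable": sm.cov_struct.Exchangeable,
}

#: absolute coefficient size on the linear-predictor scale treated as
#: evidence of separation in a logistic fit
_SEPARATION_COEF = 15.0


@dataclass
class GEEFit:
    outcome: str
    covariates: list[str]
    family: str
    cluster_var: str
    working_corr: str
    coefs: pd.Series = field(default_factory=pd.Series)
    robust_se: pd.Series = field(default_factory=pd.Series)
    p_values: pd.Series = field(default_factory=pd.Series)
    conf_int: pd.DataFrame = field(default_factory=pd.DataFrame)
    naive_se: pd.Series = field(default_factory=pd.Series)
    n_clusters: int = 0
    n_obs: int = 0
    converged: bool = False
    result: object | None = None  # underlying statsmodels results

    def coef(self, term: str) -> float:
        return float(self.coefs[self._match(term)])

    def se(self, term: str) -> float:
        return float(self.robust_se[self._match(term)])

    def p(self, term: str) -> float:
        return float(self.p_values[self._match(term)])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.conf_int.loc[self._match(term)]
        return float(row[0]), float(row[1])

    def _match(self, term: str) -> str:
        if term in self.coefs.index:
            return term
        hits = [name for name in self.coefs.index if name.startswith(term)]
        if len(hits) != 1:
            raise KeyError(f"term {term!r} not found uniquely in {list(self.coefs.index)}")
        return hits[0]


def fit_gee(
    data: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    family: str = "poisson_log",
    cluster: str = "family_id",
    working_corr: str = "exchangeable",
) -> GEEFit:
    """Fit outcome ~ covariates by GEE with cluster-robust inference.

    Count outcomes use the Poisson family with log link; binary outcomes
    the binomial family with logit link. Non-convergence yields a fit with
    ``converged=False`` and a warning; apparent separation in a logistic
    fit (a diverging coefficient) is an error naming the covariate.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if working_corr not in _CORR:
        raise ValueError(f"unknown working correlation {working_corr!r}")
    formula = f"{outcome} ~ " + (" + ".join(covariates) if covariates else "1")
    model = sm.GEE.from_formula(
        formula,
        groups=cluster,
        data=data,
        family=_FAMILIES[family](),
        cov_struct=_CORR[working_corr](),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(maxiter=200)
        for w in caught:
            if "did not converge" in str(w.message).lower() or issubclass(
                w.category, sm.tools.sm_exceptions.ConvergenceWarning
            ):
                converged = False
    if not converged:
        logger.warning("GEE fit of %s did not converge", formula)
    if family == "binomial_logit":
        big = result.params[result.params.abs() > _SEPARATION_COEF]
        big = big.drop("Intercept", errors="ignore")
        if not big.empty:
            raise ValueError(f"apparent separation on covariate {big.index[0]!r}")
    return GEEFit(
        outcome=outcome,
        covariates=list(covariates),
        family=family,
        cluster_var=cluster,
        working_corr=working_corr,
        coefs=result.params,
        robust_se=result.bse,
        p_values=result.pvalues,
        conf_int=result.conf_int(),
        naive_se=pd.Series(np.sqrt(np.diag(result.cov_naive)), index=result.params.index),
        n_clusters=int(data[cluster].nunique()),
        n_obs=int(result.nobs),
        converged=converged,
        result=result,
    )


def burden_test(
    counts: pd.DataFrame,
    group_col: str = "group",
    count_col: str = "count",
    sex_col: str = "sex",
    cluster: str = "family_id",
    working_corr: str = "exchangeable",
) -> tuple[GEEFit, float]:
    """Variant-count contrast between two groups: count ~ group + sex,
    Poisson family, family-clustered.

    Returns the fit and the rate ratio exp(group coefficient).
    """
    sizes = counts.groupby(group_col).size()
    if (sizes == 0).any() or len(sizes) < 2:
        raise ValueError(f"each group needs children; got sizes {sizes.to_dict()}")
    fit = fit_gee(counts, count_col, [group_col, sex_col], "poisson_log", cluster, working_corr)
    group_term = [t for t in fit.coefs.index if t.startswith(group_col)][0]
    return fit, float(np.exp(fit.coefs[group_term]))


def multimorbidity_burden_model(
    data: pd.DataFrame,
    count_col: str = "count",
    multimorbidity_col: str = "multimorbidity",
    sex_col: str | None = "sex",
    cluster: str = "family_id",
    interaction_outcome: str | None = None,
) -> GEEFit:
    """Association of variant burden with multimorbidity.

    Default: count ~ multimorbidity (+ sex), Poisson, family-clustered.
    With ``interaction_outcome`` (a binary column such as asd or preterm),
    fits outcome ~ multimorbidity * count by GEE logistic instead, testing
    whether burden modifies the multimorbidity association.
    """
    if interaction_outcome is None:
        covs = [multimorbidity_col] + ([sex_col] if sex_col else [])
        return fit_gee(data, count_col, covs, "poisson_log", cluster)
    covs = [f"{multimorbidity_col} * {count_col}"]
    if sex_col:
        covs.append(sex_col)
    return fit_gee(data, interaction_outcome, covs, "binomial_logit", cluster)


def adjusted_or(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: tuple[str, ...] = ("sex", "age"),
    cluster: str = "family_id",
) -> ORResult:
    """Covariate-adjusted odds ratio for one exposure by GEE logistic fit."""
    covs = [exposure] + [c for c in covariates if c in data.columns]
    fit = fit_gee(data, outcome, covs, "binomial_logit", cluster)
    term = fit._match(exposure)
    lo, hi = fit.ci(term)
    return ORResult(
        odds_ratio=float(np.exp(fit.coefs[term])),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_raw=float(fit.p_values[term]),
    )
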