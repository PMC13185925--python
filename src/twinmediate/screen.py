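"""Family-clustered association screening and multiplicity control.

Bivariate associations are estimated on z-scored variables by ordinary
least squares with a family-clustered (CR1) sandwich covariance — point
estimates equivalent to a GEE with independence working correlation,
with inference robust to the twin-within-family dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import TwinCohort


@dataclass
class AssociationResult:
    predictor: str
    outcome: str
    beta: float
    se: float
    ci: tuple[float, float]
    p: float
    n_used: int
    significant_adjusted: bool | None = None

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor, "outcome": self.outcome,
            "beta": self.beta, "se": self.se, "ci_lower": self.ci[0],
            "ci_upper": self.ci[1], "p": self.p, "n_used": self.n_used,
            "significant_adjusted": self.significant_adjusted,
        }


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Bonferroni-adjusted significance threshold ``alpha / m``.

    Returns the raw value and its 3-decimal rounding (the convention
    used when quoting the threshold, e.g. 0.05/18 -> 0.003).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive count")
    raw = alpha / m
    # half-up decimal rounding for the conventional quoted value
    from decimal import Decimal, ROUND_HALF_UP
    rounded = float(Decimal(repr(raw)).quantize(Decimal("0.001"),
                                                rounding=ROUND_HALF_UP))
    return raw, rounded


def _zscore(s: pd.Series) -> pd.Series:
    return (s - s.mean()) / s.std(ddof=1)


def cluster_robust_regression(data: pd.DataFrame | TwinCohort, outcome: str,
                              predictors, cluster: str = "family_id",
                              standardize: bool = True,
                              alpha_adjusted: float | None = None):
    """OLS of ``outcome`` on ``predictors`` with family-clustered errors.

    Variables are z-scored beforehand so coefficients are standardized
    betas.  Returns one :class:`AssociationResult` per predictor (a
    single result if one predictor is given).
    """
    df = data.data if isinstance(data, TwinCohort) else data
    predictors = [predictors] if isinstance(predictors, str) else list(predictors)
    cols = [outcome, *predictors, cluster]
    sub = df[cols].dropna()
    if sub[cluster].nunique() < 2:
        raise ValueError("need at least two clusters (families)")
    ymat = sub[outcome].astype(float)
    xmat = sub[predictors].astype(float)
    for c in predictors:
        if xmat[c].std(ddof=1) == 0:
            raise ValueError(f"predictor {c!r} is constant")
    if standardize:
        ymat = _zscore(ymat)
        xmat = xmat.apply(_zscore)
    model = sm.OLS(ymat, sm.add_constant(xmat))
    res = model.fit(cov_type="cluster", cov_kwds={"groups": sub[cluster]})
    out = []
    ci = res.conf_int()
    for c in predictors:
        r = AssociationResult(
            predictor=c, outcome=outcome, beta=float(res.params[c]),
            se=float(res.bse[c]), ci=(float(ci.loc[c, 0]), float(ci.loc[c, 1])),
            p=float(res.pvalues[c]), n_used=int(res.nobs),
        )
        if alpha_adjusted is not None:
            r.significant_adjusted = r.p < alpha_adjusted
        out.append(r)
    return out[0] if len(out) == 1 else out


def moderation_test(data: pd.DataFrame | TwinCohort, outcome: str,
                    predictor: str, moderator: str,
                    cluster: str = "family_id") -> AssociationResult:
    """Interaction test: outcome ~ predictor * binary moderator.

    The moderator must be binary with both levels present; the returned
    result is the interaction coefficient with clustered inference.
    """
    df = data.data if isinstance(data, TwinCohort) else data
    sub = df[[outcome, predictor, moderator, cluster]].dropna()
    levels = sorted(sub[moderator].unique())
    if len(levels) != 2:
        raise ValueError(
            f"moderator {moderator!r} must be binary with both levels present "
            f"(found {levels})")
    x = _zscore(sub[predictor].astype(float))
    mod = (sub[moderator] == levels[1]).astype(float)
    design = pd.DataFrame({
        predictor: x, moderator: mod, "interaction": x * mod,
    })
    res = sm.OLS(_zscore(sub[outcome].astype(float)),
                 sm.add_constant(design)).fit(
        cov_type="cluster", cov_kwds={"groups": sub[cluster]})
    ci = res.conf_int().loc["interaction"]
    return AssociationResult(
        predictor=f"{predictor}x{moderator}", outcome=outcome,
        beta=float(res.params["interaction"]), se=float(res.bse["interaction"]),
        ci=(float(ci[0]), float(ci[1])), p=float(res.pvalues["interaction"]),
        n_used=int(res.nobs),
    )


def median_split(values) -> tuple[pd.Series, dict[str, int]]:
    """Dichotomize at the median: strictly above -> 'high', else 'low'.

    Ties at the median all fall in the low group; counts are reported
    as observed.  Missing values yield missing labels.
    """
    s = pd.Series(values).astype(float)
    nonmiss = s.dropna()
    if len(nonmiss) < 2:
        raise ValueError("need at least two non-missing values")
    if nonmiss.nunique() == 1:
        raise ValueError("all values identical: median split is degenerate")
    med = nonmiss.median()
    labels = pd.Series(
        np.where(s.isna(), None, np.where(s > med, "high", "low")),
        index=s.index, dtype=object)
    counts = {"low": int((labels == "low").sum()),
              "high": int((labels == "high").sum())}
    return labels, counts


def pgs_validation(cohort: TwinCohort, phenotype: str,
                   pgs: str = "pgs") -> AssociationResult:
    """Standardized association of a phenotype with its polygenic score,
    with family-clustered errors (instrument validation)."""
    return cluster_robust_regression(cohort, phenotype, pgs)


def screen_mediators(cohort: TwinCohort, exposure: str, outcome: str,
                     mediators, alpha_adjusted: float) -> pd.DataFrame:
    """Per-mediator association screen against exposure and outcome.

    A mediator is retained only if it is associated with both the
    exposure and the outcome at the adjusted threshold; the returned
    table carries both betas, p-values, flags and the inclusion verdict.
    """
    rows = []
    for m in mediators:
        r_exp = cluster_robust_regression(cohort, m, exposure)
        r_out = cluster_robust_regression(cohort, outcome, m)
        sig_exp = r_exp.p < alpha_adjusted
        sig_out = r_out.p < alpha_adjusted
        rows.append({
            "mediator": m,
            "beta_exposure": r_exp.beta, "p_exposure": r_exp.p,
            "sig_exposure": sig_exp,
            "beta_outcome": r_out.beta, "p_outcome": r_out.p,
            "sig_outcome": sig_out,
            "included": bool(sig_exp and sig_out),
        })
    return pd.DataFrame(rows).set_index("mediator")
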