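"""Per-survey association engine.

Fits the screening model ``logit P(HIV=1) = alpha + beta * x`` for every
candidate variable by survey-weighted maximum likelihood (iteratively
reweighted least squares), with a cluster-robust sandwich variance at the
primary-sampling-unit level, Wald inference, and the Nagelkerke pseudo-R^2
as the explanatory-power measure.  An adjusted variant adds household
wealth (5 categories), age and rural residence as covariates.

Weights are normalised to sum to the analysed sample size, so rescaling
all weights leaves every estimate unchanged.  Fits that fail to converge
or run off to ``|beta| > 15`` are flagged as separated but retained:
extreme odds ratios are a real feature of sparse strata and are kept for
downstream pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .types import ADJUSTMENT_COLUMNS, AssociationResult, SurveyDataset

MAX_ITER = 100
SEPARATION_BETA = 15.0
_TOL = 1e-10


class NoVariationError(ValueError):
    """Outcome or design column has a single observed value."""


class RankDeficiencyError(ValueError):
    """Design matrix is not full column rank on the analysed rows."""


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    ll_null: float
    ll_full: float
    n: int
    n_eff: float
    converged: bool
    separated: bool


def fit_weighted_logistic(y: np.ndarray, design: np.ndarray,
                          weights: np.ndarray,
                          clusters: np.ndarray) -> LogisticFit:
    """Weighted logistic regression with a cluster-robust sandwich.

    Maximises the weighted log-likelihood
    ``sum_j w_j [y_j log p_j + (1-y_j) log(1-p_j)]`` by Newton/IRLS.  The
    covariance is ``A^-1 M A^-1`` where ``A`` is the weighted information
    and ``M`` sums outer products of cluster-aggregated score vectors,
    scaled by the small-sample factor ``G/(G-1)`` for ``G`` clusters.
    Also returns the weighted log-likelihood of the intercept-only model,
    for the pseudo-R^2.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    w = np.asarray(weights, dtype=float)
    n, p = X.shape
    if y.min() == y.max():
        raise NoVariationError("no outcome variation")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError("design matrix is rank deficient")
    w = w * (n / w.sum())

    beta = np.zeros(p)
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        wv = w * mu * (1.0 - mu)
        score = X.T @ (w * (y - mu))
        info = (X * wv[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + delta
        if np.max(np.abs(delta)) < 1e-8:
            converged = True
            break
    separated = (not converged) or bool(np.max(np.abs(beta)) > SEPARATION_BETA)

    mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
    ll_full = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
    pbar = float(np.sum(w * y) / np.sum(w))
    pbar = min(max(pbar, 1e-10), 1 - 1e-10)
    ll_null = float(np.sum(w) * (pbar * np.log(pbar)
                                 + (1 - pbar) * np.log(1 - pbar)))

    wv = w * mu * (1.0 - mu)
    info = (X * wv[:, None]).T @ X
    try:
        bread = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        bread = np.linalg.pinv(info)
    scores = X * (w * (y - mu))[:, None]
    codes, _ = pd.factorize(clusters)
    g = codes.max() + 1
    csum = np.zeros((g, p))
    np.add.at(csum, codes, scores)
    meat = csum.T @ csum
    if g > 1:
        meat = meat * (g / (g - 1.0))
    cov = bread @ meat @ bread
    return LogisticFit(beta=beta, cov=cov, ll_null=ll_null, ll_full=ll_full,
                       n=n, n_eff=float(w.sum()), converged=converged,
                       separated=separated)


def nagelkerke_r2(ll_null: float, ll_full: float, n_eff: float) -> float:
    """Cox-Snell R^2 rescaled by its attainable maximum, clipped to [0, 1].

    ``R2_CS = 1 - exp(2 (ll_null - ll_full) / n)`` and
    ``R2_max = 1 - exp(2 ll_null / n)``; the ratio reaches 1 for a
    perfectly predictive model and 0 when the variable adds nothing over
    the outcome prevalence.
    """
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")
    r2_cs = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n_eff)
    r2_max = 1.0 - np.exp(2.0 * ll_null / n_eff)
    if r2_max <= 0:
        return 0.0
    return float(np.clip(r2_cs / r2_max, 0.0, 1.0))


def _result_from_fit(fit: LogisticFit, index: int, variable: str,
                     survey: SurveyDataset) -> AssociationResult:
    beta = float(fit.beta[index])
    se = float(np.sqrt(max(fit.cov[index, index], 0.0)))
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    return AssociationResult(
        variable=variable, survey_id=survey.survey_id,
        country=survey.country, year=survey.year, sex=survey.sex,
        beta=beta, se=se, p=float(2.0 * norm.sf(abs(z))),
        r2=nagelkerke_r2(fit.ll_null, fit.ll_full, fit.n_eff),
        n=fit.n, converged=fit.converged, separated=fit.separated)


def _error_result(variable: str, survey: SurveyDataset,
                  message: str) -> AssociationResult:
    return AssociationResult(
        variable=variable, survey_id=survey.survey_id,
        country=survey.country, year=survey.year, sex=survey.sex,
        beta=np.nan, se=np.nan, p=np.nan, r2=np.nan, n=0,
        converged=False, separated=False, error=message)


def associate_univariate(survey: SurveyDataset,
                         variable: str) -> AssociationResult:
    """Screen one variable: intercept + variable, complete-case."""
    d = survey.data
    mask = d["hiv"].notna() & d[variable].notna()
    x = d.loc[mask, variable].to_numpy(dtype=float)
    y = d.loc[mask, "hiv"].to_numpy(dtype=float)
    if x.size == 0 or np.nanmin(x) == np.nanmax(x):
        return _error_result(variable, survey, "no design variation")
    X = np.column_stack([np.ones_like(x), x])
    try:
        fit = fit_weighted_logistic(
            y, X, d.loc[mask, "weight"].to_numpy(dtype=float),
            d.loc[mask, "cluster"].to_numpy())
    except (NoVariationError, RankDeficiencyError) as exc:
        return _error_result(variable, survey, str(exc))
    return _result_from_fit(fit, 1, variable, survey)


def associate_adjusted(survey: SurveyDataset,
                       variable: str) -> AssociationResult:
    """Screen one variable adjusted for wealth, age and rural residence.

    Wealth enters as 4 indicators (5 categories, lowest as reference),
    age as a continuous covariate and rural as an indicator; only the
    screened variable's coefficient is reported.
    """
    d = survey.data
    missing = [c for c in ADJUSTMENT_COLUMNS if c not in d.columns]
    if missing:
        return _error_result(variable, survey,
                             f"adjustment columns absent: {missing}")
    cols = [variable, *ADJUSTMENT_COLUMNS, "hiv"]
    mask = d[cols].notna().all(axis=1)
    sub = d.loc[mask]
    x = sub[variable].to_numpy(dtype=float)
    if x.size == 0 or x.min() == x.max():
        return _error_result(variable, survey, "no design variation")
    wealth = sub["wealth"].to_numpy(dtype=float)
    wealth_ind = [(wealth == lv).astype(float) for lv in (2.0, 3.0, 4.0, 5.0)]
    X = np.column_stack([np.ones_like(x), x, *wealth_ind,
                         sub["age"].to_numpy(dtype=float),
                         sub["rural"].to_numpy(dtype=float)])
    try:
        fit = fit_weighted_logistic(
            sub["hiv"].to_numpy(dtype=float),
            X, sub["weight"].to_numpy(dtype=float),
            sub["cluster"].to_numpy())
    except (NoVariationError, RankDeficiencyError) as exc:
        return _error_result(variable, survey, str(exc))
    return _result_from_fit(fit, 1, variable, survey)


def associate_survey(survey: SurveyDataset, mode: str = "univariate",
                     variables: Optional[Sequence[str]] = None
                     ) -> list[AssociationResult]:
    """Run the chosen screen over a survey's candidate variables."""
    if mode not in ("univariate", "adjusted"):
        raise ValueError(f"unknown mode {mode!r}")
    fn = associate_univariate if mode == "univariate" else associate_adjusted
    if variables is None:
        variables = survey.candidate_variables
    return [fn(survey, v) for v in variables]
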