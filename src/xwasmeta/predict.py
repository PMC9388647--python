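"""Country-level risk prediction and concentration of predicted risk.

Fits, per country and sex, an (unweighted) logistic model of serostatus on
the top identified variables in that country's latest survey, and scores
it in-sample with ROC-AUC, precision-recall AUC and the Gini coefficient
of the predicted-risk distribution.  A random scorer calibrates to
AUC 0.5 and PRAUC equal to the outcome prevalence, so both metrics read
as lift over prevalence-only prediction; the Gini coefficient measures
how concentrated model-predicted risk is across people (0 = evenly
spread).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assoc import NoVariationError, fit_weighted_logistic
from .types import SurveyDataset

log = logging.getLogger(__name__)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive outscores a random
    negative, with ties counted half.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = pd.Series(s).rank(method="average").to_numpy()
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def pr_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Average-precision area under the precision-recall curve.

    Step-wise summation over score thresholds (no linear interpolation
    between operating points, which is known to flatter PR curves):
    ``sum_k (R_k - R_{k-1}) P_k`` over descending unique thresholds.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_pos = float(np.sum(y == 1))
    if n_pos == 0:
        raise ValueError("at least one positive label is required")
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    s = s[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate at the last index of each tied score block
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    drecall = np.diff(np.r_[0.0, recall])
    return float(np.sum(drecall * precision))


def gini_coefficient(values: np.ndarray) -> float:
    """Gini coefficient of a nonnegative distribution (mean-difference form).

    ``G = sum_ij |p_i - p_j| / (2 n^2 pbar)``, computed from the sorted
    values in O(n log n); equivalently one minus twice the area under the
    Lorenz curve of sorted risk.
    """
    p = np.sort(np.asarray(values, dtype=float))
    n = p.size
    if n == 0 or np.any(p < 0):
        raise ValueError("values must be nonnegative and non-empty")
    total = p.sum()
    if total == 0:
        raise ValueError("values must not all be zero")
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * p) / (n * total))


def lorenz_curve(values: np.ndarray) -> pd.DataFrame:
    """Cumulative population share vs cumulative predicted-risk share."""
    p = np.sort(np.asarray(values, dtype=float))
    cum = np.cumsum(p) / p.sum()
    return pd.DataFrame({
        "population_share": np.arange(1, p.size + 1) / p.size,
        "risk_share": cum,
    })


def select_top_variables(discovery: pd.DataFrame, k: int = 10,
                         countries: Optional[Sequence[str]] = None,
                         sex: Optional[str] = None) -> list[str]:
    """Top-k identified variables assessed in every listed country.

    Ranks by mean R^2 descending with a lexicographic tie-break on the
    variable id.  When fewer than ``k`` variables qualify, all of them are
    returned with a warning.
    """
    d = discovery
    if sex is not None:
        d = d[d["sex"] == sex]
    d = d[d["identified"]]
    if countries is not None:
        d = d[d["n_countries_assessed"] >= len(set(countries))]
    ranked = d.sort_values(["mean_r2", "variable"],
                           ascending=[False, True])
    vars_ = list(dict.fromkeys(ranked["variable"]))
    if len(vars_) < k:
        warnings.warn(f"only {len(vars_)} eligible variables for the "
                      f"requested top {k}", stacklevel=2)
    return vars_[:k]


@dataclass
class PredictionReport:
    """Risk-model fit and scores for one country x sex."""

    country: str
    sex: str
    survey_id: str
    variables: list[str]
    n: int
    n_cases: int
    n_controls: int
    coefficients: np.ndarray
    probabilities: np.ndarray = field(repr=False)
    prevalence: float = np.nan
    auc: float = np.nan
    prauc: float = np.nan
    gini: float = np.nan


def latest_survey_per_country(datasets: Sequence[SurveyDataset], sex: str
                              ) -> dict[str, SurveyDataset]:
    """Most recent survey of each country for one sex (ties by survey id)."""
    chosen: dict[str, SurveyDataset] = {}
    for ds in datasets:
        if ds.sex != sex:
            continue
        cur = chosen.get(ds.country)
        if cur is None or (ds.year, ds.survey_id) > (cur.year, cur.survey_id):
            chosen[ds.country] = ds
    return chosen


def fit_risk_model(survey: SurveyDataset, variables: Sequence[str],
                   min_cases: int = 10,
                   weighted: bool = False) -> Optional[PredictionReport]:
    """Fit the country risk model and score it in-sample.

    Restricts to respondents with all ``variables`` observed (complete
    case), fits an unweighted logistic model (survey-weighted behind the
    ``weighted`` flag), and reports per-person predicted probabilities,
    AUC, PRAUC, prevalence and the Gini coefficient of predicted risk.
    Returns ``None`` (with a log entry) when fewer than ``min_cases``
    cases remain or the outcome no longer varies.
    """
    avail = [v for v in variables if v in survey.data.columns]
    if len(avail) < len(variables):
        log.warning("%s: %d of %d model variables absent", survey.survey_id,
                    len(variables) - len(avail), len(variables))
    if not avail:
        log.warning("%s: no model variables available; skipped",
                    survey.survey_id)
        return None
    d = survey.data
    mask = d["hiv"].notna() & d[list(avail)].notna().all(axis=1)
    sub = d.loc[mask]
    y = sub["hiv"].to_numpy(dtype=float)
    n_cases = int(y.sum())
    if n_cases < min_cases or n_cases == y.size:
        log.warning("%s: %d cases after complete-case restriction; skipped",
                    survey.survey_id, n_cases)
        return None
    X = np.column_stack([np.ones(len(sub)),
                         sub[list(avail)].to_numpy(dtype=float)])
    keep = [0] + [j for j in range(1, X.shape[1])
                  if np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    w = (sub["weight"].to_numpy(dtype=float) if weighted
         else np.ones(len(sub)))
    try:
        fit = fit_weighted_logistic(y, X, w, np.arange(len(sub)))
    except NoVariationError:
        log.warning("%s: no outcome variation; skipped", survey.survey_id)
        return None
    from scipy.special import expit

    prob = expit(X @ fit.beta)
    return PredictionReport(
        country=survey.country, sex=survey.sex, survey_id=survey.survey_id,
        variables=list(avail), n=int(y.size), n_cases=n_cases,
        n_controls=int(y.size - n_cases), coefficients=fit.beta,
        probabilities=prob, prevalence=float(y.mean()),
        auc=roc_auc(y, prob), prauc=pr_auc(y, prob),
        gini=gini_coefficient(prob))


def predict_all_countries(datasets: Sequence[SurveyDataset],
                          discovery: pd.DataFrame, k: int = 10,
                          weighted: bool = False,
                          lorenz_points: Optional[int] = None
                          ) -> pd.DataFrame | tuple[pd.DataFrame,
                                                    pd.DataFrame]:
    """Per-country x sex risk models from the top identified variables.

    With ``lorenz_points`` set, also returns the Lorenz curve of each
    model's predicted risk, downsampled to that many evenly spaced
    population shares.
    """
    rows = []
    lorenz_rows = []
    for sex in ("female", "male"):
        latest = latest_survey_per_country(datasets, sex)
        if not latest:
            continue
        variables = select_top_variables(discovery, k=k,
                                         countries=sorted(latest), sex=sex)
        if not variables:
            log.warning("no eligible variables for sex=%s; skipped", sex)
            continue
        for country in sorted(latest):
            rep = fit_risk_model(latest[country], variables,
                                 weighted=weighted)
            if rep is None:
                continue
            rows.append({
                "country": rep.country, "sex": rep.sex,
                "survey_id": rep.survey_id, "n": rep.n,
                "n_cases": rep.n_cases, "n_controls": rep.n_controls,
                "prevalence": rep.prevalence, "auc": rep.auc,
                "prauc": rep.prauc, "gini": rep.gini,
                "variables": ";".join(rep.variables),
            })
            if lorenz_points:
                lor = lorenz_curve(rep.probabilities)
                idx = np.unique(np.linspace(0, len(lor) - 1,
                                            lorenz_points).astype(int))
                sub = lor.iloc[idx].assign(country=rep.country, sex=rep.sex)
                lorenz_rows.append(sub)
    table = pd.DataFrame(rows, columns=[
        "country", "sex", "survey_id", "n", "n_cases", "n_controls",
        "prevalence", "auc", "prauc", "gini", "variables"])
    if lorenz_points is None:
        return table
    lorenz = (pd.concat(lorenz_rows, ignore_index=True) if lorenz_rows
              else pd.DataFrame(columns=["population_share", "risk_share",
                                         "country", "sex"]))
    return table, lorenz
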