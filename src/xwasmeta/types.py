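"""Shared containers for the survey-screening pipeline.

A *survey* is one national household-survey round for one sex
(country x year x sex).  Analyses are always sex-stratified, so a survey
dataset never mixes female and male respondents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

#: Columns with a fixed meaning in every survey file; everything else is a
#: candidate variable.
RESERVED_COLUMNS = frozenset(
    {"hiv", "weight", "cluster", "stratum", "hhid", "line",
     "wealth", "age", "rural"}
)

#: Adjustment covariates for the sensitivity (multivariate) screen.
ADJUSTMENT_COLUMNS = ("wealth", "age", "rural")


@dataclass
class SurveyDataset:
    """One survey's observations plus its value-label dictionaries.

    ``data`` holds the outcome (``hiv``, binary), sampling ``weight``
    (positive, normalised downstream), ``cluster``/``stratum`` design ids,
    merge keys (``hhid``, ``line``), the adjustment covariates
    (``wealth``, ``age``, ``rural``) and one column per candidate variable.
    ``value_labels`` maps a variable name to its ``{code: label}``
    dictionary (categorical variables only).
    """

    survey_id: str
    country: str
    year: int
    sex: str  # "female" | "male"
    data: pd.DataFrame
    value_labels: dict[str, dict[int, str]] = field(default_factory=dict)
    #: per-variable kind: "binary" | "categorical" | "continuous"
    kinds: dict[str, str] = field(default_factory=dict)
    #: per-variable (mean, sd) recorded when a continuous column is
    #: standardised, so the transform is invertible
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def candidate_variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    def copy(self) -> "SurveyDataset":
        return replace(
            self,
            data=self.data.copy(),
            value_labels={k: dict(v) for k, v in self.value_labels.items()},
            kinds=dict(self.kinds),
            scaling=dict(self.scaling),
        )


@dataclass
class AssociationResult:
    """Per (variable, survey) association estimate from the weighted screen."""

    variable: str
    survey_id: str
    country: str
    year: int
    sex: str
    beta: float
    se: float
    p: float
    r2: float  # Nagelkerke pseudo-R^2
    n: int
    converged: bool = True
    separated: bool = False
    error: Optional[str] = None

    @property
    def odds_ratio(self) -> float:
        import math

        return math.exp(self.beta)


@dataclass
class MetaResult:
    """Pooled random-effects estimate for one variable at one scope."""

    variable: str
    sex: str
    scope: str  # "pan" or a country name
    k: int
    beta: float
    se: float
    p: float
    q: float
    tau2: float
    i2: Optional[float]  # percent; None when k == 1 or Q == 0
    mean_r2: float


ASSOC_COLUMNS = [
    "variable", "survey_id", "country", "year", "sex",
    "beta", "se", "p", "r2", "n", "or", "converged", "separated",
]

META_COLUMNS = [
    "variable", "sex", "scope", "k", "beta", "se", "p", "q", "tau2",
    "i2", "mean_r2",
]


def assoc_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results, skipping errored fits."""
    rows = []
    for r in results:
        if r.error is not None:
            continue
        rows.append({
            "variable": r.variable, "survey_id": r.survey_id,
            "country": r.country, "year": r.year, "sex": r.sex,
            "beta": r.beta, "se": r.se, "p": r.p, "r2": r.r2, "n": r.n,
            "or": r.odds_ratio, "converged": r.converged,
            "separated": r.separated,
        })
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def meta_to_frame(results: list[MetaResult]) -> pd.DataFrame:
    rows = [{
        "variable": r.variable, "sex": r.sex, "scope": r.scope, "k": r.k,
        "beta": r.beta, "se": r.se, "p": r.p, "q": r.q, "tau2": r.tau2,
        "i2": r.i2, "mean_r2": r.mean_r2,
    } for r in results]
    return pd.DataFrame(rows, columns=META_COLUMNS)
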