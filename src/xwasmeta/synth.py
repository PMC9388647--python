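"""Synthetic multi-survey generator with known ground truth.

Emulates the structure of a continent-wide collection of stratified
household surveys: many surveys (country x wave x sex), cluster sampling
with right-skewed weights, a binary serostatus outcome whose prevalence
varies 1%-25% across surveys, hundreds of mixed-type candidate variables,
planted log-odds effects, duplicate/correlated variable groups, MCAR
missingness, and value-label dictionaries that can disagree between the
female and male files of the same survey.

All distributional choices are stand-ins for a survey design that is not
described generatively anywhere; they are documented in the methods note.
The generator is deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .types import SurveyDataset


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


@dataclass
class PlantedEffect:
    """A variable with a nonzero true log-odds-ratio on the outcome."""

    variable: str
    log_or_female: float
    log_or_male: float

    @classmethod
    def symmetric(cls, variable: str, log_or: float) -> "PlantedEffect":
        return cls(variable, log_or, log_or)


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic survey collection.

    Defaults describe a mid-sized continental collection: 10 countries with
    1-3 survey waves each (roughly 20 country-years, twice that in
    sex-stratified files), 4000 respondents per survey spread over 100
    sampling clusters, outcome prevalence drawn uniformly from 1%-25%.
    """

    n_countries: int = 10
    #: exact waves per country (int) or an inclusive (lo, hi) range
    waves_per_country: int | tuple[int, int] = (1, 3)
    n_per_survey: int = 4000
    prevalence_range: tuple[float, float] = (0.01, 0.25)
    n_variables: int = 500
    frac_binary: float = 0.5
    frac_categorical: float = 0.3
    frac_continuous: float = 0.2
    n_levels_range: tuple[int, int] = (3, 6)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    #: between-survey SD of each planted log-OR (0 = homogeneous truth)
    effect_heterogeneity_sd: float = 0.0
    n_duplicate_groups: int = 5
    duplicate_group_size: int = 3
    duplicate_correlation: float = 0.95
    missing_rate_range: tuple[float, float] = (0.0, 0.08)
    #: per-variable probability range of being fielded in a given country
    variable_presence_range: tuple[float, float] = (0.4, 1.0)
    n_clusters_per_survey: int = 100
    cluster_sd: float = 0.3
    weight_dispersion: float = 0.5
    label_conflict_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        fr = self.frac_binary + self.frac_categorical + self.frac_continuous
        if abs(fr - 1.0) > 1e-12:
            raise ConfigurationError(
                f"variable-kind fractions must sum to 1, got {fr!r}")
        for name in ("frac_binary", "frac_categorical", "frac_continuous",
                     "label_conflict_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("prevalence_range", "missing_rate_range",
                     "variable_presence_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(
                    f"{name} must be an ordered pair in [0, 1]")
        if self.duplicate_correlation < 0.9:
            raise ConfigurationError("duplicate_correlation must be >= 0.9")
        if self.n_per_survey < 10 * self.n_clusters_per_survey:
            raise ConfigurationError(
                "n_per_survey must be at least 10 x n_clusters_per_survey")
        if self.weight_dispersion <= 0:
            raise ConfigurationError("weight_dispersion must be positive")
        lo, hi = self._waves_range()
        if not (1 <= lo <= hi <= 3):
            raise ConfigurationError("waves_per_country must lie in 1..3")

    def _waves_range(self) -> tuple[int, int]:
        w = self.waves_per_country
        return (w, w) if isinstance(w, int) else (int(w[0]), int(w[1]))


# ----------------------------------------------------------------------
# variable schema (drawn once, shared by every survey)

@dataclass
class _VariableSpec:
    name: str
    kind: str  # binary | categorical | continuous
    prevalence: float = 0.5                    # binary marginals
    level_probs: Optional[np.ndarray] = None   # categorical marginals
    presence_prob: float = 1.0
    duplicate_of: Optional[str] = None


def _draw_schema(cfg: SyntheticConfig, rng: np.random.Generator
                 ) -> tuple[list[_VariableSpec], dict[str, np.ndarray]]:
    """Draw variable kinds, marginals, duplicate groups and country presence."""
    n = cfg.n_variables
    n_bin = int(round(cfg.frac_binary * n))
    n_cat = int(round(cfg.frac_categorical * n))
    planted = {e.variable for e in cfg.planted_effects}
    specs: list[_VariableSpec] = []
    for i in range(n):
        name = f"v{i + 1:03d}"
        kind = ("binary" if i < n_bin
                else "categorical" if i < n_bin + n_cat
                else "continuous")
        spec = _VariableSpec(name=name, kind=kind)
        if kind == "binary":
            spec.prevalence = float(rng.uniform(0.15, 0.85))
        elif kind == "categorical":
            k = int(rng.integers(cfg.n_levels_range[0],
                                 cfg.n_levels_range[1] + 1))
            spec.level_probs = rng.dirichlet(np.full(k, 2.0))
        spec.presence_prob = float(rng.uniform(*cfg.variable_presence_range))
        if name in planted:
            spec.presence_prob = 1.0  # planted variables fielded everywhere
        specs.append(spec)

    eligible = [s for s in specs if s.kind != "categorical"]
    n_groups = min(cfg.n_duplicate_groups, len(eligible))
    if n_groups:
        picks = rng.choice(len(eligible), size=n_groups, replace=False)
        for gi in picks:
            base = eligible[int(gi)]
            for j in range(1, cfg.duplicate_group_size):
                specs.append(_VariableSpec(
                    name=f"{base.name}dup{j}", kind=base.kind,
                    prevalence=base.prevalence,
                    level_probs=base.level_probs,
                    presence_prob=base.presence_prob,
                    duplicate_of=base.name))

    presence = {s.name: rng.random(cfg.n_countries) < s.presence_prob
                for s in specs if s.duplicate_of is None}
    for s in specs:
        if s.duplicate_of is not None:
            presence[s.name] = presence[s.duplicate_of]
    return specs, presence


def _value_labels_for(spec: _VariableSpec) -> Optional[dict[int, str]]:
    if spec.kind == "binary":
        return {0: "No", 1: "Yes"}
    if spec.kind == "categorical":
        return {lv: f"Level {lv}"
                for lv in range(1, len(spec.level_probs) + 1)}
    return None


def _draw_columns(specs: Sequence[_VariableSpec], n: int, target_r: float,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Person-level draws; duplicate variables are (noisy) copies of their base.

    Continuous duplicates get additive noise placed a little above the
    correlation floor (corr(x, x+e) = 1/sqrt(1+var(e)/var(x))) so sampling
    noise cannot drop the realised correlation below it; discrete duplicates
    are exact copies, which keeps their level structure intact.
    """
    cols: dict[str, np.ndarray] = {}
    for s in specs:
        if s.duplicate_of is not None:
            continue
        if s.kind == "binary":
            cols[s.name] = (rng.random(n) < s.prevalence).astype(float)
        elif s.kind == "categorical":
            k = len(s.level_probs)
            cols[s.name] = rng.choice(np.arange(1, k + 1), size=n,
                                      p=s.level_probs).astype(float)
        else:
            cols[s.name] = rng.standard_normal(n)
    r = min(0.999, target_r + 0.5 * (1.0 - target_r))
    sigma = math.sqrt(max(1.0 / (r * r) - 1.0, 0.0))
    for s in specs:
        if s.duplicate_of is None:
            continue
        base = cols[s.duplicate_of]
        if s.kind == "continuous":
            sd = float(np.std(base)) or 1.0
            cols[s.name] = base + rng.standard_normal(n) * sigma * sd
        else:
            cols[s.name] = base.copy()
    return cols


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept alpha such that mean(expit(alpha + eta)) == target."""
    return brentq(lambda a: float(np.mean(expit(a + eta))) - target,
                  -30.0, 30.0, xtol=1e-10)


def generate_multisurvey(config: SyntheticConfig
                         ) -> tuple[list[SurveyDataset], pd.DataFrame]:
    """Generate one :class:`SurveyDataset` per (country, wave, sex) plus
    a ground-truth table.

    The outcome follows a logistic model with a survey-specific intercept
    solved numerically so the linear predictor hits the drawn target
    prevalence in expectation; normal cluster intercepts (SD ``cluster_sd``
    on the logit scale) induce within-cluster correlation; weights are
    gamma-distributed (shape ``1/weight_dispersion**2``, right-skewed like
    real inverse inclusion probabilities) and normalised to sum to the
    survey size.  Male files carry an ``m``-prefixed copy of every variable
    name and value-label dictionary, mirroring the women's/men's recode
    split that harmonisation has to undo.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    schema_rng = np.random.default_rng(ss.spawn(1)[0])
    specs, presence = _draw_schema(config, schema_rng)
    spec_by_name = {s.name: s for s in specs}

    effects = {e.variable: e for e in config.planted_effects}
    unknown = set(effects) - set(spec_by_name)
    if unknown:
        raise ConfigurationError(
            f"planted effects reference unknown variables: {sorted(unknown)}")
    for v in effects:
        if spec_by_name[v].kind == "categorical":
            raise ConfigurationError(
                f"planted effect on categorical variable {v!r} is not "
                "supported; plant on a binary or continuous variable")

    waves_rng = np.random.default_rng(ss.spawn(1)[0])
    wlo, whi = config._waves_range()
    waves = waves_rng.integers(wlo, whi + 1, size=config.n_countries)

    datasets: list[SurveyDataset] = []
    for ci in range(config.n_countries):
        country = f"Country{ci + 1:02d}"
        fielded = [s for s in specs if presence[s.name][ci]]
        for wi in range(int(waves[ci])):
            year = 2003 + ci % 5 + 7 * wi
            sv_ss = ss.spawn(1)[0]
            het_rng = np.random.default_rng(sv_ss.spawn(1)[0])
            beta_sv = {v: [e.log_or_female, e.log_or_male]
                       for v, e in effects.items()}
            if config.effect_heterogeneity_sd > 0:
                for bb in beta_sv.values():
                    bb[0] += het_rng.normal(0.0, config.effect_heterogeneity_sd)
                    bb[1] += het_rng.normal(0.0, config.effect_heterogeneity_sd)
            for sex in ("female", "male"):
                rng = np.random.default_rng(sv_ss.spawn(1)[0])
                datasets.append(_make_survey(config, country, year, sex,
                                             fielded, beta_sv, rng))
    return datasets, _truth_table(specs, effects, presence)


def _make_survey(cfg: SyntheticConfig, country: str, year: int, sex: str,
                 fielded: Sequence[_VariableSpec],
                 beta_sv: dict[str, list[float]],
                 rng: np.random.Generator) -> SurveyDataset:
    n = cfg.n_per_survey
    nc = cfg.n_clusters_per_survey
    cluster = np.repeat(np.arange(nc), math.ceil(n / nc))[:n]
    stratum = (cluster < nc // 2).astype(int)
    hhid = np.arange(n) // 2 % max(n // (2 * nc), 1)
    line = np.arange(n) % 2 + 1

    cols = _draw_columns(fielded, n, cfg.duplicate_correlation, rng)
    spec_by_name = {s.name: s for s in fielded}

    b_index = 0 if sex == "female" else 1
    eta = rng.normal(0.0, cfg.cluster_sd, size=nc)[cluster]
    for v, bb in beta_sv.items():
        if v in cols:
            eta = eta + bb[b_index] * cols[v]
    target = float(rng.uniform(*cfg.prevalence_range))
    alpha = _solve_intercept(eta, target)
    y = (rng.random(n) < expit(alpha + eta)).astype(int)

    shape = 1.0 / cfg.weight_dispersion ** 2
    w = rng.gamma(shape, 1.0 / shape, size=n)
    w = w * (n / w.sum())

    frame = {
        "hiv": y, "weight": w, "cluster": cluster, "stratum": stratum,
        "hhid": hhid, "line": line,
        "wealth": rng.integers(1, 6, size=n).astype(float),
        "age": rng.integers(15, 50, size=n).astype(float),
        "rural": (rng.random(n) < 0.6).astype(float),
    }
    labels: dict[str, dict[int, str]] = {}
    kinds: dict[str, str] = {}
    prefix = "" if sex == "female" else "m"
    for spec in fielded:
        x = cols[spec.name].astype(float).copy()
        miss_rate = rng.uniform(*cfg.missing_rate_range)
        x[rng.random(n) < miss_rate] = np.nan
        name = prefix + spec.name
        frame[name] = x
        vl = _value_labels_for(spec)
        if vl is not None:
            labels[name] = vl
        kinds[name] = spec.kind
    return SurveyDataset(
        survey_id=f"{country}-{year}-{sex}", country=country, year=year,
        sex=sex, data=pd.DataFrame(frame), value_labels=labels, kinds=kinds)


def _truth_table(specs: Sequence[_VariableSpec],
                 effects: dict[str, PlantedEffect],
                 presence: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for s in specs:
        countries = [f"Country{i + 1:02d}"
                     for i in np.flatnonzero(presence[s.name])]
        for sex in ("female", "male"):
            if s.name in effects:
                e = effects[s.name]
                b = e.log_or_female if sex == "female" else e.log_or_male
                role = "effect"
            else:
                b = 0.0
                role = (f"duplicate-of:{s.duplicate_of}"
                        if s.duplicate_of else "noise")
            rows.append({"variable": s.name, "sex": sex, "true_log_or": b,
                         "role": role, "countries": ";".join(countries)})
    return pd.DataFrame(rows)


def inject_label_conflicts(datasets: list[SurveyDataset], rate: float,
                           seed: int) -> list[SurveyDataset]:
    """Relabel values in male-file dictionaries to create label conflicts.

    For a random fraction ``rate`` of labelled variables shared between a
    survey's female and male files, one value in the male dictionary gets a
    different label text for the same code (the classic ``1 = "Yes"`` vs
    ``1 = "Definitely"`` disagreement that harmonisation must resolve).
    Returns new datasets; the inputs are not modified.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("conflict rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = [ds.copy() for ds in datasets]
    females = {(ds.country, ds.year): ds for ds in out if ds.sex == "female"}
    alt = {"Yes": "Definitely", "No": "Not at all"}
    for ds in out:
        if ds.sex != "male":
            continue
        mate = females.get((ds.country, ds.year))
        if mate is None:
            continue
        for mvar in sorted(ds.value_labels):
            vl = ds.value_labels[mvar]
            fvar = mvar[1:] if mvar.startswith("m") else mvar
            if fvar not in mate.value_labels or not vl:
                continue
            if rng.random() >= rate:
                continue
            code = sorted(vl)[int(rng.integers(len(vl)))]
            old = vl[code]
            vl[code] = alt.get(old, f"{old} (alt)")
    return out
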