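"""Survey harmonisation: name mapping, label-conflict resolution, recode
merging, pruning and encoding.

The men's and women's files of a survey use systematically different
variable prefixes; ``apply_prefix_rules`` rewrites men's-file names onto
the women's-file convention, ``propose_matches`` finds near-miss matches by
Levenshtein similarity, and ``resolve_label_conflicts`` repairs value-label
dictionaries where the same stored code carries different label text in the
two files.  ``merge_recodes`` assembles the member-roster / individual /
household / test-result files of one survey with the join order and alert
thresholds used for quality control.  ``prune_variables`` and
``encode_variables`` prepare the candidate-variable matrix for screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .types import SurveyDataset


class MergeError(RuntimeError):
    """The minimum file set for merging a survey is not present."""


# ----------------------------------------------------------------------
# name mapping

#: Men's-file prefix rewrites, applied first-match-wins.  Longer, more
#: specific prefixes are ordered before the general rules they overlap
#: ("mcase" before "m", "sm6"/"sm" before the bare "s" strip), since a
#: literal top-to-bottom scan of the general rules would shadow them.
_PREFIX_RULES: list[tuple[str, str]] = [
    ("_", ""),
    ("mv304a", "v304a_"),
    ("mcase", "case"),
    ("mv", "v"),
    ("sm6", "s8"),
    ("sm", "mm"),   # falls back to "s" when no "mm" candidate exists
    ("dm", "d"),
    ("m", "v"),
    ("s", ""),
]


def apply_prefix_rules(name: str,
                       target_names: Optional[Iterable[str]] = None) -> str:
    """Rewrite a men's-file variable name onto the women's-file convention.

    The first matching prefix rule is applied and the result returned;
    names that match no rule pass through unchanged, so already-normalised
    names are left alone.  ``target_names``, when given, decides the
    ``sm -> mm`` vs ``sm -> s`` fallback: ``mm...`` is used only when such
    a candidate actually exists on the women's side.
    """
    if not name:
        raise ValueError("variable name must be non-empty")
    for prefix, repl in _PREFIX_RULES:
        if not name.startswith(prefix):
            continue
        rest = name[len(prefix):]
        if prefix == "sm" and target_names is not None:
            if "mm" + rest not in set(target_names):
                return "s" + rest
        return repl + rest
    return name


def levenshtein_similarity(a: str, b: str) -> float:
    """Normalised Levenshtein similarity ``1 - d(a, b) / max(|a|, |b|)``."""
    if not a or not b:
        raise ValueError("similarity is undefined for empty strings")
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


@dataclass
class MatchProposal:
    """Candidate variable mapping from men's-file to women's-file names."""

    accepted: dict[str, str] = field(default_factory=dict)
    #: source -> ranked [(target, similarity), ...] needing adjudication
    candidates: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)
    unmapped: set[str] = field(default_factory=set)


def propose_matches(source_vars: Sequence[str], target_vars: Sequence[str],
                    threshold: float = 0.7) -> MatchProposal:
    """Propose a mapping from source (men's) to target (women's) names.

    Each source name is first normalised by the prefix rules.  An exact
    match is auto-accepted.  Otherwise every target with similarity at or
    above ``threshold`` is listed, best first; when the best similarity is
    tied between targets the source is flagged ambiguous, and sources with
    no candidate at all are reported unmapped.  Non-exact candidates are
    never auto-accepted: resolving them needs adjudication external to this
    package.
    """
    if not source_vars or not target_vars:
        raise ValueError("variable name lists must be non-empty")
    targets = list(dict.fromkeys(target_vars))
    target_set = set(targets)
    out = MatchProposal()
    for src in source_vars:
        norm = apply_prefix_rules(src, target_set)
        if norm in target_set:
            out.accepted[src] = norm
            continue
        scored = sorted(
            ((t, levenshtein_similarity(norm, t)) for t in targets),
            key=lambda ts: (-ts[1], ts[0]))
        scored = [ts for ts in scored if ts[1] >= threshold]
        if not scored:
            out.unmapped.add(src)
            continue
        out.candidates[src] = scored
        if len(scored) > 1 and scored[0][1] == scored[1][1]:
            out.ambiguous.add(src)
    return out


# ----------------------------------------------------------------------
# value-label conflict resolution

@dataclass
class LabelResolution:
    """Merged value-label dictionary plus the relevel maps applied."""

    merged: dict[int, Optional[str]]
    relevel_a: dict[int, int] = field(default_factory=dict)
    relevel_b: dict[int, int] = field(default_factory=dict)


def resolve_label_conflicts(dict_a: dict[int, Optional[str]],
                            dict_b: dict[int, Optional[str]]
                            ) -> LabelResolution:
    """Merge two value-label dictionaries, relevelling conflicting codes.

    Both dictionaries are appended and duplicates dropped.  Where the same
    value carries two different labels, the side *without* a label keeps
    the value and the labelled side is relevelled; when both sides are
    labelled, side ``a`` keeps its value and ``b``'s entry moves to the
    next larger unused level.  A relevelled entry's label is prefixed with
    its original value in square brackets, e.g. a value moved from 1 gets
    the label ``"[1] Yes"``.
    """
    merged: dict[int, Optional[str]] = {}
    res = LabelResolution(merged=merged)
    used = set(dict_a) | set(dict_b)
    for v in sorted(used):
        la = dict_a.get(v)
        lb = dict_b.get(v)
        if v in dict_a and v in dict_b and la != lb and not (
                la is None and lb is None):
            if la is None:          # unlabelled side keeps the value
                merged[v] = None
                _relevel(res.relevel_b, merged, used, v, lb)
            elif lb is None:
                merged[v] = None
                _relevel(res.relevel_a, merged, used, v, la)
            else:                   # both labelled: a keeps, b moves
                merged[v] = la
                _relevel(res.relevel_b, merged, used, v, lb)
        else:
            merged[v] = la if v in dict_a else lb
    return res


def _relevel(relevel_map: dict[int, int], merged: dict[int, Optional[str]],
             used: set[int], value: int, label: Optional[str]) -> None:
    new = max(used) + 1  # next larger level unused by either dictionary
    used.add(new)
    relevel_map[value] = new
    merged[new] = f"[{value}] {label}" if label is not None else None


def harmonize_pair(female: SurveyDataset, male: SurveyDataset,
                   threshold: float = 0.7
                   ) -> tuple[SurveyDataset, SurveyDataset, dict]:
    """Map a male file onto its female counterpart's naming and labels.

    Male candidate columns whose prefix-normalised names exactly match a
    female column are renamed; value-label conflicts between matched
    columns are resolved, with relevelled codes rewritten in the male data.
    Returns new datasets and a report of renames, relevels and unmapped
    male names.
    """
    female = female.copy()
    male = male.copy()
    proposal = propose_matches(male.candidate_variables,
                               female.candidate_variables, threshold)
    relevels: dict[str, dict[int, int]] = {}
    for mname, fname in proposal.accepted.items():
        fa = female.value_labels.get(fname)
        mb = male.value_labels.get(mname)
        if fa is not None and mb is not None and fa != mb:
            res = resolve_label_conflicts(fa, mb)
            if res.relevel_b:
                col = male.data[mname]
                male.data[mname] = col.replace(
                    {float(old): float(new)
                     for old, new in res.relevel_b.items()})
                relevels[fname] = res.relevel_b
            if res.relevel_a:
                female.data[fname] = female.data[fname].replace(
                    {float(old): float(new)
                     for old, new in res.relevel_a.items()})
            female.value_labels[fname] = dict(res.merged)
            male.value_labels[mname] = dict(res.merged)
    rename = proposal.accepted
    male.data = male.data.rename(columns=rename)
    male.value_labels = {rename.get(k, k): v
                         for k, v in male.value_labels.items()}
    male.kinds = {rename.get(k, k): v for k, v in male.kinds.items()}
    report = {
        "renamed": dict(rename),
        "relevelled": {k: {int(a): int(b) for a, b in v.items()}
                       for k, v in relevels.items()},
        "ambiguous": sorted(proposal.ambiguous),
        "unmapped": sorted(proposal.unmapped),
    }
    return female, male, report


def resolve_label_sets(label_sets: Sequence[tuple[str, dict[int, Optional[str]]]]
                       ) -> tuple[dict[int, Optional[str]],
                                  dict[str, dict[int, int]]]:
    """Resolve one variable's value labels across many dictionaries at once.

    ``label_sets`` is an ordered list of ``(tag, {value: label})`` — one
    entry per survey file carrying the variable, women's files first.  The
    complete list of values is assembled, then per value: an unlabelled
    claimant (if any) keeps the value; otherwise the first-seen label is
    canonical; every other distinct label moves to the next larger unused
    level, assigned once so the same (value, label) conflict lands on the
    same new level in every survey.  Relevelled labels carry their original
    value in square brackets.  Returns the merged dictionary and a relevel
    map per tag.
    """
    seen_labels: dict[int, list[Optional[str]]] = {}
    for _, d in label_sets:
        for v, lab in d.items():
            labs = seen_labels.setdefault(v, [])
            if lab not in labs:
                labs.append(lab)
    merged: dict[int, Optional[str]] = {}
    for v in sorted(seen_labels):
        labs = seen_labels[v]
        merged[v] = None if None in labs else labs[0]
    assigned: dict[tuple[int, Optional[str]], int] = {}
    next_level = max(merged, default=0) + 1
    for v in sorted(seen_labels):
        for lab in seen_labels[v]:
            if lab is None or lab == merged[v]:
                continue
            assigned[(v, lab)] = next_level
            merged[next_level] = f"[{v}] {lab}"
            next_level += 1
    relevels = {
        tag: {v: assigned[(v, lab)] for v, lab in d.items()
              if (v, lab) in assigned}
        for tag, d in label_sets
    }
    return merged, {tag: m for tag, m in relevels.items() if m}


def harmonize_surveys(datasets: list[SurveyDataset], threshold: float = 0.7
                      ) -> tuple[list[SurveyDataset], dict]:
    """Harmonise a survey collection onto shared names and label levels.

    Male candidate columns are renamed onto the women's-file convention
    (exact matches after the prefix rules), then each variable's value
    labels are resolved globally across every survey, so a conflicting
    (value, label) pair is relevelled to the same new level wherever it
    occurs.  Relevelled codes are rewritten in the affected surveys' data.
    """
    out = [ds.copy() for ds in datasets]
    report: dict[str, dict] = {"renamed": {}, "relevelled": {},
                               "ambiguous": [], "unmapped": []}
    by_key: dict[tuple[str, int], dict[str, SurveyDataset]] = {}
    for ds in out:
        by_key.setdefault((ds.country, ds.year), {})[ds.sex] = ds
    for key in sorted(by_key):
        pair = by_key[key]
        if "female" not in pair or "male" not in pair:
            continue
        male = pair["male"]
        prop = propose_matches(male.candidate_variables,
                               pair["female"].candidate_variables, threshold)
        male.data = male.data.rename(columns=prop.accepted)
        male.value_labels = {prop.accepted.get(k, k): v
                             for k, v in male.value_labels.items()}
        male.kinds = {prop.accepted.get(k, k): v
                      for k, v in male.kinds.items()}
        report["renamed"][f"{key[0]}-{key[1]}"] = dict(prop.accepted)
        report["ambiguous"].extend(sorted(prop.ambiguous))
        report["unmapped"].extend(sorted(prop.unmapped))

    carriers: dict[str, list[SurveyDataset]] = {}
    for ds in sorted(out, key=lambda d: (d.sex != "female", d.survey_id)):
        for var, vl in ds.value_labels.items():
            carriers.setdefault(var, []).append(ds)
    for var, holders in carriers.items():
        sets = [(ds.survey_id, ds.value_labels[var]) for ds in holders]
        if all(s == sets[0][1] for _, s in sets):
            continue
        merged, relevels = resolve_label_sets(sets)
        for ds in holders:
            rmap = relevels.get(ds.survey_id)
            if rmap:
                ds.data[var] = ds.data[var].replace(
                    {float(a): float(b) for a, b in rmap.items()})
            ds.value_labels[var] = dict(merged)
        if relevels:
            report["relevelled"][var] = {
                tag: {int(a): int(b) for a, b in m.items()}
                for tag, m in relevels.items()}
    return out, report


# ----------------------------------------------------------------------
# recode merging

@dataclass
class MergePlan:
    """Join keys, order and quality-alert thresholds for one survey."""

    keys: tuple[str, ...] = ("cluster", "hhid", "line")
    household_keys: tuple[str, ...] = ("cluster", "hhid")
    min_individual_merge: float = 0.75
    max_individual_unmerged: float = 0.25
    min_household_merge: float = 0.75
    min_hiv_merge: float = 0.50


def merge_recodes(roster: pd.DataFrame,
                  individual: Optional[pd.DataFrame],
                  household: Optional[pd.DataFrame] = None,
                  hiv: Optional[pd.DataFrame] = None,
                  plan: MergePlan = MergePlan()
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Left-join a survey's files onto the member roster.

    Roster rows without an individual-file match are retained with empty
    individual fields; test results are left missing where absent.  Alerts
    flag poor merges: individual data covering under 75% of the roster,
    over 25% of individual rows finding no roster row, household data
    covering under 75%, and test results covering under 50% of
    respondents.  The individual file is the minimum requirement: without
    it the survey is not merged.
    """
    if individual is None:
        raise MergeError("individual recode absent: survey not merged")
    keys = list(plan.keys)
    alerts: list[str] = []
    merged = roster.merge(individual.drop_duplicates(subset=keys), on=keys,
                          how="left", suffixes=("", "_ind"))
    cov_ind = _coverage(roster, individual, keys)
    if cov_ind < plan.min_individual_merge:
        alerts.append(f"individual rows merge to only {cov_ind:.0%} of the "
                      f"roster (<{plan.min_individual_merge:.0%})")
    orphan = 1.0 - _coverage(individual, roster, keys)
    if orphan > plan.max_individual_unmerged:
        alerts.append(f"{orphan:.0%} of individual rows unmergeable "
                      f"(>{plan.max_individual_unmerged:.0%})")
    if household is not None:
        hkeys = list(plan.household_keys)
        merged = merged.merge(household.drop_duplicates(subset=hkeys),
                              on=hkeys, how="left", suffixes=("", "_hh"))
        cov_hh = _coverage(roster, household, hkeys)
        if cov_hh < plan.min_household_merge:
            alerts.append(f"household rows merge to only {cov_hh:.0%} of "
                          f"the roster (<{plan.min_household_merge:.0%})")
    if hiv is not None:
        merged = merged.merge(hiv.drop_duplicates(subset=keys), on=keys,
                              how="left", suffixes=("", "_hiv"))
        cov_hiv = _coverage(roster, hiv, keys)
        if cov_hiv < plan.min_hiv_merge:
            alerts.append(f"test-result rows cover only {cov_hiv:.0%} of "
                          f"respondents (<{plan.min_hiv_merge:.0%})")
    return merged, alerts


def _coverage(base: pd.DataFrame, other: pd.DataFrame,
              keys: list[str]) -> float:
    """Fraction of ``base`` rows with a key match in ``other``."""
    if base.empty:
        return 1.0
    hit = base[keys].merge(other[keys].drop_duplicates(), on=keys)
    return len(hit) / len(base)


# ----------------------------------------------------------------------
# encoding and pruning

def encode_variables(survey: SurveyDataset, max_levels: int = 30
                     ) -> SurveyDataset:
    """One-hot expand low-cardinality variables, standardise the rest.

    Every candidate variable with ``max_levels`` or fewer distinct observed
    values is expanded into one binary indicator per level (no reference
    level is dropped: each indicator is screened as its own candidate).
    Variables with more distinct values are treated as continuous and
    standardised to mean 0, SD 1 within the survey; the (mean, SD) pair is
    stored so the transform is invertible.  Missing values stay missing in
    every derived column.
    """
    out = survey.copy()
    encoded: dict[str, pd.Series] = {}
    drop: list[str] = []
    for var in survey.candidate_variables:
        col = out.data[var]
        levels = np.sort(col.dropna().unique())
        if len(levels) <= max_levels:
            miss = col.isna()
            for lv in levels:
                ind = (col == lv).astype(float)
                ind[miss] = np.nan
                lab = int(lv) if float(lv).is_integer() else lv
                encoded[f"{var}__{lab}"] = ind
                out.kinds[f"{var}__{lab}"] = "binary"
            drop.append(var)
            out.kinds.pop(var, None)
        else:
            mean = float(col.mean())
            sd = float(col.std(ddof=0))
            if sd > 0:
                out.data[var] = (col - mean) / sd
                out.scaling[var] = (mean, sd)
            out.kinds[var] = "continuous"
    if encoded:
        out.data = pd.concat(
            [out.data.drop(columns=drop), pd.DataFrame(encoded)], axis=1)
    return out


def destandardize(survey: SurveyDataset, variable: str) -> pd.Series:
    """Invert the standardisation of a continuous column."""
    mean, sd = survey.scaling[variable]
    return survey.data[variable] * sd + mean


def pairwise_complete_corr(frame: pd.DataFrame,
                           min_periods: int = 1) -> np.ndarray:
    """Pairwise-complete Pearson correlation matrix via matrix products.

    Equivalent to ``frame.corr(min_periods=...)`` but built from five
    BLAS products over the zero-filled data and the observation mask, so
    it scales to the thousands of encoded candidate columns a survey
    produces.  Pairs with fewer than ``min_periods`` joint observations
    (or zero variance on the joint rows) are NaN.
    """
    X = frame.to_numpy(dtype=float)
    M = np.isfinite(X).astype(float)
    X0 = np.where(M > 0, X, 0.0)
    n = M.T @ M                      # joint observation counts
    s = X0.T @ M                     # sum of x over joint rows (per pair)
    ss = (X0 * X0).T @ M             # sum of x^2 over joint rows
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - s * s.T / n
        var_x = ss - s * s / n
        corr = cov / np.sqrt(var_x * var_x.T)
        corr[(n < min_periods) | (var_x <= 0) | (var_x.T <= 0)] = np.nan
    return corr


def prune_variables(datasets: list[SurveyDataset],
                    corr_threshold: float = 0.9,
                    completeness: float = 0.9,
                    min_joint: int = 30
                    ) -> tuple[list[SurveyDataset], pd.DataFrame, list[str]]:
    """Drop constant, near-duplicate and incomplete candidate variables.

    Zero-variance columns are removed per survey.  Pairwise Pearson
    correlations (pairwise-complete, pairs with fewer than ``min_joint``
    joint observations skipped) are computed within each survey; pairs with
    ``|r| >= corr_threshold`` in any survey define a graph whose connected
    components are duplicate groups, and each group keeps the member with
    the largest average non-missing count across the surveys where it
    appears (ties broken lexicographically).  Finally, variables less than
    ``completeness`` complete in a survey are dropped from that survey.
    Returns pruned datasets, a per-variable metadata table and a log.
    """
    out = [ds.copy() for ds in datasets]
    log: list[str] = []

    for ds in out:
        for var in list(ds.candidate_variables):
            col = ds.data[var]
            if col.dropna().nunique() <= 1:
                ds.data = ds.data.drop(columns=[var])
                log.append(f"{ds.survey_id}: dropped {var} (no variation)")

    # average analysable n per variable, over surveys where it appears
    counts: dict[str, list[int]] = {}
    for ds in out:
        for var in ds.candidate_variables:
            counts.setdefault(var, []).append(int(ds.data[var].notna().sum()))
    avg_n = {v: float(np.mean(c)) for v, c in counts.items()}

    parent: dict[str, str] = {v: v for v in counts}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for ds in out:
        cand = ds.candidate_variables
        if len(cand) < 2:
            continue
        corr = pairwise_complete_corr(ds.data[cand], min_joint)
        iu, ju = np.triu_indices(len(cand), k=1)
        hits = np.abs(corr[iu, ju]) >= corr_threshold
        for i, j in zip(iu[hits], ju[hits]):
            ra, rb = find(cand[int(i)]), find(cand[int(j)])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for v in counts:
        groups.setdefault(find(v), []).append(v)
    dropped: set[str] = set()
    for members in groups.values():
        if len(members) < 2:
            continue
        keep = max(members, key=lambda v: (avg_n[v], _revlex(v)))
        for v in members:
            if v != keep:
                dropped.add(v)
                log.append(f"dropped {v} (correlated group, kept {keep})")
    for ds in out:
        drop_here = [v for v in ds.candidate_variables if v in dropped]
        ds.data = ds.data.drop(columns=drop_here)

    for ds in out:
        n = len(ds.data)
        for var in list(ds.candidate_variables):
            comp = ds.data[var].notna().sum() / n
            if comp < completeness:
                ds.data = ds.data.drop(columns=[var])
                log.append(f"{ds.survey_id}: dropped {var} "
                           f"({comp:.0%} complete)")

    rows = []
    retained = {v for ds in out for v in ds.candidate_variables}
    for v in sorted(counts):
        rows.append({"variable": v, "avg_n": avg_n[v],
                     "n_surveys": len(counts[v]),
                     "retained": v in retained})
    return out, pd.DataFrame(rows), log


class _revlex(str):
    """Reversed lexicographic order, so max() prefers the smaller name."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)
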