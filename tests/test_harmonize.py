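"""Name mapping, label-conflict resolution, merging, pruning, encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import xwasmeta as xm
from xwasmeta.harmonize import (LabelResolution, MergeError, MergePlan,
                                apply_prefix_rules, destandardize,
                                encode_variables, harmonize_pair,
                                levenshtein_similarity, merge_recodes,
                                propose_matches, prune_variables,
                                resolve_label_conflicts)
from xwasmeta.types import SurveyDataset


# ----------------------------------------------------------------------
# prefix rules and name similarity

@pytest.mark.parametrize("name, expected", [
    ("mv012", "v012"),        # men's recode prefix onto women's
    ("mcaseid", "caseid"),
    ("v012", "v012"),         # already normalised: untouched
    ("_v012", "v012"),
    ("mv304a", "v304a_"),
    ("sm611", "s811"),
    ("dmflag", "dflag"),
    ("mweight", "vweight"),
    ("sb16", "b16"),
])
def test_prefix_rules(name, expected):
    assert apply_prefix_rules(name) == expected


def test_prefix_rule_sm_falls_back_without_mm_candidate():
    assert apply_prefix_rules("sm12", ["mm12", "v001"]) == "mm12"
    assert apply_prefix_rules("sm12", ["v001"]) == "s12"


def test_prefix_rules_idempotent_on_normalised_names():
    for name in ("v012", "caseid", "v304a_", "b16", "dflag"):
        assert apply_prefix_rules(name) == name


def test_prefix_rules_reject_empty():
    with pytest.raises(ValueError):
        apply_prefix_rules("")


def _dp_levenshtein(a: str, b: str) -> int:
    """Classic dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.mark.parametrize("a, b, expected", [
    ("abcd", "abcd", 1.0),
    ("abcd", "abce", 0.75),
    ("v012", "mv012", 0.8),
])
def test_similarity_examples(a, b, expected):
    assert levenshtein_similarity(a, b) == pytest.approx(expected)


@given(st.text(alphabet="abmv019_", min_size=1, max_size=12),
       st.text(alphabet="abmv019_", min_size=1, max_size=12))
def test_similarity_matches_dp_oracle_and_stays_in_unit_interval(a, b):
    sim = levenshtein_similarity(a, b)
    assert sim == pytest.approx(1 - _dp_levenshtein(a, b) / max(len(a),
                                                                len(b)))
    assert 0.0 <= sim <= 1.0


def test_similarity_rejects_empty():
    with pytest.raises(ValueError):
        levenshtein_similarity("", "abc")


def test_propose_matches_exact_candidates_ties_unmapped():
    prop = propose_matches(["mv012", "mv876b", "zzzzzzzz"],
                           ["v012", "v876a", "v876c", "qq"])
    assert prop.accepted == {"mv012": "v012"}
    # v876b is equidistant from v876a and v876c: ambiguous, unresolved
    assert "mv876b" in prop.ambiguous
    tops = [t for t, _ in prop.candidates["mv876b"][:2]]
    assert tops == ["v876a", "v876c"]
    assert "zzzzzzzz" in prop.unmapped


# ----------------------------------------------------------------------
# value-label conflicts

def test_identical_dictionaries_unchanged():
    d = {1: "Yes", 2: "No"}
    res = resolve_label_conflicts(d, dict(d))
    assert res.merged == d
    assert res.relevel_a == {} and res.relevel_b == {}


def test_conflicting_label_relevels_second_side_with_bracket_prefix():
    res = resolve_label_conflicts({1: "Yes", 2: "No"}, {1: "Definitely"})
    assert res.merged[1] == "Yes"
    new = res.relevel_b[1]
    assert new == 3  # next larger unused level
    assert res.merged[new] == "[1] Definitely"


def test_unlabelled_value_gets_priority():
    res = resolve_label_conflicts({1: None}, {1: "Yes"})
    assert res.merged[1] is None
    assert res.merged[res.relevel_b[1]] == "[1] Yes"

    res2 = resolve_label_conflicts({1: "Yes"}, {1: None})
    assert res2.merged[1] is None
    assert res2.merged[res2.relevel_a[1]] == "[1] Yes"


@given(st.dictionaries(st.integers(0, 8),
                       st.sampled_from(["Yes", "No", "Maybe", None]),
                       max_size=6),
       st.dictionaries(st.integers(0, 8),
                       st.sampled_from(["Yes", "No", "Maybe", None]),
                       max_size=6))
def test_resolution_is_idempotent_and_conflict_free(da, db):
    res = resolve_label_conflicts(da, db)
    again = resolve_label_conflicts(res.merged, dict(res.merged))
    assert again.merged == res.merged
    assert again.relevel_a == {} and again.relevel_b == {}


def test_global_resolution_assigns_the_same_level_to_repeat_conflicts():
    from xwasmeta.harmonize import resolve_label_sets

    sets = [("f1", {0: "No", 1: "Yes"}),
            ("m1", {0: "No", 1: "Definitely"}),
            ("m2", {0: "No", 1: "Yes"}),
            ("m3", {0: "No", 1: "Definitely"})]
    merged, relevels = resolve_label_sets(sets)
    assert relevels["m1"] == {1: 2} and relevels["m3"] == {1: 2}
    assert "m2" not in relevels  # agrees with the canonical label
    assert merged == {0: "No", 1: "Yes", 2: "[1] Definitely"}


def test_injected_conflicts_round_trip_to_clean_dictionaries(
        small_collection):
    """Inject conflicts, harmonise, then scan: no value keeps two labels."""
    _, datasets, _ = small_collection
    conflicted = xm.inject_label_conflicts(datasets, 1.0, seed=3)
    harmonised, report = xm.harmonize_surveys(conflicted)
    by_key = {}
    for ds in harmonised:
        for var in ds.candidate_variables:
            vl = ds.value_labels.get(var)
            if vl is None:
                continue
            seen = by_key.setdefault((ds.country, ds.year, var), {})
            for code, lab in vl.items():
                assert seen.setdefault(code, lab) == lab, \
                    f"value {code} of {var} carries two labels"
    assert report["relevelled"]  # at least one conflict was relevelled
    # relabelled codes carry the original value in square brackets
    ds = next(d for d in harmonised if any(
        "[" in (lab or "") for vl in d.value_labels.values()
        for lab in vl.values()))
    lab = next(lab for vl in ds.value_labels.values()
               for lab in vl.values() if lab and lab.startswith("["))
    assert lab.split("]")[0].strip("[").isdigit()


# ----------------------------------------------------------------------
# recode merging

def _files(n=20, ind_frac=1.0, hiv_frac=1.0):
    rng = np.random.default_rng(0)
    roster = pd.DataFrame({
        "cluster": np.repeat([1, 2], n // 2),
        "hhid": np.tile(np.arange(n // 2), 2),
        "line": np.ones(n, dtype=int),
        "member_age": rng.integers(15, 50, n),
    })
    k = int(n * ind_frac)
    individual = roster.iloc[:k][["cluster", "hhid", "line"]].copy()
    individual["v012"] = rng.integers(15, 50, k)
    household = roster[["cluster", "hhid"]].drop_duplicates().copy()
    household["hv270"] = rng.integers(1, 6, len(household))
    m = int(n * hiv_frac)
    hiv = roster.iloc[:m][["cluster", "hhid", "line"]].copy()
    hiv["hiv03"] = rng.integers(0, 2, m)
    return roster, individual, household, hiv


def test_full_merge_keeps_roster_rows_and_raises_no_alert():
    roster, ind, hh, hiv = _files()
    merged, alerts = merge_recodes(roster, ind, hh, hiv)
    assert len(merged) == len(roster)
    assert alerts == []
    assert merged["hiv03"].notna().all()


def test_partial_individual_merge_raises_alert_but_keeps_rows():
    roster, ind, hh, hiv = _files(ind_frac=0.6)
    merged, alerts = merge_recodes(roster, ind, hh, hiv)
    assert len(merged) == len(roster)
    assert any("individual" in a for a in alerts)
    assert merged["v012"].isna().sum() == int(len(roster) * 0.4)


def test_low_hiv_coverage_alert_and_missing_results_retained():
    roster, ind, hh, hiv = _files(hiv_frac=0.4)
    merged, alerts = merge_recodes(roster, ind, hh, hiv)
    assert any("test-result" in a for a in alerts)
    assert merged["hiv03"].isna().sum() == int(len(roster) * 0.6)


def test_missing_individual_file_refuses_to_merge():
    roster, _, hh, hiv = _files()
    with pytest.raises(MergeError, match="not merged"):
        merge_recodes(roster, None, hh, hiv)


# ----------------------------------------------------------------------
# encoding

def _survey(df, labels=None, sex="female"):
    return SurveyDataset(survey_id="T-2010-" + sex, country="T", year=2010,
                         sex=sex, data=df, value_labels=labels or {})


def _base_frame(n, rng):
    return {
        "hiv": rng.integers(0, 2, n), "weight": np.ones(n),
        "cluster": np.arange(n) % 5, "stratum": np.zeros(n, dtype=int),
        "hhid": np.arange(n), "line": np.ones(n, dtype=int),
        "wealth": rng.integers(1, 6, n).astype(float),
        "age": rng.integers(15, 50, n).astype(float),
        "rural": rng.integers(0, 2, n).astype(float),
    }


def test_encode_one_hot_and_standardise():
    rng = np.random.default_rng(1)
    n = 200
    df = pd.DataFrame({
        **_base_frame(n, rng),
        "marital": rng.choice([1.0, 2.0, 3.0], n),
        "height": rng.normal(160, 10, n).round(2),  # >30 distinct values
        "flag": rng.integers(0, 2, n).astype(float),
    })
    df.loc[0, "marital"] = np.nan
    enc = encode_variables(_survey(df), max_levels=30)
    # 3-level variable expands to 3 indicators, no reference dropped
    assert {"marital__1", "marital__2", "marital__3"} <= set(enc.data)
    assert "marital" not in enc.data
    assert np.isnan(enc.data.loc[0, "marital__2"])  # missing stays missing
    ind = enc.data[["marital__1", "marital__2", "marital__3"]].dropna()
    assert (ind.sum(axis=1) == 1).all()
    # high-cardinality column standardised to mean 0, SD 1
    assert enc.data["height"].mean() == pytest.approx(0, abs=1e-9)
    assert enc.data["height"].std(ddof=0) == pytest.approx(1, abs=1e-9)
    # binary column becomes two complementary indicators
    assert {"flag__0", "flag__1"} <= set(enc.data)
    # standardisation round-trips through the stored (mean, SD)
    back = destandardize(enc, "height")
    assert np.allclose(back, df["height"], atol=1e-9)


# ----------------------------------------------------------------------
# pruning

def test_pairwise_corr_matches_pandas_reference():
    from xwasmeta.harmonize import pairwise_complete_corr

    rng = np.random.default_rng(10)
    df = pd.DataFrame(rng.normal(size=(300, 25)))
    df = df.mask(rng.random(df.shape) < 0.15)
    df[24] = 1.0  # constant column: undefined correlation
    got = pairwise_complete_corr(df, min_periods=30)
    want = df.corr(min_periods=30).to_numpy()
    assert np.array_equal(np.isnan(got), np.isnan(want))
    assert np.nanmax(np.abs(got - want)) < 1e-12


def test_prune_constants_duplicates_and_incomplete():
    rng = np.random.default_rng(2)
    n = 400
    x = rng.normal(size=n)
    df1 = pd.DataFrame({
        **_base_frame(n, rng),
        "keep": x, "copy": x + rng.normal(scale=0.01, size=n),
        "const": np.ones(n), "sparse": rng.normal(size=n),
    })
    df1.loc[df1.index[: int(0.15 * n)], "sparse"] = np.nan  # 85% complete
    # second survey lacks "copy", so "keep" has the larger average n
    df2 = pd.DataFrame({**_base_frame(n, rng), "keep": rng.normal(size=n)})
    pruned, meta, log = prune_variables(
        [_survey(df1), _survey(df2, sex="male")])
    cols1 = set(pruned[0].candidate_variables)
    assert "const" not in cols1
    assert "sparse" not in cols1
    assert "keep" in cols1 and "copy" not in cols1
    assert any("no variation" in line for line in log)
    assert meta.set_index("variable").loc["copy", "retained"] == False  # noqa: E712


def test_post_pruning_no_pair_exceeds_correlation_threshold(
        small_collection):
    """Brute-force pair scan after pruning the encoded synthetic surveys."""
    _, datasets, _ = small_collection
    harmonised, _ = xm.harmonize_surveys(datasets)
    encoded = [encode_variables(ds) for ds in harmonised]
    pruned, _, _ = prune_variables(encoded)
    for ds in pruned:
        cand = ds.candidate_variables
        corr = ds.data[cand].corr(min_periods=30).to_numpy()
        iu, ju = np.triu_indices(len(cand), k=1)
        worst = np.nanmax(np.abs(corr[iu, ju]))
        assert worst < 0.9, \
            f"{ds.survey_id}: retained pair with |r|={worst:.3f}"


def test_duplicate_group_retains_largest_average_sample_size():
    rng = np.random.default_rng(3)
    n = 300
    x = rng.normal(size=n)
    dfa = pd.DataFrame({**_base_frame(n, rng), "a": x, "b": x.copy()})
    dfa.loc[dfa.index[:60], "b"] = np.nan  # avg n: a=300, b=240
    pruned, _, _ = prune_variables([_survey(dfa)], completeness=0.5)
    assert "a" in pruned[0].candidate_variables
    assert "b" not in pruned[0].candidate_variables
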