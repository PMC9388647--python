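"""Dual-threshold discovery and country-count summaries.

A variable is *identified* when its pooled meta-analytic p-value clears a
conservative Bonferroni-style threshold (default 1e-6) and its average
per-survey Nagelkerke R^2 clears an explanatory-power floor (default
0.001, the empirical 75th-percentile equivalent).  Variables are then
binned by the number of countries in which they were assessed, and each
(sex, bin) cell is summarised by quartiles of the pooled odds ratio,
mean R^2 and I^2 -- the structure of the study's headline summary table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

BIN_LABELS = ("1", "2-10", "11-19", "20-29")


def bonferroni_threshold(n_tests_female: int, n_tests_male: int,
                         alpha: float = 0.05) -> float:
    """Family-wise threshold ``alpha / (n_female + n_male)``."""
    if n_tests_female <= 0 or n_tests_male <= 0:
        raise ValueError("test counts must be positive")
    return alpha / (n_tests_female + n_tests_male)


def country_bin(n_countries: int) -> str:
    """Bin a country count into {1, 2-10, 11-19, 20-29} (20+ in the last)."""
    if n_countries < 1:
        raise ValueError("country count must be at least 1")
    if n_countries == 1:
        return BIN_LABELS[0]
    if n_countries <= 10:
        return BIN_LABELS[1]
    if n_countries <= 19:
        return BIN_LABELS[2]
    return BIN_LABELS[3]


def identify_variables(meta: pd.DataFrame,
                       assessed: pd.DataFrame,
                       p_threshold: float = 1e-6,
                       r2_threshold: Optional[float] = 0.001,
                       r2_quantile: Optional[float] = None,
                       country_meta: Optional[pd.DataFrame] = None
                       ) -> pd.DataFrame:
    """Flag identified variables from a pan-scope meta table.

    ``meta`` is the pan-scope pooled table; ``assessed`` maps
    (variable, sex) to the number of countries in which the variable was
    screened.  The R^2 rule is either a fixed cut (``r2_threshold``) or a
    quantile of the mean-R^2 distribution pooled across sexes
    (``r2_quantile``, e.g. 0.75 for the top quartile); exactly one must be
    given.  When a country-scope meta table is supplied, per-country
    identification under the same dual rule is counted as well.
    """
    if meta.empty:
        raise ValueError("meta table is empty")
    if (r2_threshold is None) == (r2_quantile is None):
        raise ValueError("give exactly one of r2_threshold / r2_quantile")
    if r2_quantile is not None:
        r2_cut = float(meta["mean_r2"].quantile(r2_quantile))
    else:
        r2_cut = float(r2_threshold)

    out = meta.merge(assessed, on=["variable", "sex"], how="left")
    out["n_countries_assessed"] = (
        out["n_countries_assessed"].fillna(1).astype(int))
    out["identified"] = ((out["p"] < p_threshold)
                         & (out["mean_r2"] > r2_cut))
    out["or"] = np.exp(out["beta"])
    out["bin"] = out["n_countries_assessed"].map(country_bin)

    if country_meta is not None and not country_meta.empty:
        cm = country_meta.copy()
        cm["hit"] = (cm["p"] < p_threshold) & (cm["mean_r2"] > r2_cut)
        counts = (cm.groupby(["variable", "sex"])["hit"].sum()
                  .rename("n_countries_identified").reset_index())
        out = out.merge(counts, on=["variable", "sex"], how="left")
        out["n_countries_identified"] = (
            out["n_countries_identified"].fillna(0).astype(int))
    else:
        out["n_countries_identified"] = 0
    out.attrs["r2_cut"] = r2_cut
    out.attrs["p_threshold"] = p_threshold
    return out


def bin_and_summarize(discovery: pd.DataFrame) -> pd.DataFrame:
    """Per (sex, country-count bin) distribution summary.

    Reports the association count and the 25th/50th/75th percentiles of
    the pooled odds ratio, the mean Nagelkerke R^2 and I^2.  I^2 columns
    are left blank in the single-country bin, where heterogeneity is
    undefined.
    """
    rows = []
    for sex in sorted(discovery["sex"].unique()):
        for label in BIN_LABELS:
            cell = discovery[(discovery["sex"] == sex)
                             & (discovery["bin"] == label)]
            if cell.empty:
                continue
            row = {"sex": sex, "bin": label, "n_assoc": len(cell),
                   "n_identified": int(cell["identified"].sum())}
            for stem, col in (("or", "or"), ("r2", "mean_r2"), ("i2", "i2")):
                vals = cell[col].dropna().abs() if col == "or" else \
                    cell[col].dropna()
                blank = col == "i2" and label == BIN_LABELS[0]
                for q, tag in ((0.25, "q25"), (0.5, "median"), (0.75, "q75")):
                    row[f"{stem}_{tag}"] = (
                        np.nan if blank or vals.empty
                        else float(vals.quantile(q)))
            rows.append(row)
    return pd.DataFrame(rows)


def volcano_data(discovery: pd.DataFrame,
                 or_cap: tuple[float, float] = (0.01, 100.0)) -> pd.DataFrame:
    """Export -log10(p) vs R^2 / capped OR for volcano-style plotting."""
    d = discovery.copy()
    with np.errstate(divide="ignore"):
        d["neg_log10_p"] = -np.log10(d["p"])
    d["or_capped"] = d["or"].clip(*or_cap)
    return d[["variable", "sex", "neg_log10_p", "mean_r2", "or_capped",
              "i2", "identified"]]
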