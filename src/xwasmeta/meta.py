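"""DerSimonian-Laird random-effects meta-analysis across surveys.

Pools per-survey log-odds-ratios for each (variable, sex) at two scopes:
within-country across survey waves, and pan-region across every survey.
The between-survey variance ``tau^2`` is the DerSimonian-Laird moment
estimator; heterogeneity is summarised by Cochran's Q and I^2.  A variable
observed in a single survey passes through with its survey estimate and an
undefined (missing) I^2.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import MetaResult, meta_to_frame


def dersimonian_laird(betas: Sequence[float], variances: Sequence[float]
                      ) -> dict:
    """Pool effect estimates with the DerSimonian-Laird moment estimator.

    With fixed-effect weights ``w_i = 1/v_i``:
    ``Q = sum w_i (b_i - b_FE)^2``,
    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))``, and the
    pooled estimate re-weights by ``1/(v_i + tau2)``.
    ``I^2 = max(0, (Q - (k-1))/Q) * 100``, reported as missing when k = 1
    or Q = 0, where heterogeneity is undefined.
    """
    b = np.asarray(betas, dtype=float)
    v = np.asarray(variances, dtype=float)
    k = b.size
    if k == 0:
        raise ValueError("at least one estimate is required")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("variances must be positive and finite")
    if k == 1:
        beta, se = float(b[0]), float(np.sqrt(v[0]))
        return {"k": 1, "beta": beta, "se": se,
                "p": float(2 * norm.sf(abs(beta) / se)),
                "q": 0.0, "tau2": 0.0, "i2": None}
    w = 1.0 / v
    beta_fe = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - beta_fe) ** 2))
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    ws = 1.0 / (v + tau2)
    beta_re = float(np.sum(ws * b) / np.sum(ws))
    se = float(np.sum(ws) ** -0.5)
    i2 = None if q == 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return {"k": int(k), "beta": beta_re, "se": se,
            "p": float(2 * norm.sf(abs(beta_re) / se)),
            "q": q, "tau2": float(tau2), "i2": i2}


def run_meta(assoc: pd.DataFrame, scope: str = "pan",
             include_separated: bool = True) -> pd.DataFrame:
    """Pool an association table by (variable, sex) at the given scope.

    ``scope="country"`` combines the waves within each country (one result
    per variable x sex x country); ``scope="pan"`` combines every survey.
    Estimates with non-finite standard errors are always dropped; flagged
    (separated) fits are kept by default, since extreme odds ratios are
    still informative for pooling, and can be excluded with
    ``include_separated=False``.
    """
    if scope not in ("pan", "country"):
        raise ValueError(f"unknown scope {scope!r}")
    usable = assoc[np.isfinite(assoc["se"]) & (assoc["se"] > 0)
                   & np.isfinite(assoc["beta"])]
    if not include_separated and "separated" in usable:
        usable = usable[~usable["separated"].astype(bool)]
    keys = (["variable", "sex"] if scope == "pan"
            else ["variable", "sex", "country"])
    results: list[MetaResult] = []
    for key, grp in usable.groupby(keys, sort=True):
        core = dersimonian_laird(grp["beta"].to_numpy(),
                                 (grp["se"].to_numpy()) ** 2)
        results.append(MetaResult(
            variable=key[0], sex=key[1],
            scope="pan" if scope == "pan" else key[2],
            k=core["k"], beta=core["beta"], se=core["se"], p=core["p"],
            q=core["q"], tau2=core["tau2"], i2=core["i2"],
            mean_r2=float(grp["r2"].mean())))
    return meta_to_frame(results)


def countries_assessed(assoc: pd.DataFrame) -> pd.DataFrame:
    """Count distinct countries in which each (variable, sex) was screened."""
    g = (assoc.groupby(["variable", "sex"])["country"]
         .nunique().rename("n_countries_assessed"))
    return g.reset_index()
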