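"""Reading and writing survey files.

The native interchange format is one CSV per survey plus a JSON sidecar
carrying the survey tags, value-label dictionaries and variable kinds.
Stata-dialect ``.dta`` with embedded value labels is supported through
pandas' Stata reader/writer.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import SurveyDataset

SIDECAR_SUFFIX = ".labels.json"


def write_survey(ds: SurveyDataset, directory: str | Path,
                 fmt: str = "csv") -> Path:
    """Write one survey as CSV + JSON sidecar (or Stata .dta)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "survey_id": ds.survey_id, "country": ds.country, "year": ds.year,
        "sex": ds.sex,
        "value_labels": {v: {str(k): lab for k, lab in d.items()}
                         for v, d in ds.value_labels.items()},
        "kinds": ds.kinds,
    }
    if fmt == "csv":
        path = directory / f"{ds.survey_id}.csv"
        ds.data.to_csv(path, index=False)
        (directory / f"{ds.survey_id}{SIDECAR_SUFFIX}").write_text(
            json.dumps(meta, indent=1, sort_keys=True))
    elif fmt == "dta":
        path = directory / f"{ds.survey_id}.dta"
        df = ds.data.copy()
        labelled = {}
        for var, vl in ds.value_labels.items():
            if var in df.columns and df[var].dropna().mod(1).eq(0).all():
                labelled[var] = {int(k): str(lab) for k, lab in vl.items()
                                 if lab is not None}
        df.to_stata(path, write_index=False, value_labels=labelled,
                    data_label=ds.survey_id, version=118)
        (directory / f"{ds.survey_id}{SIDECAR_SUFFIX}").write_text(
            json.dumps(meta, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_survey(path: str | Path) -> SurveyDataset:
    """Read a survey written by :func:`write_survey` (CSV or .dta)."""
    path = Path(path)
    sidecar = path.with_name(path.name[: -len(path.suffix)] + SIDECAR_SUFFIX)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if path.suffix == ".csv":
        data = pd.read_csv(path)
        labels = {v: {_as_code(k): lab for k, lab in d.items()}
                  for v, d in meta.get("value_labels", {}).items()}
    elif path.suffix == ".dta":
        with pd.io.stata.StataReader(path) as rd:
            data = rd.read(convert_categoricals=False)
            raw = rd.value_labels()
            names = dict(zip(rd._varlist, rd._lbllist))
        labels = {v: {_as_code(k): lab for k, lab in raw[ln].items()}
                  for v, ln in names.items() if ln and ln in raw}
        # sidecar (when present) also covers unlabelled-value entries
        for v, d in meta.get("value_labels", {}).items():
            labels.setdefault(v, {})
            labels[v].update({_as_code(k): lab for k, lab in d.items()})
    else:
        raise ValueError(f"unsupported survey file {path.name!r}")
    stem = path.stem
    country, year, sex = (meta.get("country"), meta.get("year"),
                          meta.get("sex"))
    if country is None:
        parts = stem.rsplit("-", 2)
        country, year, sex = parts[0], int(parts[1]), parts[2]
    return SurveyDataset(
        survey_id=meta.get("survey_id", stem), country=country,
        year=int(year), sex=sex, data=data, value_labels=labels,
        kinds=dict(meta.get("kinds", {})))


def _as_code(key: str | int | float) -> int:
    return int(float(key))


def read_survey_dir(directory: str | Path) -> list[SurveyDataset]:
    """Read every survey file in a directory, CSV preferred over .dta."""
    directory = Path(directory)
    out: list[SurveyDataset] = []
    seen: set[str] = set()
    for path in sorted(directory.glob("*.csv")) + sorted(
            directory.glob("*.dta")):
        if path.stem in seen:
            continue
        sidecar = path.with_name(path.stem + SIDECAR_SUFFIX)
        if path.suffix == ".csv" and not sidecar.exists():
            continue  # auxiliary table (truth, reports), not a survey
        seen.add(path.stem)
        out.append(read_survey(path))
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
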