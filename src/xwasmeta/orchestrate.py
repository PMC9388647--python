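"""End-to-end pipeline: generate/load surveys, harmonise, screen, pool,
discover and predict, with a manifest for bit-exact reruns.

The single pipeline seed is expanded into fixed per-stage substreams, so
any stage can be rerun independently yet deterministically; rerunning the
whole pipeline with the same configuration and seed reproduces every
result table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .assoc import associate_survey
from .discover import bin_and_summarize, identify_variables, volcano_data
from .harmonize import encode_variables, harmonize_surveys, prune_variables
from .meta import countries_assessed, run_meta
from .predict import predict_all_countries
from .synth import (ConfigurationError, SyntheticConfig,
                    generate_multisurvey, inject_label_conflicts)
from .types import SurveyDataset, assoc_to_frame

log = logging.getLogger(__name__)

STAGES = ("input", "harmonize", "prepare", "assoc", "meta", "discover",
          "predict")


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    mode: str = "synthetic"              # "synthetic" | "files"
    input_dir: Optional[str] = None      # required in files mode
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    completeness: float = 0.9
    corr_threshold: float = 0.9
    max_levels: int = 30
    p_threshold: float = 1e-6
    r2_threshold: Optional[float] = 0.001
    r2_quantile: Optional[float] = None
    adjusted: bool = False
    k_predict: int = 10
    run_prediction: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            if not self.input_dir or not Path(self.input_dir).is_dir():
                raise ConfigurationError(
                    f"input directory missing: {self.input_dir!r}")
        if not 0 < self.completeness <= 1:
            raise ConfigurationError("completeness must lie in (0, 1]")
        if not 0 < self.corr_threshold <= 1:
            raise ConfigurationError("corr_threshold must lie in (0, 1]")
        if self.max_levels < 2:
            raise ConfigurationError("max_levels must be at least 2")
        if not 0 < self.p_threshold < 1:
            raise ConfigurationError("p_threshold must lie in (0, 1)")
        self.synth.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["planted_effects"] = [
            dataclasses.asdict(e) for e in self.synth.planted_effects]
        return _plainify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        from .synth import PlantedEffect

        effects = [PlantedEffect(**e)
                   for e in synth.pop("planted_effects", [])]
        for key in ("prevalence_range", "missing_rate_range",
                    "n_levels_range", "variable_presence_range",
                    "waves_per_country"):
            if key in synth and isinstance(synth[key], list):
                synth[key] = tuple(synth[key])
        cfg = cls(**d, synth=SyntheticConfig(planted_effects=effects,
                                             **synth))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _plainify(obj):
    """Coerce numpy scalars/tuples to YAML/JSON-friendly builtins."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed, kept below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage, writing artifacts and a manifest.

    Returns the run directory.  Any stage failure aborts with the stage
    name in the raised error.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: list[Path] = []

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                return False
        return _Timer()

    with stage("input"):
        if config.mode == "synthetic":
            synth_cfg = dataclasses.replace(
                config.synth, seed=_stage_seed(config.seed, "synth"))
            datasets, truth = generate_multisurvey(synth_cfg)
            datasets = inject_label_conflicts(
                datasets, synth_cfg.label_conflict_rate,
                _stage_seed(config.seed, "conflicts"))
            artifacts.append(sio.write_table(truth, out / "truth.csv"))
        else:
            datasets = sio.read_survey_dir(config.input_dir)
            truth = None
        if not datasets:
            raise ConfigurationError("no input surveys")

    with stage("harmonize"):
        datasets, harm_report = harmonize_surveys(datasets)
        p = out / "harmonization_report.json"
        p.write_text(json.dumps(harm_report, indent=1, sort_keys=True))
        artifacts.append(p)

    with stage("prepare"):
        datasets = [encode_variables(ds, config.max_levels)
                    for ds in datasets]
        datasets, varmeta, prune_log = prune_variables(
            datasets, config.corr_threshold, config.completeness)
        artifacts.append(sio.write_table(varmeta, out / "variables.csv"))
        (out / "pruning_log.txt").write_text("\n".join(prune_log) + "\n")

    with stage("assoc"):
        mode = "adjusted" if config.adjusted else "univariate"
        results = []
        for ds in datasets:
            results.extend(associate_survey(ds, mode))
        assoc_df = assoc_to_frame(results)
        artifacts.append(sio.write_table(assoc_df, out / "associations.csv"))

    with stage("meta"):
        pan = run_meta(assoc_df, scope="pan")
        country = run_meta(assoc_df, scope="country")
        assessed = countries_assessed(assoc_df)
        artifacts.append(sio.write_table(pan, out / "meta_pan.csv"))
        artifacts.append(sio.write_table(country, out / "meta_country.csv"))
        artifacts.append(sio.write_table(assessed, out / "assessed.csv"))

    with stage("discover"):
        discovery = identify_variables(
            pan, assessed, p_threshold=config.p_threshold,
            r2_threshold=config.r2_threshold,
            r2_quantile=config.r2_quantile, country_meta=country)
        artifacts.append(sio.write_table(discovery, out / "discovery.csv"))
        artifacts.append(sio.write_table(bin_and_summarize(discovery),
                                         out / "bin_summary.csv"))
        artifacts.append(sio.write_table(volcano_data(discovery),
                                         out / "volcano.csv"))

    if config.run_prediction:
        with stage("predict"):
            pred, lorenz = predict_all_countries(
                datasets, discovery, k=config.k_predict, lorenz_points=100)
            artifacts.append(sio.write_table(pred, out / "prediction.csv"))
            artifacts.append(sio.write_table(lorenz, out / "lorenz.csv"))

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seconds": timings,
        "artifacts": {p.name: _checksum(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return out


def make_report(run_dir: str | Path) -> dict:
    """Summarise a completed run directory into one report object.

    Emits per-sex identification counts, the country-count bin summary and
    (when the prediction stage ran) prediction score ranges; written to
    ``report.json`` in the run directory.
    """
    run_dir = Path(run_dir)
    required = ["manifest.json", "meta_pan.csv", "discovery.csv",
                "bin_summary.csv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run, missing: {missing}")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    discovery = pd.read_csv(run_dir / "discovery.csv")
    bins = pd.read_csv(run_dir / "bin_summary.csv")
    report: dict = {
        "seed": manifest["seed"],
        "n_meta_rows": int(len(discovery)),
        "identified": {
            sex: int(discovery[(discovery["sex"] == sex)
                               & discovery["identified"]].shape[0])
            for sex in sorted(discovery["sex"].unique())
        },
        "bin_summary": bins.to_dict(orient="records"),
    }
    if not any(discovery["identified"]):
        report["note"] = "no variables identified under the dual threshold"
    pred_path = run_dir / "prediction.csv"
    if pred_path.exists():
        pred = pd.read_csv(pred_path)
        if not pred.empty:
            report["prediction"] = {
                "n_models": int(len(pred)),
                "auc_median": float(pred["auc"].median()),
                "auc_range": [float(pred["auc"].min()),
                              float(pred["auc"].max())],
                "gini_range": [float(pred["gini"].min()),
                               float(pred["gini"].max())],
            }
        else:
            report["prediction"] = {"n_models": 0}
    else:
        report["note_prediction"] = "prediction stage was not run"
    (run_dir / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
    return report
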