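"""One-command pipeline: simulate -> fit -> validate -> stability.

Every stage writes its artifacts atomically (temp file, then rename) into
the output directory, and a manifest records the configuration, seeds,
package version and SHA-256 checksum of every artifact, so a rerun with
the same configuration reproduces the outputs bit for bit.  Wall-clock
timings live under the manifest's ``timings`` key, which is the only part
allowed to differ between identical reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import PipelineStageError
from .io import write_choice_data, write_utilities
from .models import HierarchicalBayesLogit
from .simulate import make_paper_like_dataset
from .stability import stability_report
from .validity import importance_table, validity_report


@dataclass
class PipelineConfig:
    """Settings for a full synthetic-panel run."""

    out_dir: str = "cbc_run"
    seed: int = 0
    preset: str = "paper-like"
    n_respondents: int = 241
    waves: int = 2
    lexicographic_fraction: float = 0.29
    heterogeneity_sd: float = 0.30
    drift_sd: float = 0.25
    dropout_rate: float = 0.17
    tasks: int = 12
    alternatives: int = 2
    holdout_positions: tuple[int, ...] = (5, 10)
    n_burn: int = 2000
    n_draws: int = 2000
    thin: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineStageError("config", f"unknown keys {sorted(unknown)}")
        if "holdout_positions" in raw:
            raw["holdout_positions"] = tuple(raw["holdout_positions"])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    checksums: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    notes: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    def comparable(self) -> dict:
        """Everything the determinism contract covers (timings excluded)."""
        d = dataclasses.asdict(self)
        d.pop("timings")
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    tmp.rename(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis on a synthetic panel and write all reports.

    Stages: simulate (panel + ground truth), fit (hierarchical Bayes per
    group per wave), validate (RLH / MAE / scale / lexicographic), and
    stability (kappa, Spearman, strong-preference persistence) — the last
    skipped with a notice when only one wave exists.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config), version=__version__, seed=config.seed
    )
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        panel = make_paper_like_dataset(
            seed=config.seed,
            n_respondents=config.n_respondents,
            waves=config.waves,
            lexicographic_fraction=config.lexicographic_fraction,
            heterogeneity_sd=config.heterogeneity_sd,
            drift_sd=config.drift_sd,
            dropout_rate=config.dropout_rate,
            t=config.tasks,
            a=config.alternatives,
            holdout_positions=config.holdout_positions,
        )
        schema = panel.schema
        schema.to_json(out / "schema.json")
        write_choice_data(panel.data, out / "panel.csv")
        panel.truth.to_csv(out / "ground_truth.csv", index=False)
        manifest.stages.append(stage)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "fit"
        t0 = time.perf_counter()
        posteriors, importances = {}, {}
        waves = sorted(panel.data["wave"].unique())
        for wave in waves:
            for gi, group in enumerate(sorted(panel.data["group"].unique())):
                sub = panel.data.query("wave == @wave and group == @group")
                if sub.empty:
                    continue
                est = HierarchicalBayesLogit(
                    schema=schema,
                    n_burn=config.n_burn,
                    n_draws=config.n_draws,
                    thin=config.thin,
                    seed=config.seed + 1000 * int(wave) + gi,
                ).fit(sub)
                posteriors[(group, wave)] = est.posterior_
                write_utilities(
                    est.individual_means_,
                    est.respondent_ids_,
                    schema,
                    out / f"utilities_{group}_T{wave}.csv",
                    wave=wave,
                    group=group,
                )
                imp = importance_table(
                    est.individual_means_, est.respondent_ids_, schema
                )
                imp["group"] = group
                importances.setdefault(wave, []).append(imp)
        _write_json(
            {
                f"{g}@T{w}": {
                    "population_mean": post.population_mean.tolist(),
                    "acceptance_rate": post.acceptance_rate,
                    "rhat": post.rhat,
                }
                for (g, w), post in posteriors.items()
            },
            out / "population.json",
        )
        manifest.stages.append(stage)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "validate"
        t0 = time.perf_counter()
        vreport = validity_report(
            posteriors, panel.data, schema, {h.task_id: h for h in panel.holdouts}
        )
        _write_json(vreport, out / "validity.json")
        manifest.stages.append(stage)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "stability"
        t0 = time.perf_counter()
        if len(waves) < 2:
            manifest.notes.append(
                "stability stage skipped: fewer than two waves in the data"
            )
        else:
            import pandas as pd

            w1, w2 = waves[0], waves[1]
            t1 = pd.concat(importances[w1], ignore_index=True)
            t2 = pd.concat(importances[w2], ignore_index=True)
            sreport = stability_report(t1, t2, schema)
            _write_json(sreport, out / "stability.json")
        manifest.stages.append(stage)
        manifest.timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        _write_json(dataclasses.asdict(manifest), out / "manifest.partial.json")
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc

    for f in sorted(out.iterdir()):
        if f.is_file() and not f.name.startswith("manifest"):
            manifest.checksums[f.name] = _sha256(f)
    _write_json(dataclasses.asdict(manifest), out / "manifest.json")
    return manifest
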