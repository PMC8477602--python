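"""End-to-end orchestration: simulate/ingest -> prepare -> fit -> report.

Every stage logs its row counts into the report bundle so a run is auditable,
and all randomness flows from the single seed in :class:`PipelineConfig`, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .diffstats import DEFAULT_LOGIT_FLOOR
from .models import (
    METHOD_FACTORS,
    fit_global_models,
    fit_method_models,
    fit_proportion_model,
    fit_within_study_model,
    fst_congruence_report,
    winnow_combos,
)
from .studydb import (
    average_per_comparison,
    read_database,
    to_model_rows,
    within_study_rows,
    write_database,
)
from .synthetic import DatabaseGenConfig, simulate_study_database

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """What to run and where to put it.

    Either ``database_path`` (a CSV to ingest, optionally through
    ``schema_map``) or ``generator`` (a synthetic-database config) supplies
    the input; if both are None a default generator seeded with ``seed``
    is used.
    """

    out_dir: str | Path
    database_path: Optional[str | Path] = None
    schema_map: Optional[Mapping[str, str]] = None
    generator: Optional[DatabaseGenConfig] = None
    floor: float = DEFAULT_LOGIT_FLOOR
    min_points: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.floor < 0.5):
            raise ValueError("floor must be in (0, 0.5)")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r}: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"pstfst_version": __version__, "seed": config.seed, "stages": {}}

    records = _stage("ingest")(_ingest)(config, out, log)
    model_rows, within_rows = _stage("prepare")(_prepare)(config, records, out, log)
    reports = _stage("fit")(_fit)(config, model_rows, within_rows, log)

    bundle = {"run_log": log, "reports": reports}
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle


def _ingest(config: PipelineConfig, out: Path, log: dict):
    if config.database_path is not None:
        result = read_database(config.database_path, schema_map=config.schema_map)
        records = result.records
        log["stages"]["ingest"] = {
            "source": str(config.database_path),
            "rows": len(records),
            "rejected": len(result.rejected),
        }
    else:
        gen = config.generator or DatabaseGenConfig(seed=config.seed)
        records = simulate_study_database(gen)
        log["stages"]["ingest"] = {
            "source": "synthetic",
            "generator": dataclasses.asdict(gen),
            "rows": len(records),
            "rejected": 0,
        }
    write_database(records, out / "database.csv")
    return records


def _prepare(config: PipelineConfig, records, out: Path, log: dict):
    comparisons = average_per_comparison(records)
    model_rows = to_model_rows(comparisons, floor=config.floor)
    within = within_study_rows(records, floor=config.floor)
    model_rows.to_csv(out / "model_rows.csv", index=False)
    within.to_csv(out / "within_rows.csv", index=False)
    log["stages"]["prepare"] = {
        "floor": config.floor,
        "comparisons": len(comparisons),
        "model_rows": len(model_rows),
        "within_rows": len(within),
    }
    return model_rows, within


def _fit(config: PipelineConfig, model_rows: pd.DataFrame, within_rows: pd.DataFrame, log: dict):
    reports: dict = {}
    reports["global"] = fit_global_models(model_rows).to_dict()
    reports["proportion"] = fit_proportion_model(model_rows).to_dict()

    methods: dict = {}
    for factor in METHOD_FACTORS:
        try:
            methods[factor] = fit_method_models(model_rows, factors=[factor])[factor].to_dict()
        except ValueError as exc:  # e.g. a single observed level in this database
            methods[factor] = {"error": str(exc)}
    reports["methods"] = methods

    winnowed, n_combos = winnow_combos(within_rows, min_points=config.min_points)
    if n_combos > 0:
        reports["within_study"] = fit_within_study_model(winnowed).to_dict()
    else:
        reports["within_study"] = {"n_combos": 0}

    try:
        reports["fst_congruence"] = fst_congruence_report(model_rows).to_dict()
    except ValueError as exc:
        reports["fst_congruence"] = {"error": str(exc)}

    log["stages"]["fit"] = {
        "min_points": config.min_points,
        "winnowed_rows": len(winnowed),
        "n_combos": n_combos,
    }
    return reports
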