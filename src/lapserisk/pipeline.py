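"""End-to-end pipeline: simulate → window → score → optimize → evaluate.

One JSON config drives every stage; all randomness descends from the
simulation master seed plus the evaluation seed, so re-running with the
manifest's config reproduces byte-identical outputs.  The manifest records
the config snapshot, seeds, per-stage record counts and SHA-256 digests of
every artifact (no wall-clock fields, so the manifest itself is
reproducible too).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .ema_model import CohortTable, read_cohort, write_cohort
from .lapse_windowing import WindowConfig, build_analysis_set
from .risk_scoring import RiskWeights, score_analysis_set
from .synthetic_cohort import SimConfig, generate_cohort
from .weight_search import Objective, SearchConfig, grid_search
from .evaluation import evaluate

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline",
           "read_analysis_csv"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "window", "score", "optimize", "evaluate")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


class EvaluateConfig(BaseModel):
    unweighted_cutoff: float = 3.0
    weighted_cutoff: float = 1.0
    unweighted_ge: bool = True
    weighted_ge: bool = False
    run_group_tests: bool = False
    group_method: str = "model"
    seed: int = 0


class SearchSection(BaseModel):
    weight_grid_ordinal: tuple[float, ...] = tuple(
        round(0.1 * k, 1) for k in range(11))
    weight_grid_binary: tuple[float, ...] = (0.0, 0.5, 1.0)
    objective: str = Objective.YOUDEN_MAX_OVER_CUTOFFS.value
    cutoff_grid: Optional[tuple[float, ...]] = None

    def to_search_config(self) -> SearchConfig:
        return SearchConfig(
            weight_grid_ordinal=self.weight_grid_ordinal,
            weight_grid_binary=self.weight_grid_binary,
            objective=Objective(self.objective),
            cutoff_grid=self.cutoff_grid)


class PipelineConfig(BaseModel):
    """JSON-serializable configuration of the full pipeline."""

    sim: SimConfig = Field(default_factory=SimConfig)
    window_hours: float = 4.0
    weights: Optional[dict] = None  # RiskWeights field overrides
    search: SearchSection = Field(default_factory=SearchSection)
    eval: EvaluateConfig = Field(default_factory=EvaluateConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())

    def risk_weights(self) -> RiskWeights:
        return RiskWeights(**(self.weights or {}))


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    master_seed: int
    eval_seed: int
    software_version: str
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_analysis_csv(path: str | Path) -> pd.DataFrame:
    """Read a labeled/scored stage CSV back with proper dtypes."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    for col in ("interacting_smoker", "alcohol_past_hour",
                "smoked_since_last"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map(
                lambda v: str(v).strip().lower() in ("true", "yes", "1"))
    return df


def run_pipeline(config: PipelineConfig | str | Path,
                 out_dir: str | Path) -> RunManifest:
    """Run every stage in order, writing all artifacts and a manifest.

    Artifacts under ``out_dir``: ema.csv + roster.csv (simulate),
    labeled.csv (window), scored.csv (score), search_result.json (optimize),
    eval_report.json (evaluate), manifest.json.  Any stage error raises
    :class:`PipelineError` naming the stage.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_json(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        config=json.loads(config.model_dump_json()),
        master_seed=config.sim.master_seed,
        eval_seed=config.eval.seed,
        software_version=__version__)

    def _stage(name, fn):
        try:
            info = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        manifest.stages.append({"name": name, **info})
        logger.info("stage %s: %s", name, info)

    state: dict = {}

    def _simulate():
        cohort = generate_cohort(config.sim)
        write_cohort(cohort, out / "ema.csv", out / "roster.csv")
        state["cohort"] = cohort
        return {"counts": {"participants": len(cohort.roster),
                           "records": len(cohort.ema)},
                "generator_meta": cohort.meta}

    def _window():
        labeled = build_analysis_set(
            state["cohort"], WindowConfig(config.window_hours))
        _write_stage_csv(labeled, out / "labeled.csv")
        state["labeled"] = labeled
        return {"counts": labeled.attrs.get("label_counts", {})}

    def _score():
        scored = score_analysis_set(state["labeled"],
                                    config.risk_weights())
        _write_stage_csv(scored, out / "scored.csv")
        state["scored"] = scored
        return {"counts": {"scored": len(scored)}}

    def _optimize():
        from .weight_search import positive_mask
        y = positive_mask(state["scored"])
        if len(y) == 0 or y.all() or not y.any():
            # nothing to optimize against; let evaluation report the
            # degenerate cohort
            logger.warning("optimize skipped: single proximity class")
            return {"skipped": "single_class", "counts": {"n_evaluated": 0}}
        result = grid_search(state["scored"],
                             config.search.to_search_config())
        payload = {
            "best_weights": dataclasses.asdict(result.best_weights),
            "best_cutoff": result.best_cutoff,
            "objective_value": result.objective_value,
            "n_evaluated": result.n_evaluated,
            "objective": config.search.objective,
        }
        (out / "search_result.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return {"counts": {"n_evaluated": result.n_evaluated}}

    def _evaluate():
        roster = state["cohort"].roster
        n_lapsers = int((roster["first_lapse_time"].notna()
                         & roster["consistent_reporting"]).sum())
        if n_lapsers == 0:
            raise ValueError("zero lapsers in cohort")
        ev = config.eval
        report = evaluate(
            state["scored"], state["cohort"].roster,
            unweighted_cutoff=ev.unweighted_cutoff,
            weighted_cutoff=ev.weighted_cutoff,
            unweighted_ge=ev.unweighted_ge, weighted_ge=ev.weighted_ge,
            run_group_tests=ev.run_group_tests,
            group_method=ev.group_method, seed=ev.seed)
        (out / "eval_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        return {"counts": report.class_counts}

    _stage("simulate", _simulate)
    _stage("window", _window)
    _stage("score", _score)
    _stage("optimize", _optimize)
    _stage("evaluate", _evaluate)

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.outputs[f.name] = _sha256(f)
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n")
    return manifest


def _write_stage_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = df.copy()
    if "timestamp" in tmp.columns:
        tmp["timestamp"] = tmp["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    tmp.to_csv(path, index=False)
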