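"""Pipeline orchestration: read -> align -> features -> cluster -> stats.

The stages are plain library calls; :func:`run_pipeline` wires them behind a
plain-text (YAML) run configuration with per-stage logging, and
:func:`analyze_cohort` is the in-memory equivalent for simulated cohorts.
All randomness flows from one root seed split per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .consensus import KSelection, assign_clusters, cluster_proportions, consensus_run, select_k, zscore
from .features import FEATURE_COLUMNS, extract_features
from .fictrac import read_trackball_log
from .simulate import CohortResult
from .stimuli import Schedule, schedule_from_yaml

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "analyze_cohort", "cohort_features"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Plain-text run configuration.

    ``t0`` may be a single number (all animals) or omitted when the metadata
    CSV carries a per-animal ``t0`` column.
    """

    input_dir: Path
    output_dir: Path
    schedule_file: Path
    metadata_file: Path | None = None
    dialect: str = "fictrac-v2"
    ball_diameter: float = 5.0
    frame_rate: float = 50.0
    t0: float | None = None
    k_range: tuple[int, ...] = tuple(range(2, 11))
    reps: int = 2000
    n_reference: int = 25
    item_frac: float = 0.9
    feature_frac: float = 0.8
    seed: int = 0
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["input_dir"] = Path(doc["input_dir"])
        doc["output_dir"] = Path(doc["output_dir"])
        doc["schedule_file"] = Path(doc["schedule_file"])
        if doc.get("metadata_file"):
            doc["metadata_file"] = Path(doc["metadata_file"])
        if "k_range" in doc:
            doc["k_range"] = tuple(doc["k_range"])
        return cls(**doc)


def _features_stage(config: RunConfig, schedule: Schedule, metadata: pd.DataFrame) -> pd.DataFrame:
    frames = []
    for row in metadata.itertuples():
        traj = read_trackball_log(
            Path(config.input_dir) / row.file,
            dialect=config.dialect,
            ball_diameter=config.ball_diameter,
            frame_rate=config.frame_rate,
        )
        t0 = float(getattr(row, "t0", config.t0) if hasattr(row, "t0") else config.t0)
        feats = extract_features(traj, schedule, t0, animal_id=row.animal_id)
        feats["treatment"] = row.treatment
        frames.append(feats)
    out = pd.concat(frames, ignore_index=True)
    logger.info("features: %d responses from %d animals", len(out), len(metadata))
    return out


def _cluster_stage(
    feature_table: pd.DataFrame,
    k_range,
    reps: int,
    n_reference: int,
    item_frac: float,
    feature_frac: float,
    seed: int,
    k_override: int | None = None,
) -> dict:
    complete = feature_table.dropna(subset=list(FEATURE_COLUMNS))
    n_excluded = len(feature_table) - len(complete)
    if n_excluded:
        logger.info("clustering: excluded %d responses with undefined features", n_excluded)
    Z = zscore(complete[list(FEATURE_COLUMNS)])
    selection = select_k(
        Z.to_numpy(),
        k_range=k_range,
        reps=reps,
        B=n_reference,
        item_frac=item_frac,
        feature_frac=feature_frac,
        seed=seed,
    )
    k = k_override or selection.chosen_k
    final_seed = np.random.SeedSequence(seed).spawn(1)[0]
    M = consensus_run(
        Z.to_numpy(), k, reps=reps, item_frac=item_frac, feature_frac=feature_frac, seed=final_seed
    )
    assignment = assign_clusters(M, k)
    proportions = cluster_proportions(assignment, complete[["treatment", "stimulus_label"]])
    return {
        "responses": complete.reset_index(drop=True),
        "zscored": Z,
        "selection": selection,
        "consensus_matrix": M,
        "assignment": assignment,
        "proportions": proportions,
        "n_excluded": n_excluded,
    }


def analyze_cohort(
    result: CohortResult,
    k_range=range(2, 11),
    reps: int = 200,
    n_reference: int = 25,
    item_frac: float = 0.9,
    feature_frac: float = 0.8,
    seed: int = 0,
    k_override: int | None = None,
) -> dict:
    """Features + consensus clustering for an in-memory simulated cohort.

    Returns the feature table (with planted archetype labels merged in for
    recovery checks), the k-selection report, consensus matrix, cluster
    assignment and per-(treatment, stimulus) proportions.
    """
    feats = cohort_features(result)
    out = _cluster_stage(feats, k_range, reps, n_reference, item_frac, feature_frac, seed, k_override)
    out["responses"] = out["responses"].merge(
        result.labels[["animal_id", "archetype"]], on="animal_id", how="left"
    )
    return out


def cohort_features(result: CohortResult) -> pd.DataFrame:
    """Extract the per-response feature table from a simulated cohort."""
    frames = []
    for row in result.metadata.itertuples():
        feats = extract_features(
            result.trajectories[row.animal_id], result.design.schedule, row.t0, animal_id=row.animal_id
        )
        feats["treatment"] = row.treatment
        frames.append(feats)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full file-based pipeline and write all outputs.

    Outputs under ``config.output_dir``: ``features.csv``,
    ``consensus_matrix.csv``, ``k_selection.json``, ``assignments.csv``,
    ``proportions.csv`` and ``run_report.json``.  Any stage failure raises
    :class:`PipelineStageError` naming the stage; outputs of completed
    stages are preserved.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    try:
        schedule = schedule_from_yaml(Path(config.schedule_file).read_text())
        meta_path = config.metadata_file or Path(config.input_dir) / "metadata.csv"
        metadata = pd.read_csv(meta_path)
        if len(metadata) == 0:
            raise ValueError("metadata lists no animals")
    except Exception as exc:
        raise PipelineStageError("read", exc) from exc

    try:
        feature_table = _features_stage(config, schedule, metadata)
        feature_table.to_csv(out_dir / "features.csv", index=False)
        report["n_responses"] = len(feature_table)
    except Exception as exc:
        raise PipelineStageError("features", exc) from exc

    try:
        clustered = _cluster_stage(
            feature_table,
            config.k_range,
            config.reps,
            config.n_reference,
            config.item_frac,
            config.feature_frac,
            config.seed,
        )
        np.savetxt(out_dir / "consensus_matrix.csv", clustered["consensus_matrix"], delimiter=",")
        (out_dir / "k_selection.json").write_text(
            json.dumps(
                {
                    "chosen_k": clustered["selection"].chosen_k,
                    "table": clustered["selection"].to_frame().to_dict(orient="records"),
                    "seed": config.seed,
                },
                indent=2,
            )
        )
        assigned = clustered["responses"][["animal_id", "treatment", "stimulus_label"]].copy()
        assigned["cluster"] = clustered["assignment"].labels
        assigned.to_csv(out_dir / "assignments.csv", index=False)
        clustered["proportions"].to_csv(out_dir / "proportions.csv", index=False)
        report["chosen_k"] = clustered["selection"].chosen_k
        report["n_excluded"] = clustered["n_excluded"]
    except Exception as exc:
        raise PipelineStageError("cluster", exc) from exc

    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    report["outputs"] = sorted(p.name for p in out_dir.iterdir())
    return report
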