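"""End-to-end orchestration: connectomes → gradients → metrics → grid.

`analyze_cohort` is the in-memory core (used by tests and the synthetic
recovery checks); `run_pipeline` is the disk-based entry point consuming the
layout written by `generate_cohort_files` and emitting TSV results plus a
run manifest with config hash, input checksums and stage timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .association import CorrelationGrid, run_grid, spearman
from .connectome import group_average
from .core_io import (
    ConnectivityMatrix,
    GradientSet,
    NetworkPartition,
    RunConfig,
    config_hash,
    read_matrix,
    read_participants,
    read_partition,
    write_gradients,
    write_matrix,
)
from .gradients import GradientEmbedding
from .seg_metrics import network_median_distance, segregation_report

__all__ = ["PipelineError", "RunManifest", "analyze_cohort",
           "median_distance_series", "recovered_rho", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    inputs: dict[str, str]
    stage_seconds: dict[str, float]
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)


@dataclass
class CohortResults:
    group_matrix: ConnectivityMatrix
    group_gradients: GradientSet
    subject_gradients: list[GradientSet]
    reports: pd.DataFrame
    grid: CorrelationGrid


def analyze_cohort(matrices: Sequence[ConnectivityMatrix],
                   partition: NetworkPartition,
                   participants: pd.DataFrame,
                   config: RunConfig | None = None,
                   keep_subject_gradients: bool = False) -> CohortResults:
    """Full analysis of an in-memory cohort.

    Stages: Fisher-z group average → group gradients → Procrustes-aligned
    individual gradients → per-subject segregation report → metric × trait
    correlation grid.
    """
    config = config or RunConfig()
    group = group_average(list(matrices))
    embedding = GradientEmbedding(
        n_gradients=config.n_gradients, sparsity=config.sparsity,
        kernel=config.kernel,
    ).fit(group.values)
    reports = []
    subject_gradients: list[GradientSet] = []
    for sid, m in zip(participants["subject_id"], matrices):
        gset = embedding.transform_set(m.values)
        if keep_subject_gradients:
            subject_gradients.append(gset)
        reports.append(segregation_report(gset, partition, config, subject_id=sid))
    report_df = pd.concat(reports, ignore_index=True)
    grid = run_grid(report_df, participants, alpha=config.alpha)
    return CohortResults(group_matrix=group, group_gradients=embedding.reference_,
                         subject_gradients=subject_gradients,
                         reports=report_df, grid=grid)


def median_distance_series(matrices: Sequence[ConnectivityMatrix],
                           partition: NetworkPartition,
                           net_a: str = "Vis", net_b: str = "Default",
                           config: RunConfig | None = None) -> np.ndarray:
    """Per-subject aligned visual–default median distance (light path).

    Runs only the embedding and the one metric — the workhorse for planted
    parameter-recovery simulations.
    """
    config = config or RunConfig()
    group = group_average(list(matrices))
    embedding = GradientEmbedding(
        n_gradients=config.n_gradients, sparsity=config.sparsity,
        kernel=config.kernel,
    ).fit(group.values)
    out = np.empty(len(matrices))
    for i, m in enumerate(matrices):
        gset = embedding.transform_set(m.values)
        out[i] = network_median_distance(gset, partition, net_a, net_b,
                                         signed=config.signed_median_distance)
    return out


def recovered_rho(cohort, config: RunConfig | None = None,
                  trait: str = "gsq_total") -> float:
    """Estimated Spearman between a trait and the visual–default separation."""
    distances = median_distance_series(cohort.matrices, cohort.partition,
                                       config=config)
    rho, _p = spearman(distances, cohort.participants[trait].to_numpy(float))
    return rho


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(data_dir: str | Path, out_dir: str | Path,
                 config: RunConfig | None = None) -> RunManifest:
    """Run the full pipeline on an on-disk cohort and write results.

    ``data_dir`` must hold matrices/sub-*.tsv, partition.tsv and
    participants.csv (the `generate-cohort` layout). Writes the group matrix
    and gradients, the tidy segregation report, the correlation grid and a
    manifest; results are bit-stable given fixed inputs and config.
    """
    config = config or RunConfig()
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc

        return _Timer()

    with stage("load"):
        partition = read_partition(data / "partition.tsv")
        participants = read_participants(data / "participants.csv")
        matrix_paths = sorted((data / "matrices").glob("*.tsv"))
        if len(matrix_paths) != len(participants):
            raise ValueError(
                f"{len(matrix_paths)} matrices for {len(participants)} subjects"
            )
        matrices = [
            read_matrix(p, expected_parcels=partition.n_parcels,
                        parcel_ids=partition.parcel_ids)
            for p in matrix_paths
        ]
        inputs = {p.name: _sha256(p) for p in
                  [data / "partition.tsv", data / "participants.csv"]}
        inputs["matrices"] = hashlib.sha256(
            "".join(_sha256(p) for p in matrix_paths).encode()).hexdigest()

    with stage("analyze"):
        results = analyze_cohort(matrices, partition, participants, config)

    with stage("write"):
        write_matrix(results.group_matrix, out / "group_matrix.tsv")
        write_gradients(results.group_gradients, out / "group_gradients.tsv")
        results.reports.to_csv(out / "segregation_report.tsv", sep="\t",
                               index=False, float_format="%.12g")
        results.grid.table.to_csv(out / "correlation_grid.tsv", sep="\t",
                                  index=False, float_format="%.12g")
    outputs = ["group_matrix.tsv", "group_gradients.tsv",
               "segregation_report.tsv", "correlation_grid.tsv"]
    manifest = RunManifest(config_hash=config_hash(config), seed=config.seed,
                           inputs=inputs, stage_seconds=timings,
                           outputs=outputs)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
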