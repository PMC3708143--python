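"""Readers, writers and the end-to-end analysis pipeline.

All artifacts are plain text: the burst trial table is comma-delimited with
a fixed header, cluster solutions are JSON, direct-component profiles and
comparison reports are CSV.  Floats are serialized with 6 significant
digits and all iteration orders are fixed, so repeated runs on the same
inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .burst_model import BurstObservation
from .clustering import (
    BurstStatistics,
    Cluster,
    ClusterSolution,
    PooledStats,
    assign_constrained,
    cluster_bursts,
    cluster_two_stage,
    screen_outliers,
    summarize_burst,
)
from .compare import compare_conditions, compare_solutions
from .errors import SchemaError
from .geometry import DC_GRID, derive_direct_component, evaluate_dc
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

BURST_COLUMNS = ("animal_id", "muscle", "burst_label", "condition",
                 "cycle_index", "onset", "offset", "magnitude")

FLOAT_FMT = "%.6g"


def read_burst_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a burst trial table.

    Rows violating the burst invariants are rejected with row-numbered
    messages; a missing column raises a schema error.  Magnitude may be
    empty (absent).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "muscle": str,
                                  "burst_label": str, "condition": str})
    missing = [c for c in BURST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    bad: list[str] = []
    for i, row in df.iterrows():
        try:
            BurstObservation(
                animal_id=row["animal_id"], muscle=row["muscle"],
                burst_label=row["burst_label"], condition=row["condition"],
                cycle_index=int(row["cycle_index"]),
                onset=float(row["onset"]), offset=float(row["offset"]),
                magnitude=None if pd.isna(row["magnitude"]) else float(row["magnitude"]),
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path.name} row {i + 2}: unparsable value ({exc})")
        except Exception as exc:  # invariant violations
            bad.append(f"row {i + 2}: {exc}")
    if bad:
        raise SchemaError(f"{path.name}: invalid rows\n" + "\n".join(bad))
    return df[list(BURST_COLUMNS)]


def write_burst_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy().sort_values(
        ["condition", "burst_label", "cycle_index"], kind="mergesort"
    )
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


def summarize_condition(
    df: pd.DataFrame,
    condition: str,
    screen: bool = True,
    margin: float = 2.0,
) -> tuple[list[BurstStatistics], int]:
    """Per-burst phase statistics for one condition, after outlier screening.

    Returns ``(stats sorted by label, total trials removed)``.
    """
    sub = df[df["condition"] == condition]
    stats: list[BurstStatistics] = []
    removed_total = 0
    for label in sorted(sub["burst_label"].unique()):
        pts = sub[sub["burst_label"] == label][["onset", "offset"]].to_numpy()
        if screen:
            pts, removed = screen_outliers(pts, margin=margin)
            removed_total += removed
        stats.append(summarize_burst(label, pts))
    return stats, removed_total


# ---------------------------------------------------------------------------
# cluster solution JSON


def solution_to_dict(solution: ClusterSolution) -> dict:
    return {
        "mode": solution.mode,
        "absent_labels": list(solution.absent_labels),
        "clusters": [
            {
                "id": c.id,
                "members": list(c.members),
                "centroid": [round(c.centroid[0], 9), round(c.centroid[1], 9)],
                "pooled": {
                    "X": round(c.pooled.x, 9), "sX": round(c.pooled.sx, 9),
                    "Y": round(c.pooled.y, 9), "sY": round(c.pooled.sy, 9),
                    "rho": round(c.pooled.rho, 9), "n": c.pooled.n,
                },
            }
            for c in solution.clusters
        ],
    }


def write_solution(solution: ClusterSolution, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(solution_to_dict(solution), indent=2, sort_keys=True) + "\n"
    )


def read_solution(path: str | Path) -> ClusterSolution:
    data = json.loads(Path(path).read_text())
    clusters = tuple(
        Cluster(
            id=int(c["id"]),
            members=tuple(c["members"]),
            centroid=(float(c["centroid"][0]), float(c["centroid"][1])),
            pooled=PooledStats(
                x=float(c["pooled"]["X"]), sx=float(c["pooled"]["sX"]),
                y=float(c["pooled"]["Y"]), sy=float(c["pooled"]["sY"]),
                rho=float(c["pooled"]["rho"]), n=int(c["pooled"]["n"]),
            ),
        )
        for c in data["clusters"]
    )
    return ClusterSolution(
        clusters=clusters,
        mode=data.get("mode", "unconstrained"),
        absent_labels=tuple(data.get("absent_labels", ())),
    )


# ---------------------------------------------------------------------------
# DC / report output


def write_dc_profiles(
    solutions: dict[str, ClusterSolution],
    path: str | Path,
    mode: str = "squared",
    scales: dict[str, dict[int, float]] | None = None,
) -> None:
    """Write direct-component activation profiles on the standard grid.

    One ``phase`` column plus one column ``u<id>_<condition>`` per cluster
    per condition, optionally amplitude-scaled per condition and cluster.
    """
    cols: dict[str, np.ndarray] = {"phase": DC_GRID}
    for cond in sorted(solutions):
        sol = solutions[cond]
        for c in sol.clusters:
            dc = derive_direct_component(c.pooled, cluster_id=c.id)
            values = evaluate_dc(dc, DC_GRID, mode=mode)
            if scales and cond in scales and c.id in scales[cond]:
                values = values * scales[cond][c.id]
            cols[f"u{c.id}_{cond}"] = values
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end analysis run."""

    input_path: str
    output_dir: str
    conditions: tuple[str, ...] = ("unobstructed", "lead", "trail")
    control: str = "unobstructed"
    constrain: bool = True
    reference_path: str | None = None  # reuse an existing control solution
    outlier_margin: float = 2.0
    dc_mode: str = "squared"  # or "literal"
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected key: value pairs")
        if "conditions" in data and isinstance(data["conditions"], str):
            data["conditions"] = tuple(
                s.strip() for s in data["conditions"].split(",") if s.strip()
            )
        elif "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)


@dataclass
class PipelineResult:
    solutions: dict[str, ClusterSolution]
    report: pd.DataFrame
    magnitude_table: pd.DataFrame
    mapping_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_outliers_removed: int = 0
    artifacts: dict[str, Path] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Screen -> summarize -> cluster -> (constrain) -> DCA -> compare.

    Writes ``clusters_<condition>.json``, ``dc.csv``, ``report.csv``,
    ``magnitude.csv`` and (in constrained mode) ``mapping_<condition>.csv``
    into the output directory.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = read_burst_table(cfg.input_path)
    if df.empty:
        raise SchemaError(f"{cfg.input_path}: no observations")
    logger.info("read %d trial rows, %d bursts", len(df),
                df["burst_label"].nunique())

    total_removed = 0
    stats: dict[str, list[BurstStatistics]] = {}
    for cond in cfg.conditions:
        s, removed = summarize_condition(df, cond, margin=cfg.outlier_margin)
        if not s:
            raise SchemaError(f"no observations for condition {cond!r}")
        stats[cond] = s
        total_removed += removed
    logger.info("outlier screen removed %d trial(s)", total_removed)

    # control solution: two-stage over animals when several are present
    if cfg.reference_path:
        control_solution = read_solution(cfg.reference_path)
    else:
        control_solution = _cluster_condition(df, stats[cfg.control], cfg.control)
    logger.info("control condition: %d clusters", len(control_solution.clusters))

    solutions: dict[str, ClusterSolution] = {cfg.control: control_solution}
    mapping_tables: dict[str, pd.DataFrame] = {}
    for cond in cfg.conditions:
        if cond == cfg.control:
            continue
        if cfg.constrain:
            solutions[cond] = assign_constrained(stats[cond], control_solution)
            unconstrained = _cluster_condition(df, stats[cond], cond)
            mapping_tables[cond] = compare_solutions(solutions[cond], unconstrained)
        else:
            solutions[cond] = _cluster_condition(df, stats[cond], cond)

    report, magnitude_table = compare_conditions(
        df, control_solution, conditions=cfg.conditions, control=cfg.control)

    # per-condition, per-cluster amplitude scales from magnitude percentages
    scales: dict[str, dict[int, float]] = {}
    for cond in cfg.conditions:
        if cond == cfg.control or magnitude_table.empty:
            continue
        sub = magnitude_table[magnitude_table["condition"] == cond]
        per_cluster = sub.groupby("synergy_id")["percent_of_control"].mean()
        scales[cond] = {
            int(cid): (float(pct) / 100.0 if np.isfinite(pct) else 1.0)
            for cid, pct in per_cluster.items()
        }

    artifacts: dict[str, Path] = {}
    for cond, sol in solutions.items():
        p = out / f"clusters_{cond}.json"
        write_solution(sol, p)
        artifacts[f"clusters_{cond}"] = p
    write_dc_profiles(solutions, out / "dc.csv", mode=cfg.dc_mode, scales=scales)
    artifacts["dc"] = out / "dc.csv"
    write_report(report, out / "report.csv")
    artifacts["report"] = out / "report.csv"
    write_report(magnitude_table, out / "magnitude.csv")
    artifacts["magnitude"] = out / "magnitude.csv"
    for cond, table in mapping_tables.items():
        p = out / f"mapping_{cond}.csv"
        write_report(table, p)
        artifacts[f"mapping_{cond}"] = p

    return PipelineResult(
        solutions=solutions, report=report, magnitude_table=magnitude_table,
        mapping_tables=mapping_tables, n_outliers_removed=total_removed,
        artifacts=artifacts,
    )


def _cluster_condition(
    df: pd.DataFrame, stats: Sequence[BurstStatistics], condition: str
) -> ClusterSolution:
    """Unconstrained clustering, two-stage when several animals contribute.

    The animal with the most bursts (ties: most trials, then name) forms
    the stage-1 subset; the remaining animals' bursts join in stage 2.
    """
    sub = df[df["condition"] == condition]
    per_animal = (
        sub.groupby("animal_id")["burst_label"].nunique().sort_values()
    )
    if len(per_animal) <= 1:
        return cluster_bursts(stats)
    counts = sub.groupby("animal_id").size()
    primary_animal = max(
        per_animal.index,
        key=lambda a: (per_animal[a], int(counts[a]), a),
    )
    primary_labels = set(sub[sub["animal_id"] == primary_animal]["burst_label"])
    primary = [s for s in stats if s.label in primary_labels]
    additional = [s for s in stats if s.label not in primary_labels]
    return cluster_two_stage(primary, additional)
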