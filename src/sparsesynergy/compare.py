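"""Phase and magnitude comparison of synergies across locomotor conditions.

For each constrained synergy the per-trial onset, offset, peak phase
((onset + offset)/2) and duration-normalized magnitude are pooled across
all member muscle bursts and compared across conditions with one-way
ANOVAs; condition pairs are compared with Welch two-sample t-tests.  Burst
magnitudes are expressed as a percentage of the unobstructed control
(100%); a synergy-level scale (mean member percentage / 100) rescales the
direct components so that phase and magnitude changes can be displayed
together.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clustering import ClusterSolution, centroid_distance
from .geometry import DirectComponent

logger = logging.getLogger(__name__)


def peak_phase(onset, offset):
    """Peak phase of a burst: midpoint of onset and offset."""
    return (np.asarray(onset) + np.asarray(offset)) / 2.0


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from between/within sums of squares.

    Degenerate limits are defined explicitly: all values identical gives
    F = 0, p = 1; zero within-group variance with unequal means gives
    F = inf, p = 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = float(np.concatenate(gs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(gs, means)))
    df1 = len(gs) - 1
    df2 = int(ns.sum()) - len(gs)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0)
        return AnovaResult(F=math.inf, df1=df1, df2=df2, p=0.0)
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p)


def pairwise_t(group_a: np.ndarray, group_b: np.ndarray) -> TTestResult:
    """Welch two-sample t-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    if se2 == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return TTestResult(t=t, df=float(a.size + b.size - 2), p=0.0)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Optional Bonferroni adjustment for the pairwise tests."""
    k = len(p_values)
    return [min(1.0, p * k) for p in p_values]


def magnitude_percent(condition_values: np.ndarray,
                      control_values: np.ndarray) -> float:
    """Mean condition magnitude as a percentage of the control mean.

    Undefined (raises) when the control mean is not positive — bursts
    inactive during unobstructed locomotion have no control baseline.
    """
    cond = np.asarray(condition_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if ctrl.size == 0 or ctrl.mean() <= 0:
        raise ValueError("control magnitude undefined (absent or zero-mean burst)")
    return float(100.0 * cond.mean() / ctrl.mean())


@dataclass(frozen=True)
class ScaledDC:
    """A direct component rescaled by a condition's mean magnitude change."""

    base: DirectComponent
    condition: str
    scale: float


def scale_dc(dc: DirectComponent, member_percentages: Mapping[str, float | None],
             condition: str = "") -> ScaledDC:
    """Scale a DC by the mean member magnitude percentage / 100.

    Members without a defined control percentage (novel bursts) are
    excluded; if none is defined the scale defaults to 1 with a warning.
    """
    defined = [p for p in member_percentages.values() if p is not None]
    if not defined:
        logger.warning("no member with defined control magnitude; scale := 1")
        scale = 1.0
    else:
        scale = float(np.mean(defined)) / 100.0
    return ScaledDC(base=dc, condition=condition, scale=scale)


def compare_solutions(constrained: ClusterSolution,
                      unconstrained: ClusterSolution) -> pd.DataFrame:
    """Map constrained clusters onto the unconstrained clusters they overlap.

    One row per (constrained cluster, unconstrained cluster sharing at
    least one member), with the Euclidean distance between their centroids;
    identical memberships give distance 0.
    """
    rows = []
    for c in constrained.clusters:
        cset = set(c.members)
        for u in unconstrained.clusters:
            shared = sorted(cset & set(u.members))
            if not shared:
                continue
            rows.append({
                "constrained_id": c.id,
                "constrained_members": ";".join(c.members),
                "unconstrained_id": u.id,
                "unconstrained_members": ";".join(u.members),
                "shared_members": ";".join(shared),
                "centroid_distance": centroid_distance(c, u),
            })
    return pd.DataFrame(rows, columns=[
        "constrained_id", "constrained_members", "unconstrained_id",
        "unconstrained_members", "shared_members", "centroid_distance",
    ])


MEASURES = ("onset", "offset", "peak", "magnitude")


def _measure_values(df: pd.DataFrame, measure: str) -> pd.Series:
    if measure == "peak":
        return (df["onset"] + df["offset"]) / 2.0
    return df[measure]


def compare_conditions(
    bursts: pd.DataFrame,
    reference: ClusterSolution,
    conditions: Sequence[str] = ("unobstructed", "lead", "trail"),
    control: str = "unobstructed",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-synergy condition statistics over a burst trial table.

    ``bursts`` must carry columns burst_label, condition, onset, offset and
    (optionally) magnitude.  For every synergy of the reference solution and
    every measure the function pools the per-trial values of all member
    bursts per condition, runs a one-way ANOVA across conditions and Welch
    t-tests for each condition pair.

    Returns ``(report, magnitude_table)``: the report has one row per
    (synergy, measure, condition) with the group summary and test results;
    the magnitude table has one row per (burst, non-control condition) with
    the percentage of control (NaN when the burst is absent from control).
    """
    report_rows = []
    for cluster in reference.clusters:
        sub = bursts[bursts["burst_label"].isin(cluster.members)]
        for measure in MEASURES:
            if measure == "magnitude" and (
                "magnitude" not in sub.columns or sub["magnitude"].isna().all()
            ):
                continue
            groups = {}
            for cond in conditions:
                vals = _measure_values(sub[sub["condition"] == cond], measure)
                vals = vals.dropna().to_numpy()
                if vals.size >= 2:
                    groups[cond] = vals
            anova = None
            if len(groups) >= 2:
                anova = one_way_anova(list(groups.values()))
            pair_p = {}
            for i, ca in enumerate(conditions):
                for cb in conditions[i + 1:]:
                    if ca in groups and cb in groups:
                        pair_p[f"{ca}-{cb}"] = pairwise_t(groups[ca], groups[cb]).p
            for cond in conditions:
                if cond not in groups:
                    continue
                vals = groups[cond]
                row = {
                    "synergy_id": cluster.id,
                    "measure": measure,
                    "condition": cond,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "n": int(vals.size),
                    "F": anova.F if anova else np.nan,
                    "p": anova.p if anova else np.nan,
                }
                for pair, p in pair_p.items():
                    row[f"p_{pair}"] = p
                report_rows.append(row)

    mag_rows = []
    if "magnitude" in bursts.columns:
        for cluster in reference.clusters:
            for label in cluster.members:
                sub = bursts[bursts["burst_label"] == label]
                ctrl = sub[sub["condition"] == control]["magnitude"].dropna()
                for cond in conditions:
                    if cond == control:
                        continue
                    vals = sub[sub["condition"] == cond]["magnitude"].dropna()
                    if vals.empty:
                        continue
                    if ctrl.empty or ctrl.mean() <= 0:
                        pct = np.nan  # inactive in control: change not displayable
                    else:
                        pct = magnitude_percent(vals.to_numpy(), ctrl.to_numpy())
                    mag_rows.append({
                        "synergy_id": cluster.id,
                        "burst_label": label,
                        "condition": cond,
                        "percent_of_control": pct,
                        "n": int(vals.size),
                    })
    report = pd.DataFrame(report_rows)
    magnitude_table = pd.DataFrame(mag_rows, columns=[
        "synergy_id", "burst_label", "condition", "percent_of_control", "n",
    ])
    return report, magnitude_table
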