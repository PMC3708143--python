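"""Synthetic locomotor burst data with planted sparse-synergy structure.

The generator emulates the statistical structure of marked EMG bursts
during treadmill locomotion: K clusters of bursts whose (onset, offset)
trials scatter as correlated bivariate normals in the unit-normalized step
cycle, 1-7 muscle bursts per cluster, 30-70 trials per burst,
condition-specific phase shifts (pre-swing advances in the trail condition,
post-swing delays in the lead condition) and magnitude gains, and
supplementary bursts present only during gait modifications.  Per-trial
magnitudes are lognormal around baseline x gain so they stay positive.

The packaged :func:`figure2_config` plants 10 clusters over 27 bursts from
18 muscles — 8 clusters in swing, 2 in stance — with ascending onsets and
phase-plane SDs of 0.02-0.045 cycle, and is the fixture for all
integration tests.  :func:`jitter_experiment` re-runs the clustering after
displacing every burst centroid by a random vector of bounded norm and
reports how often the cluster composition is unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import BurstStatistics, ClusterSolution, cluster_bursts
from .burst_model import EnvelopeTrace
from .errors import ConfigurationError

Vec = tuple[float, float]


@dataclass(frozen=True)
class ClusterSpec:
    """One planted cluster: centroid, scatter, members and condition effects."""

    centroid: Vec  # (mean onset, mean offset) phase
    sd: Vec  # (sigma_x, sigma_y) phase
    rho: float
    members: tuple[str, ...]  # burst labels, 1-7 of them
    shifts: Mapping[str, Vec] = field(default_factory=dict)  # condition -> (dX, dY)
    gains: Mapping[str, float] = field(default_factory=dict)  # condition -> gain
    burst_shifts: Mapping[str, Mapping[str, Vec]] = field(default_factory=dict)

    def validate(self) -> None:
        x, y = self.centroid
        if not x < y:
            raise ConfigurationError(f"centroid: onset {x} >= offset {y}")
        if self.sd[0] < 0 or self.sd[1] < 0:
            raise ConfigurationError("sd: negative standard deviation")
        if not -1.0 < self.rho < 1.0:
            raise ConfigurationError(f"rho: {self.rho} outside (-1, 1)")
        if not 1 <= len(self.members) <= 7:
            raise ConfigurationError(
                f"members: {len(self.members)} bursts (expected 1-7)"
            )
        for cond, g in self.gains.items():
            if g <= 0:
                raise ConfigurationError(f"gains[{cond}]: {g} <= 0")


@dataclass(frozen=True)
class NovelBurstSpec:
    """A burst present only in some gait-modification condition(s)."""

    label: str
    conditions: tuple[str, ...]
    centroid: Vec
    sd: Vec
    rho: float = 0.0
    associated_cluster: int | None = None  # intended home cluster (ground truth)

    def validate(self) -> None:
        if not self.centroid[0] < self.centroid[1]:
            raise ConfigurationError(f"{self.label}: onset >= offset")
        if not self.conditions:
            raise ConfigurationError(f"{self.label}: no conditions listed")


@dataclass(frozen=True)
class SynthConfig:
    """Full generator configuration; defaults mirror the study conditions."""

    clusters: tuple[ClusterSpec, ...]
    novel_bursts: tuple[NovelBurstSpec, ...] = ()
    conditions: tuple[str, ...] = ("unobstructed", "lead", "trail")
    n_trials_range: tuple[int, int] = (30, 70)
    muscle_offset_bound: float = 0.005  # delta: per-muscle centroid offset (phase)
    magnitude_cv: float = 0.2  # lognormal coefficient of variation
    baseline_range: tuple[float, float] = (0.5, 2.0)
    animal_id: str = "synthcat1"

    def validate(self) -> None:
        if not self.clusters:
            raise ConfigurationError("clusters: empty")
        for spec in self.clusters:
            spec.validate()
        for nb in self.novel_bursts:
            nb.validate()
        lo, hi = self.n_trials_range
        if not 2 <= lo <= hi:
            raise ConfigurationError(f"n_trials_range: ({lo}, {hi}) invalid")
        if self.muscle_offset_bound < 0:
            raise ConfigurationError("muscle_offset_bound: negative")
        if self.magnitude_cv < 0:
            raise ConfigurationError("magnitude_cv: negative")
        labels = [m for c in self.clusters for m in c.members]
        labels += [nb.label for nb in self.novel_bursts]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate burst labels across clusters")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: partition, per-condition shifts and gains."""

    partition: Mapping[str, int]  # burst label -> cluster id (base bursts)
    novel: Mapping[str, int | None]  # novel label -> intended cluster id
    shifts: Mapping[int, Mapping[str, Vec]]
    gains: Mapping[int, Mapping[str, float]]


def figure2_config() -> SynthConfig:
    """The packaged 10-cluster / 27-burst fixture.

    Eight clusters fall in the swing phase (onsets ascending from -0.14 to
    0.39 cycle) and two in stance; adjacent centroid separations of
    0.10-0.28 cycle against SDs of 0.02-0.04 make the planted partition
    recoverable at 30-70 trials per burst.  The trail condition advances
    the pre-swing clusters (1-3) and boosts the magnitude of clusters 2-3
    (up to 4x); the lead condition delays the post-swing clusters (7-8) and
    doubles the magnitude of the elbow/limb-transport clusters (4-5).  Two
    supplementary bursts, AcD(3) and Tri(2), appear only in the trail
    condition near clusters 1 and 3.
    """
    c = ClusterSpec
    clusters = (
        c(centroid=(-0.14, 0.00), sd=(0.02, 0.02), rho=0.3, members=("Bic(1)",),
          shifts={"trail": (-0.06, -0.05)}),
        c(centroid=(-0.06, 0.10), sd=(0.02, 0.02), rho=0.3,
          members=("EDC(1)", "AcD(1)", "TrM(1)", "LtD(1)"),
          shifts={"trail": (-0.05, -0.05)}, gains={"trail": 4.0}),
        c(centroid=(0.02, 0.16), sd=(0.02, 0.02), rho=0.3,
          members=("BrR(1)", "PrT(1)", "SpD(1)"),
          shifts={"trail": (-0.04, -0.03)}, gains={"trail": 2.5}),
        c(centroid=(0.09, 0.24), sd=(0.02, 0.02), rho=0.3, members=("Br(1)",),
          gains={"lead": 2.0}),
        c(centroid=(0.16, 0.33), sd=(0.02, 0.02), rho=0.3,
          members=("Bic(2)", "ClB(1)", "ClT(1)"), gains={"lead": 2.0}),
        c(centroid=(0.24, 0.40), sd=(0.02, 0.02), rho=0.3, members=("LvS(1)",)),
        c(centroid=(0.31, 0.48), sd=(0.02, 0.02), rho=0.3, members=("ECR(1)",),
          shifts={"lead": (0.04, 0.05)}),
        c(centroid=(0.39, 0.57), sd=(0.02, 0.02), rho=0.3,
          members=("Bic(3)", "EDC(2)", "PrT(2)", "TrM(2)", "LtD(2)", "SpD(2)"),
          shifts={"lead": (0.04, 0.04)}),
        c(centroid=(0.59, 0.76), sd=(0.03, 0.03), rho=0.3, members=("SpD(3)",)),
        c(centroid=(0.66, 0.92), sd=(0.04, 0.04), rho=0.3,
          members=("ECU(1)", "PaL(1)", "SSp(1)", "TriL(1)", "Tri(1)", "AcD(2)")),
    )
    novel = (
        NovelBurstSpec(label="AcD(3)", conditions=("trail",),
                       centroid=(-0.21, -0.06), sd=(0.02, 0.02), rho=0.3,
                       associated_cluster=1),
        NovelBurstSpec(label="Tri(2)", conditions=("trail",),
                       centroid=(-0.01, 0.14), sd=(0.02, 0.02), rho=0.3,
                       associated_cluster=3),
    )
    return SynthConfig(clusters=clusters, novel_bursts=novel)


def _muscle_of(label: str) -> str:
    return label.split("(")[0]


def _draw_bivariate(rng: np.random.Generator, mean: Vec, sd: Vec, rho: float,
                    n: int) -> np.ndarray:
    """Correlated bivariate normal via the Cholesky-style transform.

    Handles zero SDs exactly (degenerate point mass).  Trials violating
    offset > onset (possible only many SDs out) are redrawn.
    """
    out = np.empty((n, 2))
    need = np.ones(n, dtype=bool)
    while need.any():
        k = int(need.sum())
        z1 = rng.standard_normal(k)
        z2 = rng.standard_normal(k)
        x = mean[0] + sd[0] * z1
        y = mean[1] + sd[1] * (rho * z1 + math.sqrt(1.0 - rho**2) * z2)
        out[need, 0] = x
        out[need, 1] = y
        need = out[:, 1] <= out[:, 0]
    return out


def _draw_magnitudes(rng: np.random.Generator, mean_mag: float, cv: float,
                     n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean_mag)
    slog = math.sqrt(math.log(1.0 + cv**2))
    return mean_mag * rng.lognormal(mean=-0.5 * slog**2, sigma=slog, size=n)


def generate_burst_dataset(
    cfg: SynthConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a full burst trial table and its ground truth.

    Every burst gets a fixed per-muscle centroid offset (uniform in a disk
    of radius ``muscle_offset_bound``), a trial count drawn from
    ``n_trials_range``, and per condition ``n`` (onset, offset) trials from
    the correlated bivariate normal centred at
    centroid + offset + condition shift, with lognormal magnitudes around
    baseline x gain.  Bit-for-bit reproducible from (cfg, seed).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    lo, hi = cfg.n_trials_range
    rows: list[dict] = []
    partition: dict[str, int] = {}
    shifts: dict[int, dict[str, Vec]] = {}
    gains: dict[int, dict[str, float]] = {}

    for cid, spec in enumerate(cfg.clusters, start=1):
        shifts[cid] = dict(spec.shifts)
        gains[cid] = dict(spec.gains)
        for label in spec.members:
            partition[label] = cid
            n = int(rng.integers(lo, hi + 1))
            angle = rng.uniform(0.0, 2.0 * math.pi)
            radius = cfg.muscle_offset_bound * math.sqrt(rng.uniform())
            off = (radius * math.cos(angle), radius * math.sin(angle))
            baseline = rng.uniform(*cfg.baseline_range)
            for cond in cfg.conditions:
                dx, dy = spec.shifts.get(cond, (0.0, 0.0))
                bx, by = spec.burst_shifts.get(label, {}).get(cond, (0.0, 0.0))
                mean = (spec.centroid[0] + off[0] + dx + bx,
                        spec.centroid[1] + off[1] + dy + by)
                trials = _draw_bivariate(rng, mean, spec.sd, spec.rho, n)
                mags = _draw_magnitudes(
                    rng, baseline * spec.gains.get(cond, 1.0),
                    cfg.magnitude_cv, n)
                for k in range(n):
                    rows.append({
                        "animal_id": cfg.animal_id,
                        "muscle": _muscle_of(label),
                        "burst_label": label,
                        "condition": cond,
                        "cycle_index": k + 1,
                        "onset": trials[k, 0],
                        "offset": trials[k, 1],
                        "magnitude": mags[k],
                    })

    novel: dict[str, int | None] = {}
    for nb in cfg.novel_bursts:
        novel[nb.label] = nb.associated_cluster
        n = int(rng.integers(lo, hi + 1))
        baseline = rng.uniform(*cfg.baseline_range)
        for cond in nb.conditions:
            trials = _draw_bivariate(rng, nb.centroid, nb.sd, nb.rho, n)
            mags = _draw_magnitudes(rng, baseline, cfg.magnitude_cv, n)
            for k in range(n):
                rows.append({
                    "animal_id": cfg.animal_id,
                    "muscle": _muscle_of(nb.label),
                    "burst_label": nb.label,
                    "condition": cond,
                    "cycle_index": k + 1,
                    "onset": trials[k, 0],
                    "offset": trials[k, 1],
                    "magnitude": mags[k],
                })

    df = pd.DataFrame(rows, columns=[
        "animal_id", "muscle", "burst_label", "condition", "cycle_index",
        "onset", "offset", "magnitude",
    ])
    truth = GroundTruth(partition=partition, novel=novel,
                        shifts=shifts, gains=gains)
    return df, truth


# ---------------------------------------------------------------------------
# envelope traces


def generate_envelope_traces(
    cfg: SynthConfig,
    cycles: int,
    seed: int,
    condition: str = "unobstructed",
    cycle_duration_ms: int = 1000,
    noise_level: float = 0.05,
) -> tuple[dict[str, EnvelopeTrace], pd.DataFrame, np.ndarray]:
    """1-kHz rectified-envelope traces with half-cosine bursts.

    Each burst window (from the planted phases, at the given condition's
    shift) carries a half-cosine bump scaled so the within-burst 1-ms-bin
    mean equals the planted magnitude (gain x 1.0); outside bursts the trace
    is uniform noise below ``noise_level`` of the largest burst amplitude.

    Returns ``(traces by muscle, bounds table, reference onsets in ms)``.
    The bounds table carries muscle, onset_ms, offset_ms and the planted
    magnitude for round-trip checks.
    """
    cfg.validate()
    if cycle_duration_ms < 500:
        raise ConfigurationError("cycle duration must be >= 500 ms")
    rng = np.random.default_rng(seed)
    lead_in = cycle_duration_ms // 2
    total = lead_in + cycles * cycle_duration_ms + cycle_duration_ms // 2
    markers = lead_in + cycle_duration_ms * np.arange(cycles + 1, dtype=float)

    per_muscle: dict[str, list[tuple[int, int, float, str]]] = {}
    specs: list[tuple[str, Vec, float]] = []
    for cid, spec in enumerate(cfg.clusters, start=1):
        dx, dy = spec.shifts.get(condition, (0.0, 0.0))
        mag = spec.gains.get(condition, 1.0)
        for label in spec.members:
            specs.append((label, (spec.centroid[0] + dx, spec.centroid[1] + dy), mag))
    for nb in cfg.novel_bursts:
        if condition in nb.conditions:
            specs.append((nb.label, nb.centroid, 1.0))

    for label, (x, y), mag in specs:
        muscle = _muscle_of(label)
        for k in range(cycles):
            start = markers[k]
            on = int(round(start + x * cycle_duration_ms))
            off = int(round(start + y * cycle_duration_ms))
            if not 0 <= on < off <= total:
                continue
            per_muscle.setdefault(muscle, []).append((on, off, mag, label))

    traces: dict[str, EnvelopeTrace] = {}
    bound_rows = []
    for muscle in sorted(per_muscle):
        bounds = sorted(per_muscle[muscle])
        for (a0, a1, _, la), (b0, b1, _, lb) in zip(bounds, bounds[1:]):
            if b0 < a1:
                raise ConfigurationError(
                    f"{muscle}: bursts {la} and {lb} overlap in the trace"
                )
        samples = np.zeros(total)
        max_amp = 0.0
        for on, off, mag, label in bounds:
            i = np.arange(on, off)
            bump = np.sin(math.pi * (i - on + 0.5) / (off - on))
            bump *= mag / bump.mean()  # exact within-burst mean == mag
            samples[on:off] = bump
            max_amp = max(max_amp, float(bump.max()))
        if noise_level > 0:
            noise = rng.uniform(0.0, noise_level * max_amp, size=total)
            mask = np.ones(total, dtype=bool)
            for on, off, _, _ in bounds:
                mask[on:off] = False
            samples[mask] = noise[mask]
        traces[muscle] = EnvelopeTrace(
            muscle=muscle, samples=samples,
            burst_bounds=[(on, off) for on, off, _, _ in bounds])
        for on, off, mag, label in bounds:
            bound_rows.append({"muscle": muscle, "burst_label": label,
                               "onset_ms": on, "offset_ms": off,
                               "magnitude": mag})
    bounds_df = pd.DataFrame(bound_rows, columns=[
        "muscle", "burst_label", "onset_ms", "offset_ms", "magnitude"])
    return traces, bounds_df, markers


# ---------------------------------------------------------------------------
# jitter robustness


def jitter_experiment(
    reference_stats: Sequence[BurstStatistics],
    jitter_bound_sd: float,
    reps: int,
    seed: int,
    reference_solution: ClusterSolution | None = None,
) -> tuple[float, list[bool]]:
    """Stability of the clustering under bounded centroid jitter.

    Each repetition displaces every burst centroid by an independent random
    vector drawn uniformly from the disk of radius
    ``jitter_bound_sd x ||(sigma_x, sigma_y)||`` (that burst's SD
    magnitude), re-runs the unconstrained clustering, and compares the
    resulting partition with the reference partition.

    Returns ``(fraction of reps with unchanged composition, per-rep flags)``.
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    if jitter_bound_sd < 0:
        raise ConfigurationError("jitter bound must be >= 0")
    stats = sorted(reference_stats, key=lambda s: s.label)
    if reference_solution is None:
        reference_solution = cluster_bursts(stats)
    ref_sets = reference_solution.label_sets()
    rng = np.random.default_rng(seed)
    unchanged: list[bool] = []
    for _ in range(reps):
        jittered = []
        for s in stats:
            r = jitter_bound_sd * math.hypot(s.sx, s.sy) * math.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2.0 * math.pi)
            jittered.append(BurstStatistics(
                label=s.label,
                x=s.x + r * math.cos(ang),
                y=s.y + r * math.sin(ang),
                sx=s.sx, sy=s.sy, rho=s.rho, n=s.n,
            ))
        sol = cluster_bursts(jittered)
        unchanged.append(sol.label_sets() == ref_sets)
    return float(np.mean(unchanged)), unchanged


def adjusted_rand(partition_a: Mapping[str, int],
                  partition_b: Mapping[str, int]) -> float:
    """Adjusted Rand index between two labelings over their common keys."""
    from sklearn.metrics import adjusted_rand_score

    keys = sorted(set(partition_a) & set(partition_b))
    if not keys:
        raise ValueError("partitions share no labels")
    return float(adjusted_rand_score(
        [partition_a[k] for k in keys], [partition_b[k] for k in keys]))
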