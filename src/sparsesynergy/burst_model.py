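"""Burst data model, step-cycle phase normalization, and burst magnitudes.

A *burst* is one continuous period of rectified-EMG activity of a muscle
within a step cycle.  The step cycle is delimited by successive onsets of a
reference muscle (e.g. brachialis, Br) and normalized to unity, so every
event time maps to a dimensionless *phase*: phase 0 at the reference onset,
positive phases after it, negative phases before it.  Phase is treated as a
linear (non-circular) coordinate; all observed bursts live in roughly
(-0.5, 1.5).

Burst *magnitude* is the mean rectified amplitude per 1-ms bin over the
marked burst window, i.e. the integral of the envelope divided by burst
duration, which makes it invariant to changes in burst duration.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidBurstError, InvalidCycleError

logger = logging.getLogger(__name__)

#: canonical locomotor conditions; free-form strings are also accepted so
#: that obstacle types (cylindrical, high, ...) can act as conditions.
CONDITIONS = ("unobstructed", "lead", "trail")


@dataclass(frozen=True)
class BurstObservation:
    """One trial's (onset, offset, magnitude) for a named muscle burst.

    ``burst_label`` combines muscle and occurrence index, e.g. ``"Bic(1)"``
    for the first biceps burst of the cycle.  Phases are fractions of the
    step cycle; magnitude is mean rectified amplitude per ms (arbitrary
    units) and may be absent.
    """

    animal_id: str
    muscle: str
    burst_label: str
    condition: str
    cycle_index: int
    onset: float
    offset: float
    magnitude: float | None = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise InvalidBurstError(
                f"{self.burst_label}: offset {self.offset} <= onset {self.onset}"
            )
        if not -1.0 < self.onset < 1.0:
            raise InvalidBurstError(
                f"{self.burst_label}: onset phase {self.onset} outside (-1, 1)"
            )
        if not self.offset - self.onset < 1.0:
            raise InvalidBurstError(
                f"{self.burst_label}: duration {self.offset - self.onset} >= 1 cycle"
            )
        if self.magnitude is not None and self.magnitude < 0:
            raise InvalidBurstError(
                f"{self.burst_label}: negative magnitude {self.magnitude}"
            )


@dataclass(frozen=True)
class CycleMarkers:
    """Onset times (ms) of the reference muscle delimiting step cycles."""

    reference_muscle: str
    reference_onsets: tuple[float, ...]

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.reference_onsets)
        object.__setattr__(self, "reference_onsets", onsets)
        if len(onsets) < 2:
            raise InvalidCycleError("need >= 2 reference onsets to define a cycle")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InvalidCycleError("reference onsets must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.reference_onsets) - 1

    def cycle(self, k: int) -> tuple[float, float]:
        """(start, end) times in ms of cycle ``k`` (0-based)."""
        return self.reference_onsets[k], self.reference_onsets[k + 1]


@dataclass
class EnvelopeTrace:
    """A 1-kHz rectified-EMG envelope with marked burst boundaries.

    ``samples[i]`` is the mean rectified amplitude of the 1-ms bin starting
    at ``i`` ms; ``burst_bounds`` are half-open ``(onset_ms, offset_ms)``
    windows in the same time base.
    """

    muscle: str
    samples: np.ndarray
    burst_bounds: list[tuple[int, int]] = field(default_factory=list)
    sampling_interval_ms: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidBurstError("envelope samples must be one-dimensional")
        if np.any(self.samples < 0):
            raise InvalidBurstError("envelope samples must be non-negative")
        for on, off in self.burst_bounds:
            if not 0 <= on < off <= self.samples.size:
                raise InvalidBurstError(
                    f"{self.muscle}: burst bound ({on}, {off}) outside trace"
                )


def normalize_event_phase(event_time: float, cycle_start: float, cycle_end: float) -> float:
    """Map an event time (ms) to a phase of the step cycle.

    The cycle ``[cycle_start, cycle_end)`` is normalized to unit length with
    phase 0 at ``cycle_start``; events before the cycle start get negative
    phases.
    """
    duration = cycle_end - cycle_start
    if duration <= 0:
        raise InvalidCycleError(
            f"cycle duration {duration} ms is not positive"
        )
    return (event_time - cycle_start) / duration


def _majority_reconcile(
    per_cycle: dict[int, list[tuple[float, float]]],
) -> dict[int, list[int]]:
    """Occurrence indices per cycle for one muscle, reconciled across cycles.

    Within each cycle bursts are indexed by ascending onset.  Cycles with
    fewer bursts than the muscle's modal count are re-indexed by matching
    each burst to the nearest median onset of the full-count cycles, so that
    e.g. a cycle missing the first of two habitual bursts still labels its
    lone burst as occurrence 2.
    """
    counts = [len(v) for v in per_cycle.values()]
    modal = max(set(counts), key=lambda c: (counts.count(c), c))
    # median onset of each occurrence slot, over cycles with the modal count
    full = [sorted(v) for v in per_cycle.values() if len(v) == modal]
    if full:
        slot_onsets = [float(np.median([c[i][0] for c in full])) for i in range(modal)]
    else:
        slot_onsets = []

    out: dict[int, list[int]] = {}
    for cyc, bursts in per_cycle.items():
        order = sorted(range(len(bursts)), key=lambda i: bursts[i][0])
        indices = [0] * len(bursts)
        if len(bursts) == modal or not slot_onsets or len(bursts) > modal:
            for rank, i in enumerate(order):
                indices[i] = rank + 1
        else:
            # greedy nearest-slot matching, in onset order
            free = list(range(modal))
            for i in order:
                best = min(free, key=lambda s: abs(bursts[i][0] - slot_onsets[s]))
                indices[i] = best + 1
                free.remove(best)
        out[cyc] = indices
    return out


def assign_bursts_to_cycles(
    bursts: Sequence[tuple[str, float, float]],
    markers: CycleMarkers,
    condition: str,
    animal_id: str,
    magnitudes: Sequence[float | None] | None = None,
) -> tuple[list[BurstObservation], int]:
    """Assign raw (muscle, onset_ms, offset_ms) bursts to step cycles.

    A burst belongs to cycle ``k`` when its onset falls in the half-open
    window ``[start_k - 0.5*dur_k, end_k - 0.5*dur_k)``, so pre-reference
    bursts receive onset phases in [-0.5, 0.5) relative to that cycle's
    start.  Bursts outside every window are dropped and counted.

    Returns ``(observations, n_dropped)``.
    """
    if magnitudes is None:
        magnitudes = [None] * len(bursts)
    staged: dict[str, dict[int, list[tuple[float, float]]]] = defaultdict(dict)
    mags: dict[tuple[str, int, float], float | None] = {}
    n_dropped = 0
    for (muscle, on_ms, off_ms), mag in zip(bursts, magnitudes):
        assigned = None
        for k in range(markers.n_cycles):
            start, end = markers.cycle(k)
            half = 0.5 * (end - start)
            if start - half <= on_ms < end - half:
                assigned = k
                break
        if assigned is None:
            n_dropped += 1
            continue
        start, end = markers.cycle(assigned)
        on = normalize_event_phase(on_ms, start, end)
        off = normalize_event_phase(off_ms, start, end)
        staged[muscle].setdefault(assigned, []).append((on, off))
        mags[(muscle, assigned, on)] = mag
    if n_dropped:
        logger.warning("%d burst(s) fell outside all cycle windows and were dropped",
                       n_dropped)

    observations: list[BurstObservation] = []
    for muscle in sorted(staged):
        indices = _majority_reconcile(staged[muscle])
        for cyc in sorted(staged[muscle]):
            for (on, off), idx in zip(staged[muscle][cyc], indices[cyc]):
                observations.append(
                    BurstObservation(
                        animal_id=animal_id,
                        muscle=muscle,
                        burst_label=f"{muscle}({idx})",
                        condition=condition,
                        cycle_index=cyc,
                        onset=on,
                        offset=off,
                        magnitude=mags[(muscle, cyc, on)],
                    )
                )
    return observations, n_dropped


def compute_burst_magnitude(trace: EnvelopeTrace, bound_index: int) -> float:
    """Duration-normalized magnitude of one marked burst.

    Sums the 1-ms bins over the half-open window ``[onset_ms, offset_ms)``
    and divides by the duration in ms — i.e. the mean of the in-burst
    samples, independent of burst duration for a constant envelope.
    """
    on, off = trace.burst_bounds[bound_index]
    duration = off - on
    if duration < 1:
        raise InvalidBurstError(
            f"{trace.muscle}: burst ({on}, {off}) has zero length"
        )
    return float(np.sum(trace.samples[on:off]) / duration)
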