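"""Phase-level attributes: occurrence, transitions, durations.

Phase occurrence is counted in frames, phase transitions in occurrences
(one per boundary between consecutive distinct runs), and surgery duration
in frames.  Virtual START/END endpoints record how surgeries begin and end.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Hashable, Iterable, Sequence

import pandas as pd

from splitaudit.config import (
    END,
    START,
    DatasetConfig,
    SetLabel,
    SplitAssignment,
    Surgery,
)

__all__ = [
    "Direction",
    "Transition",
    "PhaseCounts",
    "TransitionCounts",
    "DurationStats",
    "run_length_encode",
    "make_transition",
    "extract_transitions",
    "aggregate_phase_counts",
    "aggregate_transition_counts",
    "per_phase_instrument_counts",
    "surgery_durations",
]


class Direction(str, Enum):
    FORWARD = "forward"
    BACKWARD = "backward"
    BOUNDARY = "boundary"  # involves a START/END sentinel


@dataclass(frozen=True)
class Transition:
    """A directed boundary between two phase runs (or a sentinel endpoint)."""

    source: str
    target: str
    direction: Direction

    @property
    def is_sentinel(self) -> bool:
        return self.source == START or self.target == END

    def __str__(self) -> str:
        return f"{self.source}->{self.target}"


def make_transition(source: str, target: str, config: DatasetConfig) -> Transition:
    """Build a transition, classifying its direction by conceptual order."""
    if source == START or target == END:
        return Transition(source, target, Direction.BOUNDARY)
    if source == target:
        raise ValueError(f"self-transition {source!r} cannot occur")
    if config.phase_order(target) > config.phase_order(source):
        direction = Direction.FORWARD
    else:
        direction = Direction.BACKWARD
    return Transition(source, target, direction)


def run_length_encode(seq: Sequence[Hashable]) -> list[tuple[Hashable, int]]:
    """Collapse a sequence into (value, run length) pairs.

    Adjacent runs always carry distinct values; concatenating the runs
    reproduces the input.
    """
    if len(seq) == 0:
        raise ValueError("cannot run-length encode an empty sequence")
    runs: list[tuple[Hashable, int]] = []
    current = seq[0]
    length = 1
    for value in seq[1:]:
        if value == current:
            length += 1
        else:
            runs.append((current, length))
            current, length = value, 1
    runs.append((current, length))
    return runs


def extract_transitions(surgery: Surgery, config: DatasetConfig) -> list[Transition]:
    """All transition occurrences of one surgery, sentinels included.

    A surgery with R runs yields R - 1 internal transitions plus
    START->first and last->END, i.e. R + 1 occurrences in total.
    """
    if surgery.phases is None:
        raise ValueError(f"surgery {surgery.surgery_id!r} has no phase labels")
    runs = run_length_encode(surgery.phases)
    phases = [p for p, _ in runs]
    out = [make_transition(START, phases[0], config)]
    for a, b in zip(phases, phases[1:]):
        out.append(make_transition(a, b, config))
    out.append(make_transition(phases[-1], END, config))
    return out


def _check_assigned(surgeries: Iterable[Surgery], split: SplitAssignment) -> None:
    for s in surgeries:
        if s.surgery_id not in split:
            raise KeyError(f"surgery {s.surgery_id!r} is not assigned to any set")


@dataclass
class PhaseCounts:
    """Per-(phase, set) frame counts and per-phase surgery counts."""

    frames: dict[tuple[str, SetLabel], int]
    surgeries: dict[str, int]
    phases: tuple[str, ...]

    def frame_count(self, phase: str, set_label: SetLabel) -> int:
        return self.frames.get((phase, set_label), 0)

    def surgery_count(self, phase: str) -> int:
        return self.surgeries.get(phase, 0)

    def total(self, phase: str) -> int:
        return sum(self.frames.get((phase, s), 0) for s in SetLabel)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"phase": p, "set": s.value, "frames": c}
            for (p, s), c in sorted(self.frames.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
        ]
        return pd.DataFrame(rows, columns=["phase", "set", "frames"])


@dataclass
class TransitionCounts:
    """Per-(transition, set) occurrence counts."""

    occurrences: dict[tuple[Transition, SetLabel], int]

    def count(self, transition: Transition, set_label: SetLabel) -> int:
        return self.occurrences.get((transition, set_label), 0)

    def transitions(self) -> list[Transition]:
        seen = {t for t, _ in self.occurrences}
        return sorted(seen, key=lambda t: (t.source, t.target))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": t.source,
                "target": t.target,
                "direction": t.direction.value,
                "set": s.value,
                "occurrences": c,
            }
            for (t, s), c in sorted(
                self.occurrences.items(),
                key=lambda kv: (kv[0][0].source, kv[0][0].target, kv[0][1].value),
            )
        ]
        return pd.DataFrame(
            rows, columns=["source", "target", "direction", "set", "occurrences"]
        )


def aggregate_phase_counts(
    surgeries: Iterable[Surgery], split: SplitAssignment, config: DatasetConfig
) -> PhaseCounts:
    """Sum frames per phase per set; count surgeries containing each phase."""
    surgeries = [s for s in surgeries if s.has_phases]
    _check_assigned(surgeries, split)
    frames: Counter = Counter()
    per_surgery_phases: dict[str, int] = defaultdict(int)
    for s in surgeries:
        set_label = split.set_of(s.surgery_id)
        for phase, n in Counter(s.phases).items():
            frames[(phase, set_label)] += n
        for phase in set(s.phases):
            per_surgery_phases[phase] += 1
    return PhaseCounts(
        frames=dict(frames),
        surgeries=dict(per_surgery_phases),
        phases=config.analysis_phases,
    )


def aggregate_transition_counts(
    surgeries: Iterable[Surgery], split: SplitAssignment, config: DatasetConfig
) -> TransitionCounts:
    """Count transition occurrences per set, sentinels included."""
    surgeries = [s for s in surgeries if s.has_phases]
    _check_assigned(surgeries, split)
    occ: Counter = Counter()
    for s in surgeries:
        set_label = split.set_of(s.surgery_id)
        for t in extract_transitions(s, config):
            occ[(t, set_label)] += 1
    return TransitionCounts(occurrences=dict(occ))


def per_phase_instrument_counts(
    surgeries: Iterable[Surgery], split: SplitAssignment, config: DatasetConfig
) -> dict[tuple[str, str, SetLabel], int]:
    """Frames per (phase, instrument, set) where the instrument is visible.

    Surgeries lacking either annotation stream are skipped; the counts
    therefore cover exactly the doubly-annotated frames.
    """
    surgeries = [s for s in surgeries if s.has_phases and s.has_instruments]
    _check_assigned(surgeries, split)
    counts: Counter = Counter()
    for s in surgeries:
        set_label = split.set_of(s.surgery_id)
        assert s.phases is not None and s.instruments is not None
        for phase, vec in zip(s.phases, s.instruments):
            for i, bit in enumerate(vec):
                if bit:
                    counts[(phase, config.instruments[i], set_label)] += 1
    return dict(counts)


@dataclass
class DurationStats:
    """Per-surgery frame counts plus per-set means (None for empty sets)."""

    durations: dict[str, int]
    by_set: dict[SetLabel, dict[str, int]] = field(default_factory=dict)
    means: dict[SetLabel, float | None] = field(default_factory=dict)


def surgery_durations(
    surgeries: Iterable[Surgery], split: SplitAssignment
) -> DurationStats:
    surgeries = list(surgeries)
    _check_assigned(surgeries, split)
    durations = {s.surgery_id: s.duration for s in surgeries}
    by_set: dict[SetLabel, dict[str, int]] = {label: {} for label in SetLabel}
    for s in surgeries:
        by_set[split.set_of(s.surgery_id)][s.surgery_id] = s.duration
    means: dict[SetLabel, float | None] = {}
    for label in SetLabel:
        vals = by_set[label]
        means[label] = (sum(vals.values()) / len(vals)) if vals else None
    return DurationStats(durations=durations, by_set=by_set, means=means)
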