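"""Split auditing: unrepresented attributes, re-assignment, greedy repair.

An *attribute* is a phase, a phase transition (sentinels included), an
individual instrument, or an exact-set instrument combination.  An attribute
is *unrepresented* in a set when it occurs somewhere in the dataset but has
zero count in that (non-empty) set.  Empty sets (e.g. a missing validation
set) are excluded from flagging.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from splitaudit import instrument_stats, workflow_stats
from splitaudit.config import (
    DatasetConfig,
    SetLabel,
    SplitAssignment,
    Surgery,
    sorted_surgeries,
)
from splitaudit.instrument_stats import classify_frame, combination_label
from splitaudit.workflow_stats import Direction, Transition, extract_transitions

__all__ = [
    "AttributeKind",
    "AttributeKey",
    "AuditReport",
    "SetTotals",
    "audit",
    "compute_attribute_counts",
    "find_unrepresented",
    "summarize_unrepresented",
    "per_set_totals",
    "reassign",
    "greedy_improve",
    "ReassignResult",
    "GreedyResult",
]

SCHEMA_VERSION = 1


class AttributeKind(str, Enum):
    PHASE = "phase"
    TRANSITION = "transition"
    INSTRUMENT = "instrument"
    COMBINATION = "combination"


@dataclass(frozen=True)
class AttributeKey:
    """Identity of one audited attribute.

    Payloads by kind: PHASE/INSTRUMENT -> label string; TRANSITION ->
    :class:`~splitaudit.workflow_stats.Transition`; COMBINATION -> tuple of
    instrument labels in config order.
    """

    kind: AttributeKind
    payload: "str | Transition | tuple[str, ...]"

    def __post_init__(self) -> None:
        if self.kind is AttributeKind.TRANSITION:
            if not isinstance(self.payload, Transition):
                raise TypeError("TRANSITION payload must be a Transition")
        elif self.kind is AttributeKind.COMBINATION:
            if not isinstance(self.payload, tuple):
                raise TypeError("COMBINATION payload must be a tuple of labels")
        elif not isinstance(self.payload, str):
            raise TypeError(f"{self.kind.value} payload must be a string")

    @property
    def is_sentinel_transition(self) -> bool:
        return (
            self.kind is AttributeKind.TRANSITION
            and isinstance(self.payload, Transition)
            and self.payload.is_sentinel
        )

    def describe(self) -> str:
        if self.kind is AttributeKind.TRANSITION:
            return str(self.payload)
        if self.kind is AttributeKind.COMBINATION:
            return "+".join(self.payload)
        return str(self.payload)

    def _sort_key(self) -> tuple:
        return (self.kind.value, self.describe())


def surgery_attribute_counts(
    surgery: Surgery, config: DatasetConfig, semantics: str = "exact"
) -> Counter:
    """Attribute occurrence counter of one surgery (frames or occurrences)."""
    counts: Counter = Counter()
    if surgery.phases is not None:
        for phase, n in Counter(surgery.phases).items():
            counts[AttributeKey(AttributeKind.PHASE, phase)] += n
        for t in extract_transitions(surgery, config):
            counts[AttributeKey(AttributeKind.TRANSITION, t)] += 1
    if surgery.instruments is not None:
        for vec in surgery.instruments:
            cls, visible = classify_frame(vec)
            for i in visible:
                counts[
                    AttributeKey(AttributeKind.INSTRUMENT, config.instruments[i])
                ] += 1
            if len(visible) >= 2:
                labels = tuple(config.instruments[i] for i in visible)
                counts[AttributeKey(AttributeKind.COMBINATION, labels)] += 1
                if semantics == "subset":
                    from itertools import combinations as _subsets

                    for k in range(2, len(visible)):
                        for sub in _subsets(visible, k):
                            sub_labels = tuple(config.instruments[i] for i in sub)
                            counts[
                                AttributeKey(AttributeKind.COMBINATION, sub_labels)
                            ] += 1
    return counts


def compute_attribute_counts(
    surgeries: Iterable[Surgery],
    split: SplitAssignment,
    config: DatasetConfig,
    semantics: str = "exact",
) -> dict[AttributeKey, dict[SetLabel, int]]:
    """Per-attribute per-set counts, built from the stats modules."""
    surgeries = list(surgeries)
    out: dict[AttributeKey, dict[SetLabel, int]] = {}

    def _put(key: AttributeKey, set_label: SetLabel, n: int) -> None:
        if n:
            out.setdefault(key, {})[set_label] = out.setdefault(key, {}).get(set_label, 0) + n

    pc = workflow_stats.aggregate_phase_counts(surgeries, split, config)
    for (phase, set_label), n in pc.frames.items():
        _put(AttributeKey(AttributeKind.PHASE, phase), set_label, n)
    tc = workflow_stats.aggregate_transition_counts(surgeries, split, config)
    for (t, set_label), n in tc.occurrences.items():
        _put(AttributeKey(AttributeKind.TRANSITION, t), set_label, n)
    ic = instrument_stats.aggregate_instrument_counts(surgeries, split, config)
    for (instr, set_label), n in ic.frames.items():
        _put(AttributeKey(AttributeKind.INSTRUMENT, instr), set_label, n)
    cc = instrument_stats.aggregate_combination_counts(
        surgeries, split, config, semantics=semantics
    )
    for (combo, set_label), n in cc.combinations.items():
        labels = tuple(config.instruments[i] for i in combo)
        _put(AttributeKey(AttributeKind.COMBINATION, labels), set_label, n)
    return out


def find_unrepresented(
    attribute_counts: Mapping[AttributeKey, Mapping[SetLabel, int]],
    split: SplitAssignment,
) -> dict[AttributeKey, frozenset[SetLabel]]:
    """Attributes with zero count in at least one non-empty set.

    An attribute absent everywhere (global count 0) is never flagged; such
    keys cannot appear in ``attribute_counts`` built by this package, and
    are ignored defensively if supplied.
    """
    audited_sets = split.nonempty_sets()
    flagged: dict[AttributeKey, frozenset[SetLabel]] = {}
    for key, counts in attribute_counts.items():
        if sum(counts.values()) == 0:
            continue
        absent = frozenset(s for s in audited_sets if counts.get(s, 0) == 0)
        if absent:
            flagged[key] = absent
    return flagged


@dataclass(frozen=True)
class SetTotals:
    surgeries: int
    frames: int
    mean_duration: float | None


def per_set_totals(
    surgeries: Iterable[Surgery], split: SplitAssignment
) -> dict[SetLabel, SetTotals]:
    """(#surgeries, #frames, mean duration) per set; empty set -> (0, 0, None)."""
    stats = workflow_stats.surgery_durations(surgeries, split)
    out: dict[SetLabel, SetTotals] = {}
    for label in SetLabel:
        vals = stats.by_set[label]
        out[label] = SetTotals(
            surgeries=len(vals),
            frames=sum(vals.values()),
            mean_duration=stats.means[label],
        )
    return out


#: Summary rows: sentinel transitions get their own sub-row because the
#: original tabulation convention for them is unknown.
SUMMARY_ROWS = (
    "phase",
    "transition",
    "transition_sentinel",
    "instrument",
    "combination",
)

_ROW_OF_KIND = {
    AttributeKind.PHASE: "phase",
    AttributeKind.INSTRUMENT: "instrument",
    AttributeKind.COMBINATION: "combination",
}


def _summary_row(key: AttributeKey) -> str:
    if key.kind is AttributeKind.TRANSITION:
        return "transition_sentinel" if key.is_sentinel_transition else "transition"
    return _ROW_OF_KIND[key.kind]


@dataclass
class AuditReport:
    """Full audit of one split: counts, flags, summary matrix, totals."""

    dataset: str
    semantics: str
    audited_sets: tuple[SetLabel, ...]
    attributes: dict[AttributeKey, dict[SetLabel, int]]
    absent_in: dict[AttributeKey, frozenset[SetLabel]]
    totals: dict[SetLabel, SetTotals]
    kinds_available: frozenset[AttributeKind]
    split: SplitAssignment
    schema_version: int = SCHEMA_VERSION

    def summary(self) -> dict[str, dict[SetLabel, int | None]]:
        """Matrix: per (summary row, set), number of attributes absent there.

        Rows whose attribute kind has no data in this dataset are ``None``
        (N/A) across all sets.
        """
        matrix: dict[str, dict[SetLabel, int | None]] = {}
        row_available = {
            "phase": AttributeKind.PHASE in self.kinds_available,
            "transition": AttributeKind.TRANSITION in self.kinds_available,
            "transition_sentinel": AttributeKind.TRANSITION in self.kinds_available,
            "instrument": AttributeKind.INSTRUMENT in self.kinds_available,
            "combination": AttributeKind.COMBINATION in self.kinds_available,
        }
        for row in SUMMARY_ROWS:
            if not row_available[row]:
                matrix[row] = {s: None for s in self.audited_sets}
                continue
            matrix[row] = {s: 0 for s in self.audited_sets}
        for key, absent in self.absent_in.items():
            row = _summary_row(key)
            for s in absent:
                if s in matrix[row] and matrix[row][s] is not None:
                    matrix[row][s] += 1  # type: ignore[operator]
        return matrix

    def flag_pairs(self) -> frozenset[tuple[AttributeKey, SetLabel]]:
        return frozenset(
            (key, s) for key, absent in self.absent_in.items() for s in absent
        )

    def objective(self, weights: Mapping[AttributeKind, float] | None = None) -> float:
        """Weighted number of (attribute, set) unrepresented flags."""
        w = dict.fromkeys(AttributeKind, 1.0)
        if weights:
            w.update(weights)
        return sum(w[key.kind] * len(absent) for key, absent in self.absent_in.items())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        attrs = []
        for key in sorted(self.attributes, key=AttributeKey._sort_key):
            counts = self.attributes[key]
            entry: dict = {"kind": key.kind.value}
            if key.kind is AttributeKind.TRANSITION:
                t = key.payload
                assert isinstance(t, Transition)
                entry.update(
                    source=t.source, target=t.target, direction=t.direction.value
                )
            elif key.kind is AttributeKind.COMBINATION:
                entry["instruments"] = list(key.payload)
            else:
                entry["label"] = key.payload
            entry["counts"] = {s.value: counts.get(s, 0) for s in self.audited_sets}
            entry["absent_in"] = sorted(
                s.value for s in self.absent_in.get(key, frozenset())
            )
            attrs.append(entry)
        return {
            "schema_version": self.schema_version,
            "dataset": self.dataset,
            "semantics": self.semantics,
            "audited_sets": [s.value for s in self.audited_sets],
            "split": self.split.to_lists(),
            "totals": {
                s.value: {
                    "surgeries": t.surgeries,
                    "frames": t.frames,
                    "mean_duration": t.mean_duration,
                }
                for s, t in self.totals.items()
            },
            "kinds_available": sorted(k.value for k in self.kinds_available),
            "attributes": attrs,
            "summary": {
                row: {s.value: v for s, v in cells.items()}
                for row, cells in self.summary().items()
            },
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: Mapping) -> "AuditReport":
        split = SplitAssignment.from_lists(
            data["split"].get("train", ()),
            data["split"].get("val", ()),
            data["split"].get("test", ()),
        )
        audited = tuple(SetLabel(s) for s in data["audited_sets"])
        attributes: dict[AttributeKey, dict[SetLabel, int]] = {}
        absent: dict[AttributeKey, frozenset[SetLabel]] = {}
        for entry in data["attributes"]:
            kind = AttributeKind(entry["kind"])
            if kind is AttributeKind.TRANSITION:
                payload: "str | Transition | tuple[str, ...]" = Transition(
                    entry["source"], entry["target"], Direction(entry["direction"])
                )
            elif kind is AttributeKind.COMBINATION:
                payload = tuple(entry["instruments"])
            else:
                payload = entry["label"]
            key = AttributeKey(kind, payload)
            attributes[key] = {
                SetLabel(s): int(n) for s, n in entry["counts"].items() if n
            }
            if entry["absent_in"]:
                absent[key] = frozenset(SetLabel(s) for s in entry["absent_in"])
        totals = {
            SetLabel(s): SetTotals(
                surgeries=t["surgeries"],
                frames=t["frames"],
                mean_duration=t["mean_duration"],
            )
            for s, t in data["totals"].items()
        }
        return cls(
            dataset=data["dataset"],
            semantics=data["semantics"],
            audited_sets=audited,
            attributes=attributes,
            absent_in=absent,
            totals=totals,
            kinds_available=frozenset(
                AttributeKind(k) for k in data["kinds_available"]
            ),
            split=split,
            schema_version=data.get("schema_version", SCHEMA_VERSION),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "AuditReport":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        return cls.from_dict(json.loads(text))


def summarize_unrepresented(report: AuditReport) -> dict[str, dict[SetLabel, int | None]]:
    """Table-style matrix of unrepresented-attribute counts per kind and set."""
    return report.summary()


def audit(
    surgeries: Iterable[Surgery],
    split: SplitAssignment,
    config: DatasetConfig,
    semantics: str = "exact",
) -> AuditReport:
    """Aggregate every attribute family and flag unrepresented attributes."""
    surgeries = sorted_surgeries(list(surgeries))
    counts = compute_attribute_counts(surgeries, split, config, semantics=semantics)
    flags = find_unrepresented(counts, split)
    kinds: set[AttributeKind] = set()
    if any(s.has_phases for s in surgeries):
        kinds |= {AttributeKind.PHASE, AttributeKind.TRANSITION}
    if any(s.has_instruments for s in surgeries):
        kinds |= {AttributeKind.INSTRUMENT, AttributeKind.COMBINATION}
    return AuditReport(
        dataset=config.name,
        semantics=semantics,
        audited_sets=split.nonempty_sets(),
        attributes=counts,
        absent_in=flags,
        totals=per_set_totals(surgeries, split),
        kinds_available=frozenset(kinds),
        split=split,
    )


# ---------------------------------------------------------------------------
# Re-assignment


@dataclass
class ReassignResult:
    """Outcome of a (pure) re-assignment of surgeries to sets."""

    split: SplitAssignment
    sizes_before: dict[SetLabel, int]
    sizes_after: dict[SetLabel, int]
    warnings: list[str] = field(default_factory=list)
    report_before: AuditReport | None = None
    report_after: AuditReport | None = None
    newly_covered: list[tuple[AttributeKey, SetLabel]] = field(default_factory=list)
    newly_lost: list[tuple[AttributeKey, SetLabel]] = field(default_factory=list)

    def summary_diff(self) -> dict[str, dict[SetLabel, tuple[int | None, int | None]]]:
        if self.report_before is None or self.report_after is None:
            raise ValueError("re-assignment was run without surgeries; no reports")
        before = self.report_before.summary()
        after = self.report_after.summary()
        out: dict[str, dict[SetLabel, tuple[int | None, int | None]]] = {}
        for row in SUMMARY_ROWS:
            sets = set(before.get(row, {})) | set(after.get(row, {}))
            out[row] = {
                s: (before.get(row, {}).get(s), after.get(row, {}).get(s))
                for s in sorted(sets, key=lambda x: x.value)
            }
        return out


def reassign(
    split: SplitAssignment,
    moves: Sequence[tuple[str, SetLabel | str]],
    surgeries: Sequence[Surgery] | None = None,
    config: DatasetConfig | None = None,
    semantics: str = "exact",
) -> ReassignResult:
    """Apply surgery->set moves, leaving the input split untouched.

    When ``surgeries`` and ``config`` are given, full audits are run before
    and after and the diff lists attributes whose flags were fixed
    (``newly_covered``) or introduced (``newly_lost``).
    """
    assignment = dict(split.assignment)
    warnings: list[str] = []
    for sid, target in moves:
        sid = str(sid)
        target = SetLabel(target) if not isinstance(target, SetLabel) else target
        if sid not in assignment:
            raise KeyError(f"unknown surgery id {sid!r} in move list")
        if assignment[sid] is target:
            warnings.append(f"surgery {sid!r} is already in {target.value!r}; no-op")
            continue
        assignment[sid] = target
    new_split = SplitAssignment(assignment)
    result = ReassignResult(
        split=new_split,
        sizes_before=split.sizes(),
        sizes_after=new_split.sizes(),
        warnings=warnings,
    )
    if surgeries is not None:
        if config is None:
            raise ValueError("config is required to diff audits")
        result.report_before = audit(surgeries, split, config, semantics=semantics)
        result.report_after = audit(surgeries, new_split, config, semantics=semantics)
        before_flags = result.report_before.flag_pairs()
        after_flags = result.report_after.flag_pairs()
        result.newly_covered = sorted(
            before_flags - after_flags, key=lambda p: (p[0]._sort_key(), p[1].value)
        )
        result.newly_lost = sorted(
            after_flags - before_flags, key=lambda p: (p[0]._sort_key(), p[1].value)
        )
    return result


# ---------------------------------------------------------------------------
# Greedy improvement


@dataclass
class GreedyResult:
    split: SplitAssignment
    objective_initial: float
    objective_final: float
    trace: list[dict] = field(default_factory=list)


def _objective_from_counters(
    set_counters: Mapping[SetLabel, Counter],
    audited_sets: Sequence[SetLabel],
    global_support: Mapping[AttributeKey, int],
    weights: Mapping[AttributeKind, float],
) -> float:
    obj = 0.0
    for key, total in global_support.items():
        if total == 0:
            continue
        w = weights[key.kind]
        for s in audited_sets:
            if set_counters[s].get(key, 0) == 0:
                obj += w
    return obj


def greedy_improve(
    surgeries: Sequence[Surgery],
    split: SplitAssignment,
    config: DatasetConfig,
    semantics: str = "exact",
    weights: Mapping[AttributeKind, float] | None = None,
    keep_set_sizes: bool = True,
    max_iter: int = 100,
    seed: int | None = None,
) -> GreedyResult:
    """Hill-climb over single swaps (or moves) to reduce unrepresented flags.

    Candidates are enumerated in lexicographic surgery-id order and a swap is
    accepted only when the objective strictly decreases (first improvement);
    ties keep the incumbent.  The default path is deterministic; a seed only
    shuffles the candidate enumeration order.  The result never has a higher
    objective than the input split.
    """
    w = dict.fromkeys(AttributeKind, 1.0)
    if weights:
        w.update(weights)
    surgeries = sorted_surgeries(list(surgeries))
    inventories = {
        s.surgery_id: surgery_attribute_counts(s, config, semantics=semantics)
        for s in surgeries
    }
    global_support: Counter = Counter()
    for inv in inventories.values():
        global_support.update(inv)

    assignment = dict(split.assignment)
    audited_sets = split.nonempty_sets()

    def counters_of(asg: Mapping[str, SetLabel]) -> dict[SetLabel, Counter]:
        counters: dict[SetLabel, Counter] = {s: Counter() for s in SetLabel}
        for sid, label in asg.items():
            if sid in inventories:
                counters[label].update(inventories[sid])
        return counters

    def objective(asg: Mapping[str, SetLabel]) -> float:
        return _objective_from_counters(
            counters_of(asg), audited_sets, global_support, w
        )

    current_obj = objective(assignment)
    initial_obj = current_obj
    trace: list[dict] = []
    rng = random.Random(seed) if seed is not None else None

    ids = sorted(assignment)
    for _ in range(max_iter):
        if current_obj == 0:
            break
        candidates: list[list[tuple[str, SetLabel]]] = []
        # swaps between every ordered pair of distinct surgeries across sets
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if assignment[a] is not assignment[b]:
                    candidates.append(
                        [(a, assignment[b]), (b, assignment[a])]
                    )
        if not keep_set_sizes:
            for a in ids:
                for target in audited_sets:
                    if assignment[a] is not target:
                        candidates.append([(a, target)])
        if rng is not None:
            rng.shuffle(candidates)
        improved = False
        for moves in candidates:
            trial = dict(assignment)
            for sid, target in moves:
                trial[sid] = target
            obj = objective(trial)
            if obj < current_obj:
                assignment = trial
                trace.append(
                    {
                        "moves": [(sid, t.value) for sid, t in moves],
                        "objective": obj,
                    }
                )
                current_obj = obj
                improved = True
                break
        if not improved:
            break

    return GreedyResult(
        split=SplitAssignment(assignment),
        objective_initial=initial_obj,
        objective_final=current_obj,
        trace=trace,
    )
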