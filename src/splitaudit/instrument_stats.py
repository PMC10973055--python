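"""Instrument-level attributes: individual occurrence, co-occurrence, idle.

Every instrument-annotated frame falls into exactly one of three classes:
idle (no instrument visible), singleton (one instrument), or a combination
(two or more).  Combinations use exact-set semantics by default: a frame
showing {A, B, C} counts toward the {A, B, C} node only.  A ``subset``
semantics switch additionally credits every contained pair/triple/...,
for comparison against superset-style counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from itertools import combinations as iter_combinations
from typing import Iterable, Sequence

import pandas as pd

from splitaudit.config import DatasetConfig, SetLabel, SplitAssignment, Surgery

__all__ = [
    "FrameClass",
    "Combination",
    "InstrumentCounts",
    "CombinationCounts",
    "classify_frame",
    "aggregate_instrument_counts",
    "aggregate_combination_counts",
    "cooccurrence_share",
    "combination_label",
]

#: Canonical key of a combination: sorted tuple of instrument indices.
Combination = tuple[int, ...]


class FrameClass(str, Enum):
    IDLE = "idle"
    SINGLETON = "singleton"
    COMBINATION = "combination"


def classify_frame(vector: Sequence[int]) -> tuple[FrameClass, Combination]:
    """Classify one 0/1 vector by its full visible-instrument set.

    Returns the class and the sorted tuple of set bit positions (empty for
    idle, length 1 for singletons).
    """
    visible = tuple(i for i, bit in enumerate(vector) if bit)
    if not visible:
        return FrameClass.IDLE, visible
    if len(visible) == 1:
        return FrameClass.SINGLETON, visible
    return FrameClass.COMBINATION, visible


def combination_label(combo: Combination, config: DatasetConfig) -> str:
    """Human-readable '+'-joined label of a combination."""
    return "+".join(config.instruments[i] for i in combo)


@dataclass
class InstrumentCounts:
    """Per-(instrument, set) visible-frame counts and per-set idle frames."""

    frames: dict[tuple[str, SetLabel], int]
    idle: dict[SetLabel, int]
    annotated_frames: dict[SetLabel, int]
    instruments: tuple[str, ...]

    def frame_count(self, instrument: str, set_label: SetLabel) -> int:
        return self.frames.get((instrument, set_label), 0)

    def total(self, instrument: str) -> int:
        return sum(self.frames.get((instrument, s), 0) for s in SetLabel)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"instrument": i, "set": s.value, "frames": c}
            for (i, s), c in sorted(
                self.frames.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
            )
        ]
        return pd.DataFrame(rows, columns=["instrument", "set", "frames"])


@dataclass
class CombinationCounts:
    """Exact-set (or subset) combination counts, with singletons and idle.

    Under exact-set semantics the three families partition the annotated
    frames of each set; under subset semantics combination counts overlap
    and no partition identity holds.
    """

    combinations: dict[tuple[Combination, SetLabel], int]
    singletons: dict[tuple[int, SetLabel], int]
    idle: dict[SetLabel, int]
    semantics: str = "exact"

    def count(self, combo: Combination, set_label: SetLabel) -> int:
        return self.combinations.get((tuple(sorted(combo)), set_label), 0)

    def singleton_count(self, instrument_index: int, set_label: SetLabel) -> int:
        return self.singletons.get((instrument_index, set_label), 0)

    def observed_combinations(self) -> list[Combination]:
        return sorted({c for c, _ in self.combinations})

    def total(self, combo: Combination) -> int:
        key = tuple(sorted(combo))
        return sum(self.combinations.get((key, s), 0) for s in SetLabel)

    def to_frame(self, config: DatasetConfig) -> pd.DataFrame:
        rows = [
            {"combination": combination_label(c, config), "set": s.value, "frames": n}
            for (c, s), n in sorted(
                self.combinations.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
            )
        ]
        return pd.DataFrame(rows, columns=["combination", "set", "frames"])


def _instrument_surgeries(
    surgeries: Iterable[Surgery], split: SplitAssignment
) -> list[tuple[Surgery, SetLabel]]:
    out = []
    for s in surgeries:
        if not s.has_instruments:
            continue
        out.append((s, split.set_of(s.surgery_id)))
    return out


def aggregate_instrument_counts(
    surgeries: Iterable[Surgery], split: SplitAssignment, config: DatasetConfig
) -> InstrumentCounts:
    """Count frames each instrument is visible, regardless of co-visibility."""
    frames: Counter = Counter()
    idle: Counter = Counter()
    annotated: Counter = Counter()
    for s, set_label in _instrument_surgeries(surgeries, split):
        assert s.instruments is not None
        annotated[set_label] += len(s.instruments)
        for vec in s.instruments:
            any_visible = False
            for i, bit in enumerate(vec):
                if bit:
                    frames[(config.instruments[i], set_label)] += 1
                    any_visible = True
            if not any_visible:
                idle[set_label] += 1
    return InstrumentCounts(
        frames=dict(frames),
        idle={label: idle.get(label, 0) for label in SetLabel},
        annotated_frames={label: annotated.get(label, 0) for label in SetLabel},
        instruments=config.instruments,
    )


def aggregate_combination_counts(
    surgeries: Iterable[Surgery],
    split: SplitAssignment,
    config: DatasetConfig,
    semantics: str = "exact",
) -> CombinationCounts:
    """Count multi-instrument frames per combination per set.

    ``semantics="exact"`` assigns each frame to its full visible set only;
    ``semantics="subset"`` additionally counts the frame toward every
    contained sub-combination of size >= 2.  Combinations never observed
    anywhere are absent from the result.
    """
    if semantics not in ("exact", "subset"):
        raise ValueError(f"unknown combination semantics {semantics!r}")
    combos: Counter = Counter()
    singles: Counter = Counter()
    idle: Counter = Counter()
    for s, set_label in _instrument_surgeries(surgeries, split):
        assert s.instruments is not None
        for vec in s.instruments:
            cls, visible = classify_frame(vec)
            if cls is FrameClass.IDLE:
                idle[set_label] += 1
            elif cls is FrameClass.SINGLETON:
                singles[(visible[0], set_label)] += 1
            else:
                combos[(visible, set_label)] += 1
                if semantics == "subset":
                    for k in range(2, len(visible)):
                        for sub in iter_combinations(visible, k):
                            combos[(sub, set_label)] += 1
    return CombinationCounts(
        combinations=dict(combos),
        singletons=dict(singles),
        idle={label: idle.get(label, 0) for label in SetLabel},
        semantics=semantics,
    )


def cooccurrence_share(
    combo: Combination,
    instrument_counts: InstrumentCounts,
    combination_counts: CombinationCounts,
) -> dict[int, float]:
    """Fraction of each involved instrument's frames spent in ``combo``.

    share(i) = count(combo) / frame_count(i), totalled over sets; always
    in [0, 1] under exact-set semantics.
    """
    key = tuple(sorted(combo))
    total = combination_counts.total(key)
    if total == 0:
        raise ValueError(f"combination {key} was never observed")
    shares: dict[int, float] = {}
    for i in key:
        instr = instrument_counts.instruments[i]
        denom = instrument_counts.total(instr)
        if denom == 0:
            raise RuntimeError(
                f"instrument {instr!r} participates in an observed combination "
                "but has zero frames — inconsistent counts"
            )
        shares[i] = total / denom
    return shares
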