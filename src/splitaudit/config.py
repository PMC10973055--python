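"""Core domain types: dataset configuration, split assignment, surgeries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

#: Virtual endpoints of every surgery's phase sequence.  They let the audit
#: reason about *how* surgeries begin and end (e.g. a skipped first phase
#: shows up as an unusual start transition).
START = "START"
END = "END"

_SENTINELS = frozenset({START, END})


class SetLabel(str, Enum):
    """The three split sets.  VAL may be empty (40/-/40-style splits)."""

    TRAIN = "train"
    VAL = "val"
    TEST = "test"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_set_label(value: "SetLabel | str") -> SetLabel:
    if isinstance(value, SetLabel):
        return value
    return SetLabel(str(value).lower())


@dataclass(frozen=True)
class SplitAssignment:
    """Partition of surgeries into train/val/test sets.

    Every surgery belongs to exactly one set; TRAIN and TEST must be
    non-empty, VAL may be empty.
    """

    assignment: Mapping[str, SetLabel]

    def __post_init__(self) -> None:
        clean = {str(k): _as_set_label(v) for k, v in self.assignment.items()}
        object.__setattr__(self, "assignment", dict(clean))
        for required in (SetLabel.TRAIN, SetLabel.TEST):
            if not any(v is required for v in clean.values()):
                raise ValueError(f"split has no surgeries in {required.value!r}")

    @classmethod
    def from_lists(
        cls,
        train: Iterable[str],
        val: Iterable[str] = (),
        test: Iterable[str] = (),
    ) -> "SplitAssignment":
        mapping: dict[str, SetLabel] = {}
        for label, ids in (
            (SetLabel.TRAIN, train),
            (SetLabel.VAL, val),
            (SetLabel.TEST, test),
        ):
            for sid in ids:
                sid = str(sid)
                if sid in mapping:
                    raise ValueError(f"surgery {sid!r} assigned to more than one set")
                mapping[sid] = label
        return cls(mapping)

    def set_of(self, surgery_id: str) -> SetLabel:
        try:
            return self.assignment[surgery_id]
        except KeyError:
            raise KeyError(f"surgery {surgery_id!r} not in split") from None

    def members(self, label: SetLabel) -> tuple[str, ...]:
        """Surgery ids of one set, in sorted order."""
        label = _as_set_label(label)
        return tuple(sorted(s for s, v in self.assignment.items() if v is label))

    @property
    def surgery_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.assignment))

    def sizes(self) -> dict[SetLabel, int]:
        out = {label: 0 for label in SetLabel}
        for v in self.assignment.values():
            out[v] += 1
        return out

    def nonempty_sets(self) -> tuple[SetLabel, ...]:
        """Sets that actually contain surgeries, in TRAIN/VAL/TEST order."""
        sizes = self.sizes()
        return tuple(label for label in SetLabel if sizes[label] > 0)

    def to_lists(self) -> dict[str, list[str]]:
        return {label.value: list(self.members(label)) for label in SetLabel}

    def __contains__(self, surgery_id: str) -> bool:
        return surgery_id in self.assignment

    def __len__(self) -> int:
        return len(self.assignment)


@dataclass(frozen=True)
class DatasetConfig:
    """Dataset vocabulary, frame rates, and split.

    ``phases`` is the conceptual order of phases (index 0 first).  The
    ``phase_fps``/``instrument_fps`` pair defines the downsampling stride used
    to align phase annotations with the (sparser) instrument annotations.
    ``idle_phase_label`` names a phase to drop at load time (e.g. a filler
    step separating every pair of real steps), yielding a linear workflow.
    """

    name: str
    phases: tuple[str, ...]
    instruments: tuple[str, ...]
    phase_fps: int = 1
    instrument_fps: int = 1
    idle_phase_label: str | None = None
    split: SplitAssignment | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "instruments", tuple(self.instruments))
        if len(set(self.phases)) != len(self.phases):
            raise ValueError("phase labels must be unique")
        if len(set(self.instruments)) != len(self.instruments):
            raise ValueError("instrument labels must be unique")
        overlap = _SENTINELS & set(self.phases)
        if overlap:
            raise ValueError(f"phase labels collide with sentinels: {sorted(overlap)}")
        if self.instrument_fps < 1:
            raise ValueError("instrument_fps must be >= 1")
        if self.phase_fps < self.instrument_fps:
            raise ValueError("phase_fps must be >= instrument_fps")
        if self.phase_fps % self.instrument_fps != 0:
            raise ValueError(
                f"phase_fps ({self.phase_fps}) must be divisible by "
                f"instrument_fps ({self.instrument_fps})"
            )
        if self.idle_phase_label is not None and self.idle_phase_label not in self.phases:
            raise ValueError(
                f"idle_phase_label {self.idle_phase_label!r} not in phase vocabulary"
            )

    @property
    def stride(self) -> int:
        """Downsampling stride from phase rate to the common instrument rate."""
        return self.phase_fps // self.instrument_fps

    def phase_order(self, phase: str) -> int:
        """Conceptual-order index of a phase."""
        try:
            return self.phases.index(phase)
        except ValueError:
            raise KeyError(f"unknown phase {phase!r}") from None

    @property
    def analysis_phases(self) -> tuple[str, ...]:
        """Phases that survive idle exclusion."""
        if self.idle_phase_label is None:
            return self.phases
        return tuple(p for p in self.phases if p != self.idle_phase_label)

    def instrument_index(self, instrument: str) -> int:
        try:
            return self.instruments.index(instrument)
        except ValueError:
            raise KeyError(f"unknown instrument {instrument!r}") from None

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        data: dict = {
            "name": self.name,
            "phases": list(self.phases),
            "instruments": list(self.instruments),
            "phase_fps": self.phase_fps,
            "instrument_fps": self.instrument_fps,
            "idle_phase_label": self.idle_phase_label,
        }
        if self.split is not None:
            data["split"] = self.split.to_lists()
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "DatasetConfig":
        split = None
        if data.get("split") is not None:
            s = data["split"]
            split = SplitAssignment.from_lists(
                s.get("train", ()), s.get("val", ()), s.get("test", ())
            )
        return cls(
            name=data["name"],
            phases=tuple(data.get("phases", ())),
            instruments=tuple(data.get("instruments", ())),
            phase_fps=int(data.get("phase_fps", 1)),
            instrument_fps=int(data.get("instrument_fps", 1)),
            idle_phase_label=data.get("idle_phase_label"),
            split=split,
        )

    @classmethod
    def from_file(cls, path: "str | Path") -> "DatasetConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: "str | Path") -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class FrameRecord:
    """One frame of a surgery at the common (post-downsampling) rate.

    ``frame_index`` is 0-based and expressed in source-video frame units, so
    at stride 25 the records sit at indices 0, 25, 50, ...  Either annotation
    stream may be absent (``None``) for datasets that ship only phases or
    only instruments.
    """

    frame_index: int
    phase: str | None
    instruments: tuple[int, ...] | None


@dataclass(frozen=True)
class Surgery:
    """One procedure's aligned frame-wise annotations.

    ``phases`` and ``instruments`` are parallel to ``frame_indices``; each
    instrument entry is a 0/1 tuple in config instrument order.  Duration is
    the number of frames at the common rate.
    """

    surgery_id: str
    frame_indices: tuple[int, ...]
    phases: tuple[str, ...] | None = None
    instruments: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.frame_indices)
        if n == 0:
            raise ValueError(f"surgery {self.surgery_id!r} has no frames")
        if any(b <= a for a, b in zip(self.frame_indices, self.frame_indices[1:])):
            raise ValueError(
                f"surgery {self.surgery_id!r}: frame indices not strictly increasing"
            )
        if self.phases is not None and len(self.phases) != n:
            raise ValueError(f"surgery {self.surgery_id!r}: phase/index length mismatch")
        if self.instruments is not None:
            if len(self.instruments) != n:
                raise ValueError(
                    f"surgery {self.surgery_id!r}: instrument/index length mismatch"
                )
            widths = {len(v) for v in self.instruments}
            if len(widths) > 1:
                raise ValueError(
                    f"surgery {self.surgery_id!r}: ragged instrument vectors"
                )
        if self.phases is None and self.instruments is None:
            raise ValueError(f"surgery {self.surgery_id!r} has no annotations at all")

    @property
    def duration(self) -> int:
        """Number of frames at the common rate."""
        return len(self.frame_indices)

    @property
    def has_phases(self) -> bool:
        return self.phases is not None

    @property
    def has_instruments(self) -> bool:
        return self.instruments is not None

    @property
    def frames(self) -> Iterator[FrameRecord]:
        for i, idx in enumerate(self.frame_indices):
            yield FrameRecord(
                frame_index=idx,
                phase=self.phases[i] if self.phases is not None else None,
                instruments=self.instruments[i] if self.instruments is not None else None,
            )


def sorted_surgeries(surgeries: Sequence[Surgery]) -> list[Surgery]:
    """Surgeries in deterministic (lexicographic id) order."""
    return sorted(surgeries, key=lambda s: s.surgery_id)
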